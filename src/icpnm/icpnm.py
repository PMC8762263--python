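"""The IC_PNM score: an information component with an informative prior.

Bayes' rule rewrites the information component as
IC = log2 P(A|D) / P(A).  IC_PNM supplies the two probabilities from
independent models instead of raw report frequencies:

* P(A_j | D_i) — the pharmacological network model's probability that the
  pair is a true association (:mod:`icpnm.pnm`);
* P(A_j) — the propensity-score-adjusted marginal ADE probability
  (:mod:`icpnm.psadjust`).

The signalling lower bound multiplies the probability ratio by a
count-dependent penalty exp(-2 / sqrt(c_ij + 1)), so

    IC_PNM_05 = IC_PNM - 2 / (sqrt(c_ij + 1) * ln 2),

which converges to the point estimate as evidence accumulates.  A pair is a
signal when IC_PNM_05 >= 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from .srs_data import ContingencyTable, DataError
from . import pnm as _pnm

logger = logging.getLogger(__name__)

SIGNAL_THRESHOLD = 2.0
_CLIP = 1e-12


def default_penalty(c_ij: float) -> float:
    """Evidence penalty exp(-2 / sqrt(c_ij + 1)) multiplying the ratio."""
    return math.exp(-2.0 / math.sqrt(c_ij + 1.0))


def _check_prob(p: float, name: str) -> float:
    if not 0.0 < p < 1.0:
        if 0.0 <= p <= 1.0:  # allow serialized endpoints, nudged inward
            return min(max(p, _CLIP), 1.0 - _CLIP)
        raise DataError(f"{name} must lie in (0, 1), got {p}")
    return p


def icpnm_point(p_a_given_d: float, p_a: float) -> float:
    """IC_PNM = log2( P(A|D) / P(A) )."""
    p1 = _check_prob(p_a_given_d, "p_a_given_d")
    p0 = _check_prob(p_a, "p_a")
    return math.log2(p1 / p0)


def icpnm_lower(p_a_given_d: float, p_a: float, c_ij: int,
                penalty: Callable[[float], float] = default_penalty) -> float:
    """Signalling lower bound log2( P(A|D)/P(A) * penalty(c_ij) )."""
    if c_ij < 0:
        raise DataError(f"c_ij must be >= 0, got {c_ij}")
    return icpnm_point(p_a_given_d, p_a) + math.log2(penalty(float(c_ij)))


@dataclass(frozen=True)
class ICPNMScore:
    """IC_PNM components and decision for one drug-ADE pair."""

    drug: str
    ade: str
    p_a_given_d: float
    p_a: float
    c_ij: int
    point: float
    lower: float
    is_signal: bool

    def __post_init__(self):
        if self.lower > self.point + 1e-12:
            raise ValueError("lower bound exceeds point estimate")


def score_pair(drug, ade, p_a_given_d: float, p_a: float, c_ij: int,
               penalty: Callable[[float], float] = default_penalty,
               threshold: float = SIGNAL_THRESHOLD) -> ICPNMScore:
    point = icpnm_point(p_a_given_d, p_a)
    lower = icpnm_lower(p_a_given_d, p_a, c_ij, penalty=penalty)
    return ICPNMScore(drug, ade, p_a_given_d, p_a, int(c_ij), point, lower,
                      lower >= threshold)


def score_icpnm(
    pairs: Iterable,
    pnm_model: "_pnm.PNMModel",
    features: Mapping,          # (drug, ade) -> FeatureVector
    p_a: Mapping,               # (drug, ade) or ade -> adjusted P(A_j)
    contingencies: Mapping,     # (drug, ade) -> ContingencyTable
    penalty: Callable[[float], float] = default_penalty,
    threshold: float = SIGNAL_THRESHOLD,
) -> dict:
    """Assemble IC_PNM scores for many pairs from precomputed components.

    ``p_a`` may be keyed by pair or by ADE alone (the adjusted marginal is a
    per-(drug, ADE) regression, but callers sharing one P(A) per ADE are
    supported).  Pairs with a missing component are skipped with a warning.
    """
    out: dict = {}
    skipped = 0
    for pair in pairs:
        drug, ade = pair
        fv = features.get(pair)
        pa = p_a.get(pair, p_a.get(ade))
        t = contingencies.get(pair)
        if fv is None or pa is None or t is None:
            skipped += 1
            continue
        p1 = _pnm.predict_prob(pnm_model, fv)
        c_ij = t.c_ij if isinstance(t, ContingencyTable) else int(t)
        out[pair] = score_pair(drug, ade, p1, pa, c_ij,
                               penalty=penalty, threshold=threshold)
    if skipped:
        logger.warning("score_icpnm: skipped %d pair(s) with missing components",
                       skipped)
    return out
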