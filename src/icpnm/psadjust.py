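"""Propensity-score confounding adjustment for the marginal ADE probability.

Co-medication is the dominant measurable confounder in spontaneous reports:
drugs prescribed together make a report's drug exposure predictable from the
rest of its medication list.  The adjustment works in three steps:

1. principal components of the (report x drug) co-medication matrix, with
   the index drug's column excluded, summarize each report's prescription
   profile;
2. a logistic regression of index-drug exposure on those components gives
   each report a propensity score PS_k = P(Drug = 1 | PC scores);
3. a logistic outcome regression logit P(ADE=1) = b0 + b1*Drug + b2*PS
   estimates the drug effect with the prescription-profile confounding
   absorbed by PS.

The adjusted marginal ADE probability P(A_j) is an average of per-report
sigmoids of the fitted linear predictor.  Which offsets enter the predictor
is configurable:

* the default, ``mode="unexposed"``, averages sigmoid(b0 + b2*PS_k) — the
  standardized (g-computation) marginal with the index-drug exposure set to
  0, i.e. the ADE probability expected were the drug-ADE association absent,
  with the co-medication confounder distribution kept;
* ``mode="literal"`` sums every offset unconditionally,
  sigmoid(b_off + b0 + b1 + b2*PS_k) with b_off = logit(c_+j/c_++) the
  frequency offset — kept for comparison, but it adds the drug's own fitted
  effect b1 (and a second baseline) into the no-association probability,
  which suppresses exactly the pairs with genuine effects (methods note).

The unadjusted version is sigmoid(logit(c_+j/c_++)) = c_+j/c_++.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .srs_data import DataError, ReportDatabase
from .pnm import LogitFit, _fit_logit

logger = logging.getLogger(__name__)

_PCLIP = 1e-12  # keep probabilities strictly inside (0, 1)


def _newton_logit(X: np.ndarray, y: np.ndarray, maxiter: int = 40,
                  tol: float = 1e-9) -> LogitFit | None:
    """Plain Newton/IRLS logistic MLE tuned for the large PS regressions.

    Returns None when the iteration diverges or the Hessian degenerates
    (separation), in which case the caller falls back to the ridge-guarded
    generic fit.
    """
    Xc = np.column_stack([np.ones(y.shape[0]), X])
    beta = np.zeros(Xc.shape[1])
    ybar = float(np.mean(y))
    if not 0.0 < ybar < 1.0:
        return None
    beta[0] = math.log(ybar / (1.0 - ybar))  # rare outcomes: start at the base rate

    def nll(b):
        eta = Xc @ b
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    cur = nll(beta)
    H = None
    for _ in range(maxiter):
        p = special.expit(Xc @ beta)
        g = Xc.T @ (p - y)
        w = p * (1.0 - p)
        H = (Xc * w[:, None]).T @ Xc
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        # step-halving keeps the iteration stable for rare outcomes
        lam, nxt = 1.0, None
        for _ in range(12):
            cand = beta - lam * step
            val = nll(cand)
            if math.isfinite(val) and val <= cur + 1e-12:
                nxt, cur = cand, val
                break
            lam *= 0.5
        if nxt is None:
            return None
        moved = np.max(np.abs(beta - nxt))
        beta = nxt
        # covariates on very different scales (PS spans ~1e-2) make large
        # coefficients legitimate; only true divergence is rejected
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e8:
            return None
        if moved < tol:
            break
    else:
        return None
    p = special.expit(Xc @ beta)
    w = p * (1.0 - p)
    H = (Xc * w[:, None]).T @ Xc
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return LogitFit(beta, bse, -cur, False)


def _logit_fast(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> LogitFit:
    fit = _newton_logit(X, y)
    return fit if fit is not None else _fit_logit(X, y, ridge=ridge)


@dataclass
class ExposureMatrix:
    """Binary report-by-drug co-medication matrix with aligned identifiers."""

    matrix: np.ndarray  # (n_reports, n_drugs) 0/1, dtype int8
    report_ids: list
    drug_columns: list  # lexicographically ordered, index drug excluded
    excluded_drug: str | None = None

    @property
    def shape(self):
        return self.matrix.shape


def build_exposure_matrix(db: ReportDatabase,
                          exclude_drug=None) -> ExposureMatrix:
    """One row per report, one 0/1 column per drug except ``exclude_drug``.

    Column order is lexicographic, so the layout is stable across runs.
    """
    cols = sorted(d for d in db.drugs if d != exclude_drug)
    col_of = {d: j for j, d in enumerate(cols)}
    m = np.zeros((db.n_reports, len(cols)), dtype=np.int8)
    for i, rep in enumerate(db.reports):
        for d in rep.drugs:
            j = col_of.get(d)
            if j is not None:
                m[i, j] = 1
    return ExposureMatrix(m, [r.report_id for r in db.reports], cols,
                          excluded_drug=exclude_drug)


@dataclass
class PSModel:
    """Principal-component loadings and (once fitted) the PS logistic model."""

    loadings: np.ndarray            # (n_drugs, n_components), orthonormal columns
    mean: np.ndarray                # per-column mean used for centering
    explained_variance_ratio: np.ndarray
    drug_columns: list
    n_components: int
    gamma: np.ndarray | None = None     # PS-regression coefficients, intercept first
    gamma_bse: np.ndarray | None = None
    ps: np.ndarray | None = None        # per-report propensity scores in (0, 1)
    drug: str | None = None             # index drug of the fitted PS

    def scores(self, m: ExposureMatrix, exclude_drug=None) -> np.ndarray:
        """PC scores of the centered matrix; optionally project out one drug.

        Excluding a drug's column from an already-computed decomposition is
        exact score arithmetic: the column's centered contribution is simply
        subtracted, which equals recomputing scores on the matrix without it.
        The base projection is cached per exposure matrix, since the PS of
        every drug reuses it.
        """
        if m.drug_columns != self.drug_columns:
            raise DataError("exposure matrix columns do not match PC loadings")
        cache = getattr(self, "_score_cache", None)
        if cache is None or cache[0] is not m.matrix:
            base = (m.matrix.astype(np.float64) - self.mean) @ self.loadings
            cache = (m.matrix, base)
            object.__setattr__(self, "_score_cache", cache)
        s = cache[1]
        if exclude_drug is not None and exclude_drug in self.drug_columns:
            j = self.drug_columns.index(exclude_drug)
            centered_j = m.matrix[:, j].astype(np.float64) - self.mean[j]
            s = s - np.outer(centered_j, self.loadings[j, :])
        else:
            s = s.copy()
        return s


def compute_pcs(m: ExposureMatrix, n: int | None = None,
                variance_target: float = 0.8, max_components: int = 20) -> PSModel:
    """Principal components of the centered co-medication matrix.

    Computed from the eigendecomposition of the column covariance (exact and
    deterministic).  When ``n`` is omitted, the smallest number of components
    explaining ``variance_target`` of the variance is used, capped at
    ``max_components``.  Sign convention: each component's largest-magnitude
    loading is positive.
    """
    X = m.matrix.astype(np.float64)
    rows, cols = X.shape
    limit = min(rows - 1, cols)
    if n is not None and not 1 <= n <= limit:
        raise DataError(f"n_components={n} outside [1, {limit}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / max(rows - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    if n is None:
        n = int(np.searchsorted(np.cumsum(ratio), variance_target) + 1)
        n = max(1, min(n, max_components, limit))
    load = evecs[:, :n].copy()
    for j in range(n):
        k = int(np.argmax(np.abs(load[:, j])))
        if load[k, j] < 0:
            load[:, j] = -load[:, j]
    return PSModel(loadings=load, mean=mean,
                   explained_variance_ratio=ratio[:n],
                   drug_columns=list(m.drug_columns), n_components=n)


def fit_ps(db: ReportDatabase, drug, pcs: PSModel, m: ExposureMatrix,
           ridge: float = 1e-6) -> PSModel:
    """Propensity scores: logistic regression of drug exposure on PC scores.

    Returns a copy of ``pcs`` carrying gamma (intercept first) and per-report
    scores PS_k; the index drug's column is projected out of the PC scores so
    a drug never predicts its own exposure.  Fit is ridge-guarded against
    separation (e.g. deterministic co-prescription).
    """
    pos = db.drug_index.get(drug, set())
    y = np.zeros(db.n_reports)
    y[list(pos)] = 1.0
    if y.min() == y.max():
        raise DataError(f"no exposure variation for drug {drug!r}")
    s = pcs.scores(m, exclude_drug=drug)
    fit = _logit_fast(s, y, ridge=ridge)
    eta = fit.params[0] + s @ fit.params[1:]
    ps = np.clip(special.expit(eta), _PCLIP, 1.0 - _PCLIP)
    return PSModel(loadings=pcs.loadings, mean=pcs.mean,
                   explained_variance_ratio=pcs.explained_variance_ratio,
                   drug_columns=pcs.drug_columns, n_components=pcs.n_components,
                   gamma=fit.params, gamma_bse=fit.bse, ps=ps, drug=drug)


def marginal_ade_prob_freq(c_plus_j: int, c_plus_plus: int) -> float:
    """Unadjusted marginal ADE probability sigmoid(logit(c_+j/c_++)) = c_+j/c_++.

    The logit/sigmoid round trip is kept explicit because the adjusted
    version perturbs the same offset; boundary counts are rejected since the
    offset must be finite.
    """
    if not 0 < c_plus_j < c_plus_plus:
        raise DataError(f"counts must satisfy 0 < c_+j < c_++: "
                        f"({c_plus_j}, {c_plus_plus})")
    rate = c_plus_j / c_plus_plus
    beta = math.log(rate / (1.0 - rate))
    return 1.0 / (1.0 + math.exp(-beta))


@dataclass
class PSAdjustedModel:
    """Fitted PS-adjusted outcome regression and the frequency offset."""

    beta0: float
    beta1: float   # drug-exposure effect on the ADE, PS-adjusted
    beta2: float   # PS coefficient
    beta_offset: float  # logit(c_+j / c_++)
    p_ade_adjusted: float = float("nan")
    bse: np.ndarray | None = None
    ridge_used: bool = False


def fit_ps_adjusted(db: ReportDatabase, drug, ade, ps: np.ndarray,
                    ridge: float = 1e-6,
                    mode: str = "unexposed") -> PSAdjustedModel:
    """Outcome regression logit P(ADE=1) = b0 + b1*Drug + b2*PS per report.

    The returned model also carries the frequency offset logit(c_+j/c_++)
    and the adjusted marginal probability under the requested offset
    ``mode`` ("unexposed" default, or "literal"; see module docstring).
    """
    ade_pos = db.ade_index.get(ade, set())
    if not 0 < len(ade_pos) < db.n_reports:
        raise DataError(f"ADE {ade!r} must occur and be absent in >= 1 report")
    ps = np.asarray(ps, dtype=float)
    if ps.shape[0] != db.n_reports:
        raise DataError("PS vector length does not match report count")
    y = np.zeros(db.n_reports)
    y[list(ade_pos)] = 1.0
    x = np.zeros(db.n_reports)
    x[list(db.drug_index.get(drug, set()))] = 1.0
    X = np.column_stack([x, ps])
    fit = _logit_fast(X, y, ridge=ridge)
    rate = len(ade_pos) / db.n_reports
    model = PSAdjustedModel(beta0=float(fit.params[0]), beta1=float(fit.params[1]),
                            beta2=float(fit.params[2]),
                            beta_offset=math.log(rate / (1.0 - rate)),
                            bse=fit.bse, ridge_used=fit.ridge_used)
    if mode == "unexposed":
        model.p_ade_adjusted = ps_adjusted_ade_prob(
            model, ps, include_exposure=False, include_offset=False)
    elif mode == "literal":
        model.p_ade_adjusted = ps_adjusted_ade_prob(model, ps)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return model


def ps_adjusted_ade_prob(model: PSAdjustedModel, ps: np.ndarray,
                         include_exposure: bool = True,
                         include_offset: bool = True) -> float:
    """Adjusted marginal ADE probability: mean_k sigmoid(offsets + b2 * PS_k).

    With both flags on, every offset is summed unconditionally into each
    report's predictor (frequency offset, b0 and b1); with both off, the
    standardized no-exposure marginal mean_k sigmoid(b0 + b2*PS_k) that the
    pipeline uses by default.  The mean over the K reports — rather
    than an unnormalized sum — makes the result a probability.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise DataError("empty propensity-score vector")
    eta = model.beta0 + model.beta2 * ps
    if include_exposure:
        eta = eta + model.beta1
    if include_offset:
        eta = eta + model.beta_offset
    p = float(np.mean(special.expit(eta)))
    return min(max(p, _PCLIP), 1.0 - _PCLIP)
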