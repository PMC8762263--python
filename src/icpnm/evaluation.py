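"""Score-based evaluation against labeled reference sets.

Implements the standard signal-detection evaluation machinery: ROC AUC via
the Mann-Whitney rank formulation (ties get half credit), Youden's index
J = sensitivity + specificity - 1 maximized over cutoffs, threshold sweeps
(sensitivity / specificity / PPV at fixed cutoffs, predicted positive when
score >= threshold), top-K ranking overlap between methods, and inter-method
score correlation.

Reference pairs a method could not score (e.g. zero-count pairs for PRR) are
excluded from that method's metrics by default, with the coverage fraction
reported; a worst-rank imputation mode is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .srs_data import DataError, ReferenceSet

WORST_RANK = "worst_rank"
EXCLUDE = "exclude"


@dataclass
class EvaluationResult:
    """AUC and Youden summary for one method against one reference set."""

    method: str
    auc: float
    youden_index: float
    youden_sensitivity: float
    youden_specificity: float
    youden_cutoff: float
    n_pos: int
    n_neg: int
    coverage: float = 1.0  # fraction of reference pairs the method scored


@dataclass
class ThresholdSweep:
    """Rows of (threshold, sensitivity, specificity, ppv); ppv NaN if undefined."""

    rows: list  # list of (threshold, sens, spec, ppv)


def _aligned(scores: Mapping, ref: ReferenceSet, missing: str = EXCLUDE):
    """Score/label arrays over the reference pairs, handling unscored pairs."""
    y, s, n_missing = [], [], 0
    finite = [v for v in scores.values() if v is not None and math.isfinite(v)]
    floor = (min(finite) - 1.0) if finite else -1.0
    for d, a, lab in ref.pairs:
        v = scores.get((d, a))
        ok = v is not None and math.isfinite(v)
        if not ok:
            n_missing += 1
            if missing == EXCLUDE:
                continue
            v = floor
        y.append(lab == "positive")
        s.append(float(v))
    y = np.asarray(y, dtype=bool)
    s = np.asarray(s, dtype=float)
    if y.size == 0 or y.all() or not y.any():
        raise DataError("need >= 1 scored positive and negative reference pair")
    coverage = 1.0 - n_missing / len(ref.pairs)
    return s, y, coverage


def roc_auc(scores: Mapping, ref: ReferenceSet, missing: str = EXCLUDE) -> float:
    """AUC by the Mann-Whitney U statistic with midranks (ties count 1/2)."""
    s, y, _ = _aligned(scores, ref, missing)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _confusion(s: np.ndarray, y: np.ndarray, t: float):
    pred = s >= t
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return sens, spec, ppv


def youden(scores: Mapping, ref: ReferenceSet, method: str = "",
           missing: str = EXCLUDE) -> EvaluationResult:
    """Maximize J = sensitivity + specificity - 1 over score cutoffs.

    Candidate cutoffs are the midpoints between adjacent distinct scores plus
    sentinels below/above all scores; ties on J are broken toward higher
    specificity (the larger cutoff).
    """
    s, y, coverage = _aligned(scores, ref, missing)
    uniq = np.unique(s)
    candidates = [uniq[0] - 1.0]
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(uniq[-1] + 1.0)
    best = None
    for t in candidates:
        sens, spec, _ = _confusion(s, y, t)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or \
                (abs(j - best[0]) <= 1e-12 and t > best[1]):
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    auc = roc_auc(scores, ref, missing)
    return EvaluationResult(method=method, auc=auc, youden_index=float(j),
                            youden_sensitivity=float(sens),
                            youden_specificity=float(spec),
                            youden_cutoff=float(t),
                            n_pos=int(y.sum()), n_neg=int((~y).sum()),
                            coverage=coverage)


def threshold_sweep(scores: Mapping, ref: ReferenceSet,
                    thresholds: Sequence, missing: str = EXCLUDE) -> ThresholdSweep:
    """Sensitivity / specificity / PPV at each fixed threshold (score >= t)."""
    s, y, _ = _aligned(scores, ref, missing)
    rows = [(float(t), *_confusion(s, y, float(t))) for t in thresholds]
    return ThresholdSweep(rows)


def topk(scores: Mapping, k: int) -> list:
    """Top-k pairs by descending score; ties broken by (drug, ade) identifiers."""
    items = [(pair, v) for pair, v in scores.items()
             if v is not None and math.isfinite(v)]
    if len(items) < k:
        raise DataError(f"only {len(items)} scored pairs, need k={k}")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return [pair for pair, _ in items[:k]]


def topk_overlap(scores_a: Mapping, scores_b: Mapping, k: int,
                 ref: ReferenceSet | None = None):
    """Overlap of two methods' top-k signal lists.

    Returns (|intersection|, validated) where validated counts, per method,
    how many of its top-k pairs are reference positives (None without a ref).
    """
    top_a = set(topk(scores_a, k))
    top_b = set(topk(scores_b, k))
    overlap = len(top_a & top_b)
    if ref is None:
        return overlap, None
    pos = set(ref.positives)
    return overlap, (len(top_a & pos), len(top_b & pos))


def score_correlation(scores_a: Mapping, scores_b: Mapping,
                      method: str = "pearson") -> float:
    """Pearson or Spearman correlation over the commonly scored pairs."""
    common = [p for p in scores_a
              if p in scores_b
              and scores_a[p] is not None and math.isfinite(scores_a[p])
              and scores_b[p] is not None and math.isfinite(scores_b[p])]
    if len(common) < 3:
        raise DataError("need >= 3 commonly scored pairs")
    a = np.array([scores_a[p] for p in common])
    b = np.array([scores_b[p] for p in common])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("zero variance in scores")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
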