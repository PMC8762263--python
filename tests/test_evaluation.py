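import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from icpnm.evaluation import (WORST_RANK, roc_auc, score_correlation,
                              threshold_sweep, topk, topk_overlap, youden)
from icpnm.srs_data import DataError, ReferenceSet


def _ref(pos, neg):
    return ReferenceSet([(d, a, "positive") for d, a in pos]
                        + [(d, a, "negative") for d, a in neg])


def _scores(pairs_values):
    return {pair: v for pair, v in pairs_values}


PERFECT_REF = _ref([("D1", "A"), ("D2", "A")], [("D3", "A"), ("D4", "A")])
PERFECT_SCORES = _scores([(("D1", "A"), 0.9), (("D2", "A"), 0.8),
                          (("D3", "A"), 0.4), (("D4", "A"), 0.2)])


def brute_force_auc(scores, ref):
    pos = [scores[p] for p in ref.positives if p in scores]
    neg = [scores[p] for p in ref.negatives if p in scores]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc(PERFECT_SCORES, PERFECT_REF) == 1.0

    def test_one_concordant_one_discordant(self):
        ref = _ref([("D1", "A"), ("D3", "A")], [("D2", "A")])
        scores = _scores([(("D1", "A"), 0.9), (("D2", "A"), 0.8),
                          (("D3", "A"), 0.4)])
        assert roc_auc(scores, ref) == 0.5

    def test_all_ties(self):
        scores = {p: 1.0 for p in PERFECT_SCORES}
        assert roc_auc(scores, PERFECT_REF) == 0.5

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            pairs = [(f"D{i}", "A") for i in range(n)]
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            ref = _ref([p for p, l in zip(pairs, labels) if l],
                       [p for p, l in zip(pairs, labels) if not l])
            scores = {p: float(rng.integers(0, 8)) for p in pairs}  # many ties
            assert roc_auc(scores, ref) == pytest.approx(
                brute_force_auc(scores, ref), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc(PERFECT_SCORES, _ref([("D1", "A")], []))

    def test_missing_scores_excluded_with_coverage(self):
        scores = dict(PERFECT_SCORES)
        del scores[("D4", "A")]
        ev = youden(scores, PERFECT_REF)
        assert ev.coverage == pytest.approx(0.75)

    def test_worst_rank_imputation_mode(self):
        scores = dict(PERFECT_SCORES)
        del scores[("D4", "A")]  # a negative: imputing at the floor keeps AUC 1
        assert roc_auc(scores, PERFECT_REF, missing=WORST_RANK) == 1.0


class TestYouden:
    def test_perfect(self):
        ev = youden(PERFECT_SCORES, PERFECT_REF)
        assert ev.youden_index == pytest.approx(1.0)
        assert ev.youden_sensitivity == ev.youden_specificity == 1.0
        assert ev.youden_index == pytest.approx(
            ev.youden_sensitivity + ev.youden_specificity - 1.0)

    def test_all_ties_zero(self):
        scores = {p: 2.0 for p in PERFECT_SCORES}
        assert youden(scores, PERFECT_REF).youden_index == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        pairs = [(f"D{i}", "A") for i in range(30)]
        labels = rng.random(30) < 0.5
        ref = _ref([p for p, l in zip(pairs, labels) if l],
                   [p for p, l in zip(pairs, labels) if not l])
        scores = {p: float(rng.integers(0, 10)) for p in pairs}
        ev = youden(scores, ref)
        best = -2.0
        for t in set(scores.values()) | {-1e9, 1e9}:
            pred = {p: scores[p] >= t for p in pairs}
            tp = sum(pred[p] for p in ref.positives)
            tn = sum(not pred[p] for p in ref.negatives)
            j = tp / len(ref.positives) + tn / len(ref.negatives) - 1.0
            best = max(best, j)
        assert ev.youden_index == pytest.approx(best, abs=1e-12)

    def test_sweep_at_cutoff_reproduces_youden_point(self):
        rng = np.random.default_rng(4)
        pairs = [(f"D{i}", "A") for i in range(40)]
        labels = rng.random(40) < 0.5
        ref = _ref([p for p, l in zip(pairs, labels) if l],
                   [p for p, l in zip(pairs, labels) if not l])
        scores = {p: float(rng.normal()) for p in pairs}
        ev = youden(scores, ref)
        sw = threshold_sweep(scores, ref, [ev.youden_cutoff])
        _, sens, spec, _ = sw.rows[0]
        assert sens == pytest.approx(ev.youden_sensitivity)
        assert spec == pytest.approx(ev.youden_specificity)


class TestSweep:
    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        pairs = [(f"D{i}", "A") for i in range(200)]
        labels = rng.random(200) < 0.4
        ref = _ref([p for p, l in zip(pairs, labels) if l],
                   [p for p, l in zip(pairs, labels) if not l])
        scores = {p: float(rng.normal(1.5, 1)) for p in pairs}
        sw = threshold_sweep(scores, ref, [1.0, 1.5, 2.0, 2.5, 3.0])
        sens = [r[1] for r in sw.rows]
        spec = [r[2] for r in sw.rows]
        assert all(b <= a for a, b in zip(sens, sens[1:]))
        assert all(b >= a for a, b in zip(spec, spec[1:]))

    def test_threshold_below_min_gives_full_sensitivity(self):
        sw = threshold_sweep(PERFECT_SCORES, PERFECT_REF, [-10.0])
        assert sw.rows[0][1] == 1.0

    def test_threshold_above_max_gives_full_specificity_and_nan_ppv(self):
        sw = threshold_sweep(PERFECT_SCORES, PERFECT_REF, [10.0])
        assert sw.rows[0][2] == 1.0
        assert math.isnan(sw.rows[0][3])


class TestTopK:
    def test_identical_scores_full_overlap(self):
        ov, val = topk_overlap(PERFECT_SCORES, PERFECT_SCORES, 3, PERFECT_REF)
        assert ov == 3
        assert val == (2, 2)

    def test_disjoint_rankings_zero_overlap(self):
        pairs = [(f"D{i}", "A") for i in range(10)]
        a = {p: float(i) for i, p in enumerate(pairs)}
        b = {p: float(-i) for i, p in enumerate(pairs)}
        ov, _ = topk_overlap(a, b, 5)
        assert ov == 0

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(13)
        pairs = [(f"D{i}", f"A{j}") for i in range(10) for j in range(10)]
        a = {p: float(rng.normal()) for p in pairs}
        b = {p: float(rng.normal()) for p in pairs}
        ov, _ = topk_overlap(a, b, 20)
        top_a = set(sorted(pairs, key=lambda p: (-a[p], p))[:20])
        top_b = set(sorted(pairs, key=lambda p: (-b[p], p))[:20])
        assert ov == len(top_a & top_b)

    def test_k_too_large(self):
        with pytest.raises(DataError):
            topk(PERFECT_SCORES, 99)


class TestCorrelation:
    def test_linear_transform_pearson_one(self):
        a = {("D%d" % i, "A"): float(i) for i in range(10)}
        b = {p: 2 * v + 1 for p, v in a.items()}
        assert score_correlation(a, b, "pearson") == pytest.approx(1.0)

    def test_rank_reversal_spearman_minus_one(self):
        a = {("D%d" % i, "A"): float(i) for i in range(10)}
        b = {p: -v ** 3 for p, v in a.items()}
        assert score_correlation(a, b, "spearman") == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        a = {("D%d" % i, "A"): v for i, v in enumerate([1.0, 2.0, 3.0, 4.0])}
        b = {("D%d" % i, "A"): v for i, v in enumerate([2.0, 1.0, 4.0, 3.0])}
        # pearson = cov/sd^2 = (sum xy - n x̄ ȳ) / ... = 0.6 by hand
        assert score_correlation(a, b, "pearson") == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        a = {("D%d" % i, "A"): 1.0 for i in range(5)}
        b = {("D%d" % i, "A"): float(i) for i in range(5)}
        with pytest.raises(DataError, match="variance"):
            score_correlation(a, b)

    def test_too_few_common_pairs(self):
        a = {("D1", "A"): 1.0, ("D2", "A"): 2.0}
        with pytest.raises(DataError):
            score_correlation(a, a)


class TestMonotoneTransformInvariance:
    @given(st.lists(st.tuples(st.integers(-500, 500), st.booleans()),
                    min_size=6, max_size=40).filter(
        lambda rows: len({l for _, l in rows}) == 2))
    def test_auc_youden_spearman_invariant(self, rows):
        # lattice-valued scores keep the warp strictly increasing in floats
        pairs = [(f"D{i}", "A") for i in range(len(rows))]
        ref = _ref([p for p, (_, l) in zip(pairs, rows) if l],
                   [p for p, (_, l) in zip(pairs, rows) if not l])
        raw = {p: v / 10.0 for p, (v, _) in zip(pairs, rows)}
        warped = {p: math.atan(v / 10.0) + 3.0 for p, v in raw.items()}
        assert roc_auc(raw, ref) == pytest.approx(roc_auc(warped, ref),
                                                  abs=1e-9)
        assert youden(raw, ref).youden_index == pytest.approx(
            youden(warped, ref).youden_index, abs=1e-9)
        if len(set(raw.values())) >= 2 and len(raw) >= 3:
            assert score_correlation(raw, warped, "spearman") == \
                pytest.approx(1.0)
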