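import datetime as dt
import math

import numpy as np
import pytest
from scipy import special

from icpnm.psadjust import (PSAdjustedModel, build_exposure_matrix,
                            compute_pcs, fit_ps, fit_ps_adjusted,
                            marginal_ade_prob_freq, ps_adjusted_ade_prob)
from icpnm.srs_data import DataError, Report, ReportDatabase


def _db_from_matrix(X, ade_rows=()):
    """Database whose drug exposure pattern equals the 0/1 matrix X."""
    drugs = [f"D{j}" for j in range(X.shape[1])]
    reports = []
    for i, row in enumerate(X):
        ds = frozenset(d for d, v in zip(drugs, row) if v) or frozenset({"Dpad"})
        ades = frozenset({"A0"} if i in ade_rows else {"B0"})
        reports.append(Report(f"R{i}", dt.date(2004, 1, 1), ds, ades))
    return ReportDatabase(reports)


class TestExposureMatrix:
    def test_toy_layout_excluding_index_drug(self, toy_db):
        m = build_exposure_matrix(toy_db, exclude_drug="D1")
        assert m.drug_columns == ["D2", "D3"]
        assert m.matrix.shape == (5, 2)
        np.testing.assert_array_equal(
            m.matrix, [[0, 0], [1, 0], [1, 0], [0, 0], [0, 1]])

    def test_single_drug_db_gives_zero_columns(self, toy_db):
        only = ReportDatabase([r for r in toy_db.reports if r.drugs == {"D3"}])
        m = build_exposure_matrix(only, exclude_drug="D3")
        assert m.matrix.shape[1] == 0

    def test_column_order_stable(self, toy_db):
        a = build_exposure_matrix(toy_db).drug_columns
        b = build_exposure_matrix(toy_db).drug_columns
        assert a == b == sorted(a)


class TestPCs:
    def test_rank_one_matrix_single_component(self):
        X = np.zeros((40, 3), dtype=np.int8)
        X[::2] = [1, 1, 1]
        db = _db_from_matrix(X)
        m = build_exposure_matrix(db)
        m.matrix = m.matrix[:, [c != "Dpad" for c in m.drug_columns]]
        m.drug_columns = [c for c in m.drug_columns if c != "Dpad"]
        pcs = compute_pcs(m, n=1)
        assert pcs.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, toy_db):
        m = build_exposure_matrix(toy_db)
        pcs = compute_pcs(m, n=2)
        gram = pcs.loadings.T @ pcs.loadings
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)

    def test_two_column_closed_form(self):
        # covariance [[p(1-p), c], [c, q(1-q)]] with hand-solvable eigvecs:
        # perfectly correlated columns -> leading eigenvector (1,1)/sqrt(2)
        X = np.zeros((50, 2), dtype=np.int8)
        X[:25] = [1, 1]
        db = _db_from_matrix(X)
        m = build_exposure_matrix(db)
        keep = [c != "Dpad" for c in m.drug_columns]
        m.matrix = m.matrix[:, keep]
        m.drug_columns = [c for c, k in zip(m.drug_columns, keep) if k]
        pcs = compute_pcs(m, n=1)
        np.testing.assert_allclose(np.abs(pcs.loadings[:, 0]),
                                   [1 / math.sqrt(2)] * 2, atol=1e-12)

    def test_n_too_large(self, toy_db):
        m = build_exposure_matrix(toy_db)
        with pytest.raises(DataError, match="n_components"):
            compute_pcs(m, n=10)


class TestFitPS:
    def test_null_exposure_ps_mean_matches_rate(self):
        rng = np.random.default_rng(5)
        K, p = 10_000, 0.1
        X = (rng.random((K, 6)) < 0.2).astype(np.int8)
        X[:, 0] = rng.random(K) < p  # independent of the co-medication
        db = _db_from_matrix(X)
        m = build_exposure_matrix(db, exclude_drug="D0")
        pcs = compute_pcs(m, n=3)
        fitted = fit_ps(db, "D0", pcs, m)
        assert float(np.mean(fitted.ps)) == pytest.approx(p, abs=0.02)

    def test_deterministic_coexposure_separates_groups(self):
        rng = np.random.default_rng(6)
        K = 2000
        other = (rng.random(K) < 0.3).astype(np.int8)
        X = np.column_stack([other, other, (rng.random(K) < 0.2).astype(np.int8)])
        db = _db_from_matrix(X)
        m = build_exposure_matrix(db, exclude_drug="D0")
        pcs = compute_pcs(m, n=2)
        fitted = fit_ps(db, "D0", pcs, m)
        exposed = fitted.ps[other == 1]
        unexposed = fitted.ps[other == 0]
        assert exposed.mean() > unexposed.mean() + 0.5

    def test_constant_exposure_rejected(self, toy_db):
        m = build_exposure_matrix(toy_db, exclude_drug="D9")
        pcs = compute_pcs(m, n=2)
        with pytest.raises(DataError, match="exposure variation"):
            fit_ps(toy_db, "D9", pcs, m)


class TestMarginalFreq:
    @pytest.mark.parametrize("cj,cpp,expected", [(100, 1000, 0.1),
                                                 (500, 1000, 0.5)])
    def test_sigmoid_logit_identity(self, cj, cpp, expected):
        assert marginal_ade_prob_freq(cj, cpp) == pytest.approx(expected,
                                                                abs=1e-12)

    @pytest.mark.parametrize("cj,cpp", [(0, 1000), (1000, 1000)])
    def test_boundary_counts_rejected(self, cj, cpp):
        with pytest.raises(DataError):
            marginal_ade_prob_freq(cj, cpp)


class TestPSAdjusted:
    def test_known_beta1_recovered_within_ci(self):
        # outcome truly depends on exposure only (beta2 = 0 world)
        hits = 0
        b1_true = 1.2
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            K = 4000
            X = (rng.random((K, 5)) < 0.15).astype(np.int8)
            eta = -3.0 + b1_true * X[:, 0]
            y_rows = set(np.flatnonzero(rng.random(K) < special.expit(eta)))
            db = _db_from_matrix(X, ade_rows=y_rows)
            m = build_exposure_matrix(db, exclude_drug="D0")
            pcs = compute_pcs(m, n=3)
            ps = fit_ps(db, "D0", pcs, m).ps
            fit = fit_ps_adjusted(db, "D0", "A0", ps)
            se = fit.bse[1]
            if abs(fit.beta1 - b1_true) <= 1.96 * se:
                hits += 1
        assert hits >= 18  # 90% of 20 replicates

    def test_ade_never_occurs_rejected(self, toy_db):
        with pytest.raises(DataError):
            fit_ps_adjusted(toy_db, "D1", "A9", np.full(5, 0.2))


class TestAdjustedProbability:
    def test_offset_only_reproduces_rate(self):
        m = PSAdjustedModel(0.0, 0.0, 0.0, beta_offset=special.logit(0.1))
        assert ps_adjusted_ade_prob(m, np.array([0.3, 0.9])) == \
            pytest.approx(0.1)

    def test_all_zero_coefficients_give_half(self):
        m = PSAdjustedModel(0.0, 0.0, 0.0, beta_offset=0.0)
        assert ps_adjusted_ade_prob(m, np.array([0.5])) == pytest.approx(0.5)

    def test_hand_value(self):
        m = PSAdjustedModel(0.0, 1.0, 1.0, beta_offset=0.0)
        got = ps_adjusted_ade_prob(m, np.array([0.2, 0.8]))
        want = (special.expit(1.2) + special.expit(1.8)) / 2
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.8133, abs=5e-4)

    def test_empty_ps_rejected(self):
        m = PSAdjustedModel(0.0, 0.0, 0.0, beta_offset=0.0)
        with pytest.raises(DataError):
            ps_adjusted_ade_prob(m, np.array([]))

    def test_beta2_zero_constant_in_ps(self):
        m = PSAdjustedModel(-1.0, 0.5, 0.0, beta_offset=0.3)
        a = ps_adjusted_ade_prob(m, np.array([0.01, 0.02]))
        b = ps_adjusted_ade_prob(m, np.array([0.98, 0.99]))
        assert a == pytest.approx(b, abs=1e-15)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            m = PSAdjustedModel(*rng.normal(scale=5, size=3),
                                beta_offset=float(rng.normal(scale=5)))
            p = ps_adjusted_ade_prob(m, rng.random(10))
            assert 0.0 < p < 1.0
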