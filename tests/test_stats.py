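"""Statistics layer: ROI medians, Dice, log-CoV, correlations, PLSR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fibromap as fm
from fibromap.stats import (roi_median, dice, cov_log, correlation_matrix,
                            plsr_loocv)


class TestRoiMedian:
    def test_plain_median(self):
        m = np.array([[1.0, 2.0, 3.0]])
        assert roi_median(m, np.ones_like(m, bool)) == 2.0

    def test_outlier_damped(self):
        m = np.array([1.0, 2.0, 3.0, 100.0])
        assert roi_median(m, np.ones(4, bool)) == 2.5

    def test_flagged_voxels_excluded(self):
        m = np.array([1.0, np.nan, 3.0])
        assert roi_median(m, np.ones(3, bool)) == 2.0

    def test_all_flagged_is_an_error(self):
        with pytest.raises(ValueError):
            roi_median(np.full(3, np.nan), np.ones(3, bool))
        with pytest.raises(ValueError):
            roi_median(np.ones(3), np.zeros(3, bool))


class TestDice:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((8, 8)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool); a[0] = True
        b = np.zeros((4, 4), bool); b[2] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(200, bool); a[:100] = True
        b = np.zeros(200, bool); b[50:150] = True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros(4, bool), np.zeros(4, bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros(3, bool), np.zeros(4, bool))


class TestCovLog:
    def test_identical_pairs_give_zero(self):
        assert cov_log([(2.0, 2.0), (5.0, 5.0)]) == 0.0

    def test_constant_log_ratio(self):
        # every pair differs by factor e^0.1: sigma_w^2 = 0.005
        pairs = [(x, x * np.exp(0.1)) for x in (1.0, 3.0, 10.0)]
        expect = 100 * np.sqrt(np.exp(0.005) - 1)
        assert cov_log(pairs) == pytest.approx(expect)
        assert cov_log(pairs) == pytest.approx(7.0799, abs=5e-4)

    @given(st.floats(min_value=0.1, max_value=1e4))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.2, size=(6, 2))
        assert cov_log(base * scale) == pytest.approx(cov_log(base))

    def test_simple_mode_first_order(self):
        pairs = [(x, x * np.exp(0.1)) for x in (1.0, 3.0)]
        assert cov_log(pairs, simple=True) == pytest.approx(100 * np.sqrt(0.005))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cov_log([(1.0, -1.0), (2.0, 2.0)])


class TestCorrelationMatrix:
    def test_bonferroni_threshold(self):
        df = fm.make_cohort(fm.CohortSpec(seed=0))
        res = correlation_matrix(df, ["ka"], ["picrosirius_pct"],
                                 n_comparisons=4, family_alpha=0.05)
        assert res.adjusted_alpha == 0.0125

    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2.0 * np.arange(10.0)})
        res = correlation_matrix(df, ["x"], ["y"])
        assert res.r.loc["x", "y"] == pytest.approx(1.0)

    def test_cohort_generator_oracle(self):
        df = fm.make_cohort(fm.CohortSpec(n_sections=1000,
                                          collagen_mt_r=0.85, seed=3))
        res = correlation_matrix(df, ["ka"], ["picrosirius_pct"])
        assert abs(res.r.loc["ka", "picrosirius_pct"] - 0.85) < 0.05

    def test_significance_monotone_in_family_alpha(self):
        df = fm.make_cohort(fm.CohortSpec(seed=4))
        lo = correlation_matrix(df, fm.MR_PARAMS, fm.HISTO_MARKERS,
                                family_alpha=0.01)
        hi = correlation_matrix(df, fm.MR_PARAMS, fm.HISTO_MARKERS,
                                family_alpha=0.10)
        assert (lo.significant.to_numpy() <= hi.significant.to_numpy()).all()

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": np.ones(6), "y": np.arange(6.0)})
        with pytest.raises(ValueError):
            correlation_matrix(df, ["x"], ["y"])


def brute_force_loocv(X, y, n_lv):
    """Independent leave-one-out loop used as the oracle."""
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.linear_model import LinearRegression
    preds = []
    for i in range(len(y)):
        keep = [j for j in range(len(y)) if j != i]
        Xtr, ytr = X[keep], y[keep]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        if X.shape[1] == 1:
            mdl = LinearRegression().fit((Xtr - mu) / sd, ytr)
        else:
            mdl = PLSRegression(n_components=n_lv, scale=False).fit(
                (Xtr - mu) / sd, ytr)
        preds.append(float(np.ravel(mdl.predict((X[i:i + 1] - mu) / sd))[0]))
    return np.array(preds)


class TestPlsrLoocv:
    def test_perfect_single_predictor(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "y": 3.0 + 2.0 * x})
        res = plsr_loocv(df, ["x"], "y")
        assert res.nrmse < 1e-6

    def test_matches_brute_force_loop(self):
        df = fm.make_cohort(fm.CohortSpec(n_sections=18, seed=6))
        mt_params = ["MTR", "T1", "T1s", "ka", "delta"]
        res = plsr_loocv(df, mt_params, "picrosirius_pct", n_lv=2)
        oracle = brute_force_loocv(df[mt_params].to_numpy(),
                                   df["picrosirius_pct"].to_numpy(), 2)
        assert np.allclose(res.predictions, oracle)

    def test_record_order_invariance(self):
        df = fm.make_cohort(fm.CohortSpec(n_sections=16, seed=7))
        cols = ["MTR", "ka", "delta"]
        a = plsr_loocv(df, cols, "picrosirius_pct", n_lv=1).nrmse
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = plsr_loocv(shuffled, cols, "picrosirius_pct", n_lv=1).nrmse
        assert a == pytest.approx(b)

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"x": np.arange(8.0), "y": np.ones(8)})
        with pytest.raises(ValueError):
            plsr_loocv(df, ["x"], "y")

    def test_lv_selection_never_beats_oracle(self):
        df = fm.make_cohort(fm.CohortSpec(n_sections=18, seed=8))
        cols = ["MTR", "T1", "T1s", "ka", "delta"]
        res = plsr_loocv(df, cols, "picrosirius_pct")
        oracle = brute_force_loocv(df[cols].to_numpy(),
                                   df["picrosirius_pct"].to_numpy(), res.n_lv)
        y = df["picrosirius_pct"].to_numpy()
        assert res.nrmse == pytest.approx(
            np.sqrt(np.mean((oracle - y) ** 2)) / np.ptp(y))
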