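"""NIPALS PLS against independent oracles; LOOCV, metrics, factor selection."""

import numpy as np
import pytest

from nitramap.chemometrics import (
    CalibrationTable,
    CVResult,
    NIPALSPLS,
    fit_pls,
    loocv,
    regression_metrics,
    select_factors,
    summarize_references,
)
from nitramap.preprocess import SpectrumMatrix


def ols_predictions(X, y):
    """Least-squares oracle via pseudoinverse of centered X."""
    Xc = X - X.mean(axis=0)
    b = np.linalg.pinv(Xc) @ (y - y.mean())
    return y.mean() + Xc @ b


def loocv_loop_oracle(X, y, max_factors):
    """Brute force: for each held-out sample and factor count, refit from scratch."""
    n = X.shape[0]
    preds = np.empty((n, max_factors))
    for i in range(n):
        keep = np.arange(n) != i
        for k in range(1, max_factors + 1):
            m = NIPALSPLS(n_factors=k).fit(X[keep], y[keep])
            preds[i, k - 1] = m.predict(X[i : i + 1])[0]
    return np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0)), preds


class TestNIPALSFit:
    def test_rank_one_single_factor_exact(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=12)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        y = X @ rng.normal(size=6)
        m = NIPALSPLS(n_factors=1).fit(X, y)
        np.testing.assert_allclose(m.predict(X), y, rtol=1e-8, atol=1e-8 * np.abs(y).max())

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_matches_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        m = NIPALSPLS(n_factors=10).fit(X, y)
        want = ols_predictions(X, y)
        np.testing.assert_allclose(m.predict(X), want, atol=1e-6 * np.abs(want).max())

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        a = NIPALSPLS(n_factors=4).fit(X, y)
        b = NIPALSPLS(n_factors=4).fit(X[perm], y[perm])
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        T = NIPALSPLS(n_factors=8).fit(X, y).x_scores_
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = np.abs(G / np.outer(norms, norms) - np.eye(8))
        assert off.max() < 1e-8

    def test_training_rmse_non_increasing_in_factors(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        rmse = [
            np.sqrt(np.mean((NIPALSPLS(n_factors=k).fit(X, y).predict(X) - y) ** 2))
            for k in range(1, 10)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(rmse, rmse[1:]))

    def test_y_scale_equivariance(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        base = NIPALSPLS(n_factors=3).fit(X, y).predict(X)
        scaled = NIPALSPLS(n_factors=3).fit(X, 10.0 * y).predict(X)
        np.testing.assert_allclose(scaled, 10.0 * base, rtol=1e-10)

    def test_matches_sklearn_pls(self, rng):
        """Independent cross-check against sklearn's PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        ours = NIPALSPLS(n_factors=5).fit(X, y).predict(X)
        theirs = PLSRegression(n_components=5, scale=False).fit(X, y).predict(X).ravel()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_too_many_factors_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="n_factors"):
            NIPALSPLS(n_factors=5).fit(X, rng.normal(size=5))

    def test_sklearn_get_set_params_round_trip(self):
        m = NIPALSPLS(n_factors=7)
        assert NIPALSPLS(**m.get_params()).n_factors == 7


class TestPredict:
    def test_mean_row_predicts_mean_response(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        m = NIPALSPLS(n_factors=3).fit(X, y)
        np.testing.assert_allclose(m.predict(X.mean(axis=0)[None]), [y.mean()], atol=1e-10)

    def test_band_axis_mismatch_raises(self, rng):
        m = NIPALSPLS(n_factors=2).fit(rng.normal(size=(8, 6)), rng.normal(size=8))
        with pytest.raises(ValueError, match="bands"):
            m.predict(np.zeros((1, 5)))

    def test_low_noise_synthetic_validation_r2(self, config):
        from dataclasses import replace

        from nitramap.preprocess import PreprocessRecipe
        from nitramap.synthetic import generate_calibration_set

        quiet = replace(config, noise_sd=2e-4, offset_sd=2e-3)
        train = generate_calibration_set(quiet, n_samples=60, seed=3)
        test = generate_calibration_set(quiet, n_samples=30, seed=4)
        rec = PreprocessRecipe.default()
        Xtr, _ = rec.apply(train.spectra.values, train.spectra.wavelengths)
        Xte, _ = rec.apply(test.spectra.values, test.spectra.wavelengths)
        m = NIPALSPLS(n_factors=4).fit(Xtr, train.nitrate_mg_per_kg)
        r2 = regression_metrics(test.nitrate_mg_per_kg, m.predict(Xte))["r2"]
        assert r2 >= 0.95


class TestLOOCV:
    @pytest.mark.parametrize("n,p,max_factors", [(5, 4, 3), (8, 6, 4), (12, 5, 3)])
    def test_matches_brute_force_oracle(self, n, p, max_factors):
        rng = np.random.default_rng(n * 100 + p)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        cv = loocv(X, y, max_factors=max_factors)
        want_rmsecv, want_preds = loocv_loop_oracle(X, y, max_factors)
        np.testing.assert_allclose(cv.rmsecv_by_factor, want_rmsecv, atol=1e-9)
        np.testing.assert_allclose(cv.predictions_by_factor, want_preds, atol=1e-9)

    def test_constant_y_has_nan_r2(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        y = np.full(6, 5.0)
        cv = loocv(X, y, max_factors=2)
        assert np.isnan(cv.r2_by_factor).all()

    def test_duplicated_samples_do_not_worsen_rmsecv(self, rng):
        X = rng.normal(size=(8, 5))
        y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=8)
        cv1 = loocv(X, y, max_factors=3)
        cv2 = loocv(np.vstack([X, X]), np.concatenate([y, y]), max_factors=3)
        assert np.all(cv2.rmsecv_by_factor <= cv1.rmsecv_by_factor + 1e-9)

    def test_rmsecv_scales_with_y(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        a = loocv(X, y, max_factors=3).rmsecv_by_factor
        b = loocv(X, 7.0 * y, max_factors=3).rmsecv_by_factor
        np.testing.assert_allclose(b, 7.0 * a, rtol=1e-10)

    def test_max_factors_bound_enforced(self, rng):
        X = rng.normal(size=(5, 8))
        with pytest.raises(ValueError, match="max_factors"):
            loocv(X, rng.normal(size=5), max_factors=4)


class TestSelectFactors:
    @staticmethod
    def _cv(rmsecv):
        r = np.asarray(rmsecv, float)
        return CVResult(r, np.zeros_like(r), np.zeros_like(r),
                        int(np.argmin(r)) + 1, np.zeros(3))

    def test_convex_curve_argmin(self):
        assert select_factors(self._cv([5, 3, 1, 2, 4])) == 3

    def test_tie_breaks_toward_fewer_factors(self):
        assert select_factors(self._cv([5, 4, 2, 3, 2, 6, 2])) == 3

    def test_monotone_decreasing_picks_last(self):
        assert select_factors(self._cv([5, 4, 3, 2, 1])) == 5


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert m["r2"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0)

    def test_constant_offset(self):
        m = regression_metrics([1.0, 2, 3, 4], [3.5, 4.5, 5.5, 6.5])
        assert m["rmse"] == pytest.approx(2.5)
        assert m["r2"] == pytest.approx(1.0)

    def test_hand_computed_small_case(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        p = np.array([1.5, 2.5, 3.5, 5.5])
        # from-scratch arithmetic
        rmse = np.sqrt(((y - p) ** 2).mean())
        r = np.sum((y - y.mean()) * (p - p.mean())) / np.sqrt(
            np.sum((y - y.mean()) ** 2) * np.sum((p - p.mean()) ** 2))
        m = regression_metrics(y, p)
        assert m["rmse"] == pytest.approx(rmse)
        assert m["r2"] == pytest.approx(r**2)

    def test_zero_variance_gives_nan_r2(self):
        m = regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(m["r2"])


class TestCalibrationTable:
    def test_summary_statistics(self):
        s = summarize_references(np.array([1.0, 2.0, 3.0]))
        assert s == {"n": 3, "min": 1.0, "max": 3.0, "mean": 2.0, "median": 2.0, "sd": 1.0}

    def test_single_value_sd_zero(self):
        assert summarize_references(np.array([4.0]))["sd"] == 0.0

    def test_generated_set_respects_design_range(self, config):
        from nitramap.synthetic import generate_calibration_set

        table = generate_calibration_set(config, n_samples=210, seed=9)
        s = summarize_references(table)
        assert s["n"] == 210
        assert s["min"] >= config.blade_range[0]
        assert s["max"] <= config.blade_range[1]

    def test_duplicate_ids_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            CalibrationTable(
                sample_ids=["a", "a"],
                nitrate_mg_per_kg=[1.0, 2.0],
                spectra=SpectrumMatrix(rng.uniform(size=(2, 4)), np.arange(4)),
            )

    def test_csv_round_trip(self, tmp_path, cal_small):
        cal_small.to_csv(tmp_path / "cal.csv")
        back = CalibrationTable.from_csv(tmp_path / "cal.csv")
        np.testing.assert_allclose(back.nitrate_mg_per_kg, cal_small.nitrate_mg_per_kg)
        np.testing.assert_allclose(back.spectra.values, cal_small.spectra.values, atol=1e-12)

    def test_fit_pls_wrapper_accepts_spectrum_matrix(self, cal_small):
        m = fit_pls(cal_small.spectra, cal_small.nitrate_mg_per_kg, n_factors=3)
        assert m.n_factors_ == 3
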