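"""Regression algorithms, prediction maps, constraint and bias correction."""

import numpy as np
import pytest

import corespec as cs
from corespec.cube import SOCMap
from corespec.models import REFERENCE_SVM_POINT
from corespec.roi import CalibrationSample, CalibrationSet

from conftest import tiny_cube


def make_cal(X, y, treatment=cs.SNV, X_val=None, y_val=None) -> CalibrationSet:
    """Calibration set straight from matrices (one sample per row)."""
    samples = []
    for i, (x, t) in enumerate(zip(X, y)):
        samples.append(
            CalibrationSample(
                roi_id=f"r{i}", spectrum=np.asarray(x, float), statistic="mean",
                subset_id="r1", role="train", soc=float(t),
            )
        )
    if X_val is not None:
        for i, (x, t) in enumerate(zip(X_val, y_val)):
            samples.append(
                CalibrationSample(
                    roi_id=f"v{i}", spectrum=np.asarray(x, float),
                    statistic="mean", subset_id="full", role="validate",
                    soc=float(t),
                )
            )
    y = np.asarray(y, float)
    lo, hi = float(y.min()), float(y.max())
    if hi <= lo:
        lo, hi = lo - 0.5, lo + 0.5  # degenerate sets only for RF edge cases
    return CalibrationSet(samples=samples, treatment=treatment,
                          soc_min=lo, soc_max=hi)


def _linear_data(n=40, p=12, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, p))
    w = rng.normal(size=p)
    y = X @ w + noise * rng.normal(size=n)
    return X, y


class TestPLS:
    def test_linear_response_identified_with_few_components(self):
        X, y = _linear_data()
        model = cs.fit_pls(make_cal(X, y))
        pred = model.predict(X)
        ss_res = np.sum((pred - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999
        assert model.hyperparameters["cv_optimal_components"] <= 12

    def test_band_permutation_symmetry(self):
        X, y = _linear_data(seed=3)
        perm = np.random.default_rng(1).permutation(X.shape[1])
        m1 = cs.fit_pls(make_cal(X, y))
        m2 = cs.fit_pls(make_cal(X[:, perm], y))
        np.testing.assert_allclose(
            m1.predict(X), m2.predict(X[:, perm]), atol=1e-8
        )

    def test_one_component_matches_nipals_deflation_oracle(self):
        """fit with a single latent variable == hand-rolled rank-1 NIPALS."""
        rng = np.random.default_rng(7)
        X = rng.random((5, 4))
        y = rng.random(5)
        cfg = cs.ModelConfig(algorithm="pls", pls_max_components=1,
                             pls_cv_folds=2, pls_force_components=1)
        model = cs.fit_pls(make_cal(X, y), cfg)

        # independent oracle: one NIPALS step on centred data
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w = w / np.linalg.norm(w)
        t = Xc @ w
        q = (yc @ t) / (t @ t)
        Xnew = rng.random((8, 4))
        oracle = y.mean() + q * ((Xnew - X.mean(axis=0)) @ w)
        np.testing.assert_allclose(model.predict(Xnew), oracle, atol=1e-8)

    def test_component_cap_warns(self):
        X, y = _linear_data(n=8, p=30)
        with pytest.warns(UserWarning, match="capped"):
            cs.fit_pls(make_cal(X, y),
                       cs.ModelConfig(algorithm="pls", pls_max_components=20,
                                      pls_cv_folds=2))


class TestRF:
    def test_predictions_bounded_by_training_range(self, study, rf_model):
        """Tree ensembles cannot extrapolate outside the response range."""
        cal = study["cal"]
        y = cal.y("train")
        pred = rf_model.predict(cal.X("validate"))
        assert pred.min() >= y.min() - 1e-9
        assert pred.max() <= y.max() + 1e-9

    def test_constant_response_predicts_constant(self):
        X, _ = _linear_data(n=20)
        model = cs.fit_rf(make_cal(X, np.full(20, 4.2)))
        np.testing.assert_allclose(model.predict(X), 4.2, atol=1e-12)

    def test_oob_split_uses_one_third_in_bag(self):
        X, y = _linear_data(n=30)
        model = cs.fit_rf(make_cal(X, y))
        est = model.estimator
        sizes = {len(np.unique(s)) for s in est.estimators_samples_}
        assert sizes == {int(0.33 * 30)}  # without replacement: all distinct

    def test_seeded_fit_is_deterministic(self):
        X, y = _linear_data(n=25, seed=5)
        m1 = cs.fit_rf(make_cal(X, y), cs.ModelConfig(algorithm="rf", seed=9))
        m2 = cs.fit_rf(make_cal(X, y), cs.ModelConfig(algorithm="rf", seed=9))
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class TestSVM:
    def test_single_point_grid_reports_exactly_those_parameters(self):
        X, y = _linear_data(n=30, seed=2)
        cfg = cs.ModelConfig(
            algorithm="svm",
            svm_grid={k: list(v) for k, v in REFERENCE_SVM_POINT.items()},
            svm_bootstrap_reps=5,
        )
        with pytest.warns(UserWarning, match="single point"):
            model = cs.fit_svm(make_cal(X, y), cfg)
        assert model.hyperparameters["gamma"] == 0.01
        assert model.hyperparameters["C"] == 8.0
        assert model.hyperparameters["epsilon"] == 0.1
        assert model.hyperparameters["n_support_vectors"] > 0

    def test_huge_epsilon_gives_near_constant_predictions(self):
        X, y = _linear_data(n=25, seed=4)
        cfg = cs.ModelConfig(
            algorithm="svm",
            svm_grid={"gamma": [0.1], "C": [4], "epsilon": [100.0]},
            svm_bootstrap_reps=2,
        )
        with pytest.warns(UserWarning, match="single point"):
            model = cs.fit_svm(make_cal(X, y), cfg)
        assert np.ptp(model.predict(X)) < 1e-6

    def test_grid_search_deterministic_at_fixed_seed(self):
        X, y = _linear_data(n=30, seed=6, noise=0.3)
        cfg = cs.ModelConfig(
            algorithm="svm",
            svm_grid={"gamma": [0.01, 0.1], "C": [1, 8], "epsilon": [0.1]},
            svm_cv_folds=4,
            svm_bootstrap_reps=3,
            seed=12,
        )
        m1 = cs.fit_svm(make_cal(X, y), cfg)
        m2 = cs.fit_svm(make_cal(X, y), cfg)
        assert m1.hyperparameters["gamma"] == m2.hyperparameters["gamma"]
        assert m1.hyperparameters["C"] == m2.hyperparameters["C"]
        np.testing.assert_allclose(m1.predict(X), m2.predict(X))

    def test_scaling_is_stored_and_applied(self):
        X, y = _linear_data(n=20, seed=8)
        cfg = cs.ModelConfig(
            algorithm="svm",
            svm_grid={"gamma": [0.1], "C": [4], "epsilon": [0.1]},
            svm_bootstrap_reps=2,
        )
        with pytest.warns(UserWarning):
            model = cs.fit_svm(make_cal(X, y), cfg)
        assert model.scaler is not None
        # predictions on raw spectra go through the stored scaler
        assert np.all(np.isfinite(model.predict(X)))


class TestPredictMap:
    def test_whole_cube_equals_pixel_loop(self, study, rf_model):
        cube = study["snv"]["core0"]
        sub = cube.replace(
            values=cube.values[:12, :6], mask=cube.mask[:12, :6]
        )
        soc_map = cs.predict_map(rf_model, sub)
        for r in range(12):
            for c in range(6):
                if sub.mask[r, c]:
                    one = rf_model.predict(sub.values[r, c][None, :])[0]
                    assert soc_map.values[r, c] == pytest.approx(one, abs=1e-10)
                else:
                    assert np.isnan(soc_map.values[r, c])

    def test_masked_pixels_excluded_downstream(self, study, rf_model):
        cube = study["snv"]["core0"]
        sub = cube.replace(values=cube.values[:10, :5],
                           mask=cube.mask[:10, :5].copy())
        sub.mask[0, 0] = False
        soc_map = cs.predict_map(rf_model, sub)
        summary = cs.summarize_distribution(soc_map, upper_limit=20.0)
        assert summary.n == int(sub.mask.sum())

    def test_treatment_and_band_mismatch_rejected(self, study, rf_model):
        nr = study["nr"]["core0"]
        with pytest.raises(ValueError, match="treatment"):
            cs.predict_map(rf_model, nr)
        small = tiny_cube(np.ones((2, 2, 3)), treatment=cs.SNV)
        with pytest.raises(ValueError, match="[Bb]and"):
            cs.predict_map(rf_model, small)


class TestConstraint:
    def _map(self, values):
        values = np.asarray(values, float)
        return SOCMap(values=values, mask=np.isfinite(values),
                      pixel_size_um=2000.0)

    def test_reference_worked_examples(self):
        m = self._map([[-187.0, 562.0, 5.0]])
        out = cs.constrain_predictions(m, 1.6, 15.5)
        np.testing.assert_allclose(out.values, [[1.6, 15.5, 5.0]])

    def test_values_between_zero_and_minimum_not_raised(self):
        out = cs.constrain_predictions(self._map([[0.5, 1.0]]), 1.6, 15.5)
        np.testing.assert_allclose(out.values, [[0.5, 1.0]])

    def test_idempotent_and_raw_preserved(self):
        m = self._map([[-3.0, 20.0, 7.0]])
        once = cs.constrain_predictions(m, 1.6, 15.5)
        twice = cs.constrain_predictions(once, 1.6, 15.5)
        np.testing.assert_array_equal(once.values, twice.values)
        np.testing.assert_array_equal(once.raw_values, m.values)
        np.testing.assert_array_equal(twice.raw_values, m.values)

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            cs.constrain_predictions(self._map([[1.0]]), 5.0, 2.0)


class TestBiasCorrection:
    def test_mean_underestimation_becomes_positive_offset(self):
        depth = np.array([10.0] * 4 + [60.0] * 4)
        measured = np.full(8, 8.0)
        predicted = measured + np.array([-1.5] * 4 + [1.5] * 4)
        bc = cs.estimate_bias_correction(predicted, measured, depth, 30.0)
        assert bc.topsoil_offset == pytest.approx(1.5)
        assert bc.subsoil_offset == pytest.approx(-1.5)

    def test_unbiased_residuals_give_identity_correction(self):
        depth = np.array([10.0, 20.0, 15.0, 50.0, 60.0, 70.0])
        y = np.array([9.0, 8.5, 9.2, 4.0, 3.0, 2.5])
        bc = cs.estimate_bias_correction(y, y, depth, 30.0)
        assert bc.topsoil_offset == 0.0
        assert bc.subsoil_offset == 0.0

    def test_monte_carlo_recovery_of_group_biases(self):
        rng = np.random.default_rng(0)
        depth = np.concatenate([np.full(200, 10.0), np.full(200, 60.0)])
        measured = rng.normal(6.0, 1.0, 400)
        bias = np.where(depth < 30, 0.8, -0.4)
        predicted = measured + bias + rng.normal(0, 0.5, 400)
        bc = cs.estimate_bias_correction(predicted, measured, depth, 30.0)
        se = 0.5 / np.sqrt(200)
        assert bc.topsoil_offset == pytest.approx(-0.8, abs=4 * se)
        assert bc.subsoil_offset == pytest.approx(0.4, abs=4 * se)

    def test_missing_horizon_rejected(self):
        depth = np.full(6, 50.0)
        with pytest.raises(ValueError, match="topsoil"):
            cs.estimate_bias_correction(depth, depth, depth, 30.0)

    def test_apply_shifts_match_reference_equations(self):
        values = np.array([[7.0], [3.0]])
        m = SOCMap(values=values, mask=np.ones((2, 1), bool),
                   pixel_size_um=2000.0)
        # row 0 centre at 0.1 cm (topsoil), row 1 forced subsoil by boundary
        bc = cs.BiasCorrection(topsoil_offset=1.5, subsoil_offset=-1.5,
                               horizon_boundary_cm=0.25)
        out = cs.apply_bias_correction(m, bc)
        np.testing.assert_allclose(out.values, [[8.5], [1.5]])

    def test_zero_offsets_leave_map_unchanged(self, study, rf_model):
        cube = study["snv"]["core0"]
        m = cs.predict_map(rf_model, cube.replace(values=cube.values[:20],
                                                  mask=cube.mask[:20]))
        bc = cs.BiasCorrection(0.0, 0.0, 30.0)
        np.testing.assert_array_equal(cs.apply_bias_correction(m, bc).values,
                                      m.values)

    def test_correction_is_exact_additive_shift(self):
        rng = np.random.default_rng(3)
        values = rng.random((50, 4)) * 10
        m = SOCMap(values=values, mask=np.ones((50, 4), bool),
                   pixel_size_um=10000.0)  # 1 cm pixels
        bc = cs.BiasCorrection(1.5, -1.5, 30.0)
        out = cs.apply_bias_correction(m, bc)
        shifts = np.unique(np.round(out.values - m.values, 12))
        assert set(shifts) == {-1.5, 1.5}
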