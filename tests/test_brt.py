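"""Boosted-tree fitting: deviance, step selection, influence, dependence."""

import numpy as np
import pandas as pd
import pytest

from eidhotspots.brt import (BoostConfig, bernoulli_deviance, fit_step,
                             load_fit, partial_dependence, predict,
                             relative_influence, save_fit)
from eidhotspots.validation import deviance_explained


def logistic_design(n=300, n_features=10, beta=None, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    beta = np.zeros(n_features) if beta is None else np.asarray(beta)
    p = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(int)
    cols = [f"x{i}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y


class TestDeviance:
    def test_perfect_probs_near_zero(self):
        y = np.array([0, 1, 1, 0])
        p = np.where(y == 1, 1.0 - 1e-9, 1e-9)
        assert bernoulli_deviance(y, p) == pytest.approx(0.0, abs=1e-6)

    def test_half_probs_closed_form(self):
        y = np.array([0, 1] * 10)
        assert bernoulli_deviance(y, np.full(20, 0.5)) == \
            pytest.approx(2 * np.log(2))

    def test_matches_per_sample_summation_oracle(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.01, 0.99, 50)
        oracle = -2 * sum(yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                          for yi, pi in zip(y, p)) / 50
        assert bernoulli_deviance(y, p) == pytest.approx(oracle, rel=1e-12)

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_deviance(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            bernoulli_deviance(np.array([1]), np.array([0.5, 0.5]))


class TestFitStep:
    def test_pure_noise_explains_nothing(self, fast_boost, rng):
        X, y = logistic_design(n=300, seed=1)
        fit = fit_step(X, y, fast_boost, rng)
        if not fit.is_null:
            assert abs(deviance_explained(fit, X, y)) <= 100.0
            # CV deviance, unlike training deviance, should sit at the null
            assert fit.cv_deviance >= fit.null_deviance - 0.05

    def test_separable_signal_beats_null(self, fast_boost, rng):
        X, y = logistic_design(n=400, beta=[3, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                               seed=2)
        fit = fit_step(X, y, fast_boost, rng)
        assert not fit.is_null
        assert fit.cv_deviance < fit.null_deviance
        assert fit.n_trees_selected >= fast_boost.step_size
        assert fit.n_trees_selected % fast_boost.step_size == 0

    def test_same_seed_same_selection(self, fast_boost):
        X, y = logistic_design(n=300, beta=[2] + [0] * 9, seed=3)
        f1 = fit_step(X, y, fast_boost, np.random.default_rng(5))
        f2 = fit_step(X, y, fast_boost, np.random.default_rng(5))
        assert f1.n_trees_selected == f2.n_trees_selected
        np.testing.assert_array_equal(f1.cv_deviance_trajectory,
                                      f2.cv_deviance_trajectory)

    def test_single_class_rejected(self, fast_boost, rng):
        X, _ = logistic_design(n=50)
        with pytest.raises(ValueError, match="both classes"):
            fit_step(X, np.ones(50, dtype=int), fast_boost, rng)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BoostConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            BoostConfig(step_size=0)


class TestPredict:
    def test_training_predictions_reproduce_training_deviance(self, fast_boost,
                                                              rng):
        X, y = logistic_design(n=300, beta=[2] + [0] * 9, seed=4)
        fit = fit_step(X, y, fast_boost, rng)
        dev = bernoulli_deviance(y, predict(fit, X))
        assert dev == pytest.approx(fit.training_deviance, rel=1e-9)

    def test_duplicated_rows_identical_predictions(self, fast_boost, rng):
        X, y = logistic_design(n=300, beta=[2] + [0] * 9, seed=5)
        fit = fit_step(X, y, fast_boost, rng)
        X2 = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        p = predict(fit, X2)
        assert p[0] == p[1]
        assert ((p > 0) & (p < 1)).all()

    def test_wrong_columns_rejected(self, fast_boost, rng):
        X, y = logistic_design(n=300, beta=[2] + [0] * 9, seed=6)
        fit = fit_step(X, y, fast_boost, rng)
        with pytest.raises(ValueError, match="do not match"):
            predict(fit, X.rename(columns={"x0": "zz"}))

    def test_monotone_signal_gives_monotone_response(self, fast_boost, rng):
        X, y = logistic_design(n=800, n_features=3, beta=[4, 0, 0], seed=7)
        fit = fit_step(X, y, fast_boost, rng)
        probes, curve = partial_dependence(fit, X, "x0", n_points=9)
        # allow small non-monotone wiggles: overall trend must be increasing
        assert curve[-1] > curve[0]
        diffs = np.diff(curve)
        assert (diffs >= -0.02).all()


class TestRelativeInfluence:
    def test_sums_to_100_and_dominant_driver(self, fast_boost, rng):
        X, y = logistic_design(n=500, n_features=11,
                               beta=[4] + [0] * 10, seed=8)
        fit = fit_step(X, y, fast_boost, rng)
        ri = fit.relative_influence
        assert ri.sum() == pytest.approx(100.0, abs=1e-6)
        assert ri.idxmax() == "x0"
        assert ri["x0"] > 50.0

    def test_unused_predictor_scores_zero(self, fast_boost, rng):
        # a constant column can never be split on
        X, y = logistic_design(n=400, n_features=5, beta=[3, 0, 0, 0, 0],
                               seed=9)
        X["const"] = 1.0
        fit = fit_step(X, y, fast_boost, rng)
        assert fit.relative_influence["const"] == 0.0


class TestPartialDependence:
    def test_flat_for_irrelevant_predictor(self, fast_boost, rng):
        X, y = logistic_design(n=500, n_features=4, beta=[3, 0, 0, 0], seed=10)
        fit = fit_step(X, y, fast_boost, rng)
        _, curve = partial_dependence(fit, X, "x3", n_points=9)
        assert np.ptp(curve) < 0.05

    def test_matches_column_replacement_oracle(self, fast_boost, rng):
        X, y = logistic_design(n=200, n_features=4, beta=[2, -1, 0, 0],
                               seed=11)
        fit = fit_step(X, y, fast_boost, rng)
        probes, curve = partial_dependence(fit, X, "x1", n_points=5)
        for v, got in zip(probes, curve):
            Xmod = X.copy()
            Xmod["x1"] = v
            oracle = predict(fit, Xmod).mean()
            assert got == pytest.approx(oracle, rel=1e-9)

    def test_probe_grid_spans_10th_to_90th_percentile(self, fast_boost, rng):
        X, y = logistic_design(n=300, n_features=3, beta=[2, 0, 0], seed=12)
        fit = fit_step(X, y, fast_boost, rng)
        probes, _ = partial_dependence(fit, X, "x0", n_points=7)
        assert probes[0] == pytest.approx(np.quantile(X["x0"], 0.10))
        assert probes[-1] == pytest.approx(np.quantile(X["x0"], 0.90))

    def test_unknown_predictor_rejected(self, fast_boost, rng):
        X, y = logistic_design(n=300, n_features=3, beta=[2, 0, 0], seed=13)
        fit = fit_step(X, y, fast_boost, rng)
        with pytest.raises(ValueError):
            partial_dependence(fit, X, "nope")


class TestInvariances:
    def test_deviance_explained_invariant_to_relabeling(self):
        # relabel 0↔1 with complemented probabilities: both the residual and
        # null deviances are unchanged, hence so is deviance explained
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = rng.uniform(0.01, 0.99, 200)
        d_res = bernoulli_deviance(y, p)
        d_null = bernoulli_deviance(y, np.full(200, y.mean()))
        d_res_c = bernoulli_deviance(1 - y, 1 - p)
        d_null_c = bernoulli_deviance(1 - y, np.full(200, 1 - y.mean()))
        assert 1 - d_res / d_null == pytest.approx(1 - d_res_c / d_null_c,
                                                   rel=1e-12)

    def test_monotone_transform_of_predictor_keeps_predictions(self,
                                                               fast_boost):
        X, y = logistic_design(n=300, n_features=3, beta=[3, 1, 0], seed=15)
        f1 = fit_step(X, y, fast_boost, np.random.default_rng(2))
        Xt = X.copy()
        Xt["x0"] = np.exp(Xt["x0"])  # strictly monotone
        f2 = fit_step(Xt, y, fast_boost, np.random.default_rng(2))
        # tree models depend only on predictor order, so refitting on the
        # transformed design reproduces the same model
        assert f1.n_trees_selected == f2.n_trees_selected
        np.testing.assert_allclose(predict(f1, X), predict(f2, Xt),
                                   atol=1e-9)


class TestSerialization:
    def test_archive_roundtrip(self, fast_boost, rng, tmp_path):
        X, y = logistic_design(n=300, n_features=4, beta=[2, 0, 0, 0], seed=16)
        fit = fit_step(X, y, fast_boost, rng)
        path = tmp_path / "fit.joblib"
        save_fit(fit, path)
        back = load_fit(path)
        np.testing.assert_allclose(predict(back, X), predict(fit, X))
        assert back.n_trees_selected == fit.n_trees_selected
        pd.testing.assert_series_equal(back.relative_influence,
                                       fit.relative_influence)
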