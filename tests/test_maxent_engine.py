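import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from sdmshift.grid_io import harmonize_stack
from sdmshift.maxent_engine import (
    DataError, Feature, FeatureSet, MaxentModel, TrainConfig, build_features,
    fit_maxent, jackknife_importance, percent_contribution,
    regularization_weights, response_curve, sample_background,
)

from conftest import make_grid


def linear_config(**kw):
    kw.setdefault("feature_classes", ("linear",))
    kw.setdefault("max_iterations", 5000)
    kw.setdefault("convergence_tol", 1e-12)
    return TrainConfig(**kw)


class TestBuildFeatures:
    def test_single_linear_feature(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        fs = build_features(df, TrainConfig(feature_classes=("linear",)))
        assert len(fs.features) == 1
        np.testing.assert_allclose(fs.design_matrix(df)[:, 0], [0, 0.5, 1])

    def test_combinatorial_count(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "y": [2.0, 3.0]})
        fs = build_features(df, TrainConfig(
            feature_classes=("linear", "quadratic", "product")))
        assert len(fs.features) == 5  # 2 linear + 2 quadratic + 1 product

    def test_hinge_count_and_range(self):
        df = pd.DataFrame({"x": np.linspace(0, 10, 30)})
        fs = build_features(df, TrainConfig(
            feature_classes=("hinge",), n_hinge_knots=6))
        assert len(fs.features) == 12  # 6 forward + 6 reverse
        X = fs.design_matrix(df)
        assert X.min() >= 0 and X.max() <= 1

    def test_categorical_indicators_average_to_frequency(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"v": rng.choice([1.0, 2.0, 5.0], size=300, p=[0.5, 0.3, 0.2])})
        fs = build_features(df, TrainConfig(feature_classes=("categorical",)),
                            categorical=["v"])
        assert len(fs.features) == 3
        X = fs.design_matrix(df)
        for j, lv in enumerate(fs.categorical_levels["v"]):
            assert X[:, j].mean() == pytest.approx((df["v"] == lv).mean())

    def test_constant_variable_excluded_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "c": [3.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(df, TrainConfig(feature_classes=("linear",)))
        assert [f.variables[0] for f in fs.features] == ["x"]

    def test_projection_clamped_to_training_bounds(self):
        train = pd.DataFrame({"x": [0.0, 10.0]})
        fs = build_features(train, TrainConfig(feature_classes=("linear",)))
        X = fs.design_matrix(pd.DataFrame({"x": [-5.0, 15.0]}))
        np.testing.assert_allclose(X[:, 0], [0.0, 1.0])


class TestSampleBackground:
    def stack(self):
        return harmonize_stack({"a": make_grid(np.arange(12.0).reshape(3, 4))})

    def test_exhaustive_when_n_equals_valid(self):
        bg = sample_background(self.stack(), 12, seed=0)
        assert sorted(bg["a"]) == list(np.arange(12.0))

    def test_deterministic(self):
        s = self.stack()
        pd.testing.assert_frame_equal(sample_background(s, 5, seed=7),
                                      sample_background(s, 5, seed=7))

    def test_uniformity_binomial(self):
        s = self.stack()
        n, N, trials = 4, 12, 2000
        hits = np.zeros(N)
        for seed in range(trials):
            hits[sample_background(s, n, seed=seed)["a"].astype(int)] += 1
        p = n / N
        sigma = np.sqrt(trials * p * (1 - p))
        assert np.all(np.abs(hits - trials * p) < 3.5 * sigma)


class TestFitMaxent:
    def tiny_instance(self):
        rng = np.random.default_rng(0)
        Xb = rng.random((6, 2))
        Xp = Xb[[0, 2, 4]]
        return Xp, Xb

    def test_full_shrinkage_zero_model(self):
        Xp, Xb = self.tiny_instance()
        m = fit_maxent(Xp, Xb, linear_config(beta_multiplier=1e6))
        assert np.all(m.lam == 0)
        np.testing.assert_allclose(m.raw_from_design(Xb), 1 / 6, rtol=1e-12)
        assert m.trace == []

    def test_moment_matching_beta_zero(self):
        Xp, Xb = self.tiny_instance()
        m = fit_maxent(Xp, Xb, linear_config(beta_multiplier=0.0))
        q = m.raw_from_design(Xb)
        np.testing.assert_allclose(q @ Xb, Xp.mean(axis=0), atol=1e-6)

    def test_matches_convex_oracle(self):
        # dense generic convex optimization as the independent oracle
        Xp, Xb = self.tiny_instance()
        for mult in (0.0, 1.0):
            m = fit_maxent(Xp, Xb, linear_config(beta_multiplier=mult))
            beta = regularization_weights(Xp, Xb, mult)

            def J(lam):
                return (-Xp.mean(0) @ lam + logsumexp(Xb @ lam)
                        + beta @ np.abs(lam))

            res = minimize(J, np.zeros(2), method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 20000})
            assert np.abs(m.lam - res.x).max() < 1e-4
            assert J(m.lam) - res.fun < 1e-6

    def test_duplicating_background_leaves_lambda_unchanged(self):
        Xp, Xb = self.tiny_instance()
        cfg = linear_config()
        m1 = fit_maxent(Xp, Xb, cfg)
        m2 = fit_maxent(Xp, np.vstack([Xb, Xb]), cfg)
        np.testing.assert_allclose(m1.lam, m2.lam, atol=1e-12)
        assert m2.log_z == pytest.approx(m1.log_z + np.log(2))

    def test_gain_nonnegative_and_monotone_from_trace(self):
        Xp, Xb = self.tiny_instance()
        m = fit_maxent(Xp, Xb, linear_config())
        gains = np.array([g for _, g in m.trace])
        assert np.all(gains >= 0)
        assert m.gain >= 0
        assert m.gain == pytest.approx(gains.sum(), abs=1e-9)

    def test_non_finite_features_rejected(self):
        Xp, Xb = self.tiny_instance()
        Xb = Xb.copy()
        Xb[0, 0] = np.nan
        with pytest.raises(DataError):
            fit_maxent(Xp, Xb, linear_config())

    def test_raw_sums_to_one_random_models(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            Xb = rng.random((40, 4))
            Xp = Xb[rng.choice(40, 8, replace=False)]
            m = fit_maxent(Xp, Xb, linear_config(max_iterations=50))
            assert m.raw_from_design(Xb).sum() == pytest.approx(1.0, abs=1e-9)


class TestOutputs:
    def fitted(self, seed=4, n=30):
        rng = np.random.default_rng(seed)
        Xb = rng.random((n, 3))
        Xp = Xb[rng.choice(n, 6, replace=False)]
        return fit_maxent(Xp, Xb, linear_config(max_iterations=200)), Xb

    def test_uniform_raw_gives_logistic_half(self):
        rng = np.random.default_rng(1)
        Xb = rng.random((10, 2))
        m = fit_maxent(Xb[:2], Xb, linear_config(beta_multiplier=1e6))
        # zero model: H = log N, c*q = 1, p = 0.5 everywhere
        assert m.entropy == pytest.approx(np.log(10), rel=1e-12)
        np.testing.assert_allclose(m.logistic_from_raw(m.raw_from_design(Xb)),
                                   0.5, rtol=1e-12)

    def test_logistic_zero_and_monotone(self):
        m, Xb = self.fitted()
        assert m.logistic_from_raw(np.array([0.0]))[0] == 0.0
        q = np.sort(m.raw_from_design(Xb))
        p = m.logistic_from_raw(q)
        assert np.all(np.diff(p) >= 0)

    def test_json_round_trip(self, tmp_path):
        m, Xb = self.fitted()
        m.to_json(tmp_path / "m.json")
        back = MaxentModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.lam, m.lam)
        df = pd.DataFrame(Xb, columns=["f0", "f1", "f2"])
        np.testing.assert_allclose(back.raw_output(df), m.raw_from_design(Xb),
                                   rtol=1e-12)


class TestContribution:
    def test_single_variable_gets_100(self):
        rng = np.random.default_rng(2)
        x = rng.random(50)
        df = pd.DataFrame({"x": x})
        fs = build_features(df, TrainConfig(feature_classes=("linear", "quadratic")))
        X = fs.design_matrix(df)
        m = fit_maxent(X[x > 0.6], X, linear_config(), feature_set=fs)
        contrib = percent_contribution(m)
        assert contrib["x"] == pytest.approx(100.0)

    def test_sums_to_100(self, small_landscape):
        land, occ = small_landscape
        from sdmshift.evaluation import run_replicates
        cfg = TrainConfig(n_background=800, max_iterations=60, n_hinge_knots=5)
        _, _, models = run_replicates(occ, land.stack, cfg, n_replicates=1,
                                      base_seed=0)
        contrib = percent_contribution(models[0])
        assert contrib.sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_model_all_zero(self):
        rng = np.random.default_rng(0)
        Xb = rng.random((8, 2))
        m = fit_maxent(Xb[:2], Xb, linear_config(beta_multiplier=1e6))
        assert (percent_contribution(m) == 0).all()

    def test_informative_beats_noise_over_seeds(self):
        # truth depends only on A; B is pure noise
        wins = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n = 400
            df = pd.DataFrame({"A": rng.random(n), "B": rng.random(n)})
            p_true = 1 / (1 + np.exp(-(6 * df["A"] - 3)))
            pres_idx = rng.random(n) < p_true
            cfg = TrainConfig(feature_classes=("linear", "quadratic"),
                              max_iterations=100)
            fs = build_features(df, cfg)
            X = fs.design_matrix(df)
            m = fit_maxent(X[pres_idx.to_numpy()], X, cfg, feature_set=fs)
            c = percent_contribution(m)
            wins += c["A"] > c["B"]
        assert wins >= 0.95 * n_runs


class TestJackknife:
    def build(self, seed=0, duplicate=False):
        rng = np.random.default_rng(seed)
        n = 500
        df = pd.DataFrame({"A": rng.random(n), "noise": rng.random(n)})
        if duplicate:
            df["A2"] = df["A"] + rng.normal(0, 1e-3, n)
        p_true = 1 / (1 + np.exp(-(8 * df["A"] - 4)))
        pres = df[rng.random(n) < p_true]
        cfg = TrainConfig(feature_classes=("linear", "quadratic"),
                          max_iterations=200)
        return pres, df, cfg

    def test_gain_without_bounded_by_full_gain(self):
        pres, bg, cfg = self.build()
        jk = jackknife_importance(pres, bg, ["A", "noise"], cfg)
        assert (jk["gain_without"] <= jk["full_gain"] + 1e-6).all()

    def test_duplicate_variable_compensates(self):
        pres, bg, cfg = self.build(duplicate=True)
        jk = jackknife_importance(pres, bg, ["A", "A2", "noise"], cfg)
        # removing one twin barely hurts: its copy carries the signal
        assert jk.loc["A", "gain_without"] >= 0.9 * jk.loc["A", "full_gain"]

    def test_noise_variable_gain_near_zero(self):
        pres, bg, cfg = self.build()
        jk = jackknife_importance(pres, bg, ["A", "noise"], cfg)
        assert jk.loc["noise", "gain_only"] < 0.1 * jk.loc["A", "gain_only"]
        assert jk.loc["noise", "gain_only"] < 0.05

    def test_single_variable_rejected(self):
        pres, bg, cfg = self.build()
        with pytest.raises(DataError):
            jackknife_importance(pres, bg, ["A"], cfg)


class TestResponseCurve:
    def model_with(self, lam_linear, lam_quad):
        fs = FeatureSet(
            [Feature("linear", ("x",)), Feature("quadratic", ("x",))],
            {"x": (0.0, 10.0)}, {}, {"x": 5.0},
        )
        return MaxentModel(fs, np.array([lam_linear, lam_quad]),
                           log_z=0.0, entropy=1.0, n_background=10)

    def test_positive_linear_monotone(self):
        m = self.model_with(3.0, 0.0)
        curve = response_curve(m, "x", n_steps=50)
        assert np.all(np.diff(curve["p"]) > 0)

    def test_quadratic_peak_at_vertex(self):
        # scaled quadratic a*xs + b*xs^2 peaks at xs = -a/(2b)
        a, b = 2.0, -4.0
        m = self.model_with(a, b)
        curve = response_curve(m, "x", n_steps=401)
        xs_peak = (curve["value"][np.argmax(curve["p"])] - 0.0) / 10.0
        assert xs_peak == pytest.approx(-a / (2 * b), abs=0.01)

    def test_endpoints_match_direct_evaluation(self):
        m = self.model_with(1.5, -1.0)
        curve = response_curve(m, "x", n_steps=7)
        direct = m.predict(pd.DataFrame({"x": [0.0, 10.0]}))
        assert curve["p"].iloc[0] == pytest.approx(direct[0], rel=1e-12)
        assert curve["p"].iloc[-1] == pytest.approx(direct[1], rel=1e-12)

    def test_replicate_averaged_curve(self, small_landscape):
        from sdmshift.evaluation import run_replicates
        from sdmshift.maxent_engine import averaged_response_curves
        land, occ = small_landscape
        cfg = TrainConfig(n_background=600, max_iterations=50, n_hinge_knots=5)
        _, _, models = run_replicates(occ, land.stack, cfg, n_replicates=3,
                                      base_seed=1)
        curve = averaged_response_curves(models, "temp", n_steps=20)
        assert len(curve) == 20
        assert (curve["p_sd"] >= 0).all()
        single = averaged_response_curves(models[:1], "temp", n_steps=20)
        direct = response_curve(models[0], "temp", n_steps=20)
        np.testing.assert_allclose(single["p_mean"], direct["p"], rtol=1e-12)

    def test_categorical_levelwise(self):
        fs = FeatureSet(
            [Feature("categorical_indicator", ("v",), 1.0),
             Feature("categorical_indicator", ("v",), 2.0)],
            {}, {"v": [1.0, 2.0]}, {"v": 1.0},
        )
        m = MaxentModel(fs, np.array([0.5, -0.5]), 0.0, 1.0, 10)
        curve = response_curve(m, "v")
        assert len(curve) == 2
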