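import math

import numpy as np
import pytest

import famliab as fl
from famliab.evaluation import WaicResult
from famliab.models import ModelSpec


def brute_force_waic(ll):
    """Direct-loop WAIC oracle (naive arithmetic, no vectorization)."""
    S, n = ll.shape
    lppd = 0.0
    p = 0.0
    for i in range(n):
        vals = [math.exp(ll[s][i]) for s in range(S)]
        lppd += math.log(sum(vals) / S)
        mean = sum(ll[s][i] for s in range(S)) / S
        p += sum((ll[s][i] - mean) ** 2 for s in range(S)) / (S - 1)
    return -2.0 * (lppd - p), lppd, p


class TestWaic:
    def test_zero_variance_draws(self):
        ll = np.full((5, 1), np.log(0.5))
        res = fl.waic(ll)
        assert np.isclose(res.p_waic, 0.0)
        assert np.isclose(res.waic, -2 * np.log(0.5))

    def test_two_draw_hand_example(self):
        ll = np.log(np.array([[0.5], [0.25]]))
        res = fl.waic(ll)
        assert np.isclose(res.lppd, np.log(0.375), atol=1e-12)
        assert np.isclose(res.p_waic, np.log(2) ** 2 / 2, atol=1e-12)
        exact = -2.0 * (np.log(0.375) - np.log(2) ** 2 / 2)  # = 2.44211...
        assert np.isclose(res.waic, exact, atol=1e-12)
        assert round(res.waic, 4) == 2.4421

    def test_additive_over_individuals(self):
        rng = np.random.default_rng(1)
        ll = -rng.exponential(size=(6, 2))
        both = fl.waic(ll)
        one = fl.waic(ll[:, [0]])
        two = fl.waic(ll[:, [1]])
        assert np.isclose(both.waic, one.waic + two.waic)

    def test_matches_brute_force_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ll = -rng.exponential(size=(5, 4))
            res = fl.waic(ll)
            waic, lppd, p = brute_force_waic(ll)
            assert abs(res.waic - waic) < 1e-10
            assert abs(res.lppd - lppd) < 1e-10
            assert abs(res.p_waic - p) < 1e-10

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2 draws"):
            fl.waic(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="finite"):
            fl.waic(np.array([[0.0, -np.inf], [0.0, 0.0]]))


def _waic_result(value, n=10):
    return WaicResult(waic=value, lppd=-value / 2, p_waic=0.0,
                      pointwise_lppd=np.zeros(n), pointwise_p=np.zeros(n),
                      n_individuals=n)


class TestRankModels:
    def test_orders_ascending(self):
        out = fl.rank_models({"A": _waic_result(10.0), "B": _waic_result(5.0)},
                             component_counts={"A": 3, "B": 5})
        assert out == ["B", "A"]

    def test_tie_prefers_fewer_components(self):
        out = fl.rank_models({"A": _waic_result(5.0), "B": _waic_result(5.0)},
                             component_counts={"A": 9, "B": 2})
        assert out == ["B", "A"]

    def test_mismatched_individuals_error(self):
        with pytest.raises(ValueError, match="different individual"):
            fl.rank_models({"A": _waic_result(1.0, n=10), "B": _waic_result(2.0, n=11)})


class TestVariancePartition:
    def test_equal_components_symmetric(self):
        spec = fl.get_model_spec("IM2")
        draws = {c: np.full(50, 0.3) for c in spec.random_components}
        part = fl.variance_partition(draws, spec)
        assert np.allclose(part["mean"], 0.1)

    def test_simple_ratio(self):
        spec = fl.get_model_spec("LM0")
        part = fl.variance_partition(
            {"h": np.full(20, np.sqrt(3.0)), "e": np.ones(20)}, spec)
        assert np.isclose(part.loc["h2", "mean"], 0.75)
        assert np.isclose(part.loc["e2", "mean"], 0.25)

    def test_fractions_sum_to_one_probit(self):
        rng = np.random.default_rng(5)
        spec = fl.get_model_spec("IM1")
        draws = {c: rng.exponential(size=100) for c in spec.random_components}
        part = fl.variance_partition(draws, spec)
        assert np.isclose(part["mean"].sum(), 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        spec = fl.get_model_spec("LM1")
        draws = {c: rng.exponential(size=50) + 0.1 for c in spec.random_components}
        p1 = fl.variance_partition(draws, spec)
        p2 = fl.variance_partition({c: 7.3 * v for c, v in draws.items()}, spec)
        assert np.allclose(p1["mean"], p2["mean"])

    def test_signed_draws_equivalent(self):
        # scales are signed internally; fractions see only sigma^2
        spec = fl.get_model_spec("LM0")
        p1 = fl.variance_partition({"h": np.full(9, 0.8), "e": np.ones(9)}, spec)
        p2 = fl.variance_partition({"h": np.full(9, -0.8), "e": np.ones(9)}, spec)
        assert np.allclose(p1["mean"], p2["mean"])

    def test_logit_folds_logistic_residual(self):
        spec = fl.ModelSpec("LM0", frozenset({"h", "e"}), "none", "logit")
        part = fl.variance_partition({"h": np.ones(5), "e": np.ones(5) * 1e-9}, spec)
        expected_h2 = 1.0 / (1.0 + np.pi**2 / 3)
        assert np.isclose(part.loc["h2", "mean"], expected_h2, atol=1e-6)

    def test_inactive_component_absent_not_zero(self):
        spec = fl.get_model_spec("LM0")
        part = fl.variance_partition({"h": np.ones(5), "e": np.ones(5)}, spec)
        assert "c2" not in part.index
        assert set(part.index) == {"h2", "e2"}

    def test_missing_active_component_error(self):
        spec = fl.get_model_spec("LM0")
        with pytest.raises(ValueError, match="lack active"):
            fl.variance_partition({"e": np.ones(5)}, spec)


class TestTetrachoric:
    def test_recovers_known_correlation(self):
        rng = np.random.default_rng(8)
        rho, thr = 0.45, 1.2
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=150_000)
        x, y = (z[:, 0] > thr).astype(int), (z[:, 1] > thr).astype(int)
        est = fl.tetrachoric_correlation(x, y)
        assert abs(est - rho) < 0.04

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(9)
        x = (rng.random(50_000) < 0.2).astype(int)
        y = (rng.random(50_000) < 0.2).astype(int)
        assert abs(fl.tetrachoric_correlation(x, y)) < 0.05

    def test_degenerate_margin_error(self):
        with pytest.raises(ValueError):
            fl.tetrachoric_correlation(np.zeros(10, int), np.ones(10, int))


class TestEffectCurvePower:
    def test_strong_monotone_effect_detected_at_extremes(self):
        """A strong linear air-quality effect produces a significant
        segment at high percentiles, and the 50th-percentile reference
        pins the curve at zero."""
        from famliab.inference import McmcConfig

        truth = fl.TruthConfig(
            n_families=1500, n_counties=80,
            sigma2={"h": 0.3, "f": 0.05, "c": 0.03, "s": 0.02, "p": 0.005,
                    "e": 0.2},
            beta_eqi=(0.5, 0.0, 0.0, 0.0, 0.0),
            seed=81)
        cohort, eqi_table, _ = fl.simulate_cohort(truth)
        cfg = McmcConfig(n_chains=2, n_warmup=500, n_samples=250, seed=4,
                         store_loglik=False)
        d = fl.fit(cohort, eqi_table, fl.get_model_spec("LM2"), cfg=cfg)
        curve = fl.effect_curve(d, "air")

        ref = int(np.argmin(np.abs(curve.grid - 50.0)))
        assert abs(curve.mean[ref]) < 1e-9
        assert curve.hi[ref] - curve.lo[ref] < 1e-9

        high = curve.grid >= 80.0
        flags = np.zeros(len(curve.grid), dtype=bool)
        for s, e, sig in curve.segments:
            flags |= (curve.grid >= s) & (curve.grid <= e) & sig
        assert flags[high].any(), curve.segments
        # and the fitted difference is increasing overall
        assert curve.mean[-1] > curve.mean[0]
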