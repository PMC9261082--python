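import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import famliab as fl
from famliab.simulate import (simulate_counties, simulate_family_structure,
                              simulate_genetic_latents,
                              simulate_liability_and_outcome)


class TestCounties:
    def test_seeded_determinism(self):
        m1, t1 = simulate_counties(50, 10, seed=1)
        m2, t2 = simulate_counties(50, 10, seed=1)
        assert np.array_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noise_free_factor_gives_rank_one(self):
        m, _ = simulate_counties(40, 8, seed=3, factor_share=1.0)
        res = fl.compute_eqi(m)
        assert np.isclose(res.variance_explained_pc1, 1.0)

    def test_one_factor_variance_share(self):
        """PC1 share approaches (1 + (p-1) rho) / p for a one-factor model."""
        m, _ = simulate_counties(400, 30, seed=7, factor_share=0.5)
        res = fl.compute_eqi(m)
        expected = (1 + 29 * 0.5) / 30
        assert abs(res.variance_explained_pc1 - expected) < 0.06

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            simulate_counties(2, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_counties(10, 1, seed=0)


class TestGeneticLatents:
    def test_midparent_construction(self, small_sim):
        _, cohort, _, _ = small_sim
        A = simulate_genetic_latents(cohort, 5)
        ix = cohort.index_arrays()
        child = ix["is_child"]
        mid = 0.5 * (A[ix["father_pos"]] + A[ix["mother_pos"]])[ix["fam"][child]]
        resid = A[child] - mid
        # segregation noise has variance ~ 1/2 and is centred
        assert abs(resid.var() - 0.5) < 0.1
        assert abs(resid.mean()) < 0.1

    def test_kinship_moments_large_sample(self):
        truth = fl.TruthConfig(n_families=20_000, n_counties=10, seed=4)
        cohort = simulate_family_structure(truth)
        A = simulate_genetic_latents(cohort, 11)
        ix = cohort.index_arrays()
        child = ix["is_child"]
        fam = ix["fam"]
        father = A[ix["father_pos"][fam[child]]]
        kid = A[child]
        assert abs(np.corrcoef(father, kid)[0, 1] - 0.5) < 0.02
        assert abs(kid.var() - 1.0) < 0.03
        assert abs(A[ix["father_pos"]] @ A[ix["mother_pos"]]
                   / len(ix["father_pos"])) < 0.02  # spouses unrelated


class TestLiability:
    def test_intercept_only_prevalence(self):
        truth = fl.TruthConfig(n_families=20_000, n_counties=20,
                               sigma2={"h": 1e-12, "e": 1.0},
                               intercept=special.ndtri(0.2), seed=9)
        cohort, eqi, meta = fl.simulate_cohort(truth)
        # with unit total variance, prevalence = Phi(intercept)
        assert abs(meta["realized_prevalence_pct"] / 100 - 0.2) < 0.01

    def test_couple_terms_touch_parents_only(self, small_sim):
        truth0, cohort, eqi, _ = small_sim
        truth = dataclasses.replace(
            truth0, sigma2={"h": 1e-12, "e": 1e-6, "c": 1e-12, "hc": 4.0})
        out, lat = simulate_liability_and_outcome(cohort, truth, eqi)
        ix = cohort.index_arrays()
        eta = out["liability"].to_numpy() - lat["intercept"]
        child_eta = eta[ix["is_child"]]
        # children carry only the (tiny) h and e pieces, no hc contribution
        assert np.abs(child_eta).max() < 0.1
        assert np.abs(eta[~ix["is_child"]]).max() > 0.5

    def test_pairwise_liability_covariance_closed_form(self):
        """Without interactions, pair covariance = sum of sigma2 over shared
        layers plus kinship-weighted genetics, for all six pair types."""
        sig = {"h": 0.4, "f": 0.15, "c": 0.1, "s": 0.12, "p": 0.05, "e": 0.18}
        truth = fl.TruthConfig(n_families=40_000, n_counties=5, sigma2=sig, seed=13)
        cohort, eqi, _ = fl.simulate_cohort(truth)
        out, lat = simulate_liability_and_outcome(cohort, truth, eqi)
        ix = cohort.index_arrays()
        eta = out["liability"].to_numpy()
        fam = ix["fam"]
        child = ix["is_child"]
        fpos, mpos = ix["father_pos"], ix["mother_pos"]

        first_child = np.full(len(fpos), -1)
        second_child = np.full(len(fpos), -1)
        for pos in np.flatnonzero(child)[::-1]:
            f = fam[pos]
            second_child[f] = first_child[f]
            first_child[f] = pos

        def cov(a_pos, b_pos):
            ok = (a_pos >= 0) & (b_pos >= 0)
            x, y = eta[a_pos[ok]], eta[b_pos[ok]]
            return np.cov(x, y)[0, 1]

        shared_place = sig["p"]
        expected = {
            "spouse": sig["f"] + sig["c"] + shared_place,
            "father_child": 0.5 * sig["h"] + sig["f"] + shared_place,
            "sibling": 0.5 * sig["h"] + sig["f"] + sig["s"] + shared_place,
        }
        got = {
            "spouse": cov(fpos, mpos),
            "father_child": cov(fpos, first_child),
            "sibling": cov(first_child, second_child),
        }
        for pair, want in expected.items():
            assert abs(got[pair] - want) < 0.03, pair

    def test_marginal_variance_sums_per_role(self):
        """Each individual's liability variance is the sum of the sigma2 of
        the layers that individual carries: couple terms for parents,
        sibling terms for children, everything else for everyone."""
        sig = {"h": 0.3, "f": 0.1, "c": 0.05, "s": 0.05, "p": 0.02, "e": 0.2,
               "hf": 0.08, "hc": 0.1, "hs": 0.04, "he": 0.06}
        truth = fl.TruthConfig(n_families=30_000, n_counties=40, sigma2=sig, seed=17)
        cohort, eqi, _ = fl.simulate_cohort(truth)
        out, _ = simulate_liability_and_outcome(cohort, truth, eqi)
        eta = out["liability"].to_numpy()
        ix = cohort.index_arrays()
        total = truth.total_variance
        v_parent = total - sig["s"] - sig["hs"]
        v_child = total - sig["c"] - sig["hc"]
        assert abs(eta[ix["is_parent"]].var() - v_parent) < 0.03
        assert abs(eta[ix["is_child"]].var() - v_child) < 0.03

    def test_bit_reproducibility(self):
        truth = fl.TruthConfig(n_families=200, n_counties=10, seed=23)
        c1, e1, m1 = fl.simulate_cohort(truth)
        c2, e2, m2 = fl.simulate_cohort(truth)
        pd.testing.assert_frame_equal(c1.df, c2.df)
        pd.testing.assert_frame_equal(e1, e2)
        assert m1["config_hash"] == m2["config_hash"]


class TestCalibrateIntercept:
    def test_probit_closed_form(self):
        t = fl.TruthConfig(sigma2={"h": 0.5, "e": 0.5}, target_prevalence=0.5)
        assert np.isclose(fl.calibrate_intercept(t), 0.0)
        t = fl.TruthConfig(sigma2={"h": 0.5, "e": 0.5}, target_prevalence=0.1587)
        assert np.isclose(fl.calibrate_intercept(t), special.ndtri(0.1587))
        t = fl.TruthConfig(sigma2={"h": 2.0, "e": 2.0}, target_prevalence=0.0019)
        assert np.isclose(fl.calibrate_intercept(t), 2.0 * special.ndtri(0.0019))

    def test_logit_root_matches_simulation(self):
        t = fl.TruthConfig(sigma2={"h": 0.6, "e": 0.4}, link="logit",
                           target_prevalence=0.08)
        b = fl.calibrate_intercept(t)
        rng = np.random.default_rng(3)
        draws = special.expit(b + rng.standard_normal(400_000))
        assert abs(draws.mean() - 0.08) < 0.002

    def test_config_validation(self):
        with pytest.raises(ValueError):
            fl.TruthConfig(sigma2={"h": 0.5})           # no e component
        with pytest.raises(ValueError):
            fl.TruthConfig(sigma2={"h": -0.1, "e": 1.0})
        with pytest.raises(ValueError):
            fl.TruthConfig(target_prevalence=0.9)


def test_shipped_truth_configs_load():
    im2 = fl.load_truth_config("im2_recovery")
    assert np.isclose(sum(im2.sigma2.values()), 1.0)
    assert np.isclose(im2.sigma2["h"], 0.46)
    assert np.isclose(im2.sigma2["hc"], 0.21)
    assert np.isclose(im2.sigma2["p"], 0.005)
    assert np.isclose(sum(im2.sigma2[k] for k in ("hf", "hc", "hs", "he")), 0.35)
    lm0 = fl.load_truth_config("lm0_recovery")
    assert np.isclose(lm0.sigma2["h"], 0.79)
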