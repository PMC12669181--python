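"""Bayesian path model: sampling, diagnostics, derived effects, comparisons.

Fits in this module use reduced sampler settings (4 chains, 250 warmup, 750
retained) — the release default is 4 x (1,000 + 5,000).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fosnet.datasets import MicrocircuitSpec, generate_dg_microcircuit
from fosnet.mediation import (
    EffectSummary,
    PathModelSpec,
    PosteriorDraws,
    derived_effects,
    dic,
    fit_path_model,
    group_difference,
    information_criteria,
    multigroup_fit_compare,
    posterior_predictive_p,
    r_squared_gc,
    rhat,
)

from oracles import microcircuit_covariance

FAST = dict(chains=4, warmup=250, draws=750)
TRUTH = dict(a1=-0.5, a2=0.5, b1=0.6, b2=-0.7, b3=0.3)


def truth_data(n: int, seed: int, **overrides) -> pd.DataFrame:
    return generate_dg_microcircuit(
        MicrocircuitSpec(**{**TRUTH, **overrides}, n_animals=n, seed=seed)
    )


def fake_posterior(params: dict[str, np.ndarray]) -> PosteriorDraws:
    chains, draws = next(iter(params.values())).shape
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.standard_normal((20, 4)), columns=["MC", "PV_H", "PV_GL", "GC"]
    )
    return PosteriorDraws(
        params=params, spec=PathModelSpec(), data=data, seed=0,
        chains=chains, warmup=0, draws=draws,
    )


class TestFit:
    def test_deterministic_under_seed(self):
        data = truth_data(60, seed=1)
        f1 = fit_path_model(data, **FAST, seed=5)
        f2 = fit_path_model(data, **FAST, seed=5)
        for name in f1.params:
            np.testing.assert_array_equal(f1.params[name], f2.params[name])

    def test_recovers_generator_coefficients(self):
        data = truth_data(2000, seed=2)
        fit = fit_path_model(data, **FAST, seed=0, standardize=False)
        for name, true in [("a1", -0.5), ("a2", 0.5), ("b1", 0.6), ("b2", -0.7), ("b3", 0.3)]:
            assert fit.params[name].mean() == pytest.approx(true, abs=0.05)
        for name in ("sigma_MC", "sigma_PV_GL", "sigma_GC"):
            assert fit.params[name].mean() == pytest.approx(1.0, abs=0.05)

    def test_pure_noise_outcome_covers_zero(self):
        data = truth_data(2000, seed=3)
        rng = np.random.default_rng(4)
        data["GC"] = rng.standard_normal(len(data))
        fit = fit_path_model(data, **FAST, seed=1)
        for name in ("b1", "b2", "b3"):
            lo, hi = np.percentile(fit.stacked(name), [2.5, 97.5])
            assert lo < 0 < hi

    def test_rejects_bad_inputs(self):
        data = truth_data(20, seed=4)
        with pytest.raises(ValueError, match="non-finite"):
            fit_path_model(data.assign(GC=np.nan), **FAST)
        with pytest.raises(ValueError, match="at least 4"):
            fit_path_model(data.head(3), **FAST)
        with pytest.raises(ValueError, match="model_id"):
            PathModelSpec(model_id="bogus")
        with pytest.raises(ValueError, match="causal order"):
            PathModelSpec(
                model_id="custom",
                equations=(("GC", ("MC",)), ("MC", ("PV_H",))),
            )

    def test_model2_fits_single_equation(self):
        data = truth_data(200, seed=5)
        fit = fit_path_model(data, PathModelSpec(model_id="model2_direct_only"), **FAST)
        assert set(fit.params) == {"b1", "b2", "b3", "sigma_GC"}


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(6)
        post = fake_posterior({"a1": rng.standard_normal((4, 1000))})
        assert 0.99 < rhat(post)["a1"] < 1.02

    def test_offset_chain_detected(self):
        rng = np.random.default_rng(7)
        draws = rng.standard_normal((4, 1000))
        draws[0] += 10.0
        post = fake_posterior({"a1": draws})
        assert rhat(post)["a1"] > 1.5

    def test_single_chain_rejected(self):
        post = fake_posterior({"a1": np.zeros((1, 100))})
        with pytest.raises(ValueError):
            rhat(post)

    def test_real_fit_converges(self):
        fit = fit_path_model(truth_data(200, seed=8), **FAST, seed=2)
        assert max(rhat(fit).values()) < 1.01


class TestPosteriorPredictive:
    def test_true_model_is_calibrated(self):
        fit = fit_path_model(truth_data(200, seed=9), **FAST, seed=3)
        ppp = posterior_predictive_p(fit, max_draws=500, seed=0)
        assert 0.2 <= ppp <= 0.8

    def test_omitted_path_misfit_detected(self):
        # structural misspecification: the data carry a strong direct
        # PV_H -> PV_GL path that the model cannot represent
        rng = np.random.default_rng(10)
        n = 200
        pvh = rng.standard_normal(n)
        mc = -0.5 * pvh + rng.normal(0, 1, n)
        pvgl = 0.5 * mc + 1.2 * pvh + rng.normal(0, 1, n)
        gc = 0.6 * mc - 0.7 * pvgl + 0.3 * pvh + rng.normal(0, 1, n)
        bad = pd.DataFrame({"MC": mc, "PV_H": pvh, "PV_GL": pvgl, "GC": gc})
        fit = fit_path_model(bad, **FAST, seed=4)
        assert posterior_predictive_p(fit, max_draws=500, seed=0) < 0.05


class TestInformationCriteria:
    def test_waic_prefers_true_model(self):
        data = truth_data(100, seed=11)  # omitted path b2 has |beta| = 0.7
        omitting = PathModelSpec(
            model_id="model1_with_indirect",
            equations=(("MC", ("PV_H",)), ("PV_GL", ("MC",)), ("GC", ("MC", "PV_H"))),
        )
        ic_true = information_criteria(fit_path_model(data, **FAST, seed=5))
        ic_omit = information_criteria(fit_path_model(data, omitting, **FAST, seed=5))
        assert ic_true.waic < ic_omit.waic

    def test_waic_and_looic_agree_when_stable(self):
        fit = fit_path_model(truth_data(200, seed=12), **FAST, seed=6)
        ic = information_criteria(fit)
        assert abs(ic.waic - ic.looic) < 2.0

    def test_duplicating_observations_doubles_deviance_scale(self):
        data = truth_data(200, seed=13)
        doubled = pd.concat([data, data], ignore_index=True)
        ic1 = information_criteria(fit_path_model(data, chains=2, **{k: v for k, v in FAST.items() if k != "chains"}, seed=7))
        ic2 = information_criteria(fit_path_model(doubled, chains=2, **{k: v for k, v in FAST.items() if k != "chains"}, seed=7))
        for a, b in zip(ic2, ic1):
            assert a / b == pytest.approx(2.0, abs=0.1)


class TestDerivedEffects:
    def test_degenerate_a2_zeroes_indirect(self):
        shape = (2, 100)
        rng = np.random.default_rng(14)
        params = {
            name: rng.standard_normal(shape)
            for name in ("a1", "b1", "b2", "b3")
        }
        params["a2"] = np.zeros(shape)
        params |= {f"sigma_{v}": np.ones(shape) for v in ("MC", "PV_GL", "GC")}
        eff = derived_effects(fake_posterior(params))
        assert (eff.draws["indirect MC->PV_GL->GC"] == 0).all()

    def test_indirect_matches_product_of_paths_oracle(self):
        data = truth_data(2000, seed=15)
        fit = fit_path_model(data, **FAST, seed=8)
        eff = derived_effects(fit)
        cov = microcircuit_covariance(**TRUTH)
        expected = (
            TRUTH["a2"] * TRUTH["b2"]
            * np.sqrt(cov[("MC", "MC")]) / np.sqrt(cov[("GC", "GC")])
        )
        row = eff.table.set_index("effect").loc["indirect MC->PV_GL->GC"]
        assert row.beta == pytest.approx(expected, abs=0.05)
        assert row.significant

    def test_indirect_draws_are_exact_products(self):
        fit = fit_path_model(truth_data(80, seed=16), **FAST, seed=9)
        eff = derived_effects(fit)
        np.testing.assert_array_equal(
            eff.draws["indirect MC->PV_GL->GC"],
            eff.draws["component a2"] * eff.draws["component b2"],
        )
        np.testing.assert_array_equal(
            eff.draws["total MC->GC"],
            eff.draws["component b1"] + eff.draws["indirect MC->PV_GL->GC"],
        )

    def test_standardized_betas_invariant_to_rescaling(self):
        data = truth_data(300, seed=17)
        scaled = data.copy()
        scaled["MC"] = scaled["MC"] * 37.0
        scaled["GC"] = scaled["GC"] * 0.01
        e1 = derived_effects(fit_path_model(data, **FAST, seed=10))
        e2 = derived_effects(fit_path_model(scaled, **FAST, seed=10))
        np.testing.assert_allclose(
            e1.table.beta.to_numpy(), e2.table.beta.to_numpy(), atol=1e-10
        )


class TestRSquared:
    def test_zero_paths_near_zero(self):
        data = truth_data(2000, seed=18, b1=0.0, b2=0.0, b3=0.0)
        fit = fit_path_model(data, **FAST, seed=11)
        assert r_squared_gc(fit) < 0.02

    def test_vanishing_residual_approaches_one(self):
        data = truth_data(500, seed=19, residual_sd=(1.0, 1.0, 0.01))
        fit = fit_path_model(data, **FAST, seed=12)
        assert r_squared_gc(fit) > 0.99

    def test_matches_analytic_variance_decomposition(self):
        cov = microcircuit_covariance(**TRUTH)
        expected = (cov[("GC", "GC")] - 1.0) / cov[("GC", "GC")]
        fit = fit_path_model(truth_data(2000, seed=20), **FAST, seed=13)
        assert r_squared_gc(fit) == pytest.approx(expected, abs=0.05)


class TestMultigroup:
    def test_identical_coefficients_prefer_restricted(self):
        groups = {
            g: truth_data(200, seed=40 + k) for k, g in enumerate(["A", "B"])
        }
        res = multigroup_fit_compare(groups, **FAST, seed=11)
        assert res["preferred"] == "restricted"
        assert set(res["free"]) == {"A", "B"}

    def test_different_b2_prefers_free(self):
        groups = {
            "A": truth_data(200, seed=50, b2=-1.0),
            "B": truth_data(200, seed=51, b2=0.0),
        }
        res = multigroup_fit_compare(groups, **FAST, seed=12)
        assert res["preferred"] == "free"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            multigroup_fit_compare({"A": truth_data(50, seed=52)}, **FAST)


class TestGroupDifference:
    def test_identical_posterior_nothing_flagged(self):
        fit = fit_path_model(truth_data(100, seed=21), **FAST, seed=14)
        out = group_difference(fit, fit)
        assert (out.diff_mean == 0).all()
        assert not out.flagged.any()
        # all difference mass sits exactly at zero for identical posteriors
        np.testing.assert_allclose(out.p_gt_0 + out.p_lt_0, 0.0)

    def test_changed_equation_flagged_selectively(self):
        # groups differ only in b2; upstream equations (a1, a2) must not flag
        fa = fit_path_model(truth_data(200, seed=50, b2=-1.0), **FAST, seed=15)
        fb = fit_path_model(truth_data(200, seed=51, b2=0.0), **FAST, seed=16)
        out = group_difference(fa, fb).set_index("parameter")
        assert out.loc["b2", "flagged"]
        assert not out.loc["a1", "flagged"] and not out.loc["a2", "flagged"]
        # continuous draws: essentially no mass exactly at zero
        np.testing.assert_allclose(out.p_gt_0 + out.p_lt_0, 1.0, atol=1e-9)

    def test_disjoint_parameters_rejected(self):
        f1 = fit_path_model(truth_data(50, seed=22), **FAST, seed=17)
        f2 = fit_path_model(
            truth_data(50, seed=23), PathModelSpec(model_id="model2_direct_only"),
            **FAST, seed=18,
        )
        out = group_difference(f1, f2)
        assert set(out.parameter) == {"b1", "b2", "b3"}  # the shared paths
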