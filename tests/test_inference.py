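"""Composite likelihood, ECM fitting, model comparison and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stepstone.coalescent import simulate_snp_sfs
from stepstone.demography import DemeConfig, Demography, split
from stepstone.inference import (
    aic_from_log10,
    compare_models,
    composite_log_likelihood,
    fit_model_ecm,
    fit_with_restarts,
    parametric_bootstrap_ci,
    profile_likelihood,
)
from stepstone.models import BEST_FIT_SE_NC_ADMIX, build_named_model
from stepstone.sfs import SFS

FIVE = ("SW", "SE", "C", "NC", "N")
FIX_N = {f"N_{k}": 2000.0 for k in FIVE}


@pytest.fixture(scope="module")
def obs_bestfit(bestfit_demography):
    return simulate_snp_sfs(bestfit_demography, n_snps=4000, n_trees=1500, seed=88)


class TestCompositeLikelihood:
    def test_all_mass_on_certain_cell_scores_zero(self):
        counts = np.zeros((3, 3))
        counts[1, 1] = 50
        probs = np.zeros((3, 3))
        probs[1, 1] = 1.0
        obs = SFS(("a", "b"), counts)
        assert composite_log_likelihood(obs, probs, p_min=1e-8) == 0.0

    def test_hand_case(self):
        obs = SFS(("p",), np.array([0.0, 3.0, 1.0, 0.0]))
        probs = np.array([0.0, 0.75, 0.25, 0.0])
        expected = 3 * np.log(0.75) + 1 * np.log(0.25)
        assert composite_log_likelihood(obs, probs, 1e-9) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        obs = SFS(("p",), np.zeros(4))
        with pytest.raises(ValueError, match="shape"):
            composite_log_likelihood(obs, np.zeros(5), 1e-9)

    def test_p_min_floors_unseen_cells(self):
        obs = SFS(("p",), np.array([0.0, 1.0, 1.0, 0.0]))
        probs = np.array([0.0, 1.0, 0.0, 0.0])
        val = composite_log_likelihood(obs, probs, p_min=1e-4)
        assert val == pytest.approx(np.log(1e-4))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_gibbs_inequality(self, seed):
        """No probability vector beats the empirical proportions."""
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 20, size=8).astype(float)
        m[0] = m[-1] = 0.0
        if m.sum() == 0:
            return
        obs = SFS(("p",), m)
        mle = m / m.sum()
        q = rng.random(8)
        q[0] = q[-1] = 0.0
        q /= q.sum()
        best = composite_log_likelihood(obs, mle, 1e-300)
        other = composite_log_likelihood(obs, q, 1e-300)
        assert best >= other - 1e-9


class TestAIC:
    def test_natural_log_convention(self):
        from stepstone.inference import FitResult

        f = FitResult(model="m", params={}, lnCL=-100.0, k=3, n_sims=100)
        assert f.AIC == 2 * 3 - 2 * (-100.0)

    def test_log10_converter(self):
        assert aic_from_log10(3, -100.0) == pytest.approx(6 + 2 * np.log(10) * 100)


class TestECM:
    def test_single_free_parameter_recovery(self, obs_bestfit):
        """With everything else pinned at truth, the free admixture
        fraction comes back within 10% of its simulation value."""
        fixed = {k: v for k, v in BEST_FIT_SE_NC_ADMIX.items() if k != "alpha_SE"}
        fit = fit_model_ecm(
            "model4_SE_NC_admix", obs_bestfit, n_sims=5000, cycles=2, seed=4,
            fixed=fixed, line_search_iters=10,
        )
        assert fit.params["alpha_SE"] == pytest.approx(0.37, rel=0.10)

    def test_trace_non_decreasing_under_crn(self, obs_bestfit):
        fixed = {k: v for k, v in BEST_FIT_SE_NC_ADMIX.items()
                 if k not in ("alpha_SE", "T4")}
        fit = fit_model_ecm(
            "model4_SE_NC_admix", obs_bestfit, n_sims=500, cycles=3, seed=5,
            fixed=fixed, crn_across_cycles=True,
        )
        assert all(b >= a - 1e-9 for a, b in zip(fit.trace, fit.trace[1:]))

    def test_seed_determinism(self, obs_bestfit):
        fixed = {k: v for k, v in BEST_FIT_SE_NC_ADMIX.items() if k != "T3"}
        kw = dict(n_sims=300, cycles=1, seed=11, fixed=fixed)
        a = fit_model_ecm("model4_SE_NC_admix", obs_bestfit, **kw)
        b = fit_model_ecm("model4_SE_NC_admix", obs_bestfit, **kw)
        assert a.params == b.params and a.lnCL == b.lnCL and a.trace == b.trace

    def test_best_of_restarts_dominates(self, obs_bestfit):
        fixed = {k: v for k, v in BEST_FIT_SE_NC_ADMIX.items() if k != "alpha_NC"}
        fits = fit_with_restarts(
            "model4_SE_NC_admix", obs_bestfit, n_restarts=3, seed=7,
            n_sims=300, cycles=1, fixed=fixed,
        )
        best = max(f.lnCL for f in fits)
        assert all(best >= f.lnCL for f in fits)


class TestCompare:
    def _fit(self, model, lnCL, k=4, obs_hash="h"):
        from stepstone.inference import FitResult

        return FitResult(model=model, params={}, lnCL=lnCL, k=k, n_sims=1,
                         obs_hash=obs_hash)

    def test_equal_lnCL_smaller_k_wins_by_4(self):
        rank = compare_models([self._fit("a", -100.0, k=5), self._fit("b", -100.0, k=7)])
        assert rank[0]["model"] == "a"
        assert rank[1]["delta_AIC"] == pytest.approx(4.0)

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            compare_models([self._fit("a", -1.0)])

    def test_different_obs_rejected(self):
        with pytest.raises(ValueError, match="different observed"):
            compare_models([self._fit("a", -1.0), self._fit("b", -2.0, obs_hash="g")])

    def test_best_restart_selected_per_model(self):
        rank = compare_models(
            [self._fit("a", -120.0), self._fit("a", -100.0), self._fit("b", -110.0)]
        )
        assert rank[0]["model"] == "a" and rank[0]["lnCL"] == -100.0


class TestProfile:
    def test_empty_grid_rejected(self, obs_bestfit):
        with pytest.raises(ValueError, match="empty"):
            profile_likelihood(
                "model4_SE_NC_admix", obs_bestfit, "T1", [], BEST_FIT_SE_NC_ADMIX
            )

    def test_argmax_near_truth(self, obs_bestfit):
        grid = np.geomspace(0.15, 0.85, 8)
        res = profile_likelihood(
            "model4_SE_NC_admix", obs_bestfit, "alpha_SE", grid,
            BEST_FIT_SE_NC_ADMIX, n_sims=1500, seed=3,
        )
        # within one geometric grid step of the simulated truth
        step = grid[1] / grid[0]
        assert abs(np.log(res["argmax"] / 0.37)) <= np.log(step) * 1.01

    def test_constraint_violating_points_masked(self, obs_bestfit):
        grid = [500.0, 900.0, 2000.0]  # 2000 > T3=1350 violates ordering
        res = profile_likelihood(
            "model4_SE_NC_admix", obs_bestfit, "T4", grid,
            BEST_FIT_SE_NC_ADMIX, n_sims=200, seed=3,
        )
        assert np.isneginf(res["lnCL"][2])
        assert res["argmax"] in (500.0, 900.0)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def toy(self):
        """One free split time on a small two-population model."""
        d = Demography(
            demes=(DemeConfig("X", 1000.0, 3), DemeConfig("Y", 1000.0, 3)),
            events=(split(2000.0, "Y", "X"),),
            mu=1e-8,
        )
        return d

    def test_degenerate_two_replicates_wellformed(self, obs_bestfit):
        from stepstone.inference import FitResult, obs_digest

        fit = FitResult(
            model="model4_SE_NC_admix",
            params=dict(BEST_FIT_SE_NC_ADMIX),
            lnCL=-1.0, k=1, n_sims=100, converged=True,
            obs_hash=obs_digest(obs_bestfit),
        )
        ci = parametric_bootstrap_ci(
            fit, obs_bestfit, n_boot=2, seed=1, refit_free=["alpha_SE"],
            n_sims=200, n_trees=200,
        )
        assert ci.lower["alpha_SE"] <= ci.upper["alpha_SE"]
        assert ci.n_boot == 2

    def test_unconverged_fit_rejected(self, obs_bestfit):
        from stepstone.inference import FitResult

        fit = FitResult(model="model1_stepping", params={}, lnCL=-1.0, k=1,
                        n_sims=10, converged=False)
        with pytest.raises(ValueError, match="unconverged"):
            parametric_bootstrap_ci(fit, obs_bestfit, n_boot=2)

    def test_intervals_widen_with_fewer_sites(self, bestfit_demography):
        """Less data, wider parametric-bootstrap intervals."""
        from stepstone.inference import FitResult, obs_digest

        widths = []
        for n_snps in (4000, 250):
            obs = simulate_snp_sfs(bestfit_demography, n_snps, 600, seed=19)
            fit = FitResult(
                model="model4_SE_NC_admix", params=dict(BEST_FIT_SE_NC_ADMIX),
                lnCL=-1.0, k=1, n_sims=100, converged=True,
                obs_hash=obs_digest(obs),
            )
            ci = parametric_bootstrap_ci(
                fit, obs, n_boot=8, seed=2, refit_free=["alpha_SE"],
                n_sims=400, n_trees=400,
            )
            widths.append(ci.upper["alpha_SE"] - ci.lower["alpha_SE"])
        assert widths[1] > widths[0]
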