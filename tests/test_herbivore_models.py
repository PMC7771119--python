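import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hostphylo import (
    ModelSpec,
    aicc,
    candidate_set,
    check_pi_leafarea_confounding,
    fit_lmm,
    guild_site_contrasts,
    lrt_vs_null,
    rank_and_select,
)
from hostphylo.herbivore_models import FitResult


def simulate_lmm_table(
    seed,
    n_plants=60,
    pi_slope=-0.5,
    site_offsets=(0.0, 1.0, -0.8),
    guild_effect=0.6,
    re_sd=0.3,
    resid_sd=0.2,
):
    """Plant x guild table drawn from a known mixed model (pi + site + guild)."""
    rng = np.random.default_rng(seed)
    sites = ["A", "B", "C"]
    site = rng.choice(sites, size=n_plants)
    pi = rng.normal(0, 1, n_plants)
    la = rng.normal(0, 1, n_plants)
    u = rng.normal(0, re_sd, n_plants)
    offsets = dict(zip(sites, site_offsets))
    rows = []
    for i in range(n_plants):
        for guild in ("exposed", "shelter"):
            mu = (
                1.0
                + pi_slope * pi[i]
                + offsets[site[i]]
                + (guild_effect if guild == "exposed" else 0.0)
                + u[i]
            )
            rows.append(
                {
                    "tree_id": f"pl{i:02d}",
                    "site": site[i],
                    "guild": guild,
                    "pi": pi[i],
                    "leaf_area_sqrt": la[i],
                    "value": mu + rng.normal(0, resid_sd),
                }
            )
    return pd.DataFrame(rows)


class TestCandidateSet:
    def test_twenty_specs(self):
        specs = candidate_set("richness")
        assert len(specs) == 20
        assert sum(s.is_null for s in specs) == 1
        assert sum(s.interaction for s in specs) == 4
        assert len(set(specs)) == 20

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ModelSpec("richness", ("guild",), interaction=True)


class TestAicc:
    def test_closed_form(self):
        assert aicc(-50.0, 4, 30) == pytest.approx(109.6)

    def test_limits_to_aic(self):
        aic = -2 * (-50.0) + 2 * 4
        assert aicc(-50.0, 4, 10**8) == pytest.approx(aic, abs=1e-6)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(-50.0, 4, 5)


class TestFitting:
    def test_null_model_fits_grand_mean(self):
        table = simulate_lmm_table(0)
        fit = fit_lmm(ModelSpec("richness"), table)
        assert fit.converged
        assert fit.coefficients["Intercept"] == pytest.approx(
            table["value"].mean(), abs=0.05
        )
        assert fit.k == 3

    def test_duplicated_predictor_rank_deficient(self):
        table = simulate_lmm_table(1)
        table["leaf_area_sqrt"] = table["pi"]
        with pytest.raises(ValueError, match="rank"):
            fit_lmm(ModelSpec("richness", ("pi", "leaf_area_sqrt")), table)

    def test_known_model_recovery_small(self):
        hits = 0
        for rep in range(10):
            table = simulate_lmm_table(100 + rep)
            fit = fit_lmm(ModelSpec("richness", ("pi", "site", "guild")), table)
            hits += abs(fit.coefficients["pi"] - (-0.5)) <= 2 * fit.bse["pi"]
        assert hits >= 8


class TestRanking:
    def _fit(self, response, label_fixed, aicc_value, k):
        spec = ModelSpec(response, label_fixed)
        return FitResult(
            spec, 40, k, np.nan, aicc_value,
            pd.Series(dtype=float), pd.Series(dtype=float), True,
        )

    def test_weights_for_delta_two(self):
        fits = [
            self._fit("richness", (), 100.0, 3),
            self._fit("richness", ("pi",), 102.0, 4),
        ]
        table, _ = rank_and_select(fits)
        np.testing.assert_allclose(
            table["weight"].to_numpy(), [0.7311, 0.2689], atol=5e-5
        )

    def test_identical_aicc_equal_weights(self):
        fits = [
            self._fit("richness", (), 100.0, 3),
            self._fit("richness", ("pi",), 100.0, 4),
        ]
        table, _ = rank_and_select(fits)
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_parsimony_rule_prefers_smaller_k(self):
        fits = [
            self._fit("richness", ("pi", "site"), 100.0, 6),
            self._fit("richness", ("pi",), 101.5, 4),
        ]
        _, best = rank_and_select(fits)
        assert best.k == 4

    def test_weights_sum_to_one(self):
        fits = [
            self._fit("richness", sub, 100 + 3 * i, 3 + i)
            for i, sub in enumerate([(), ("pi",), ("site",), ("guild",)])
        ]
        table, _ = rank_and_select(fits)
        assert table["weight"].sum() == pytest.approx(1.0)


class TestLRT:
    def test_best_equals_null(self):
        table = simulate_lmm_table(2)
        null = fit_lmm(ModelSpec("richness"), table)
        out = lrt_vs_null(null, null)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == 1.0

    def test_chi2_tail_value(self):
        # chi2=10, df=1
        assert stats.chi2.sf(10, 1) == pytest.approx(0.001565, abs=1e-6)
        table = simulate_lmm_table(3)
        null = fit_lmm(ModelSpec("richness"), table)
        best = fit_lmm(ModelSpec("richness", ("pi", "site", "guild")), table)
        out = lrt_vs_null(best, null)
        assert out["df"] == best.k - null.k
        assert 0 < out["p"] < 1e-6  # strong planted effects

    def test_nesting_violation_detected(self):
        table = simulate_lmm_table(4)
        null = fit_lmm(ModelSpec("richness"), table)
        worse = FitResult(
            ModelSpec("richness", ("pi",)), null.n_obs, 4, null.loglik - 5.0,
            np.nan, pd.Series(dtype=float), pd.Series(dtype=float), True,
        )
        with pytest.raises(ValueError):
            lrt_vs_null(worse, null)


class TestContrasts:
    def test_no_interaction_contrast_constant_across_sites(self):
        table = simulate_lmm_table(5)
        fit = fit_lmm(ModelSpec("richness", ("site", "guild")), table)
        out = guild_site_contrasts(fit, table)
        assert len(out) == 3
        np.testing.assert_allclose(
            out["estimate"], out["estimate"].iloc[0], atol=1e-9
        )

    def test_not_applicable_without_guild(self):
        table = simulate_lmm_table(6)
        fit = fit_lmm(ModelSpec("richness", ("pi",)), table)
        assert guild_site_contrasts(fit, table).empty

    def test_null_guild_difference_calibration(self):
        rejections = 0
        for rep in range(20):
            table = simulate_lmm_table(300 + rep, guild_effect=0.0)
            fit = fit_lmm(
                ModelSpec("richness", ("site", "guild"), interaction=True), table
            )
            out = guild_site_contrasts(fit, table)
            rejections += int((out["p_holm"] < 0.05).any())
        assert rejections <= 4  # ~alpha-level with Holm control


class TestPrecheck:
    def _community(self, seed, rho=0.0, n=60):
        rng = np.random.default_rng(seed)
        sites = rng.choice(["A", "B", "C"], size=n)
        pi = rng.normal(10, 3, n)
        sqrt_area = 5 + rho * (pi - 10) + rng.normal(0, 1.0, n)
        return pd.DataFrame(
            {"site": sites, "pi": pi, "leaf_area_m2": np.maximum(sqrt_area, 0.1) ** 2}
        )

    def test_exact_linear_relation_r2_one(self):
        comm = self._community(0)
        comm["leaf_area_m2"] = (2.0 + 0.5 * comm["pi"]) ** 2
        out = check_pi_leafarea_confounding(comm)
        assert out["r2_adj"] == pytest.approx(1.0, abs=1e-9)
        assert out["slope"] == pytest.approx(0.5, abs=1e-9)

    def test_null_slope_ci_coverage(self):
        covered = 0
        for rep in range(40):
            out = check_pi_leafarea_confounding(self._community(rep, rho=0.0))
            lo, hi = out["slope_ci"]
            covered += lo <= 0.0 <= hi
        assert covered >= 36  # >= 90%

    def test_negative_coupling_recovered(self):
        out = check_pi_leafarea_confounding(self._community(7, rho=-0.6))
        assert out["slope"] < 0
        assert out["p"] < 0.01

    def test_single_site_drops_covariate(self, caplog):
        comm = self._community(1).assign(site="only")
        out = check_pi_leafarea_confounding(comm)
        assert out["n"] == 60
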