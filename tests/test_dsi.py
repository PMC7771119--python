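import numpy as np
import pandas as pd
import pytest

from hostphylo import (
    DistanceMatrix,
    assemblage_mean_dsi,
    compute_specialization,
    dsi,
    dsi_lim,
    dsi_star,
    filter_rare_herbivores,
    null_mpd,
    observed_mpd,
)
from hostphylo.dsi import (
    DegenerateNullError,
    NullDistribution,
    max_mpd,
    n_compositions,
)

from _oracles import max_mpd_enumerate, mpd_pairs_oracle
from conftest import random_distance_matrix, two_host_distance


def make_null(mean, sd, n=100):
    # synthetic draws with exactly the requested moments
    half = np.full(n // 2, mean - sd * np.sqrt((n - 1) / n))
    draws = np.concatenate([half, 2 * mean - half])
    return NullDistribution(draws, n, seed=None)


class TestObservedMPD:
    def test_monophage_is_zero(self):
        D = two_host_distance()
        assert observed_mpd({"A": 5}, D) == 0.0

    def test_single_cross_pair(self):
        assert observed_mpd({"A": 1, "B": 1}, two_host_distance(2.0)) == pytest.approx(2.0)

    def test_two_and_two(self):
        # 4 cross pairs of d=2, 2 same-host pairs of 0, over 6 pairs
        assert observed_mpd({"A": 2, "B": 2}, two_host_distance(2.0)) == pytest.approx(8 / 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        D = random_distance_matrix(6, seed)
        rng = np.random.default_rng(seed)
        counts = {
            lab: int(c)
            for lab, c in zip(D.labels, rng.integers(0, 4, size=6))
            if c > 0
        }
        if sum(counts.values()) < 2:
            counts = {D.labels[0]: 1, D.labels[1]: 2}
        expected = mpd_pairs_oracle(counts, list(D.labels), D.values)
        assert observed_mpd(counts, D) == pytest.approx(expected, abs=1e-12)

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            observed_mpd({"A": 1}, two_host_distance())

    def test_unknown_host_rejected(self):
        with pytest.raises(KeyError):
            observed_mpd({"Z": 3}, two_host_distance())

    def test_leaf_area_weighting_single_host(self):
        areas = pd.Series({"A": 3.0, "B": 1.0})
        assert observed_mpd(
            {"A": 4}, two_host_distance(), weighting="host_leaf_area", leaf_areas=areas
        ) == 0.0


class TestNullMPD:
    def test_two_host_closed_form(self):
        # equal areas, d=2, n_i=2: MPD is 2 w.p. 1/2 else 0 -> mean 1, sd 1
        D = two_host_distance(2.0)
        areas = pd.Series({"A": 1.0, "B": 1.0})
        null = null_mpd(2, areas, D, n_iterations=100_000, seed=0)
        assert null.mean == pytest.approx(1.0, abs=0.02)
        assert null.sd == pytest.approx(1.0, abs=0.02)

    def test_zero_area_host_never_drawn(self):
        D = two_host_distance(2.0)
        areas = pd.Series({"A": 1.0, "B": 0.0})
        null = null_mpd(3, areas, D, n_iterations=500, seed=1)
        assert null.degenerate
        assert null.mean == 0.0 and null.sd == 0.0

    def test_seed_reproducibility(self):
        D = random_distance_matrix(5, 3)
        areas = pd.Series(1.0, index=list(D.labels))
        a = null_mpd(6, areas, D, n_iterations=99, seed=7)
        b = null_mpd(6, areas, D, n_iterations=99, seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestDSI:
    def test_formula_cases(self):
        null = make_null(1.0, 1.0)
        assert dsi(null.mean, null) == pytest.approx(0.0)
        assert dsi(0.0, null) == pytest.approx(1.0)
        assert dsi(2.0, null) == pytest.approx(-1.0)

    def test_degenerate_null_raises(self):
        null = NullDistribution(np.zeros(10), 10, None)
        with pytest.raises(DegenerateNullError):
            dsi(0.5, null)

    def test_monotone_in_observed_mpd(self):
        null = make_null(1.0, 0.5)
        values = [dsi(m, null) for m in np.linspace(0, 3, 7)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestDSILim:
    def test_two_host_hand_case(self):
        D = two_host_distance(2.0)
        null = make_null(1.0, 1.0)
        lim_min, lim_max, exact = dsi_lim(2, D, null)
        assert exact
        assert lim_max == pytest.approx(1.0)   # MPD_min = 0
        assert lim_min == pytest.approx(-1.0)  # MPD_max = 2 at {1,1}
        assert dsi_star(dsi(2.0, null), lim_min, lim_max) == pytest.approx(-1.0)

    def test_lim_max_is_positive_null_ratio(self):
        D = random_distance_matrix(5, 9)
        null = make_null(40.0, 13.0)
        _, lim_max, _ = dsi_lim(4, D, null)
        assert lim_max == pytest.approx(40.0 / 13.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        n_i = int(rng.integers(2, 7))
        D = random_distance_matrix(k, seed + 50)
        exact = max_mpd_enumerate(n_i, D.values)
        greedy, _ = max_mpd(n_i, D, composition_limit=0)  # force greedy
        assert greedy == pytest.approx(exact, rel=1e-9)

    def test_composition_count(self):
        assert n_compositions(2, 2) == 3  # {2,0},{1,1},{0,2}
        assert n_compositions(6, 5) == 210


class TestScoresTable:
    def test_monophage_scores_one(self):
        D = random_distance_matrix(5, 2)
        areas = pd.Series(np.linspace(1, 5, 5), index=list(D.labels))
        community = pd.DataFrame(
            {
                "site": "S1",
                "plant_species": list(D.labels),
                "leaf_area_m2": areas.to_numpy(),
                "n_tree_individuals": 1,
            }
        )
        records = pd.DataFrame(
            [
                ("S1", "t1", D.labels[0], "mono", "exposed", 5),
                ("S1", "t1", D.labels[0], "duo", "shelter", 3),
                ("S1", "t2", D.labels[3], "duo", "shelter", 3),
            ],
            columns=[
                "site", "tree_individual", "plant_species",
                "herbivore_species", "guild", "n_individuals",
            ],
        )
        scores = compute_specialization(
            records, community, {"S1": D}, n_iterations=199, seed=4
        ).set_index("herbivore_species")
        assert scores.loc["mono", "dsi_star"] == 1.0
        assert -1.0 <= scores.loc["duo", "dsi_star"] <= 1.0

    def test_proportional_sampler_has_mean_dsi_near_zero(self):
        # hosts drawn proportional to leaf area == the null; DSI centered on 0
        D = random_distance_matrix(8, 21)
        areas = pd.Series(
            np.random.default_rng(2).lognormal(0, 1, 8), index=list(D.labels)
        )
        rng = np.random.default_rng(3)
        p = (areas / areas.sum()).to_numpy()
        values = []
        for s in range(120):
            counts = rng.multinomial(20, p)
            mpd = observed_mpd(dict(zip(D.labels, counts)), D)
            null = null_mpd(20, areas, D, n_iterations=299, seed=1000 + s)
            values.append(dsi(mpd, null))
        values = np.asarray(values)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean()) <= 3 * se

    def test_reproducible_under_seed(self, small_dataset):
        filtered = filter_rare_herbivores(small_dataset.interactions)
        kw = dict(n_iterations=59, seed=9)
        a = compute_specialization(
            filtered, small_dataset.community, small_dataset.site_distances(), **kw
        )
        b = compute_specialization(
            filtered, small_dataset.community, small_dataset.site_distances(), **kw
        )
        pd.testing.assert_frame_equal(a, b)


class TestAssemblageMeanDSI:
    def test_hand_assigned_profiles(self):
        scores = pd.DataFrame(
            {
                "site": ["S1"] * 3,
                "herbivore_species": ["h1", "h2", "h3"],
                "dsi_star": [0.4, 0.6, -0.2],
                "degenerate": [False, False, False],
            }
        )
        records = pd.DataFrame(
            [
                ("S1", "t", "P1", "h1", "exposed", 3),
                ("S1", "t", "P1", "h2", "exposed", 3),
                ("S1", "t", "P2", "h3", "shelter", 3),
            ],
            columns=[
                "site", "tree_individual", "plant_species",
                "herbivore_species", "guild", "n_individuals",
            ],
        )
        out = assemblage_mean_dsi(scores, records)
        p1_all = out[
            (out["plant_species"] == "P1") & (out["guild_scope"] == "all")
        ].iloc[0]
        assert p1_all["mean_dsi_star"] == pytest.approx(0.5)
        assert p1_all["n_species"] == 2
        p2_shelter = out[
            (out["plant_species"] == "P2") & (out["guild_scope"] == "shelter")
        ].iloc[0]
        assert p2_shelter["mean_dsi_star"] == pytest.approx(-0.2)
        # P2 hosts no exposed species -> omitted from that scope
        assert out[
            (out["plant_species"] == "P2") & (out["guild_scope"] == "exposed")
        ].empty
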