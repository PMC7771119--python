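"""Distance-based specialization index (DSI, DSI_lim, DSI*).

A herbivore species' host-use specialization is measured against the
phylogeny and the availability of its local plant community:

* ``MPD_i`` — mean pairwise phylogenetic distance among the hosts of the
  species' individual records. The default is individual-based: with counts
  n_h on hosts h, the mean of d(host(a), host(b)) over all N(N-1)/2
  unordered pairs of individuals, same-host pairs contributing 0.
* ``Null_i`` — the availability-weighted null: each iteration re-allocates
  the same N individuals to hosts drawn with replacement with probability
  proportional to the host's summed leaf area (m2), and records the MPD of
  the draw.
* ``DSI_i = -(MPD_i - mean(Null_i)) / sd(Null_i)`` — a z-score with the
  sign flipped so that larger values mean *more* specialized (observed
  hosts more closely related than expected from availability alone).
* ``DSI_lim`` — the extreme achievable DSI values for the same N and null:
  the maximum corresponds to MPD = 0 (all individuals on one host), the
  minimum to the allocation maximizing MPD.
* ``DSI*_i = DSI_i / DSI_lim_max`` if DSI_i >= 0 else ``DSI_i / |DSI_lim_min|``
  — rescaled to [-1, 1], with 1 = maximum specialization (monophagy) and
  -1 = maximum generalization.

The score and both limits share a single null distribution per species, so
the monophage identity DSI* = 1 holds exactly rather than up to Monte-Carlo
error. Scores are computed independently per site.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hostphylo.interactions import GUILDS
from hostphylo.phylo_metrics import DistanceMatrix

logger = logging.getLogger(__name__)

#: Default number of null-model iterations per species.
DEFAULT_NULL_ITERATIONS = 999

#: Allocations are enumerated exhaustively for MPD_max while the number of
#: compositions of N individuals into k hosts stays at or below this bound;
#: beyond it a greedy local search takes over (flagged ``approximate_lim``).
COMPOSITION_LIMIT = 100_000


class DegenerateNullError(ValueError):
    """Null distribution has zero spread; DSI is undefined."""


@dataclass
class NullDistribution:
    """Monte-Carlo null distribution of MPD for one species' frequency N."""

    draws: np.ndarray
    n_iterations: int
    seed: int | None

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1))

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


@dataclass
class SpecializationScore:
    """Per-species specialization: observed MPD, DSI, limits and DSI*."""

    mpd: float
    dsi: float
    dsi_lim_min: float
    dsi_lim_max: float
    dsi_star: float
    exact_lim: bool
    degenerate: bool = False


def _counts_vector(
    counts: Mapping[str, int] | pd.Series, D: DistanceMatrix
) -> np.ndarray:
    vec = np.zeros(len(D.labels))
    for host, n in (counts.items() if hasattr(counts, "items") else counts):
        if host not in D._index:
            raise KeyError(f"host {host!r} not in distance matrix")
        if n < 0:
            raise ValueError("negative interaction count")
        vec[D._index[host]] = n
    return vec


def _mpd_quadratic(c: np.ndarray, D: np.ndarray) -> float:
    # individual-based MPD: sum_{a<b} d(host_a, host_b) / C(N,2)
    # = c' D c / (N (N-1)) since the diagonal of D is zero
    N = c.sum()
    return float(c @ D @ c / (N * (N - 1)))


def observed_mpd(
    counts: Mapping[str, int] | pd.Series,
    D: DistanceMatrix,
    weighting: str = "interaction_counts",
    leaf_areas: pd.Series | None = None,
) -> float:
    """Observed mean pairwise phylogenetic distance of a host-use profile.

    ``weighting="interaction_counts"`` (default) is the individual-based
    MPD over the species' records. ``weighting="host_leaf_area"`` instead
    weights host pairs by the community leaf areas of the utilized hosts
    (same-host pairs excluded), requiring ``leaf_areas``.
    """
    c = _counts_vector(counts, D)
    if weighting == "interaction_counts":
        if c.sum() < 2:
            raise ValueError("observed MPD needs at least 2 individual records")
        return _mpd_quadratic(c, D.values)
    if weighting == "host_leaf_area":
        if leaf_areas is None:
            raise ValueError("leaf_areas required for host_leaf_area weighting")
        used = c > 0
        if used.sum() < 1:
            raise ValueError("empty host-use profile")
        w = np.zeros_like(c)
        for i, lab in enumerate(D.labels):
            if used[i]:
                w[i] = float(leaf_areas[lab])
        denom = w.sum() ** 2 - (w**2).sum()
        if denom == 0:
            return 0.0  # single utilized host
        return float(w @ D.values @ w / denom)
    raise ValueError(f"unknown weighting {weighting!r}")


def null_mpd(
    n_i: int,
    leaf_areas: pd.Series,
    D: DistanceMatrix,
    n_iterations: int = DEFAULT_NULL_ITERATIONS,
    seed: int | None = None,
    mode: str = "with_replacement",
) -> NullDistribution:
    """Availability-weighted null distribution of MPD for frequency ``n_i``.

    Each iteration allocates ``n_i`` individuals to hosts drawn with
    replacement, probability proportional to leaf area, from all plant
    species of the site community, and records the individual-based MPD.
    ``mode="distinct_hosts"`` (experimental) instead draws ``n_i`` distinct
    hosts without replacement.
    """
    if n_i < 2:
        raise ValueError("null MPD needs n_i >= 2")
    areas = np.array([float(leaf_areas.get(lab, 0.0)) for lab in D.labels])
    if np.any(areas < 0) or not np.all(np.isfinite(areas)):
        raise ValueError("leaf areas must be finite and non-negative")
    if (areas > 0).sum() == 0:
        raise ValueError("no host with positive leaf area")
    probs = areas / areas.sum()
    rng = np.random.default_rng(seed)
    if (areas > 0).sum() == 1:
        logger.warning("single-host community: null MPD degenerate at 0")
        return NullDistribution(np.zeros(n_iterations), n_iterations, seed)
    if mode == "with_replacement":
        C = rng.multinomial(n_i, probs, size=n_iterations).astype(float)
        draws = np.einsum("ij,jk,ik->i", C, D.values, C) / (n_i * (n_i - 1))
    elif mode == "distinct_hosts":
        k = int((areas > 0).sum())
        if n_i > k:
            raise ValueError(
                f"distinct_hosts mode: n_i={n_i} exceeds {k} available hosts"
            )
        draws = np.empty(n_iterations)
        idx = np.arange(len(probs))
        for it in range(n_iterations):
            chosen = rng.choice(idx, size=n_i, replace=False, p=probs)
            c = np.bincount(chosen, minlength=len(probs)).astype(float)
            draws[it] = _mpd_quadratic(c, D.values)
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    return NullDistribution(draws, n_iterations, seed)


def dsi(mpd_obs: float, null: NullDistribution) -> float:
    """Sign-flipped z-score of observed MPD against its null.

    Positive = hosts more related than the availability-weighted
    expectation (specialization); negative = overdispersed host use.
    """
    if null.degenerate:
        raise DegenerateNullError(
            "null MPD distribution has zero spread; DSI undefined"
        )
    return -(mpd_obs - null.mean) / null.sd


def _max_mpd_exhaustive(n_i: int, D: np.ndarray) -> float:
    k = D.shape[0]
    best = 0.0
    # compositions of n_i into k non-negative parts
    for cuts in itertools.combinations(range(n_i + k - 1), k - 1):
        c = np.diff((-1, *cuts, n_i + k - 1)) - 1
        best = max(best, float(c @ D @ c))
    return best / (n_i * (n_i - 1))


def _max_mpd_greedy(n_i: int, D: np.ndarray) -> float:
    # start from an even split across the two most distant hosts, then
    # hill-climb on single-individual moves
    k = D.shape[0]
    a, b = np.unravel_index(np.argmax(D), D.shape)
    c = np.zeros(k)
    c[a] = math.ceil(n_i / 2)
    c[b] = n_i - c[a]
    obj = float(c @ D @ c)
    improved = True
    while improved:
        improved = False
        best_move, best_obj = None, obj
        for u in np.flatnonzero(c > 0):
            for v in range(k):
                if v == u:
                    continue
                c[u] -= 1
                c[v] += 1
                cand = float(c @ D @ c)
                c[u] += 1
                c[v] -= 1
                if cand > best_obj + 1e-12:
                    best_obj, best_move = cand, (u, v)
        if best_move is not None:
            u, v = best_move
            c[u] -= 1
            c[v] += 1
            obj = best_obj
            improved = True
    return obj / (n_i * (n_i - 1))


def n_compositions(n_i: int, k: int) -> int:
    """Number of allocations of ``n_i`` individuals to ``k`` hosts."""
    return math.comb(n_i + k - 1, k - 1)


def max_mpd(
    n_i: int, D: DistanceMatrix, composition_limit: int = COMPOSITION_LIMIT
) -> tuple[float, bool]:
    """Maximum individual-based MPD over all allocations; (value, exact)."""
    if n_i < 2:
        raise ValueError("n_i must be >= 2")
    if n_compositions(n_i, len(D.labels)) <= composition_limit:
        return _max_mpd_exhaustive(n_i, D.values), True
    return _max_mpd_greedy(n_i, D.values), False


def dsi_lim(
    n_i: int,
    D: DistanceMatrix,
    null: NullDistribution,
    composition_limit: int = COMPOSITION_LIMIT,
) -> tuple[float, float, bool]:
    """Extreme achievable DSI values under the species' own null.

    Returns ``(dsi_lim_min, dsi_lim_max, exact)``. The maximum comes from
    MPD = 0 (monophagy); the minimum from the allocation maximizing MPD,
    found exhaustively when the composition count permits and by greedy
    local search otherwise.
    """
    mpd_max, exact = max_mpd(n_i, D, composition_limit)
    return dsi(mpd_max, null), dsi(0.0, null), exact


def dsi_star(
    dsi_value: float, dsi_lim_min: float, dsi_lim_max: float, exact_lim: bool = True
) -> float:
    """Rescale DSI to [-1, 1] by the achievable extremes.

    Positive scores divide by the maximum, negative by the magnitude of the
    minimum. Clamping is applied only when the limits were approximate (a
    greedy MPD_max can undershoot), with a warning.
    """
    if dsi_value >= 0:
        out = dsi_value / dsi_lim_max
    else:
        out = dsi_value / abs(dsi_lim_min)
    if not exact_lim and not -1.0 <= out <= 1.0:
        logger.warning("DSI* %.4f outside [-1, 1] under approximate limits; clamped", out)
        out = min(1.0, max(-1.0, out))
    return out


def compute_specialization(
    records: pd.DataFrame,
    community: pd.DataFrame,
    site_distances: Mapping[str, DistanceMatrix],
    n_iterations: int = DEFAULT_NULL_ITERATIONS,
    seed: int | None = None,
    weighting: str = "interaction_counts",
    null_mode: str = "with_replacement",
    composition_limit: int = COMPOSITION_LIMIT,
) -> pd.DataFrame:
    """Specialization scores for every (site, herbivore species).

    Records must already be rare-species filtered. One independent,
    seed-derived null distribution is drawn per species and shared between
    its DSI and its limits. Species whose null is degenerate (single-host
    community) get NaN scores and ``degenerate=True`` rather than a silent 0.
    """
    keys = sorted(
        records.groupby(["site", "herbivore_species"]).groups.keys()
    )
    children = np.random.SeedSequence(seed).spawn(len(keys))
    rows = []
    for (site, herb), child in zip(keys, children):
        sub = records[(records["site"] == site) & (records["herbivore_species"] == herb)]
        counts = sub.groupby("plant_species")["n_individuals"].sum()
        guild = sub["guild"].iloc[0]
        n_i = int(counts.sum())
        D = site_distances[site]
        comm = community[community["site"] == site]
        areas = comm.set_index("plant_species")["leaf_area_m2"]
        child_seed = int(child.generate_state(1)[0] % (2**31))
        base = {
            "site": site,
            "herbivore_species": herb,
            "guild": guild,
            "n_i": n_i,
            "n_hosts": int((counts > 0).sum()),
        }
        if n_i < 2:
            logger.warning(
                "species %r at %r has n_i=%d < 2; specialization undefined",
                herb, site, n_i,
            )
            rows.append({**base, "mpd": np.nan, "null_mean": np.nan,
                         "null_sd": np.nan, "dsi": np.nan, "dsi_lim_min": np.nan,
                         "dsi_lim_max": np.nan, "dsi_star": np.nan,
                         "exact_lim": True, "degenerate": True})
            continue
        null = null_mpd(
            n_i, areas, D, n_iterations=n_iterations, seed=child_seed, mode=null_mode
        )
        mpd = observed_mpd(counts, D, weighting=weighting, leaf_areas=areas)
        if null.degenerate:
            rows.append({**base, "mpd": mpd, "null_mean": null.mean,
                         "null_sd": null.sd, "dsi": np.nan, "dsi_lim_min": np.nan,
                         "dsi_lim_max": np.nan, "dsi_star": np.nan,
                         "exact_lim": True, "degenerate": True})
            continue
        value = dsi(mpd, null)
        lim_min, lim_max, exact = dsi_lim(n_i, D, null, composition_limit)
        star = dsi_star(value, lim_min, lim_max, exact)
        rows.append({**base, "mpd": mpd, "null_mean": null.mean,
                     "null_sd": null.sd, "dsi": value, "dsi_lim_min": lim_min,
                     "dsi_lim_max": lim_max, "dsi_star": star,
                     "exact_lim": exact, "degenerate": False})
    return pd.DataFrame(rows)


def assemblage_mean_dsi(
    scores: pd.DataFrame,
    records: pd.DataFrame,
    guild_scopes: Sequence[str] = ("all",) + GUILDS,
) -> pd.DataFrame:
    """Unweighted mean DSI* of the herbivores recorded on each plant.

    For every (site, plant, guild scope), averages DSI* over the
    (post-filter) herbivore species recorded on that plant under the scope.
    Plants hosting no species under a scope are omitted; degenerate scores
    are excluded from the mean.
    """
    usable = scores.loc[~scores["degenerate"],
                        ["site", "herbivore_species", "dsi_star"]]
    links = records[["site", "plant_species", "herbivore_species", "guild"]].drop_duplicates()
    merged = links.merge(usable, on=["site", "herbivore_species"], how="inner")
    rows = []
    for scope in guild_scopes:
        sub = merged if scope == "all" else merged[merged["guild"] == scope]
        grouped = sub.groupby(["site", "plant_species"])["dsi_star"]
        for (site, plant), vals in grouped:
            rows.append({
                "site": site,
                "plant_species": plant,
                "guild_scope": scope,
                "mean_dsi_star": float(vals.mean()),
                "n_species": int(vals.count()),
            })
    return pd.DataFrame(rows)
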