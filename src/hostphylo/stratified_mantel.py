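"""Site-stratified Mantel test of assemblage overlap against phylogenetic distance.

The sites of a multi-site study share essentially no plant or herbivore
species, so a single global distance matrix across sites would manufacture
meaningless between-site pairs. The stratified (modified) Mantel protocol
avoids this:

1. build the phylogenetic-distance / assemblage-similarity matrix pair
   separately for each site;
2. vectorize each pair (strictly lower triangle) and concatenate across
   sites; the observed statistic is the Pearson correlation r of the two
   concatenated vectors;
3. for the null, permute each site's distance matrix independently (the
   standard Mantel null: one uniform random relabeling applied to rows and
   columns simultaneously, similarities held fixed), re-concatenate and
   recompute r;
4. p = (1 + #{null r at least as extreme}) / (1 + n_permutations).

The default alternative is ``less`` — the hypothesis is that assemblage
overlap decays with host phylogenetic distance — and the default
permutation count is 9,999.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from hostphylo.interactions import GUILD_SCOPES, build_assemblage_matrix
from hostphylo.assemblage_similarity import SIMILARITY_INDICES, similarity_matrix
from hostphylo.phylo_metrics import DistanceMatrix

logger = logging.getLogger(__name__)

ALTERNATIVES = ("less", "greater", "two_sided")


@dataclass(frozen=True)
class SiteMatrixPair:
    """One site's aligned phylogenetic-distance and similarity matrices.

    ``mask``, when given, marks the strictly-lower-triangle pair positions
    (row-major) to keep; excluded positions are removed from both vectors.
    """

    site: str
    labels: tuple[str, ...]
    D: np.ndarray
    S: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.labels)
        if self.D.shape != (n, n) or self.S.shape != (n, n):
            raise ValueError(f"site {self.site!r}: matrix shapes do not match labels")
        if n < 3:
            raise ValueError(
                f"site {self.site!r}: need >= 3 species (>= 3 off-diagonal pairs)"
            )
        if self.mask is not None and self.mask.shape != (n * (n - 1) // 2,):
            raise ValueError(f"site {self.site!r}: mask length mismatch")

    @classmethod
    def from_matrices(
        cls, site: str, D: DistanceMatrix, S: pd.DataFrame
    ) -> "SiteMatrixPair":
        """Align a DistanceMatrix and a similarity DataFrame on shared labels."""
        labels = [lab for lab in S.index if lab in set(D.labels)]
        dropped = [lab for lab in S.index if lab not in set(D.labels)]
        if dropped:
            raise KeyError(f"site {site!r}: plants missing from tree: {dropped}")
        sub = D.submatrix(labels)
        return cls(
            site=site,
            labels=tuple(labels),
            D=sub.values,
            S=S.loc[labels, labels].to_numpy(dtype=float),
        )


def vectorize_pair(pair: SiteMatrixPair) -> tuple[np.ndarray, np.ndarray]:
    """Strictly-lower-triangle vectors of D and S in canonical row-major order."""
    i, j = np.tril_indices(len(pair.labels), k=-1)
    d, s = pair.D[i, j], pair.S[i, j]
    if pair.mask is not None:
        d, s = d[pair.mask], s[pair.mask]
    return d, s


@dataclass
class MantelResult:
    """Observed correlation, permutation null summary and p-value."""

    r_obs: float
    p_value: float
    n_permutations: int
    alternative: str
    method: str
    n_pairs_per_site: dict[str, int]
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    seed: int | None
    null_r: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "r_obs": self.r_obs,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "alternative": self.alternative,
            "method": self.method,
            "n_pairs_per_site": self.n_pairs_per_site,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_quantiles": self.null_quantiles,
            "seed": self.seed,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    return float((x @ y) / denom)


def stratified_mantel(
    pairs: Sequence[SiteMatrixPair],
    n_permutations: int = 9999,
    alternative: str = "less",
    seed: int | None = None,
    method: str = "pearson",
    standardize_per_site: bool = False,
    keep_null: bool = False,
) -> MantelResult:
    """Stratified Mantel test over one or more site matrix pairs.

    With a single site this reduces exactly to the classic simple Mantel
    test. ``standardize_per_site`` z-scores each site's d- and s-vectors
    before concatenation (sensitivity analysis only; the default follows
    the raw-concatenation protocol). ``method`` is ``pearson`` (classic) or
    ``spearman`` (ranks of the concatenated vectors).
    """
    if not pairs:
        raise ValueError("need at least one site matrix pair")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")

    tril = [np.tril_indices(len(p.labels), k=-1) for p in pairs]
    d_vecs, s_vecs = [], []
    for p in pairs:
        d, s = vectorize_pair(p)
        if len(d) < 3:
            raise ValueError(f"site {p.site!r}: fewer than 3 usable pairs")
        if np.ptp(d) == 0:
            raise ValueError(f"site {p.site!r}: degenerate (constant) distance vector")
        d_vecs.append(d)
        s_vecs.append(s)
    s_all = np.concatenate(s_vecs)
    if np.ptp(s_all) == 0:
        raise ValueError(
            "degenerate (constant) similarity vector across sites "
            + str([p.site for p in pairs])
        )

    def _prep(vecs):
        if standardize_per_site:
            return np.concatenate([(v - v.mean()) / v.std(ddof=1) for v in vecs])
        return np.concatenate(vecs)

    def _stat(d_concat):
        if method == "spearman":
            return _pearson(rankdata(d_concat), rankdata(s_all_c))
        return _pearson(d_concat, s_all_c)

    s_all_c = _prep(s_vecs)
    r_obs = _stat(_prep(d_vecs))

    rng = np.random.default_rng(seed)
    null_r = np.empty(n_permutations)
    sizes = [len(p.labels) for p in pairs]
    for it in range(n_permutations):
        perm_vecs = []
        for p, (ti, tj), n in zip(pairs, tril, sizes):
            perm = rng.permutation(n)
            d = p.D[perm[:, None], perm[None, :]][ti, tj]
            if p.mask is not None:
                d = d[p.mask]
            perm_vecs.append(d)
        null_r[it] = _stat(_prep(perm_vecs))

    if alternative == "less":
        extreme = int(np.sum(null_r <= r_obs))
    elif alternative == "greater":
        extreme = int(np.sum(null_r >= r_obs))
    else:
        extreme = int(np.sum(np.abs(null_r) >= abs(r_obs)))
    p_value = (1 + extreme) / (1 + n_permutations)

    qs = np.quantile(null_r, [0.025, 0.5, 0.975])
    return MantelResult(
        r_obs=r_obs,
        p_value=p_value,
        n_permutations=n_permutations,
        alternative=alternative,
        method=method,
        n_pairs_per_site={p.site: len(v) for p, v in zip(pairs, d_vecs)},
        null_mean=float(null_r.mean()),
        null_sd=float(null_r.std(ddof=1)),
        null_quantiles={"q025": float(qs[0]), "q50": float(qs[1]), "q975": float(qs[2])},
        seed=seed,
        null_r=null_r if keep_null else None,
    )


def run_overlap_analysis(
    records: pd.DataFrame,
    site_distances: Mapping[str, DistanceMatrix],
    guild_scopes: Sequence[str] = GUILD_SCOPES,
    indices: Sequence[str] = SIMILARITY_INDICES,
    n_permutations: int = 9999,
    alternative: str = "less",
    seed: int | None = None,
    **mantel_kwargs,
) -> dict[tuple[str, str], MantelResult]:
    """Stratified Mantel tests for every guild scope x similarity index.

    ``site_distances`` maps each site to the patristic DistanceMatrix of its
    (pruned) host phylogeny. Records must already be rare-species filtered.
    Scopes with no usable site (e.g. an absent guild) are skipped with a
    warning rather than raising.
    """
    sites = sorted(records["site"].unique())
    results: dict[tuple[str, str], MantelResult] = {}
    ss = np.random.SeedSequence(seed)
    combos = [(sc, ix) for sc in guild_scopes for ix in indices]
    child_seeds = ss.spawn(len(combos))
    for (scope, index), child in zip(combos, child_seeds):
        pairs = []
        for site in sites:
            mat = build_assemblage_matrix(records, site, scope)
            if mat.empty or (mat.sum(axis=1) > 0).sum() < 3:
                logger.warning(
                    "skipping site %r for scope %r: fewer than 3 non-empty assemblages",
                    site, scope,
                )
                continue
            S = similarity_matrix(mat, index)
            pairs.append(SiteMatrixPair.from_matrices(site, site_distances[site], S))
        if not pairs:
            logger.warning("no usable sites for scope %r; skipped", scope)
            continue
        results[(scope, index)] = stratified_mantel(
            pairs,
            n_permutations=n_permutations,
            alternative=alternative,
            seed=int(child.generate_state(1)[0] % (2**31)),
            **mantel_kwargs,
        )
    return results
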