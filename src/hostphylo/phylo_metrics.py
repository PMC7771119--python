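"""Host-phylogeny metrics: tree I/O, pruning, patristic distances, distinctiveness.

Trees are time-calibrated host-plant phylogenies (branch lengths in millions
of years, tips = plant species). Two quantities drive everything downstream:

* the patristic distance between two tips — the sum of branch lengths on the
  path connecting them — which is the phylogenetic distance d(j, k) used by
  the Mantel stage and by the DSI* null model; and
* fair-proportions evolutionary distinctiveness (ED), the per-tip score
  obtained by dividing every branch length equally among the tips descending
  from it and summing along the root-to-tip path. High ED means the species
  has no close relatives in the tree; it is used as "phylogenetic isolation"
  (PI) in the regression stage.

Newick parsing and tree surgery are delegated to dendropy; polytomies are
accepted everywhere and zero-length branches are legal (a tip whose whole
root path has zero length gets ED = 0 and is logged).
"""

from __future__ import annotations

import logging
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "read_tree",
    "read_tree_file",
    "prune_to_taxa",
    "patristic_distances",
    "evolutionary_distinctiveness",
    "total_branch_length",
]


class TreeValidationError(ValueError):
    """Tree violates a structural requirement (labels, lengths, rooting)."""


class DistanceMatrix:
    """Square symmetric matrix of patristic distances with species labels.

    Parameters
    ----------
    labels : sequence of str
        Ordered, unique species labels.
    values : (n, n) array_like
        Symmetric, hollow (zero diagonal), non-negative distances in My.
    """

    __slots__ = ("labels", "values", "_index")

    def __init__(self, labels: Iterable[str], values) -> None:
        labels = tuple(str(x) for x in labels)
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise TreeValidationError("duplicate labels in distance matrix")
        if values.shape != (n, n):
            raise TreeValidationError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(values)):
            raise TreeValidationError("non-finite distances")
        if np.any(values < 0):
            raise TreeValidationError("negative distances")
        if not np.allclose(values, values.T, rtol=0, atol=1e-9):
            raise TreeValidationError("distance matrix not symmetric")
        if np.any(np.diag(values) != 0):
            raise TreeValidationError("nonzero diagonal")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.labels = labels
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        """Restrict to `labels` in the given order."""
        labels = list(labels)
        try:
            idx = [self._index[lab] for lab in labels]
        except KeyError as exc:
            raise KeyError(f"label not in distance matrix: {exc.args[0]!r}") from None
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.labels), columns=list(self.labels)
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise TreeValidationError("row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float))


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not (leaf.taxon.label or "").strip():
            raise TreeValidationError("unlabeled tip in tree")
        labels.append(leaf.taxon.label.strip())
        leaf.taxon.label = leaf.taxon.label.strip()
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge may legitimately be absent
        if edge.length is None:
            raise TreeValidationError(
                "missing branch length above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'!r}"
            )
        if not np.isfinite(edge.length) or edge.length < 0:
            raise TreeValidationError(f"invalid branch length {edge.length!r}")
    return tree


def read_tree(newick_text: str) -> dendropy.Tree:
    """Parse one Newick tree, validating labels and branch lengths.

    The tree is treated as rooted as written (no re-rooting). Raises
    ``ValueError`` on malformed Newick, duplicate tip labels, or a missing
    branch length — a silent default length would corrupt every distance
    downstream.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"could not parse Newick: {exc}") from exc
    return _validate_tree(tree)


def read_tree_file(path) -> dendropy.Tree:
    """Read a single-tree Newick file (see :func:`read_tree`)."""
    with open(path, "r", encoding="utf-8") as fh:
        return read_tree(fh.read())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths, including a root edge if present."""
    return float(
        sum(e.length for e in tree.preorder_edge_iter() if e.length is not None)
    )


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Prune to a site's species pool, preserving patristic distances.

    Unary internal nodes left by the pruning are collapsed with their branch
    lengths summed, so every pairwise distance among retained tips equals the
    distance on the master tree.
    """
    taxa = {str(t).strip() for t in taxa}
    present = set(tip_labels(tree))
    unknown = taxa - present
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if len(taxa) < 2:
        raise ValueError(f"need at least 2 taxa to prune to, got {len(taxa)}")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=taxa, suppress_unifurcations=True
    )
    pruned.is_rooted = tree.is_rooted
    return _validate_tree(pruned)


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between tips, in My.

    Labels are sorted so that the matrix layout is deterministic regardless
    of Newick rotation.
    """
    labels = tip_labels(tree)
    if len(labels) < 2:
        raise ValueError("patristic distances need at least 2 tips")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    values = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def evolutionary_distinctiveness(tree: dendropy.Tree) -> pd.Series:
    """Fair-proportions evolutionary distinctiveness (phylogenetic isolation).

    Each branch's length is divided equally among the tips descending from
    it; a tip's score sums its shares along the root path:

        ED(tip) = sum over edges e on root->tip path of len(e) / n_tips(e)

    Scores sum to the total branch length of the tree. A root edge, if the
    Newick carries one, is shared by all tips. Defined on polytomies without
    modification.

    Returns
    -------
    pandas.Series
        ED per tip label (My per tip-share), sorted by label, name ``"ED"``.
    """
    if not tree.is_rooted:
        raise TreeValidationError(
            "evolutionary distinctiveness requires a rooted tree"
        )
    _validate_tree(tree)
    scores: dict[str, float] = {}
    # accumulate shares in one postorder pass: each node reports its tip set
    tipsets: dict[int, list[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips = [node.taxon.label]
        else:
            tips = [t for ch in node.child_nodes() for t in tipsets.pop(id(ch))]
        tipsets[id(node)] = tips
        length = node.edge.length
        if length:
            share = length / len(tips)
            for t in tips:
                scores[t] = scores.get(t, 0.0) + share
        else:
            for t in tips:
                scores.setdefault(t, 0.0)
    ed = pd.Series(scores, name="ED").sort_index()
    ed.index.name = "species"
    zero = ed.index[ed == 0.0]
    if len(zero):
        logger.warning(
            "tips with zero evolutionary distinctiveness (zero-length root path): %s",
            list(zero),
        )
    return ed
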