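"""Pairwise similarity of herbivore assemblages between host plants.

Three classical overlap indices, all in [0, 1]:

* Jaccard (incidence): shared species over union of species;
* Bray-Curtis similarity (abundance): 2 * sum(min(x, y)) / (sum x + sum y),
  i.e. one minus the Bray-Curtis dissimilarity;
* Morisita-Horn (abundance): 2 * sum(x_i y_i) /
  [(sum x_i^2 / X^2 + sum y_i^2 / Y^2) * X * Y], invariant to rescaling
  either assemblage.

The exposed quantity is similarity, not dissimilarity, because the overlap
hypothesis is a negative correlation of similarity with phylogenetic
distance. Pairs where either assemblage is empty are undefined and excluded
(never coerced to 0, which would conflate "no data" with "no overlap").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIMILARITY_INDICES = ("jaccard", "bray_curtis", "morisita_horn")


class UndefinedPairError(ValueError):
    """Both assemblages empty; the similarity is undefined for this pair."""


def _as_counts(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("count vectors must be 1-D")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("counts must be finite and non-negative")
    return x


def jaccard(x_counts, y_counts) -> float:
    """Incidence-based Jaccard similarity of two aligned count vectors."""
    x, y = _as_counts(x_counts), _as_counts(y_counts)
    px, py = x > 0, y > 0
    union = np.count_nonzero(px | py)
    if union == 0:
        raise UndefinedPairError("both assemblages empty")
    return np.count_nonzero(px & py) / union


def bray_curtis_similarity(x_counts, y_counts) -> float:
    """Abundance-based Bray-Curtis similarity (1 - dissimilarity)."""
    x, y = _as_counts(x_counts), _as_counts(y_counts)
    total = x.sum() + y.sum()
    if total == 0:
        raise UndefinedPairError("both assemblages empty")
    return float(2.0 * np.minimum(x, y).sum() / total)


def morisita_horn(x_counts, y_counts) -> float:
    """Morisita-Horn similarity; 1 for proportional assemblages."""
    x, y = _as_counts(x_counts), _as_counts(y_counts)
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise UndefinedPairError("empty assemblage")
    dx = (x**2).sum() / X**2
    dy = (y**2).sum() / Y**2
    return float(2.0 * (x * y).sum() / ((dx + dy) * X * Y))


_INDEX_FUNCTIONS = {
    "jaccard": jaccard,
    "bray_curtis": bray_curtis_similarity,
    "morisita_horn": morisita_horn,
}


def similarity_matrix(assemblage_matrix: pd.DataFrame, index: str) -> pd.DataFrame:
    """All pairwise assemblage similarities between the plant rows.

    Rows with empty assemblages are excluded up front (with a log entry);
    the result is a symmetric plant x plant DataFrame with unit diagonal.
    """
    if index not in _INDEX_FUNCTIONS:
        raise ValueError(
            f"unknown index {index!r}; expected one of {list(_INDEX_FUNCTIONS)}"
        )
    fn = _INDEX_FUNCTIONS[index]
    counts = assemblage_matrix.to_numpy(dtype=float)
    usable = counts.sum(axis=1) > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "excluding %d empty assemblages from %s similarity matrix",
            n_excluded, index,
        )
    labels = assemblage_matrix.index[usable]
    counts = counts[usable]
    if len(labels) < 2:
        raise ValueError(
            f"need at least 2 non-empty assemblages, have {len(labels)}"
        )
    n = len(labels)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(counts[i], counts[j])
    out = pd.DataFrame(values, index=labels, columns=labels)
    out.index.name = out.columns.name = "plant_species"
    return out
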