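"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit path walks, pair loops and
composition enumeration — and shares no code with the package's own
computation paths.
"""

from __future__ import annotations

import numpy as np


def path_sum_distances(tree):
    """Patristic distances by explicit root-path edge bookkeeping.

    For each tip, record the (node id -> branch length) map along its path
    to the root; the distance between two tips is the summed length of the
    symmetric difference of their path edge sets.
    """
    paths = {}
    for leaf in tree.leaf_node_iter():
        node, edges = leaf, {}
        while node.parent_node is not None:
            edges[id(node)] = node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    labels = sorted(paths)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ea, eb = paths[labels[i]], paths[labels[j]]
            shared = set(ea) & set(eb)
            d = sum(v for k, v in ea.items() if k not in shared)
            d += sum(v for k, v in eb.items() if k not in shared)
            out[i, j] = out[j, i] = d
    return labels, out


def fair_proportions_by_edge(tree):
    """ED recomputed edge-wise: each edge's length split over its tip set."""
    scores = {leaf.taxon.label: 0.0 for leaf in tree.leaf_node_iter()}
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if not length:
            continue
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        for t in tips:
            scores[t] += length / len(tips)
    return scores


def jaccard_oracle(x, y):
    sx = {i for i, v in enumerate(x) if v > 0}
    sy = {i for i, v in enumerate(y) if v > 0}
    return len(sx & sy) / len(sx | sy)


def bray_curtis_oracle(x, y):
    num = sum(min(a, b) for a, b in zip(x, y))
    return 2.0 * num / (sum(x) + sum(y))


def morisita_horn_oracle(x, y):
    X, Y = sum(x), sum(y)
    dx = sum(v * v for v in x) / (X * X)
    dy = sum(v * v for v in y) / (Y * Y)
    return 2.0 * sum(a * b for a, b in zip(x, y)) / ((dx + dy) * X * Y)


def mpd_pairs_oracle(counts, labels, dist):
    """Individual-based MPD by expanding every record and looping all pairs."""
    individuals = []
    for host, n in counts.items():
        individuals.extend([host] * int(n))
    total, npairs = 0.0, 0
    for a in range(len(individuals)):
        for b in range(a + 1, len(individuals)):
            i = labels.index(individuals[a])
            j = labels.index(individuals[b])
            total += dist[i, j]
            npairs += 1
    return total / npairs


def max_mpd_enumerate(n_i, dist):
    """Maximum individual-based MPD over all allocations, by recursion."""
    k = dist.shape[0]
    best = [0.0]

    def rec(pos, remaining, alloc):
        if pos == k - 1:
            alloc = alloc + [remaining]
            c = np.array(alloc, dtype=float)
            val = float(c @ dist @ c) / (n_i * (n_i - 1))
            if val > best[0]:
                best[0] = val
            return
        for take in range(remaining + 1):
            rec(pos + 1, remaining - take, alloc + [take])

    rec(0, n_i, [])
    return best[0]


def naive_simple_mantel(D, S, n_permutations, alternative, seed):
    """Textbook single-matrix Mantel test with the shared permutation scheme.

    Returns (r_obs, p). Correlation via np.corrcoef; the null permutes the
    rows/columns of D with one uniform permutation per iteration drawn from
    np.random.default_rng(seed), similarities fixed.
    """
    n = D.shape[0]
    i, j = np.tril_indices(n, k=-1)
    d, s = D[i, j], S[i, j]
    r_obs = float(np.corrcoef(d, s)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for it in range(n_permutations):
        p = rng.permutation(n)
        Dp = D[np.ix_(p, p)]
        null[it] = np.corrcoef(Dp[i, j], s)[0, 1]
    if alternative == "less":
        extreme = np.sum(null <= r_obs)
    elif alternative == "greater":
        extreme = np.sum(null >= r_obs)
    else:
        extreme = np.sum(np.abs(null) >= abs(r_obs))
    return r_obs, (1 + int(extreme)) / (1 + n_permutations)
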