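import numpy as np
import pandas as pd
import pytest

from hostphylo import (
    DistanceMatrix,
    SiteConfig,
    SyntheticConfig,
    generate_dataset,
    read_tree,
    simulate_tree,
)


def random_tree(n_tips, seed, depth=100.0, jitter=False, prefix="P"):
    """Random tree for oracle checks; ``jitter`` breaks ultrametricity."""
    tree = simulate_tree(n_tips, seed=seed, depth=depth, prefix=prefix)
    if jitter:
        rng = np.random.default_rng(seed + 1)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= rng.uniform(0.2, 2.0)
    return tree


def random_distance_matrix(n, seed, prefix="P"):
    """Patristic distances of a random (jittered) tree — a valid tree metric."""
    tree = random_tree(n, seed, jitter=True, prefix=prefix)
    from hostphylo import patristic_distances

    return patristic_distances(tree)


@pytest.fixture(scope="session")
def toy_tree():
    return read_tree("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture(scope="session")
def toy_records():
    rows = [
        ("S1", "P1_t1", "P1", "H1", "exposed", 2),
        ("S1", "P1_t1", "P1", "H2", "shelter", 1),
        ("S1", "P2_t1", "P2", "H1", "exposed", 4),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "tree_individual",
            "plant_species",
            "herbivore_species",
            "guild",
            "n_individuals",
        ],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Compact two-site synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        sites=(
            SiteConfig("S1", 7, {"exposed": 10, "shelter": 8}),
            SiteConfig("S2", 9, {"exposed": 10, "shelter": 8}),
        ),
        seed=123,
    )
    return generate_dataset(cfg)


def two_host_distance(d=2.0):
    return DistanceMatrix(["A", "B"], [[0.0, d], [d, 0.0]])
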