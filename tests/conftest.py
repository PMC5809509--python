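"""Shared fixtures: small hand-built trees and random-instance factories."""

import numpy as np
import pytest

from elevphylo import PairwiseDistance, Phylogeny, simulate_tree


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2) — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def star_tree() -> Phylogeny:
    """Five tips hanging directly off the root, all pendant edges 1."""
    return Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1):0;")


@pytest.fixture
def abc_distance() -> PairwiseDistance:
    """d(A,B)=2, d(A,C)=4, d(B,C)=6."""
    return PairwiseDistance(
        ["A", "B", "C"],
        np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]]),
    )


@pytest.fixture
def random_distance():
    """Factory for random symmetric distance matrices with generic entries."""

    def make(n: int, seed: int) -> PairwiseDistance:
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(n, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        labels = [f"t{i:02d}" for i in range(n)]
        return PairwiseDistance(labels, D)

    return make


@pytest.fixture
def random_tree():
    """Factory for small simulated ultrametric trees."""

    def make(n: int, seed: int) -> Phylogeny:
        return simulate_tree(n, birth=1.0, death=0.0, seed=seed)

    return make
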