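"""Functional trait space: log/standardize preprocessing, PCA, Euclidean
trait distances and the UPGMA dendrogram used as the "functional tree".

The dendrogram is scaled so that the tip-to-tip path distance equals the
between-cluster average distance at the merge (merge height = half that
average), which makes the functional tree directly substitutable for the
phylogeny in the dispersion statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import DataError, PairwiseDistance, Phylogeny, TraitTable

__all__ = [
    "PcaResult",
    "preprocess_traits",
    "pca",
    "euclidean_distance",
    "upgma",
    "functional_dendrogram",
]


def preprocess_traits(traits: TraitTable) -> pd.DataFrame:
    """Log-transform and column-standardize a trait table.

    Each column becomes ``(log x - mean(log x)) / sd(log x)`` (sample SD,
    ddof=1): zero mean and unit SD per trait.

    Raises
    ------
    DataError
        If any value is nonpositive or a trait has zero variance after
        the log transform.
    """
    X = traits.traits
    if (X.to_numpy() <= 0).any():
        bad = X.stack()[X.stack() <= 0]
        sp, tr = bad.index[0]
        raise DataError(f"nonpositive trait value for species {sp!r}, trait {tr!r}")
    L = np.log(X)
    sd = L.std(axis=0, ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise DataError(f"zero-variance trait column(s): {zero}")
    return (L - L.mean(axis=0)) / sd


@dataclass
class PcaResult:
    """Principal component analysis of a standardized matrix.

    ``scores`` are the projections of the rows on the top-k eigenvectors
    of the column covariance, ``loadings`` the eigenvectors (columns),
    ``var_explained`` the fraction of total variance per component.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(X: pd.DataFrame, k: int | None = None,
        min_var_explained: float | None = None) -> PcaResult:
    """Covariance PCA with a deterministic sign convention.

    Exactly one of ``k`` and ``min_var_explained`` may be given; with
    neither, all components are returned.  Sign convention: within each
    component the loading of largest magnitude is made positive.
    """
    if k is not None and min_var_explained is not None:
        raise DataError("give either k or min_var_explained, not both")
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    max_k = min(n - 1, p)
    if k is not None and not (1 <= k <= max_k):
        raise DataError(f"k={k} out of range [1, {max_k}]")
    centred = A - A.mean(axis=0)
    # SVD route: eigenvalues of the covariance are s^2/(n-1)
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    frac = eigvals / total if total > 0 else eigvals
    if k is None:
        if min_var_explained is not None:
            cum = np.cumsum(frac)
            k = int(np.searchsorted(cum, min_var_explained - 1e-12) + 1)
            k = min(k, max_k)
        else:
            k = max_k
    load = Vt[:k].T  # p x k
    # deterministic signs
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    scores = centred @ load
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(load, index=X.columns, columns=comp_names),
        var_explained=frac[:k].copy(),
    )


def euclidean_distance(scores: pd.DataFrame) -> PairwiseDistance:
    """Euclidean distance between the rows of a score matrix."""
    D = squareform(pdist(scores.to_numpy(dtype=float), metric="euclidean"))
    return PairwiseDistance(list(scores.index), D)


def upgma(dist: PairwiseDistance) -> Phylogeny:
    """UPGMA (size-weighted average linkage) dendrogram as a newick tree.

    Merge height is half the between-cluster average distance, so the
    dendrogram's tip-to-tip path distance reproduces that average and the
    result is ultrametric.  Ties in the minimum distance are broken by
    merging the pair whose (sorted) representative labels are smallest
    lexicographically, making the merge order reproducible.
    """
    n = len(dist)
    if n < 2:
        raise DataError("UPGMA needs at least 2 items")
    labels = list(dist.labels)
    dmat: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = float(dist.D[i, j])
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    # representative label of a cluster = lexicographically smallest member
    rep = {i: labels[i] for i in range(n)}
    nxt = n

    def get(a: int, b: int) -> float:
        return dmat[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        best_key = None
        best_pair = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (get(a, b), *sorted((rep[a], rep[b])))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (a, b)
        a, b = best_pair
        d_ab = best_key[0]
        h = d_ab / 2.0
        newick[nxt] = (f"({newick[a]}:{h - height[a]:.12g},"
                       f"{newick[b]}:{h - height[b]:.12g})")
        rep[nxt] = min(rep[a], rep[b])
        height[nxt] = h
        size[nxt] = size[a] + size[b]
        active.remove(a)
        active.remove(b)
        # size-weighted average linkage to every remaining cluster
        for c in active:
            d_new = (size[a] * get(a, c) + size[b] * get(b, c)) / size[nxt]
            dmat[(c, nxt) if c < nxt else (nxt, c)] = d_new
        active.append(nxt)
        nxt += 1
    root = active[0]
    return Phylogeny.from_newick(newick[root] + ";")


def functional_dendrogram(traits: TraitTable, k: int | None = None,
                          min_var_explained: float | None = 0.948
                          ) -> tuple[Phylogeny, PcaResult]:
    """Full trait-space pipeline: preprocess, PCA, Euclidean distance, UPGMA.

    By default keeps the smallest number of components explaining at least
    94.8% of trait variance; pass ``k=4`` to fix the component count.
    """
    Z = preprocess_traits(traits)
    if k is not None:
        min_var_explained = None
    res = pca(Z, k=k, min_var_explained=min_var_explained)
    dist = euclidean_distance(res.scores)
    return upgma(dist), res
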