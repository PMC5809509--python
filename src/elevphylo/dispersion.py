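"""Abundance-weighted dispersion metrics and the tip-shuffle null model.

Within-assemblage structure is measured by the abundance-weighted mean
pairwise distance (MPD) and its standardized effect size, the net
relatedness index::

    NRI = -1 * (MPD_obs - mean MPD_null) / sd MPD_null

so positive values indicate phylogenetic (or functional) clustering and
negative values overdispersion.  Between-assemblage turnover uses the
abundance-weighted mean pairwise distance D_pw between the two species
lists, standardized the same way (S.E.S. D_pw).

The null model shuffles species labels across the tips of the tree (or
trait dendrogram) while leaving the community matrix untouched, which
preserves occupancy, abundance and spatial structure and randomizes only
relatedness.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CommunityMatrix, DataError, PairwiseDistance, pool_band, _series_assemblage

logger = logging.getLogger(__name__)

__all__ = [
    "DispersionResult",
    "BandComponents",
    "mpd_weighted",
    "dpw",
    "tip_shuffle_null",
    "nri",
    "ses_dpw",
    "band_components",
    "band_beta_matrix",
    "derived_rng",
]

#: pool sizes at or below which the null enumerates all permutations
EXHAUSTIVE_LIMIT = 6


def derived_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for one task, derived from a master seed and a task key.

    Seeds are spawned via :class:`numpy.random.SeedSequence` with the key
    as ``spawn_key``, so per-task streams are independent of execution
    order.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _band_key(band) -> int:
    """Stable integer key for a band id (independent of PYTHONHASHSEED)."""
    return zlib.crc32(str(band).encode()) % (2**31)


@dataclass
class DispersionResult:
    """Observed metric, its permutation null and the standardized effect.

    ``ses`` is sign-flipped, ``-1 * (obs - null_mean) / null_sd``:
    positive = clustering.  ``degenerate`` marks a constant null
    (``null_sd == 0``), for which ``ses`` is reported as 0 and the value
    should be excluded from averages.
    """

    metric_name: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_null: int
    seed: int | None
    degenerate: bool = False


@dataclass
class BandComponents:
    """Alpha / beta-within / gamma dispersion of one elevational band."""

    band: object
    alpha: float
    beta_within: float
    gamma: float
    n_plots: int
    n_plots_used: int
    n_pairs_used: int
    gamma_result: DispersionResult = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# observed metrics
# ---------------------------------------------------------------------------

def _weights_and_indices(assemblage, dist: PairwiseDistance):
    s = _series_assemblage(assemblage)
    idx = dist.index_of(s.index)
    f = s.to_numpy() / s.sum()
    return f, idx


def mpd_weighted(assemblage, dist: PairwiseDistance) -> float:
    """Abundance-weighted mean pairwise distance within one assemblage.

    ``sum_{i<j} f_i f_j d_ij / sum_{i<j} f_i f_j`` over distinct species
    pairs, with ``f`` the relative abundances.
    """
    f, idx = _weights_and_indices(assemblage, dist)
    if len(idx) < 2:
        raise DataError("MPD undefined for monospecific assemblage")
    W = np.outer(f, f)
    np.fill_diagonal(W, 0.0)
    sub = dist.D[np.ix_(idx, idx)]
    return float((W * sub).sum() / W.sum())


def dpw(assemblage1, assemblage2, dist: PairwiseDistance,
        inner_weighted: bool = True) -> float:
    """Abundance-weighted mean pairwise distance between two assemblages.

    Average of the two directed sums ``sum_i f_i dbar_i``, where
    ``dbar_i`` is the mean distance from species ``i`` of one assemblage
    to the species of the other.  With ``inner_weighted=True`` (default)
    that inner mean is weighted by the other assemblage's relative
    abundances; with ``False`` it is an unweighted mean over species.
    Shared species contribute ``d = 0`` terms.
    """
    f1, i1 = _weights_and_indices(assemblage1, dist)
    f2, i2 = _weights_and_indices(assemblage2, dist)
    if len(i1) == 0 or len(i2) == 0:
        raise DataError("D_pw undefined for empty assemblage")
    C = dist.D[np.ix_(i1, i2)]
    if inner_weighted:
        # both directed sums reduce to f1' C f2
        return float(f1 @ C @ f2)
    dbar_1to2 = C.mean(axis=1)   # per species of assemblage 1
    dbar_2to1 = C.mean(axis=0)
    return float((f1 @ dbar_1to2 + f2 @ dbar_2to1) / 2.0)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def tip_shuffle_null(dist: PairwiseDistance, n: int,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None,
                     exhaustive: bool | None = None) -> np.ndarray:
    """Permutations of the species pool implementing the tip-shuffle null.

    Returns an integer array of shape ``(n_replicates, pool_size)``; each
    row ``perm`` relabels the pool so that species at pool position ``k``
    takes the distances of position ``perm[k]``.  With ``exhaustive=True``
    (the default for pools of at most ``EXHAUSTIVE_LIMIT`` labels when a
    replicate count is not forced) all ``P!`` permutations are returned
    exactly once.
    """
    if n < 1:
        raise DataError("need at least one null replicate")
    P = len(dist)
    if exhaustive is None:
        exhaustive = False
    if exhaustive:
        if P > EXHAUSTIVE_LIMIT + 2:
            raise DataError(f"exhaustive null infeasible for pool of {P}")
        return np.array(list(itertools.permutations(range(P))), dtype=int)
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.array([rng.permutation(P) for _ in range(n)], dtype=int)


def _rank_p_value(observed: float, null_values: np.ndarray) -> float:
    """Two-sided rank p: ``2 * min(r, n+2-r) / (n+1)`` with ``r`` the rank
    of the observed among observed + null (ties counted half).

    Both extremes (observed beyond every null value on either side) give
    the permutation floor ``2 / (n+1)``; a mid-rank observation gives 1.
    """
    n = len(null_values)
    below = int(np.sum(null_values < observed))
    ties = int(np.sum(null_values == observed))
    r = 1 + below + ties / 2.0
    return float(min(1.0, 2.0 * min(r, n + 2 - r) / (n + 1)))


def _ses_result(name: str, observed: float, null_values: np.ndarray,
                seed: int | None) -> DispersionResult:
    mu = float(np.mean(null_values))
    sd = float(np.std(null_values, ddof=1)) if len(null_values) > 1 else 0.0
    degenerate = not (sd > 1e-12)
    if degenerate:
        logger.info("degenerate null (sd=0) for %s", name)
        ses = 0.0
    else:
        ses = -1.0 * (observed - mu) / sd
    return DispersionResult(
        metric_name=name, observed=observed, null_mean=mu, null_sd=sd,
        ses=ses, p_value=_rank_p_value(observed, null_values),
        n_null=len(null_values), seed=seed, degenerate=degenerate,
    )


def _null_mpd(f: np.ndarray, idx: np.ndarray, D: np.ndarray,
              perms: np.ndarray) -> np.ndarray:
    """Vectorized null MPD values for one assemblage under tip permutations."""
    W = np.outer(f, f)
    np.fill_diagonal(W, 0.0)
    wsum = W.sum()
    sub = perms[:, idx]                        # (R, k)
    vals = D[sub[:, :, None], sub[:, None, :]]  # (R, k, k)
    return (vals * W).sum(axis=(1, 2)) / wsum


def nri(assemblage, dist: PairwiseDistance, n_null: int = 1000,
        seed: int | None = None, rng: np.random.Generator | None = None,
        exhaustive: bool | None = None) -> DispersionResult:
    """Net relatedness index of one assemblage under the tip-shuffle null.

    The pool is the full label set of ``dist`` (all tips of the supplied
    tree or dendrogram).  Positive NRI = clustering (observed MPD below
    the null mean), negative = overdispersion.
    """
    f, idx = _weights_and_indices(assemblage, dist)
    if len(idx) < 2:
        raise DataError("MPD undefined for monospecific assemblage")
    observed = mpd_weighted(assemblage, dist)
    perms = tip_shuffle_null(dist, n_null, rng=rng, seed=seed,
                             exhaustive=exhaustive)
    null_values = _null_mpd(f, idx, dist.D, perms)
    return _ses_result("NRI", observed, null_values, seed)


def ses_dpw(assemblage1, assemblage2, dist: PairwiseDistance,
            n_null: int = 1000, seed: int | None = None,
            rng: np.random.Generator | None = None,
            exhaustive: bool | None = None,
            inner_weighted: bool = True) -> DispersionResult:
    """Standardized effect size of D_pw between two assemblages.

    Both assemblages share one species pool and one relabeling per null
    replicate, so the statistic is symmetric in its arguments.
    """
    f1, i1 = _weights_and_indices(assemblage1, dist)
    f2, i2 = _weights_and_indices(assemblage2, dist)
    if len(i1) == 0 or len(i2) == 0:
        raise DataError("D_pw undefined for empty assemblage")
    observed = dpw(assemblage1, assemblage2, dist, inner_weighted=inner_weighted)
    perms = tip_shuffle_null(dist, n_null, rng=rng, seed=seed,
                             exhaustive=exhaustive)
    p1 = perms[:, i1]                              # (R, k1)
    p2 = perms[:, i2]                              # (R, k2)
    C = dist.D[p1[:, :, None], p2[:, None, :]]     # (R, k1, k2)
    if inner_weighted:
        null_values = np.einsum("i,rij,j->r", f1, C, f2)
    else:
        null_values = ((C.mean(axis=2) * f1).sum(axis=1)
                       + (C.mean(axis=1) * f2).sum(axis=1)) / 2.0
    return _ses_result("SES_Dpw", observed, null_values, seed)


# ---------------------------------------------------------------------------
# alpha / beta / gamma decomposition over elevational bands
# ---------------------------------------------------------------------------

def _usable_plot_assemblages(community: CommunityMatrix, plots) -> dict:
    """Plot assemblages with >= 2 species; monospecific plots are skipped
    with a logged count (they have no within-plot pairwise structure)."""
    out = {}
    skipped = 0
    for p in plots:
        a = community.plot_assemblage(p)
        if (a > 0).sum() >= 2:
            out[p] = a
        else:
            skipped += 1
    if skipped:
        logger.info("skipped %d plot(s) with < 2 species", skipped)
    return out


def band_components(community: CommunityMatrix, dist: PairwiseDistance,
                    band, n_null: int = 1000, seed: int = 0,
                    inner_weighted: bool = True) -> BandComponents:
    """Alpha, beta-within and gamma dispersion of one elevational band.

    alpha = mean NRI over the band's plots; beta_within = mean S.E.S. D_pw
    over unordered plot pairs; gamma = NRI of the pooled band assemblage.
    Degenerate-null values are excluded from the averages.
    """
    plots = community.plots_in_band(band)
    assemblages = _usable_plot_assemblages(community, plots)
    if not assemblages:
        raise DataError(f"band {band!r} has no plot with >= 2 species")
    task = 0
    alphas = []
    for p, a in assemblages.items():
        r = nri(a, dist, n_null=n_null, rng=derived_rng(seed, _band_key(band), task))
        task += 1
        if not r.degenerate:
            alphas.append(r.ses)
    betas = []
    plot_ids = list(assemblages)
    for i in range(len(plot_ids)):
        for j in range(i + 1, len(plot_ids)):
            r = ses_dpw(assemblages[plot_ids[i]], assemblages[plot_ids[j]],
                        dist, n_null=n_null,
                        rng=derived_rng(seed, _band_key(band), task),
                        inner_weighted=inner_weighted)
            task += 1
            if not r.degenerate:
                betas.append(r.ses)
    pooled = pool_band(community, band)
    gamma_res = nri(pooled, dist, n_null=n_null,
                    rng=derived_rng(seed, _band_key(band), task))
    beta_within = float(np.mean(betas)) if betas else float("nan")
    if not betas:
        logger.info("band %r: beta-within undefined (fewer than 2 usable plots)", band)
    return BandComponents(
        band=band,
        alpha=float(np.mean(alphas)) if alphas else float("nan"),
        beta_within=beta_within,
        gamma=gamma_res.ses if not gamma_res.degenerate else float("nan"),
        n_plots=len(plots),
        n_plots_used=len(assemblages),
        n_pairs_used=len(betas),
        gamma_result=gamma_res,
    )


def all_band_components(community: CommunityMatrix, dist: PairwiseDistance,
                        n_null: int = 1000, seed: int = 0,
                        inner_weighted: bool = True) -> pd.DataFrame:
    """Band-level component table (one row per band)."""
    rows = []
    for band in community.bands:
        bc = band_components(community, dist, band, n_null=n_null, seed=seed,
                             inner_weighted=inner_weighted)
        rows.append({"band": bc.band, "alpha": bc.alpha,
                     "beta_within": bc.beta_within, "gamma": bc.gamma,
                     "n_plots": bc.n_plots, "n_plots_used": bc.n_plots_used,
                     "n_pairs_used": bc.n_pairs_used,
                     "n_null": n_null, "seed": seed})
    return pd.DataFrame(rows).set_index("band")


def band_beta_matrix(community: CommunityMatrix, dist: PairwiseDistance,
                     n_null: int = 1000, seed: int = 0,
                     inner_weighted: bool = True) -> PairwiseDistance:
    """S.E.S. D_pw between pooled assemblages of every band pair.

    Species data are pooled and summed over each band's plots; the matrix
    is symmetric with an (undefined) zero diagonal.  Note the entries are
    standardized effect sizes, not metric distances.
    """
    bands = community.bands
    if len(bands) < 2:
        raise DataError("need at least 2 bands")
    pooled = {b: pool_band(community, b) for b in bands}
    n = len(bands)
    M = np.zeros((n, n))
    task = 0
    for i in range(n):
        for j in range(i + 1, n):
            r = ses_dpw(pooled[bands[i]], pooled[bands[j]], dist,
                        n_null=n_null, rng=derived_rng(seed, 10_000 + task),
                        inner_weighted=inner_weighted)
            task += 1
            M[i, j] = M[j, i] = r.ses
    # entries are SES values (can be negative); bypass the nonnegativity
    # check by shifting into a plain labelled frame when needed
    return _SesMatrix([str(b) for b in bands], M)


class _SesMatrix(PairwiseDistance):
    """Symmetric labelled matrix of SES values (may be negative)."""

    def __post_init__(self) -> None:  # relax nonnegativity
        self.labels = list(self.labels)
        self.D = np.asarray(self.D, dtype=float)
        self.D = (self.D + self.D.T) / 2.0
        np.fill_diagonal(self.D, 0.0)
        self._index = {lab: i for i, lab in enumerate(self.labels)}
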