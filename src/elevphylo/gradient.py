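"""Gradient statistics: environmental ordination and distance construction,
polynomial OLS with AIC model choice, per-variable screening, forward
stepwise multiple regression, Mantel tests, multiple regression on distance
matrices (MRM), and three-set variation partitioning.

Ordinary fits go through :mod:`statsmodels`; the permutation machinery
(Mantel, MRM) is implemented here because the label-permutation schemes
are part of the method, not generic fitting.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import DataError, PairwiseDistance
from .traits import pca

logger = logging.getLogger(__name__)

__all__ = [
    "GradientFit",
    "DistanceSet",
    "env_pca",
    "build_distances",
    "ols_poly",
    "choose_poly_model",
    "simple_ols_screen",
    "stepwise_forward",
    "mantel",
    "mrm",
    "variation_partition",
]


@dataclass
class GradientFit:
    """A fitted diversity ~ environment model."""

    form: str                      # linear | quadratic | multiple
    terms: list[str]
    coef: pd.Series
    se: pd.Series
    r2: float
    fstat: float
    p: float
    aic: float
    n: int
    extra: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC (the extra penalty vanishes as n
        grows); preferred for band-level fits where n is 10-20."""
        k = len(self.coef) + 1
        if self.n - k - 1 <= 0:
            return float("inf")
        return self.aic + 2.0 * k * (k + 1) / (self.n - k - 1)


@dataclass
class DistanceSet:
    """Band-pair distance matrices used as Mantel/MRM predictors."""

    ele: PairwiseDistance
    rarea: PairwiseDistance
    clim: PairwiseDistance
    habit: PairwiseDistance

    def as_dict(self) -> dict[str, PairwiseDistance]:
        return {"Dist_ele": self.ele, "Dist_rarea": self.rarea,
                "Dist_clim": self.clim, "Dist_habit": self.habit}


# ---------------------------------------------------------------------------
# environmental ordination and distances
# ---------------------------------------------------------------------------

def env_pca(env: pd.DataFrame, climate_cols: list[str],
            hetero_cols: list[str]) -> pd.DataFrame:
    """Attach PC columns from two separate PCAs of the environment table.

    Climate variables yield ``PC1_clim``; the standard deviations of
    topographic variables yield ``PC1_hetero`` and ``PC2_hetero``.
    Inputs are standardized (z-scored) before each PCA.
    """
    if len(env) < 3:
        raise DataError("need at least 3 bands for the environmental PCA")
    out = env.copy()

    def _zscore(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(axis=0, ddof=1)
        zero = sd.index[sd == 0].tolist()
        if zero:
            raise DataError(f"zero-variance environmental column(s): {zero}")
        return (df - df.mean(axis=0)) / sd

    clim = pca(_zscore(env[climate_cols]), k=1)
    out["PC1_clim"] = clim.scores["PC1"]
    k_het = min(2, len(hetero_cols), len(env) - 1)
    het = pca(_zscore(env[hetero_cols]), k=k_het)
    out["PC1_hetero"] = het.scores["PC1"]
    out["PC2_hetero"] = het.scores["PC2"] if k_het >= 2 else 0.0
    return out


def _abs_diff_matrix(v: pd.Series) -> PairwiseDistance:
    x = v.to_numpy(dtype=float)
    return PairwiseDistance([str(i) for i in v.index],
                            np.abs(x[:, None] - x[None, :]))


def build_distances(env: pd.DataFrame, elevation_col: str = "elevation",
                    rarea_col: str = "RArea") -> DistanceSet:
    """Band-pair distance matrices.

    Elevational difference is the geographic-distance proxy; RArea
    distance the absolute difference of (log) regional area; climatic
    distance Euclidean on ``PC1_clim``; habitat distance Euclidean on
    ``PC1_hetero``/``PC2_hetero``.
    """
    for col in (elevation_col, rarea_col, "PC1_clim", "PC1_hetero", "PC2_hetero"):
        if col not in env.columns:
            raise DataError(f"environment table lacks column {col!r}")
    labels = [str(i) for i in env.index]
    H = env[["PC1_hetero", "PC2_hetero"]].to_numpy(dtype=float)
    Dh = np.sqrt(((H[:, None, :] - H[None, :, :]) ** 2).sum(axis=2))
    return DistanceSet(
        ele=_abs_diff_matrix(env[elevation_col]),
        rarea=_abs_diff_matrix(env[rarea_col]),
        clim=_abs_diff_matrix(env["PC1_clim"]),
        habit=PairwiseDistance(labels, Dh),
    )


# ---------------------------------------------------------------------------
# OLS with AIC model choice
# ---------------------------------------------------------------------------

def _aic(n: int, rss: float, k_mean: int, tss: float = 0.0) -> float:
    """Gaussian-profile AIC, ``n ln(RSS/n) + 2k`` with k = mean parameters
    + 1 for the error variance.

    RSS is floored at a scale-relative epsilon (1e-12 of the total sum of
    squares) so that nested noise-free fits compare by parameter count
    rather than by rounding noise in an exactly-zero residual.
    """
    floor = max(tss * 1e-12, np.finfo(float).tiny)
    rss = max(rss, floor)
    return n * math.log(rss / n) + 2 * (k_mean + 1)


def ols_poly(y: pd.Series, x: pd.Series, degree: int = 1) -> GradientFit:
    """Polynomial OLS of a band-level response on (centered) elevation."""
    if degree not in (1, 2):
        raise DataError("degree must be 1 or 2")
    yv = y.to_numpy(dtype=float)
    xv = x.to_numpy(dtype=float)
    n = len(yv)
    if n < degree + 2:
        raise DataError(f"need at least {degree + 2} points for degree {degree}")
    xc = xv - xv.mean()
    cols = {"x": xc}
    if degree == 2:
        cols["x2"] = xc**2
    X = sm.add_constant(pd.DataFrame(cols))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DataError("degenerate design (collinear polynomial terms)")
    fit = sm.OLS(yv, X).fit()
    rss = float(fit.ssr)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    return GradientFit(
        form="linear" if degree == 1 else "quadratic",
        terms=list(X.columns),
        coef=pd.Series(fit.params.to_numpy(), index=X.columns),
        se=pd.Series(fit.bse.to_numpy(), index=X.columns),
        r2=float(fit.rsquared),
        fstat=float(fit.fvalue),
        p=float(fit.f_pvalue),
        aic=_aic(n, rss, k_mean=X.shape[1], tss=tss),
        n=n,
    )


def choose_poly_model(y: pd.Series, x: pd.Series,
                      small_sample: bool = True
                      ) -> tuple[GradientFit, GradientFit, str]:
    """Fit linear and quadratic models; report both plus the preferred form.

    With ``small_sample=True`` (default) the choice uses AICc, which is
    the appropriate criterion at band-level sample sizes (n of order 10;
    plain AIC admits a spurious quadratic term in roughly a fifth of
    truly linear datasets at any noise level).  Set ``False`` to choose
    by plain AIC.
    """
    lin = ols_poly(y, x, degree=1)
    quad = ols_poly(y, x, degree=2)
    if small_sample:
        best = "linear" if lin.aicc <= quad.aicc else "quadratic"
    else:
        best = "linear" if lin.aic <= quad.aic else "quadratic"
    return lin, quad, best


def simple_ols_screen(y: pd.Series, env: pd.DataFrame,
                      predictors: list[str] | None = None) -> pd.DataFrame:
    """One univariate OLS per environmental predictor: R^2 and F-test p."""
    if predictors is None:
        predictors = ["RArea", "PC1_clim", "PC1_hetero", "PC2_hetero"]
    rows = []
    for name in predictors:
        fit = ols_poly(y, env[name], degree=1)
        rows.append({"predictor": name, "r2": fit.r2, "p": fit.p,
                     "slope": fit.coef["x"], "stars": _stars(fit.p)})
    return pd.DataFrame(rows).set_index("predictor")


def stepwise_forward(y: pd.Series, X: pd.DataFrame,
                     alpha_enter: float = 0.05) -> GradientFit:
    """Forward stepwise multiple regression by partial-F p-value.

    At each step the candidate with the smallest partial-F p-value is
    added if that p-value is below ``alpha_enter``; otherwise selection
    stops.  An empty selection yields an intercept-only fit flagged in
    ``extra['intercept_only']``.
    """
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if n <= X.shape[1] + 2:
        raise DataError("too few observations for stepwise selection")
    selected: list[str] = []
    remaining = list(X.columns)
    while remaining:
        pvals = {}
        for cand in remaining:
            cols = selected + [cand]
            Xd = sm.add_constant(X[cols].astype(float))
            fit = sm.OLS(yv, Xd).fit()
            # partial F for one added term == squared t-test of its slope
            pvals[cand] = float(fit.pvalues[cand])
        best = min(pvals, key=lambda c: (pvals[c], c))
        if pvals[best] < alpha_enter:
            selected.append(best)
            remaining.remove(best)
        else:
            break
    Xd = sm.add_constant(X[selected].astype(float)) if selected else (
        pd.DataFrame({"const": np.ones(n)}, index=X.index))
    fit = sm.OLS(yv, Xd).fit()
    return GradientFit(
        form="multiple",
        terms=list(Xd.columns),
        coef=pd.Series(fit.params.to_numpy(), index=Xd.columns),
        se=pd.Series(fit.bse.to_numpy(), index=Xd.columns),
        r2=float(fit.rsquared) if selected else 0.0,
        fstat=float(fit.fvalue) if selected else float("nan"),
        p=float(fit.f_pvalue) if selected else float("nan"),
        aic=_aic(n, float(fit.ssr), k_mean=Xd.shape[1],
                 tss=float(np.sum((yv - yv.mean()) ** 2))),
        n=n,
        extra={"intercept_only": not selected, "alpha_enter": alpha_enter},
    )


# ---------------------------------------------------------------------------
# distance-matrix statistics
# ---------------------------------------------------------------------------

def _tri(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def _check_same_labels(*mats: PairwiseDistance) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if list(m.labels) != list(labels):
            raise DataError("distance matrices have different labels")


def mantel(Dy: PairwiseDistance, Dx: PairwiseDistance, n_perm: int = 10000,
           seed: int | None = None, rng: np.random.Generator | None = None,
           alternative: str = "two-sided",
           exhaustive: bool | None = None) -> tuple[float, float]:
    """Simple Mantel test between two labelled distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    p-value permutes the labels of ``Dy`` (rows and columns together)
    and counts permutations at least as extreme as the observed value,
    observed included in numerator and denominator.  With
    ``exhaustive=True`` (or n <= 7 items and ``exhaustive=None``) all
    n! permutations are enumerated.
    """
    _check_same_labels(Dy, Dx)
    n = len(Dy)
    if n < 4:
        raise DataError("Mantel test needs at least 4 items")
    yv, xv = _tri(Dy.D), _tri(Dx.D)
    if np.std(yv) == 0 or np.std(xv) == 0:
        raise DataError("constant distances; Mantel r undefined")
    r_obs = float(np.corrcoef(yv, xv)[0, 1])
    iu = np.triu_indices(n, k=1)

    def perm_r(perm: np.ndarray) -> float:
        yp = Dy.D[perm[iu[0]], perm[iu[1]]]
        return float(np.corrcoef(yp, xv)[0, 1])

    if exhaustive is None:
        exhaustive = n <= 7
    if exhaustive:
        perms = itertools.permutations(range(n))
        r_perm = np.array([perm_r(np.array(p)) for p in perms])
        count = _extreme_count(r_perm, r_obs, alternative)
        p = count / len(r_perm)   # identity permutation plays the observed
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        r_perm = np.array([perm_r(rng.permutation(n)) for _ in range(n_perm)])
        count = 1 + _extreme_count(r_perm, r_obs, alternative)
        p = count / (n_perm + 1)
    return r_obs, float(p)


def _extreme_count(r_perm: np.ndarray, r_obs: float, alternative: str) -> int:
    tol = 1e-12
    if alternative == "two-sided":
        return int(np.sum(np.abs(r_perm) >= np.abs(r_obs) - tol))
    if alternative == "greater":
        return int(np.sum(r_perm >= r_obs - tol))
    if alternative == "less":
        return int(np.sum(r_perm <= r_obs + tol))
    raise DataError(f"unknown alternative {alternative!r}")


def mrm(Dy: PairwiseDistance, Dxs: dict[str, PairwiseDistance],
        n_perm: int = 1000, seed: int | None = None,
        rng: np.random.Generator | None = None) -> dict:
    """Multiple regression on distance matrices.

    OLS of the response's lower triangle on the predictors' lower
    triangles; per-coefficient significance by permuting the labels of
    the response matrix, refitting, and comparing |t| (two-sided,
    observed included).
    """
    _check_same_labels(Dy, *Dxs.values())
    n = len(Dy)
    if n < 5:
        raise DataError("MRM needs at least 5 items")
    names = list(Dxs)
    Xcols = [_tri(Dxs[k].D) for k in names]
    X = np.column_stack([np.ones(len(Xcols[0]))] + Xcols)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        # identify the offending predictor pair for the error message
        worst = None
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                c = abs(np.corrcoef(Xcols[a], Xcols[b])[0, 1])
                if worst is None or c > worst[0]:
                    worst = (c, names[a], names[b])
        raise DataError(
            f"collinear distance predictors (condition number {cond:.2g}); "
            f"most correlated pair: {worst[1]}, {worst[2]}")
    yv = _tri(Dy.D)
    iu = np.triu_indices(n, k=1)

    def fit(yvec: np.ndarray):
        beta, *_ = np.linalg.lstsq(X, yvec, rcond=None)
        resid = yvec - X @ beta
        dof = len(yvec) - X.shape[1]
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        t = beta / np.sqrt(np.diag(cov))
        tss = np.sum((yvec - yvec.mean())**2)
        r2 = 1.0 - (resid @ resid) / tss if tss > 0 else 0.0
        return beta, t, r2

    beta_obs, t_obs, r2_obs = fit(yv)
    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = Dy.D[perm[iu[0]], perm[iu[1]]]
        _, t_p, _ = fit(yp)
        exceed += np.abs(t_p) >= np.abs(t_obs) - 1e-12
    pvals = (1 + exceed) / (n_perm + 1)
    index = ["intercept"] + names
    return {
        "coef": pd.Series(beta_obs, index=index),
        "t": pd.Series(t_obs, index=index),
        "p": pd.Series(pvals, index=index),
        "r2": float(r2_obs),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, X: pd.DataFrame) -> float:
    Xd = sm.add_constant(X.astype(float))
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise DataError("rank-deficient design in variation partitioning")
    return float(sm.OLS(y, Xd).fit().rsquared)


def variation_partition(y: pd.Series, groups: dict[str, pd.DataFrame]) -> dict:
    """Three-set variation partitioning via partial regressions.

    ``groups`` maps group name -> predictor block (e.g. regional area,
    climate PCs, heterogeneity PCs).  The R^2 of all 7 nonempty subsets
    is computed; the unique fraction of a group is R2(all) minus R2 of
    the other two combined, the total combined (shared) fraction is
    R2(all) minus the sum of uniques, and the residual is 1 - R2(all).
    Negative shared fractions are reported as-is and flagged.
    """
    names = list(groups)
    if len(names) != 3:
        raise DataError("variation_partition expects exactly 3 groups")
    yv = y.to_numpy(dtype=float)
    total_preds = sum(g.shape[1] for g in groups.values())
    if len(yv) <= total_preds + 2:
        raise DataError("too few observations for variation partitioning")
    subset_r2: dict[frozenset, float] = {}
    for k in range(1, 4):
        for combo in itertools.combinations(names, k):
            X = pd.concat([groups[g] for g in combo], axis=1)
            subset_r2[frozenset(combo)] = _r2(yv, X)
    full = subset_r2[frozenset(names)]
    unique = {}
    for g in names:
        others = frozenset(set(names) - {g})
        unique[g] = full - subset_r2[others]
    combined = full - sum(unique.values())
    out = {
        "unique": unique,
        "combined": combined,
        "r2_full": full,
        "residual": 1.0 - full,
        "subset_r2": {tuple(sorted(k)): v for k, v in subset_r2.items()},
        "negative_fractions": combined < 0 or any(v < 0 for v in unique.values()),
    }
    if out["negative_fractions"]:
        logger.info("variation partitioning produced negative fraction(s)")
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
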