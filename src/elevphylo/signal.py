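"""Phylogenetic signal statistics: Blomberg's K and Pagel's lambda.

Both statistics treat a continuous trait as the outcome of Brownian
motion (BM) along the tree.  K compares the observed ratio of the
trait's cross-species variance to its phylogenetically corrected
(GLS) variance against the BM expectation of that ratio; K = 1 under
BM, K < 1 when close relatives resemble each other less than BM
predicts.  Lambda rescales all off-diagonal entries of the BM
covariance by a factor in [0, lambda_max] and is estimated by profile
maximum likelihood; lambda = 1 is BM, lambda = 0 a star phylogeny
(no signal).

Significance: K is tested by permuting trait values across tips and
comparing the variance of phylogenetically independent contrasts
(PICs); lambda by a likelihood-ratio test of lambda_hat against
lambda = 0 on chi-square with 1 df (conservative at the boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import DataError, Phylogeny, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "SignalResult",
    "bm_covariance",
    "blomberg_k",
    "lambda_transform",
    "pagel_lambda",
    "pic_matrix",
    "signal_report",
]


@dataclass
class SignalResult:
    """Signal statistics of one trait."""

    trait: str
    K: float
    p_K: float
    lam: float
    logL_lambda: float
    logL_lambda0: float
    p_lambda: float
    lambda_identifiable: bool = True


# ---------------------------------------------------------------------------
# BM covariance and the lambda transform
# ---------------------------------------------------------------------------

def bm_covariance(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance of tip values.

    ``C[i, j]`` is the root-to-MRCA path length shared by tips i and j;
    the diagonal holds root-to-tip depths.  Labels are sorted.
    """
    if tree.tree.seed_node is None:
        raise DataError("tree has no root")
    labels = tree.tips
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depth: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    tips_below: dict[int, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
            continue
        children = [tips_below[id(c)] for c in node.child_nodes()]
        here = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.array(children[a], dtype=int)
                jb = np.array(children[b], dtype=int)
                C[np.ix_(ia, jb)] = here
                C[np.ix_(jb, ia)] = here
        tips_below[id(node)] = [i for c in children for i in c]
    return labels, C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries of a BM covariance by ``lam``.

    ``lam`` must lie in [0, lambda_max] with lambda_max the largest
    value keeping every off-diagonal at or below the smaller of its two
    diagonals.
    """
    lmax = lambda_max(C)
    if not (0.0 <= lam <= lmax + 1e-12):
        raise DataError(f"lambda {lam} outside [0, {lmax:.6g}]")
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def lambda_max(C: np.ndarray) -> float:
    """Largest admissible lambda for a BM covariance."""
    d = np.diag(C)
    n = C.shape[0]
    off = C[~np.eye(n, dtype=bool)]
    if np.all(off <= 1e-15):
        return 1.0
    lim = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if C[i, j] > 1e-15:
                lim = min(lim, min(d[i], d[j]) / C[i, j])
    return float(lim)


# ---------------------------------------------------------------------------
# GLS helpers
# ---------------------------------------------------------------------------

def _gls_mean(C: np.ndarray, x: np.ndarray) -> float:
    one = np.ones(len(x))
    Ci1 = np.linalg.solve(C, one)
    return float(Ci1 @ x / (one @ Ci1))


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def pic_matrix(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Linear map from tip values to phylogenetically independent contrasts.

    Felsenstein's pruning algorithm: ancestral values are branch-length
    weighted averages of descendants, so each standardized contrast is a
    fixed linear combination of tip values.  Returns (tip labels sorted,
    matrix M of shape (n-1, n)) with contrasts = M @ x.  Polytomies are
    resolved arbitrarily (zero-length internal edges), which leaves the
    contrast variance unchanged in distribution.
    """
    work = tree.tree.clone(depth=1)
    work.resolve_polytomies(limit=2, update_bipartitions=False)
    labels = sorted(leaf.taxon.label for leaf in work.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    rows = []
    coeff: dict[int, np.ndarray] = {}
    blen: dict[int, float] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(n)
            v[index[node.taxon.label]] = 1.0
            coeff[id(node)] = v
            blen[id(node)] = node.edge.length or 0.0
            continue
        ch = node.child_nodes()
        assert len(ch) == 2, "tree must be bifurcating after resolution"
        a, b = ch
        va, vb = coeff[id(a)], coeff[id(b)]
        ba, bb = blen[id(a)], blen[id(b)]
        if ba + bb <= 0:
            # zero-length cherry: contrast undefined at zero scale; use a
            # tiny epsilon to keep the linear map finite
            ba = bb = 1e-12
        rows.append((va - vb) / np.sqrt(ba + bb))
        coeff[id(node)] = (bb * va + ba * vb) / (ba + bb)
        extra = ba * bb / (ba + bb)
        blen[id(node)] = (node.edge.length or 0.0) + extra
    return labels, np.array(rows)


def blomberg_k(tree: Phylogeny, x: pd.Series, n_perm: int = 999,
               seed: int | None = None,
               rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Blomberg's K with a PIC-variance randomization test.

    K = (MSE0/MSE) / E_BM[MSE0/MSE], where MSE0 is the trait variance
    about the GLS mean, MSE the GLS (phylogenetically corrected) mean
    square, and the expectation is the analytic BM value
    (tr C - n / (1' C^-1 1)) / (n - 1).  The p-value is the proportion
    of tip permutations (observed included) whose PIC variance is at or
    below the observed PIC variance.
    """
    labels, C = bm_covariance(tree)
    xv = x.reindex(labels).to_numpy(dtype=float)
    if np.any(~np.isfinite(xv)):
        raise DataError("trait values missing or non-finite for some tips")
    n = len(xv)
    if n < 4:
        raise DataError("Blomberg's K needs at least 4 tips")
    if np.allclose(xv, xv[0]):
        raise DataError("constant trait")
    one = np.ones(n)
    try:
        Ci1 = np.linalg.solve(C, one)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular BM covariance") from exc
    a_hat = float(Ci1 @ xv / (one @ Ci1))
    resid = xv - a_hat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ np.linalg.solve(C, resid) / (n - 1)
    expected = (np.trace(C) - n / (one @ Ci1)) / (n - 1)
    K = float((mse0 / mse) / expected)

    if n_perm == 0:
        return K, float("nan")
    pic_labels, M = pic_matrix(tree)
    xp = x.reindex(pic_labels).to_numpy(dtype=float)
    obs_var = np.var(M @ xp, ddof=1)
    if rng is None:
        rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_vars = np.var(xp[perm_idx] @ M.T, axis=1, ddof=1)
    p = (1 + int(np.sum(perm_vars <= obs_var))) / (n_perm + 1)
    return K, float(p)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

def _lambda_loglik(lam: float, C: np.ndarray, x: np.ndarray) -> float:
    """Profile log-likelihood at lambda (GLS mean and sigma^2 profiled out)."""
    n = len(x)
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    try:
        L = np.linalg.cholesky(Cl)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    one = np.ones(n)
    w = np.linalg.solve(L, np.column_stack([x, one]))
    xw, ow = w[:, 0], w[:, 1]
    a_hat = float(ow @ xw / (ow @ ow))
    r = xw - a_hat * ow
    s2 = float(r @ r) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagel_lambda(tree: Phylogeny, x: pd.Series,
                 test_against: float = 0.0
                 ) -> tuple[float, float, float, float, bool]:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    Returns ``(lambda_hat, logL_at_hat, logL_at_reference, p, identifiable)``.
    The reference for the LR test is lambda = ``test_against`` (0 by
    default; pass 1.0 to test departure from BM).  On a star tree the
    likelihood is flat in lambda; lambda is reported as 0 with
    ``identifiable=False``.
    """
    labels, C = bm_covariance(tree)
    xv = x.reindex(labels).to_numpy(dtype=float)
    if np.any(~np.isfinite(xv)):
        raise DataError("trait values missing or non-finite for some tips")
    if np.allclose(xv, xv[0]):
        raise DataError("constant trait")
    n = len(xv)
    off = C[~np.eye(n, dtype=bool)]
    if np.all(off <= 1e-15):
        logL = _lambda_loglik(0.0, C, xv)
        return 0.0, logL, logL, 1.0, False
    lmax = lambda_max(C)
    # coarse grid to dodge flat or multimodal profiles, then local refine
    grid = np.linspace(0.0, lmax, 21)
    vals = [_lambda_loglik(l, C, xv) for l in grid]
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -_lambda_loglik(l, C, xv),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat = float(res.x)
    logL_hat = float(-res.fun)
    # keep the better of grid optimum and refined optimum
    if vals[i] > logL_hat:
        lam_hat, logL_hat = float(grid[i]), float(vals[i])
    logL_ref = _lambda_loglik(test_against, C, xv)
    lr = max(0.0, 2.0 * (logL_hat - logL_ref))
    p = float(stats.chi2.sf(lr, df=1))
    return lam_hat, logL_hat, logL_ref, p, True


# ---------------------------------------------------------------------------
# per-trait report
# ---------------------------------------------------------------------------

def signal_report(tree: Phylogeny, traits: TraitTable, n_perm: int = 999,
                  seed: int = 0, log_transform: bool = True,
                  lambda_test_against: float = 0.0) -> pd.DataFrame:
    """K and lambda for every trait column, as a delimited-ready table.

    Trait values are log-transformed by default (they are strictly
    positive measurements); both statistics are invariant to the
    subsequent affine standardization so none is applied.
    """
    rows = []
    for t, (name) in enumerate(traits.trait_names):
        x = traits.traits[name]
        if log_transform:
            x = np.log(x)
        K, pK = blomberg_k(tree, x, n_perm=n_perm,
                           rng=np.random.default_rng(
                               np.random.SeedSequence(seed, spawn_key=(t,))))
        lam, lL, lL0, pl, ident = pagel_lambda(tree, x,
                                               test_against=lambda_test_against)
        rows.append({
            "trait": name, "K": K, "p_K": pK, "K_stars": stars(pK),
            "lambda": lam, "p_lambda": pl, "lambda_stars": stars(pl),
            "logL_lambda": lL, "logL_ref": lL0,
            "lambda_identifiable": ident,
        })
    return pd.DataFrame(rows).set_index("trait")


def stars(p: float) -> str:
    """Significance stars: *P<0.05, **P<0.01, ***P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
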