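"""Core data containers: phylogenies, community matrices, trait tables and
pairwise-distance matrices.

Trees are held as :class:`dendropy.Tree` objects wrapped in a thin
:class:`Phylogeny` facade that enforces the invariants the downstream
dispersion and signal statistics rely on (unique tip labels, branch lengths
present and nonnegative).  Tabular data are plain :class:`pandas.DataFrame`
objects wrapped with light validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "CommunityMatrix",
    "TraitTable",
    "PairwiseDistance",
    "read_newick",
    "write_newick",
    "prune_to_species",
    "cophenetic_distance",
    "pool_band",
    "assign_bands",
]


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# PairwiseDistance
# ---------------------------------------------------------------------------

@dataclass
class PairwiseDistance:
    """A labelled symmetric distance matrix with zero diagonal.

    Parameters
    ----------
    labels
        Item labels, one per row/column of ``D``.
    D
        Square symmetric nonnegative matrix, zero on the diagonal.
    """

    labels: list[str]
    D: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise DataError(
                f"distance matrix shape {self.D.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise DataError("duplicate labels in distance matrix")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise DataError("distance matrix diagonal is not zero")
        if np.any(self.D < -1e-12):
            raise DataError("negative distances")
        # exact symmetry / zero diagonal after validation
        self.D = (self.D + self.D.T) / 2.0
        np.fill_diagonal(self.D, 0.0)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise DataError(f"label {exc.args[0]!r} not in distance matrix") from exc

    def get(self, a: str, b: str) -> float:
        return float(self.D[self._index[a], self._index[b]])

    def subset(self, labels: Sequence[str]) -> "PairwiseDistance":
        idx = self.index_of(labels)
        return PairwiseDistance(list(labels), self.D[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairwiseDistance":
        return cls(list(df.index), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """A rooted tree with branch lengths over a set of uniquely labelled tips.

    Wraps a :class:`dendropy.Tree`; polytomies are allowed, zero-length
    edges are allowed (zero cophenetic distances between distinct tips are
    logged).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate()

    def _validate(self) -> None:
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in self.tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise DataError("tree has unlabelled tips")
        if len(set(labels)) != len(labels):
            raise DataError("tip labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise DataError(
                    "branch length missing on an edge; lengths are required"
                )
            if edge.length < 0:
                raise DataError(f"negative branch length {edge.length}")

    # -- properties -------------------------------------------------------

    @property
    def tips(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise DataError(f"malformed newick: {exc}") from exc
        return cls(tree)

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    # -- operations -------------------------------------------------------

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single rooted newick tree with branch lengths from ``path``."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    tree.write(path)


def prune_to_species(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Prune ``tree`` down to the tip set ``keep``.

    Path lengths between retained tips are preserved; internal nodes of
    degree two created by the pruning are collapsed with their edge lengths
    summed.
    """
    keep = set(keep)
    tips = set(tree.tips)
    missing = sorted(keep - tips)
    if missing:
        raise DataError(f"species not in tree: {missing}")
    pruned = tree.tree.clone(depth=1)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    pruned.retain_taxa(taxa)
    # retain_taxa suppresses unifurcations internally; make sure the root
    # is clean too
    pruned.suppress_unifurcations()
    return Phylogeny(pruned)


def cophenetic_distance(tree: Phylogeny) -> PairwiseDistance:
    """Tip-to-tip path-length (cophenetic / patristic) distance matrix.

    Labels are sorted alphabetically.  Computed in a single post-order
    pass accumulating root distances, then pairing tips at their most
    recent common ancestor.
    """
    labels = tree.tips
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    # root distance per node
    depth: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    tip_depth = np.zeros(n)
    for leaf in tree.tree.leaf_node_iter():
        tip_depth[index[leaf.taxon.label]] = depth[id(leaf)]
    # tips in distinct child subtrees of a node have that node as their MRCA:
    # d(i, j) = depth(i) + depth(j) - 2 * depth(mrca)
    tips_below: dict[int, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = [index[node.taxon.label]]
            continue
        children = [tips_below[id(c)] for c in node.child_nodes()]
        here = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.array(children[a], dtype=int)
                jb = np.array(children[b], dtype=int)
                block = tip_depth[ia][:, None] + tip_depth[jb][None, :] - 2.0 * here
                D[np.ix_(ia, jb)] = block
                D[np.ix_(jb, ia)] = block.T
        tips_below[id(node)] = [i for c in children for i in c]
    if n > 1:
        off = D[~np.eye(n, dtype=bool)]
        if np.any(np.isclose(off, 0.0)):
            logger.info("zero cophenetic distance between distinct tips")
    return PairwiseDistance(labels, D)


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------

class CommunityMatrix:
    """Plot-by-species abundance matrix with per-plot metadata.

    ``abundance`` is a wide DataFrame (index = plot ids, columns = species,
    values = stem counts); ``plot_meta`` carries at least ``transect`` and
    ``elevation`` columns and, once bands are assigned, a ``band`` column.
    """

    def __init__(self, abundance: pd.DataFrame, plot_meta: pd.DataFrame):
        abundance = abundance.astype(float)
        if (abundance.to_numpy() < 0).any():
            raise DataError("negative abundances")
        if not abundance.index.equals(plot_meta.index):
            missing = set(abundance.index) ^ set(plot_meta.index)
            raise DataError(f"plot ids of abundance and metadata differ: {sorted(missing)!r}")
        if "elevation" not in plot_meta.columns:
            raise DataError("plot_meta must contain an 'elevation' column")
        self.abundance = abundance
        self.plot_meta = plot_meta.copy()

    # -- properties -------------------------------------------------------

    @property
    def plots(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def bands(self) -> list:
        if "band" not in self.plot_meta.columns:
            raise DataError("bands not assigned; call assign_bands first")
        return sorted(self.plot_meta["band"].unique())

    # -- band handling ----------------------------------------------------

    def assign_bands(self, width: float = 100.0) -> "CommunityMatrix":
        """Bin plots into contiguous elevational bands ``[e, e+width)``.

        The band id is the integer lower edge of the interval.
        """
        if width <= 0:
            raise DataError("band width must be positive")
        edges = np.floor(self.plot_meta["elevation"].to_numpy() / width) * width
        out = CommunityMatrix(self.abundance, self.plot_meta)
        out.plot_meta["band"] = edges.astype(int)
        return out

    def plots_in_band(self, band) -> list[str]:
        meta = self.plot_meta
        if "band" not in meta.columns:
            raise DataError("bands not assigned")
        sel = meta.index[meta["band"] == band]
        return list(sel)

    def plot_assemblage(self, plot: str) -> pd.Series:
        """Nonzero abundance vector of one plot."""
        row = self.abundance.loc[plot]
        return row[row > 0]

    # -- species/tree reconciliation --------------------------------------

    def check_against_tree(self, tree: Phylogeny, drop_missing: bool = False
                           ) -> "CommunityMatrix":
        """Verify every species is a tip of ``tree``.

        Hard error by default; with ``drop_missing=True`` the offending
        species columns are dropped with a logged warning.
        """
        tips = set(tree.tips)
        missing = [s for s in self.species if s not in tips]
        if not missing:
            return self
        if not drop_missing:
            raise DataError(f"species absent from tree: {missing}")
        logger.warning("dropping %d species absent from tree: %s",
                       len(missing), missing)
        return CommunityMatrix(self.abundance.drop(columns=missing),
                               self.plot_meta)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read_csv(cls, abundance_path: str | Path, meta_path: str | Path,
                 sep: str = ",") -> "CommunityMatrix":
        """Read community data from delimited text.

        The abundance table may be wide (plot rows, species columns) or
        long (columns ``plot``, ``species``, ``abundance``); the form is
        auto-detected from the column signature.
        """
        ab = pd.read_csv(abundance_path, sep=sep)
        if {"plot", "species", "abundance"}.issubset(ab.columns):
            wide = ab.pivot_table(index="plot", columns="species",
                                  values="abundance", fill_value=0.0,
                                  aggfunc="sum")
        else:
            wide = ab.set_index(ab.columns[0])
        meta = pd.read_csv(meta_path, sep=sep).set_index("plot")
        wide = wide.loc[meta.index]
        return cls(wide, meta)

    def write_csv(self, abundance_path: str | Path, meta_path: str | Path
                  ) -> None:
        long = (self.abundance.stack()
                .rename("abundance")
                .rename_axis(["plot", "species"])
                .reset_index())
        long = long[long["abundance"] > 0]
        long.to_csv(abundance_path, index=False)
        self.plot_meta.rename_axis("plot").reset_index().to_csv(
            meta_path, index=False)


def assign_bands(community: CommunityMatrix, width: float = 100.0
                 ) -> CommunityMatrix:
    """Functional wrapper over :meth:`CommunityMatrix.assign_bands`."""
    return community.assign_bands(width)


def pool_band(community: CommunityMatrix, band) -> pd.Series:
    """Pool and sum abundances of all plots of one elevational band.

    Species whose pooled abundance is zero are dropped.
    """
    plots = community.plots_in_band(band)
    if not plots:
        raise DataError(f"band {band!r} has no plots")
    pooled = community.abundance.loc[plots].sum(axis=0)
    return pooled[pooled > 0]


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------

class TraitTable:
    """Species-by-trait numeric table.

    Trait values must be strictly positive (they are log-transformed
    before PCA) and complete; there is no imputation.
    """

    def __init__(self, traits: pd.DataFrame):
        if traits.isna().any().any():
            bad = traits.columns[traits.isna().any()].tolist()
            raise DataError(f"missing trait values in columns {bad}")
        self.traits = traits.astype(float)

    @property
    def species(self) -> list[str]:
        return list(self.traits.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    @classmethod
    def read_csv(cls, path: str | Path, sep: str = ",") -> "TraitTable":
        df = pd.read_csv(path, sep=sep)
        return cls(df.set_index(df.columns[0]))

    def write_csv(self, path: str | Path) -> None:
        self.traits.rename_axis("species").reset_index().to_csv(path, index=False)


def _series_assemblage(assemblage: Mapping[str, float] | pd.Series) -> pd.Series:
    """Normalize an assemblage mapping to a nonzero float Series."""
    s = pd.Series(assemblage, dtype=float)
    s = s[s > 0]
    return s
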