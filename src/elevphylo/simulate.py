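"""Synthetic elevational-transect data with known assembly mechanisms.

The generator emulates the data structure the analysis consumes: a dated
(ultrametric) phylogeny over a regional species pool, five positive
functional traits evolved on that tree, a band-level environment table
with monotone climate gradients and hump-or-flat topographic
heterogeneity, and plot-by-species stem counts assembled under one of
three rules:

``neutral``
    individuals sampled in proportion to fixed lognormal regional
    abundances (no trait involvement);
``filtering``
    sampling weights multiplied by a Gaussian filter
    ``exp(-(t_s - mu(e))^2 / (2 sigma_f^2))`` around an elevation-dependent
    trait optimum, producing phylogenetic/functional clustering when the
    assembly trait is conserved;
``competition``
    sequential draws under neutral weights in which a candidate closer
    than ``delta`` in assembly-trait distance to any resident is
    rejected (limiting similarity), producing overdispersion.

All randomness flows from one master seed through order-independent
substreams.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .core import CommunityMatrix, DataError, Phylogeny, TraitTable
from .dispersion import derived_rng
from .signal import bm_covariance, lambda_transform

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_traits",
    "simulate_environment",
    "assemble_communities",
    "generate_dataset",
    "CLIMATE_COLS",
    "HETERO_COLS",
]

#: column names of the synthetic environment table
CLIMATE_COLS = ["temp_mean", "temp_min", "temp_seasonality",
                "growing_degree_days", "precip_log", "precip_summer_log"]
HETERO_COLS = ["sd_slope", "sd_aspect", "sd_convexity"]


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic transect.

    Defaults describe a single transect of 10 contiguous 100-m bands
    (200-1200 m), 10 plots per band and 100 stems per plot over a pool
    of 100 species, with a conserved assembly trait (``trait_lambda=1``).
    ``filter_sigma`` and ``competition_delta`` are in units of the
    latent assembly trait (whose SD is roughly 2 at the default tree
    depth and ``sigma2=1``).
    """

    scenario: str = "neutral"            # neutral | filtering | competition
    n_species: int = 100
    n_bands: int = 10
    band_width: float = 100.0            # m
    base_elevation: float = 200.0        # m, lower edge of the lowest band
    plots_per_band: int = 10
    individuals_per_plot: int = 100
    birth: float = 1.0                   # birth-death rates, per unit time
    death: float = 0.0
    sigma2: float = 1.0                  # BM rate of the latent traits
    trait_lambda: float = 1.0            # Pagel-lambda scaling of trait cov
    filter_sigma: float = 0.5            # Gaussian filter width, trait units
    optimum_slope: float | None = None   # trait units per m; None = auto
    competition_delta: float = 1.0       # limiting-similarity radius
    abundance_sdlog: float = 1.0         # lognormal regional abundances
    climate_noise: float = 0.1           # noise SD as fraction of signal SD
    hetero_profile: str = "hump"         # hump | flat
    rarea_profile: str = "decreasing"    # decreasing | hump
    retry_cap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("neutral", "filtering", "competition"):
            raise DataError(f"unknown scenario {self.scenario!r}")
        if self.birth <= 0 or self.death < 0:
            raise DataError("need birth > death >= 0")
        if self.birth <= self.death:
            raise DataError("need birth > death for the tree to grow")
        if self.scenario == "filtering" and self.filter_sigma <= 0:
            raise DataError("filter_sigma must be positive")
        if self.scenario == "competition" and self.competition_delta <= 0:
            raise DataError("competition_delta must be positive")


@dataclass
class SyntheticDataset:
    """Everything one scenario produces."""

    tree: Phylogeny
    traits: TraitTable
    latent: pd.DataFrame     # columns z1 (assembly trait), z2
    env: pd.DataFrame
    community: CommunityMatrix
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, birth: float = 1.0, death: float = 0.0,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> Phylogeny:
    """Birth-death tree conditioned on ``n_species`` extant tips.

    Forward simulation from a crown with two lineages; the simulation
    stops when the extant count first reaches ``n_species``, after which
    every surviving lineage is extended by one further exponential
    waiting time (the time to the next, unexecuted, event).  Extinct
    lineages are pruned.  For a pure-birth process the expected tree
    height is ``(H_n - 1) / birth`` with ``H_n`` the n-th harmonic
    number.
    """
    if birth <= 0:
        raise DataError("birth rate must be positive")
    if death < 0 or death >= birth:
        raise DataError("need 0 <= death < birth")
    if n_species < 2:
        raise DataError("need at least 2 species")
    if rng is None:
        rng = np.random.default_rng(seed)
    total_rate = birth + death
    for _attempt in range(1000):
        # each active lineage: [parent_record | None, birth_time, children]
        root = _Lineage(None, 0.0)
        root.children = [_Lineage(root, 0.0), _Lineage(root, 0.0)]
        active = list(root.children)
        t = 0.0
        failed = False
        while len(active) < n_species:
            k = len(active)
            t += rng.exponential(1.0 / (k * total_rate))
            lin = active[rng.integers(k)]
            if rng.random() < birth / total_rate:
                lin.length = t - lin.start
                kids = [_Lineage(lin, t), _Lineage(lin, t)]
                lin.children = kids
                active.remove(lin)
                active.extend(kids)
            else:
                lin.length = t - lin.start
                lin.dead = True
                active.remove(lin)
                if not active:
                    failed = True
                    break
        if failed:
            continue
        t += rng.exponential(1.0 / (n_species * total_rate))
        for lin in active:
            lin.length = t - lin.start
        return _lineages_to_phylogeny(root, n_species)
    raise DataError("birth-death simulation failed repeatedly")  # pragma: no cover


class _Lineage:
    __slots__ = ("parent", "start", "length", "children", "dead")

    def __init__(self, parent, start):
        self.parent = parent
        self.start = start
        self.length = 0.0
        self.children = []
        self.dead = False


def _lineages_to_phylogeny(root: "_Lineage", n_species: int) -> Phylogeny:
    """Convert the lineage records to a pruned dendropy tree."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    width = len(str(n_species))
    counter = {"i": 0}

    def build(lin: "_Lineage") -> dendropy.Node | None:
        node = dendropy.Node()
        node.edge.length = lin.length
        if lin.children:
            kids = [build(c) for c in lin.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            for k in kids:
                node.add_child(k)
            return node
        if lin.dead:
            return None
        counter["i"] += 1
        node.taxon = taxa.new_taxon(f"s{counter['i']:0{width}d}")
        return node

    children = [build(c) for c in root.children]
    children = [c for c in children if c is not None]
    seed = dendropy.Node()
    seed.edge.length = 0.0
    for c in children:
        seed.add_child(c)
    tree.seed_node = seed
    tree.suppress_unifurcations()
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

#: log-scale construction of the five observable traits: parent latent,
#: intercept, slope on the latent, SD of independent noise
TRAIT_RECIPE = {
    "height_m":        ("z1", 1.5, 1.00, 0.15),
    "leaf_length_cm":  ("z1", 1.0, 0.80, 0.15),
    "leaf_width_cm":   ("z1", 0.3, 0.70, 0.15),
    "flowering_month": ("z2", 1.8, 0.15, 0.05),
    "seed_mass_mg":    ("z2", 2.0, 1.20, 0.20),
}


def simulate_traits(tree: Phylogeny, sigma2: float = 1.0,
                    lambda_sim: float = 1.0, seed: int | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[TraitTable, pd.DataFrame]:
    """Evolve latent traits on the tree and derive five observable traits.

    Two independent latent traits ``z1`` and ``z2`` are multivariate
    normal with covariance ``sigma2 * C(lambda_sim)`` (the
    lambda-rescaled BM covariance).  Each observable trait is
    ``exp(a + b * z + noise)`` of one latent (strictly positive, so the
    downstream log transform is always valid).  ``z1`` is the assembly
    trait used by the community generator.
    """
    if not (0.0 <= lambda_sim <= 1.0):
        raise DataError("lambda_sim must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels, C = bm_covariance(tree)
    Cl = lambda_transform(C, lambda_sim)
    n = len(labels)
    if sigma2 > 0:
        # sample via Cholesky with a small jitter for zero-length cherries
        L = np.linalg.cholesky(sigma2 * Cl + 1e-10 * np.eye(n))
        Z = (L @ rng.standard_normal((n, 2)))
    else:
        Z = np.zeros((n, 2))
    latent = pd.DataFrame(Z, index=labels, columns=["z1", "z2"])
    cols = {}
    for name, (parent, a, b, noise_sd) in TRAIT_RECIPE.items():
        log_t = a + b * latent[parent] + noise_sd * rng.standard_normal(n)
        cols[name] = np.exp(log_t)
    traits = TraitTable(pd.DataFrame(cols, index=labels))
    return traits, latent


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_environment(n_bands: int = 10, band_width: float = 100.0,
                         base_elevation: float = 200.0,
                         climate_noise: float = 0.1,
                         hetero_profile: str = "hump",
                         rarea_profile: str = "decreasing",
                         seed: int | None = None,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Band-level environment table with realistic gradient structure.

    Climate variables are monotone linear in elevation (temperature-like
    decreasing, precipitation-like increasing, already log scale) plus
    Gaussian noise whose SD is ``climate_noise`` times the across-band
    signal SD.  RArea (log regional area) decreases with elevation (or
    is hump-shaped); topographic-heterogeneity SDs follow a hump or flat
    profile.  The index is the integer lower band edge; ``elevation``
    is the band midpoint.
    """
    if n_bands < 3:
        raise DataError("need at least 3 bands")
    if hetero_profile not in ("hump", "flat"):
        raise DataError(f"unknown hetero_profile {hetero_profile!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    lower = base_elevation + band_width * np.arange(n_bands)
    e = lower + band_width / 2.0
    mid = e.mean()
    span = e.max() - e.min()

    def noisy(signal: np.ndarray) -> np.ndarray:
        sd = np.std(signal) * climate_noise
        return signal + rng.normal(0.0, sd, size=len(signal))

    env = pd.DataFrame(index=pd.Index(lower.astype(int), name="band"))
    env["elevation"] = e
    # climate: decreasing temperature-like, increasing precipitation-like
    env["temp_mean"] = noisy(14.0 - 0.0055 * e)
    env["temp_min"] = noisy(4.0 - 0.0060 * e)
    env["temp_seasonality"] = noisy(30.0 - 0.0040 * e)
    env["growing_degree_days"] = noisy(3200.0 - 1.5 * e)
    env["precip_log"] = noisy(6.9 + 0.00040 * e)
    env["precip_summer_log"] = noisy(6.2 + 0.00055 * e)
    # regional area (log scale)
    if rarea_profile == "decreasing":
        rarea = 7.0 - 0.0015 * e
    elif rarea_profile == "hump":
        rarea = 6.0 + 1.5 * np.exp(-((e - mid) ** 2) / (2 * (span / 4) ** 2))
    else:
        raise DataError(f"unknown rarea_profile {rarea_profile!r}")
    env["RArea"] = rarea + rng.normal(0.0, np.std(rarea) * climate_noise + 1e-9,
                                      size=n_bands)
    # topographic heterogeneity
    if hetero_profile == "hump":
        hump = np.exp(-((e - mid) ** 2) / (2 * (span / 4) ** 2))
        base = {"sd_slope": (5.0, 6.0), "sd_aspect": (40.0, 30.0),
                "sd_convexity": (1.0, 1.5)}
        for col, (lo, amp) in base.items():
            sig = lo + amp * hump
            env[col] = sig + rng.normal(0.0, 0.1 * np.std(sig), size=n_bands)
    else:  # flat: noise only
        base = {"sd_slope": 8.0, "sd_aspect": 55.0, "sd_convexity": 1.7}
        for col, lo in base.items():
            env[col] = lo + rng.normal(0.0, 0.02 * lo, size=n_bands)
    return env


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def assemble_communities(tree: Phylogeny, latent: pd.DataFrame,
                         env: pd.DataFrame, config: ScenarioConfig,
                         rng: np.random.Generator | None = None
                         ) -> CommunityMatrix:
    """Assemble plot communities under the configured scenario."""
    if rng is None:
        rng = derived_rng(config.seed, 3)
    species = tree.tips
    if list(latent.index) != species:
        latent = latent.reindex(species)
    z = latent["z1"].to_numpy(dtype=float)
    n_sp = len(species)
    regional = rng.lognormal(mean=0.0, sigma=config.abundance_sdlog, size=n_sp)

    e_lo = float(env["elevation"].min())
    e_hi = float(env["elevation"].max())
    if config.optimum_slope is None:
        # map the transect onto the central latent-trait range
        q05, q95 = np.quantile(z, [0.05, 0.95])
        slope = (q95 - q05) / max(e_hi - e_lo, 1.0)
        intercept = q05 - slope * e_lo
    else:
        slope = config.optimum_slope
        intercept = float(np.mean(z)) - slope * (e_lo + e_hi) / 2.0

    rows = []
    meta = []
    retry_failures = 0
    total_draws = 0
    for band, row in env.iterrows():
        lower = float(band)
        for p in range(config.plots_per_band):
            elev = lower + rng.uniform(0.0, config.band_width)
            mu = intercept + slope * elev
            counts = _draw_plot(rng, config, regional, z, mu)
            total_draws += config.individuals_per_plot
            retry_failures += counts[1]
            rows.append(counts[0])
            meta.append({"plot": f"b{int(band):04d}_p{p:02d}",
                         "transect": "T1", "elevation": elev,
                         "band": int(band)})
    if total_draws and retry_failures / total_draws > 0.10:
        logger.warning("competition retry cap exhausted for %.1f%% of draws",
                       100.0 * retry_failures / total_draws)
    meta_df = pd.DataFrame(meta).set_index("plot")
    ab = pd.DataFrame(np.array(rows), index=meta_df.index, columns=species)
    return CommunityMatrix(ab, meta_df)


def _draw_plot(rng: np.random.Generator, config: ScenarioConfig,
               regional: np.ndarray, z: np.ndarray, mu: float
               ) -> tuple[np.ndarray, int]:
    """Counts vector for one plot plus the number of retry-cap failures."""
    n_sp = len(regional)
    m = config.individuals_per_plot
    if config.scenario == "neutral":
        w = regional
        return rng.multinomial(m, w / w.sum()), 0
    if config.scenario == "filtering":
        w = regional * np.exp(-((z - mu) ** 2) / (2.0 * config.filter_sigma**2))
        if w.sum() <= 0:
            w = regional
        return rng.multinomial(m, w / w.sum()), 0
    # competition: sequential draws with limiting-similarity rejection
    w = regional / regional.sum()
    counts = np.zeros(n_sp, dtype=int)
    failures = 0
    residents: list[int] = []
    for _ in range(m):
        accepted = None
        for _try in range(config.retry_cap):
            cand = rng.choice(n_sp, p=w)
            if counts[cand] > 0:
                accepted = cand     # conspecifics always allowed
                break
            if all(abs(z[cand] - z[r]) >= config.competition_delta
                   for r in residents):
                accepted = cand
                break
        if accepted is None:
            accepted = cand
            failures += 1
        if counts[accepted] == 0:
            residents.append(accepted)
        counts[accepted] += 1
    return counts, failures


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Tree, traits, environment and community for one scenario.

    Each stage draws from its own substream of ``config.seed``, so e.g.
    the tree is identical across scenarios sharing a seed.
    """
    tree = simulate_tree(config.n_species, config.birth, config.death,
                         rng=derived_rng(config.seed, 0))
    traits, latent = simulate_traits(tree, sigma2=config.sigma2,
                                     lambda_sim=config.trait_lambda,
                                     rng=derived_rng(config.seed, 1))
    env = simulate_environment(config.n_bands, config.band_width,
                               config.base_elevation, config.climate_noise,
                               config.hetero_profile, config.rarea_profile,
                               rng=derived_rng(config.seed, 2))
    community = assemble_communities(tree, latent, env, config,
                                     rng=derived_rng(config.seed, 3))
    return SyntheticDataset(tree=tree, traits=traits, latent=latent,
                            env=env, community=community, config=config)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset in the package's standard input formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.tree.write(out / "tree.nwk")
    ds.traits.write_csv(out / "traits.csv")
    ds.env.reset_index().to_csv(out / "environment.csv", index=False)
    ds.community.write_csv(out / "community.csv", out / "plots.csv")
    ds.latent.rename_axis("species").reset_index().to_csv(
        out / "latent_traits.csv", index=False)
    (out / "scenario.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(ds.config), sort_keys=False))
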