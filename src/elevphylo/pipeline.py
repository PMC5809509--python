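"""End-to-end orchestration: simulate (or ingest) data, build the
functional dendrogram, compute dispersion components, signal statistics
and gradient statistics, and write a report bundle of delimited tables.

Every output file is deterministic given the run configuration; the
configuration itself is serialized into the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DataError, cophenetic_distance
from .dispersion import all_band_components, band_beta_matrix
from .gradient import (build_distances, choose_poly_model, env_pca, mantel,
                       mrm, simple_ols_screen, stepwise_forward,
                       variation_partition)
from .signal import signal_report
from .simulate import (CLIMATE_COLS, HETERO_COLS, ScenarioConfig,
                       SyntheticDataset, generate_dataset, write_dataset)
from .traits import functional_dendrogram

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    band_width: float | None = None     # defaults to the scenario's width
    n_null: int = 1000                  # tip-shuffle replicates
    n_perm: int = 10000                 # Mantel/MRM permutations
    seed: int = 0
    pca_components: int | None = None   # None = smallest k reaching 94.8%
    inner_weighted: bool = True         # D_pw inner-mean weighting
    alpha_enter: float = 0.05           # stepwise entry threshold
    outdir: str = "elevphylo_run"


def run_full(config: RunConfig,
             dataset: SyntheticDataset | None = None) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns a dict of the in-memory results keyed by stage.  Stages:
    data, dendrogram, dispersion (phylogenetic and functional),
    signal, gradient.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "configure"
    try:
        cfg = dataclasses.asdict(config)
        cfg["scenario"] = dataclasses.asdict(config.scenario)
        (out / "run_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))

        stage = "data"
        t0 = time.perf_counter()
        if dataset is None:
            dataset = generate_dataset(config.scenario)
        write_dataset(dataset, out / "data")
        results["data"] = dataset
        logger.info("stage data: %.1fs", time.perf_counter() - t0)

        stage = "dendrogram"
        t0 = time.perf_counter()
        dendro, pca_res = functional_dendrogram(dataset.traits,
                                                k=config.pca_components)
        dendro.write(out / "trait_dendrogram.nwk")
        pca_res.loadings.assign(var_explained=np.nan).to_csv(
            out / "trait_pca_loadings.csv")
        pd.DataFrame({"component": pca_res.scores.columns,
                      "var_explained": pca_res.var_explained}).to_csv(
            out / "trait_pca_variance.csv", index=False)
        results["dendrogram"] = dendro
        results["trait_pca"] = pca_res
        logger.info("stage dendrogram: %.1fs", time.perf_counter() - t0)

        stage = "dispersion"
        t0 = time.perf_counter()
        dist_phy = cophenetic_distance(dataset.tree)
        dist_fun = cophenetic_distance(dendro)
        community = dataset.community
        if config.band_width is not None:
            community = community.assign_bands(config.band_width)
        disp = {}
        for tag, dist in (("phy", dist_phy), ("fun", dist_fun)):
            comps = all_band_components(community, dist, n_null=config.n_null,
                                        seed=config.seed,
                                        inner_weighted=config.inner_weighted)
            beta = band_beta_matrix(community, dist, n_null=config.n_null,
                                    seed=config.seed,
                                    inner_weighted=config.inner_weighted)
            comps.to_csv(out / f"band_components_{tag}.csv")
            beta.to_dataframe().to_csv(out / f"band_beta_{tag}.csv")
            disp[tag] = {"components": comps, "beta": beta}
        results["dispersion"] = disp
        logger.info("stage dispersion: %.1fs", time.perf_counter() - t0)

        stage = "signal"
        t0 = time.perf_counter()
        sig = signal_report(dataset.tree, dataset.traits, seed=config.seed)
        sig.to_csv(out / "signal_report.csv")
        results["signal"] = sig
        logger.info("stage signal: %.1fs", time.perf_counter() - t0)

        stage = "gradient"
        t0 = time.perf_counter()
        env = env_pca(dataset.env, CLIMATE_COLS, HETERO_COLS)
        env.to_csv(out / "environment_pca.csv")
        distances = build_distances(env)
        results["gradient"] = _gradient_stage(
            out, env, distances, disp, config)
        logger.info("stage gradient: %.1fs", time.perf_counter() - t0)
    except Exception:
        logger.error("pipeline aborted in stage %r; partial outputs kept in %s",
                     stage, out)
        raise
    return results


def _gradient_stage(out: Path, env: pd.DataFrame, distances, disp,
                    config: RunConfig) -> dict:
    """Elevation fits, OLS screens, stepwise models, Mantel/MRM tables and
    variation partitioning for both dispersion facets."""
    res: dict = {}
    elev = env["elevation"]
    fits_rows = []
    screen_frames = []
    step_rows = []
    mantel_rows = []
    vp_rows = []
    groups = {
        "rarea": env[["RArea"]],
        "climate": env[["PC1_clim"]],
        "hetero": env[["PC1_hetero", "PC2_hetero"]],
    }
    for tag in ("phy", "fun"):
        comps = disp[tag]["components"]
        beta = disp[tag]["beta"]
        for comp in ("alpha", "beta_within", "gamma"):
            y = comps[comp].astype(float)
            ok = y.notna()
            if ok.sum() < 4:
                continue
            ysub = y[ok]
            esub = elev.loc[ysub.index]
            lin, quad, best = choose_poly_model(ysub, esub)
            fits_rows.append({
                "facet": tag, "component": comp, "n": lin.n,
                "aic_linear": lin.aic, "aic_quadratic": quad.aic,
                "aicc_linear": lin.aicc, "aicc_quadratic": quad.aicc,
                "chosen": best,
                "r2_linear": lin.r2, "r2_quadratic": quad.r2,
                "p_linear": lin.p, "p_quadratic": quad.p,
            })
            envsub = env.loc[ysub.index]
            scr = simple_ols_screen(ysub, envsub)
            scr.insert(0, "component", comp)
            scr.insert(0, "facet", tag)
            screen_frames.append(scr.reset_index())
            try:
                step = stepwise_forward(
                    ysub,
                    envsub[["RArea", "PC1_clim", "PC1_hetero", "PC2_hetero"]],
                    alpha_enter=config.alpha_enter)
                step_rows.append({
                    "facet": tag, "component": comp,
                    "equation": _equation(step), "r2": step.r2,
                    "F": step.fstat, "p": step.p,
                    "intercept_only": step.extra.get("intercept_only", False),
                })
            except DataError as exc:
                logger.warning("stepwise skipped for %s/%s: %s", tag, comp, exc)
            try:
                vp = variation_partition(ysub, {k: v.loc[ysub.index]
                                                for k, v in groups.items()})
                vp_rows.append({"facet": tag, "component": comp,
                                "unique_rarea": vp["unique"]["rarea"],
                                "unique_climate": vp["unique"]["climate"],
                                "unique_hetero": vp["unique"]["hetero"],
                                "combined": vp["combined"],
                                "r2_full": vp["r2_full"],
                                "residual": vp["residual"]})
            except DataError as exc:
                logger.warning("variation partitioning skipped for %s/%s: %s",
                               tag, comp, exc)
        # band-pair beta against the four distance matrices
        for name, dmat in distances.as_dict().items():
            sub = dmat.subset(beta.labels)
            r, p = mantel(beta, sub, n_perm=config.n_perm,
                          seed=config.seed)
            mantel_rows.append({"facet": tag, "distance": name,
                                "r": r, "p": p})
        mrm_res = mrm(beta, {k: v.subset(beta.labels)
                             for k, v in distances.as_dict().items()},
                      n_perm=min(config.n_perm, 1000), seed=config.seed)
        res[f"mrm_{tag}"] = mrm_res
    res["elevation_fits"] = pd.DataFrame(fits_rows)
    res["ols_screen"] = pd.concat(screen_frames, ignore_index=True)
    res["stepwise"] = pd.DataFrame(step_rows)
    res["mantel"] = pd.DataFrame(mantel_rows)
    res["variation_partition"] = pd.DataFrame(vp_rows)
    res["elevation_fits"].to_csv(out / "elevation_fits.csv", index=False)
    res["ols_screen"].to_csv(out / "ols_screen.csv", index=False)
    res["stepwise"].to_csv(out / "stepwise_models.csv", index=False)
    res["mantel"].to_csv(out / "mantel_tests.csv", index=False)
    res["variation_partition"].to_csv(out / "variation_partition.csv",
                                      index=False)
    return res


def _equation(fit) -> str:
    terms = [f"{fit.coef.get('const', 0.0):+.3f}"]
    for name, b in fit.coef.items():
        if name == "const":
            continue
        terms.append(f"{b:+.3f} {name}")
    return "y = " + " ".join(terms)
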