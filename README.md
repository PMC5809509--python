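# elevphylo

Phylogenetic and functional diversity of ecological assemblages along
elevational gradients.

Community ecologists use the phylogenetic and functional structure of
assemblages to tell apart the processes that build them: environmental
filtering concentrates closely related (or functionally similar) species
and produces *clustering*, while competitive exclusion of similar species
produces *overdispersion*. `elevphylo` is a tested, reusable pipeline for
this style of analysis on woody-plant (or any multi-plot) survey data
arranged along elevational transects: plots binned into elevational bands,
a dated phylogeny over the regional species pool, a species-by-trait
table, and band-level environmental covariates.

## What it computes

**Dispersion metrics.** The abundance-weighted mean pairwise distance
within an assemblage,

    MPD = Σ_{i<j} f_i f_j d_ij / Σ_{i<j} f_i f_j,

with `f` the relative abundances and `d` cophenetic distances on the
phylogeny (or on a trait dendrogram), and the between-assemblage analogue

    D_pw = ( Σ_i f_i d̄_ik₂ + Σ_j f_j d̄_jk₁ ) / 2,

where `d̄_ik₂` is the abundance-weighted mean distance from species *i*
of one assemblage to the species of the other. Both are standardized
against a tip-shuffle null (species names permuted across the tips of the
tree, community matrix untouched):

    NRI       = −(MPD_obs − mean MPD_null) / sd MPD_null
    SES D_pw  = −(D_pw_obs − mean D_pw_null) / sd D_pw_null

so positive values mean clustering, negative overdispersion. These are
decomposed over elevational bands into an α component (mean plot NRI per
band), two β components (mean SES D_pw between plots within a band, and
SES D_pw between pooled band assemblages), and a γ component (NRI of the
pooled band).

**Trait space.** Traits are log-transformed, standardized, reduced by PCA,
turned into a Euclidean distance matrix and clustered by UPGMA into an
ultrametric "functional tree" that can stand in for the phylogeny in every
dispersion statistic.

**Phylogenetic signal.** Blomberg's K (with a randomization test on the
variance of phylogenetically independent contrasts) and Pagel's λ (profile
maximum likelihood with a likelihood-ratio test against λ = 0).

**Gradient statistics.** Linear/quadratic OLS of each diversity component
on elevation with information-criterion model choice, per-variable OLS
screening, forward stepwise multiple regression, simple Mantel tests of
band-pair β against elevational/environmental distance matrices, multiple
regression on distance matrices (MRM), and three-set variation
partitioning (regional area vs. climate vs. topographic heterogeneity).

**Synthetic data.** A first-class generator produces birth–death
phylogenies, λ-scaled Brownian traits, monotone climate gradients, and
communities assembled under *neutral*, *filtering* (Gaussian trait filter
around an elevation-dependent optimum) or *competition* (limiting
similarity) rules — so every stage of the pipeline is testable end to end
with known ground truth.

## Worked example

```python
from elevphylo import (ScenarioConfig, generate_dataset, cophenetic_distance,
                       nri, signal_report, functional_dendrogram)

cfg = ScenarioConfig(scenario="filtering", n_species=50, n_bands=8,
                     plots_per_band=4, individuals_per_plot=60, seed=11)
data = generate_dataset(cfg)

dist = cophenetic_distance(data.tree)
plot = data.community.plots[0]
r = nri(data.community.plot_assemblage(plot), dist, n_null=999, seed=1)
print(f"plot {plot}: NRI = {r.ses:.2f} (p = {r.p_value:.3f})")

dendro, pca_res = functional_dendrogram(data.traits, k=4)
print(f"4 PCs explain {100 * pca_res.var_explained.sum():.1f}% of trait variance")

report = signal_report(data.tree, data.traits, seed=0)
print(report[["K", "K_stars", "lambda", "lambda_stars"]].round(3))
```

prints

```
plot b0200_p00: NRI = 4.55 (p = 0.002)
4 PCs explain 99.8% of trait variance
                     K K_stars  lambda lambda_stars
trait
height_m         0.903      **   0.986          ***
leaf_length_cm   0.636      **   0.968          ***
leaf_width_cm    0.599      **   0.935          ***
flowering_month  0.446      **   0.956          ***
seed_mass_mg     0.567      **   0.983          ***
```

The plot's NRI of 4.55 (observed MPD far below the null mean) is the
clustering the filtering scenario is built to produce; the K and λ values
below 1 with significance stars mirror the situation where traits carry
real but sub-Brownian phylogenetic signal, which is what licenses using
phylogenetic dispersion as a proxy for functional dispersion.

The same analysis is available from the shell:

```sh
elevphylo simulate --scenario filtering --seed 11 --out data/
elevphylo full --scenario filtering --seed 11 --out run/
```

`run/` then contains the signal report, band-level α/β/γ component tables
for both facets, band-pair β matrices, elevation fits with AIC/AICc,
OLS screens, stepwise model equations, Mantel tables and variation
partitions, all as delimited text.

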