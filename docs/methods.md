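# Methods

This note records the statistical model behind each stage of the
pipeline, the conventions chosen where several are defensible, and what
the synthetic-data tests do and do not demonstrate.

## Dispersion metrics and the null model

Within-assemblage dispersion is the abundance-weighted mean pairwise
distance over *distinct* species pairs,
`MPD = Σ_{i<j} f_i f_j d_ij / Σ_{i<j} f_i f_j`, undefined for
monospecific assemblages (such plots are excluded from band averages with
a logged count). Between-assemblage dispersion `D_pw` averages the two
directed sums `Σ_i f_i d̄_i(other)`. The inner mean `d̄` is
abundance-weighted by the *other* assemblage's relative abundances by
default, which makes `D_pw = f₁ᵀ D f₂` exactly and symmetric; an
unweighted inner mean is available via `inner_weighted=False`. The
weighted form is the default because the statistic is used throughout in
its abundance-weighted version; with the unweighted inner mean the two
directed sums genuinely differ and are averaged.

The null model permutes species labels across the tips of the supplied
tree (equivalently, applies a random row/column permutation to the
distance matrix) while leaving the community matrix untouched. The pool
is the full label set of the distance matrix — all species of the
transect — and is constant across plots and bands. Standardized effects
are sign-flipped (`−(obs − mean)/sd`) so positive = clustering. For
pools of ≤ 6 labels an exhaustive mode enumerates all permutations; the
sampled mode is checked against it in the tests.

Degenerate nulls (null SD = 0, e.g. a star phylogeny where the metric is
permutation-invariant) report an SES of 0 with an explicit flag rather
than NaN; flagged values are excluded from α/β averages so band tables
stay computable.

Two-sided permutation p-values use the rank of the observed value among
observed + null: `p = 2·min(r, n+2−r)/(n+1)`, ties counted half. Both
extreme ranks give the permutation floor `2/(n+1)`; a mid-rank value
gives 1.

Randomness policy: one master seed; each task (plot, plot pair, band
pair, replicate) draws from a substream spawned with a deterministic key
(`numpy.random.SeedSequence(seed, spawn_key=...)`), so results do not
depend on execution order.

## α / β / γ decomposition

Per elevational band: α is the arithmetic mean of plot NRIs, β-within the
mean SES D_pw over unordered plot pairs, γ the NRI of the pooled band
assemblage (raw abundances summed over plots, zero-total species
dropped). Bands are contiguous elevation intervals `[e, e + width)` with
a default width of 100 m; the width is a configuration knob, not an
asserted field value. Band-pair β uses pooled-and-summed band
assemblages.

## Trait space

Traits must be strictly positive; they are log-transformed and
standardized to zero mean, unit sample SD per column (missing values are
an error — there is no imputation). PCA is computed on the covariance of
the standardized matrix (equal to the correlation PCA of the raw logs)
via SVD, with a deterministic sign convention (largest-magnitude loading
positive per component). The component count defaults to the smallest k
explaining ≥ 94.8% of variance and can be fixed (e.g. `k=4`).

UPGMA uses size-weighted average linkage; the merge height is *half* the
between-cluster average distance, so tip-to-tip dendrogram distance
equals that average and the output is ultrametric by construction. Ties
in the minimum distance are broken by the lexicographically smallest pair
of cluster representative labels (a convention adopted to make merge
order, and hence the newick output, reproducible; it is not claimed to
match any particular legacy implementation).

## Phylogenetic signal

Blomberg's K is the observed ratio `MSE₀/MSE` (variance about the GLS
mean over the phylogenetically corrected mean square, both with the BM
covariance C) divided by its analytic BM expectation
`(tr C − n/(1ᵀC⁻¹1))/(n−1)`; K = 1 under Brownian motion. Significance
comes from permuting trait values across tips and comparing the variance
of phylogenetically independent contrasts (999 permutations, seeded);
because Felsenstein's contrasts are linear in the tip values, the
contrast operator is precomputed once as a matrix, making the
permutation test O(n) per replicate. Polytomies are resolved arbitrarily
with zero-length edges before computing contrasts.

Pagel's λ multiplies the off-diagonal of C by λ ∈ [0, λ_max] (λ_max keeps
off-diagonals ≤ diagonals). For fixed λ the GLS mean and σ² have closed
forms; the profile likelihood is maximized by a coarse 21-point grid
followed by bounded Brent refinement around the best grid point (the
grid guards against the flat or multimodal profiles that a single local
search can mishandle). The LR test compares λ̂ against λ = 0 on χ²₁,
which is conservative at the boundary; testing against λ = 1 is
available via `test_against=1.0`. On a star tree λ is unidentifiable and
is reported as 0 with an explicit flag. Both K and λ̂ are invariant to
affine rescaling of the trait, so the signal report applies only the log
transform.

Non-ultrametric trees are accepted (C is built from actual node depths);
the statistics are usually reported on dated trees.

## Gradient statistics

Environmental ordination standardizes each variable and runs two separate
PCAs: climate (PC1 kept) and topographic-heterogeneity SDs (PC1 and PC2
kept). Distance matrices over bands: elevational difference (geographic
proxy), |ΔRArea| on log area, Euclidean distance on PC1_clim, and on
(PC1_hetero, PC2_hetero).

Polynomial OLS centers elevation before adding powers. AIC uses the
Gaussian profile form `n·ln(RSS/n) + 2k` with k = mean parameters + 1
for the variance; RSS is floored at 10⁻¹² of the TSS so noise-free
nested fits compare by parameter count. Because only AIC *differences*
are used, the additive constant convention is immaterial. The
linear-vs-quadratic choice defaults to AICc: at band-level sample sizes
(n ≈ 10–20) plain AIC admits a spurious quadratic term in roughly a
fifth of truly linear datasets whatever the noise level, while AICc
keeps that rate below ~10%; plain-AIC choice remains available
(`small_sample=False`) and both criteria are written to the reports.

Forward stepwise regression enters, at each step, the candidate with the
smallest partial-F p-value while it is below α = 0.05 (for a single
added term the partial F equals the squared t of its slope). An AIC-based
criterion is deliberately not the default; the entry threshold is
reported in the fit metadata. The Mantel test permutes the response
matrix's labels; its two-sided p counts permutations with |r| at least
the observed, observed included (exhaustive enumeration at n ≤ 7). MRM
regresses lower-triangle vectors by OLS with label-permutation inference
on |t|; predictor collinearity beyond condition number 10⁸ is an error
naming the most correlated pair. Variation partitioning fits the seven
nonempty subsets of the three predictor groups; unique fractions are
`R²(all) − R²(others)`, the shared fraction is the remainder, and
negative fractions (a standard artifact of partialling) are reported
as-is with a flag.

Conditional-autoregressive (CAR) spatial models are out of scope; where a
robustness check against spatial autocorrelation is wanted, the reports
note that simple OLS results stand alone.

## Synthetic data: what it emulates

The generator produces one transect: `n_bands` contiguous 100-m bands
starting at 200 m (defaults: 10 bands, 10 plots per band, 100 stems per
plot, 100 species), a pure-birth phylogeny conditioned on the species
count (birth rate 1/unit time; the simulation stops one exponential
waiting time after the n-th lineage appears, giving a clean closed-form
height expectation `(H_n − 1)/birth` used as a test oracle), and two
latent traits evolved as multivariate normal draws with covariance
σ²·C(λ_sim). Five observable traits (height m, leaf length cm, leaf
width cm, flowering onset month, seed mass mg) are exponentials of affine
images of the latents plus independent noise — strictly positive by
construction, with PCA structure known in advance. The latent `z1` is
the assembly trait, so functional and phylogenetic dispersion are coupled
but not identical, as in real data where trait signal is significant but
sub-Brownian. `trait_lambda` defaults to 1 (conserved assembly trait):
that is the regime in which the clustering ⇒ filtering and
overdispersion ⇒ competition inferences are valid, and the regime the
mechanism scenarios are meant to exhibit.

Climate variables are monotone linear functions of elevation
(temperature-like decreasing, precipitation-like increasing, already on
log scale) with Gaussian noise at 10% of the across-band signal SD — small
enough that climate PC1 is a clean elevation axis, as in real transects
where lapse rates dominate. Log regional area decreases with elevation
(hump option available); heterogeneity SDs follow a hump or flat profile.

Assembly: *neutral* draws each plot's stems multinomially in proportion
to fixed lognormal(0, 1) regional abundances; *filtering* multiplies the
weights by `exp(−(t_s − μ(e))²/(2σ_f²))` with the optimum μ linear in
elevation (by default mapped so the transect spans the central 90% of the
latent trait range) and σ_f = 0.5 trait units (≈ a quarter of the latent
SD — strong filtering); *competition* draws stems sequentially under
neutral weights, rejecting a new species closer than δ = 1.0 trait units
(≈ half the latent SD) to any resident, retrying up to 100 times before
accepting with a logged violation. δ was set where the limiting-similarity
constraint actually binds: at the neutral expectation of ~20 species over
a ~8-unit trait range the mean nearest-neighbor spacing is already ~0.4,
so a radius much below ~1 leaves assemblages essentially neutral.
Conspecific draws are always accepted, so plot abundance totals are exact.

What the generator does **not** emulate: spatial dispersal kernels and
distance-dependent migration, temporal dynamics, speciation along the
gradient, intraspecific trait variation, observation error in abundances,
and multi-transect structure within one dataset (each dataset is one
transect; multi-transect comparisons are made across datasets). Passing
tests on this generator therefore demonstrate the *statistical machinery*
— calibration, sign recovery, oracle equivalence — not the realism of any
particular field system.

A statistical point that shapes the tests: plots simulated within one
dataset share a single realization of the species-to-tree assignment, so
their NRIs are correlated; the across-plot SD of NRI within one dataset
is well below 1 even under neutrality. Calibration and mechanism-direction
checks therefore pool plots across independent realizations, where the
tip-shuffle null is exact (under neutral assembly the assignment of
abundances to tips is exchangeable) and t-tests get the independence they
assume.

## Problem sizes used by the checks

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is statistically decidable: pools
of 40–100 species, 3–10 bands, 60–100 stems per plot; 199–999 null
replicates (999 for calibration, the full 1000/10000 defaults are used in
production runs); 100 random instances per brute-force oracle; 300–500
Brownian simulations for K; 100 replicates per λ recovery point
(5 trees × 20 traits at 200 tips); 200 plots pooled over 40 realizations
for the competition direction. Exhaustive permutation oracles use pools
of 4–6 (≤ 720 permutations) and Mantel enumeration uses n = 5 (120
permutations).

## Known limitations

- The tip-shuffle null is the only null model (no independent swap /
  trial swap); NTI/MNTD metrics are not implemented.
- The λ likelihood-ratio p-value uses plain χ²₁, conservative at the
  λ = 0 boundary; the 50:50 mixture correction is not applied by default.
- UPGMA is O(n³) with a dict-based distance store — fine for hundreds of
  species, not for tens of thousands.
- Stepwise selection inherits the usual caveats of sequential testing;
  it reproduces a legacy analysis style rather than a recommended one,
  and variation partitioning is the preferred summary of predictor
  importance.
- Negative variation-partition fractions are reported, not truncated.
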