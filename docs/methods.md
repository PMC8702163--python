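# Methods

## The problem and the estimand

Wildlife managers need population sizes, but the methods that produce them
differ in invasiveness and cost. The quantity compared here is deliberately
modest: the **number of distinct individuals detected** in one population
over one study period, by live trapping, by camera trapping, or by genetic
identification from noninvasively collected tissue. No detection
probability is modelled and no formal density is estimated — the pipeline
asks only whether two methods applied to the same population count similar
numbers of animals, and what study features explain the disagreements.

Counts enter as positive reals: when a source study reports a density, the
count is derived as density × area and not rounded. All regressions operate
on natural logs, where rounding would be immaterial anyway; the log base is
recorded in the report provenance and switchable to base 10 (slope and R²
are base-invariant, residual magnitudes are not).

## Through-origin regression

For n populations with log less-invasive count xᵢ and log live-trap count
yᵢ (and analogously log camera → log genetic), the model is y = βx with no
intercept, so equality of methods corresponds to β = 1:

- β̂ = Σxᵢyᵢ / Σxᵢ², residuals rᵢ = yᵢ − β̂xᵢ,
- σ̂² = RSS/(n − 1) — one estimated parameter, hence df = n − 1,
- SE(β̂) = σ̂/√Σxᵢ², uncentered R² = 1 − RSS/Σyᵢ²,
- F = (Σyᵢ² − RSS)/σ̂² on (1, n − 1) df.

The uncentered R² is the correct fit measure for a no-intercept model (the
grand mean is not in the model space). Degenerate inputs are rejected:
n < 3, all-zero predictor, or a perfect fit when studentizing.

**Axis convention.** The response is the live-trap count and the predictor
the less-invasive count (genetic is the response in the camera–genetic
comparison). The convention is stored in the report provenance and a
`--swap-axes` flag exposes the reverse orientation; the two slopes are
linked by the identity slope(y~x)·slope(x~y) = uncentered R², which the
test suite asserts. Note the residual sign flips with orientation: under
the default convention, a method feature that inflates the *predictor*
(e.g. spatial camera analysis) pushes that population's residual *down*.

**Standardized residuals** are internally studentized:
rᵢ/(σ̂√(1 − hᵢᵢ)) with leverage hᵢᵢ = xᵢ²/Σxᵢ² — the standard meaning in
regression software. A `plain` option (rᵢ/sd(r)) is available for
sensitivity analysis. Neither recenters or rescales to exactly (0, 1).

## Bootstrap mean differences

The effect size reported alongside each regression is the mean paired count
difference in individuals, with an explicit sign convention stored in the
result label (e.g. `less_invasive - live_trap`). Uncertainty comes from an
m-out-of-n bootstrap: B = 1000 replicates, each drawing
m = round(0.8·n) pairs (minimum 2) with replacement; the 95% interval is
the [2.5, 97.5] percentile band of the replicate means with linear
interpolation between order statistics. The reported point estimate is the
full-data mean, not the mean of bootstrap means. Identical seeds give
bit-identical intervals, and adding a constant to every difference shifts
the estimate and both bounds by exactly that constant (the resample indices
depend only on the seed). Simulation places the interval's coverage of a
true zero mean at ≈ 95% at n = 27 (checked to ±3% in the suite).

## Residual-driver regressions

Each set of studentized residuals is regressed on one covariate at a time,
dropping populations with a missing covariate listwise (camera-analysis
method exists only for camera-monitored populations, tissue source only for
genetic ones — which is why the rows have different df):

- **continuous** (log site area in km², log body mass in kg): OLS with
  intercept, slope tested by F(1, n − 2);
- **binary** (random = 0 / spatial = 1; hair = 0 / scat = 1): same model;
  the slope equals the difference of group means exactly;
- **cell-means** (realm): one mean per observed category with pooled
  variance; overall F compares the category model to the grand mean on
  (k − 1, n − k) df.

Two R² flavours are kept: raw, and adjusted-truncated-at-zero
(max(R²_adj, 0)), the latter being what the summary table prints — small
null fits routinely have negative adjusted R², and truncation matches the
way such tables are conventionally reported without losing the raw value.
No multiple-testing correction is applied (each driver is a separate,
singly-reported hypothesis), and no multivariable models are fit.

When a driver regression is significant, the camera-analysis subgroups are
summarized directly: the bootstrap mean difference (camera − live-trap)
restricted to spatially analyzed and to random-movement camera studies.

## Taxonomy tree and PGLS

A surrogate phylogeny is built by nesting the four taxonomic ranks with
every branch length 1: each tip sits at depth 4, and two tips share a path
of length 3/2/1/0 when they share a genus/only a family/only an order/
nothing. Under Brownian motion, tip covariance equals shared path length,
giving a VCV with diagonal 4 and off-diagonals in {0, 1, 2, 3}. The root
edge is excluded (depth 4, not 5), the standard VCV convention. Trees
serialize to Newick (via dendropy) with internal-node rank labels, and the
VCV is recomputed from tree traversal, so export → import → identical
matrix.

The phylogeny–residual relationship is quantified as an intercept-only GLS:
μ̂ = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y, σ̂² = (y − μ̂1)ᵀV⁻¹(y − μ̂1)/(n − 1),
SE = √(σ̂²(1ᵀV⁻¹1)⁻¹), with a two-sided t test on n − 1 df. When V is a
multiple of the identity this reduces exactly to the ordinary mean and its
standard error, and rescaling V leaves μ̂ and SE unchanged. No
phylogenetic-signal parameter (Pagel's λ, OU) is estimated: the question is
only whether the GLS mean of the residuals differs from zero under the
Brownian covariance.

**Repeated species.** Several populations can share a species; identical
VCV rows would be singular. Each same-species pair receives off-diagonal
4 − ε (ε = 1e-6 by default, configurable), i.e. a small independent
within-species component. This is a workable convention, not an inference:
with ε this small, same-species populations whose residuals differ
noticeably inflate σ̂² (the model treats them as near-replicates), so the
PGLS standard error can be large on data with many repeated species. The
intercept itself remains well-behaved. Users with many repeated species
should consider a larger ε representing a genuine within-species variance.

## Synthetic-data generator

The generator emulates a compiled literature table, not individual
encounter histories (no spatial capture-recapture likelihoods):

| parameter | default | meaning |
|---|---|---|
| `n_trap_populations` | 27 | populations with live-trap + one less-invasive method |
| `n_camgen_populations` | 17 | populations with camera + genetic |
| `camera_fraction` | 0.5 | share of the trap arm whose less-invasive method is camera |
| `abundance_log_mean`, `abundance_log_sd` | 3.0, 1.2 | latent log-normal abundance; counts span ≈ 1–200 |
| `detect_prob` | trap .80, camera .75, genetic .85 | fraction of individuals each method detects |
| `lessinvasive_bias` | 1.05 | small multiplicative excess of camera/genetic counts |
| `spatial_effect` | 1.5 | multiplier on spatially analyzed camera counts |
| `noise_sd` | 0.3 | log-scale study noise per method count |
| `count_floor` | 0.5 | lower bound keeping logs defined (floored rows flagged) |

Each method count is N·p·bias·exp(ε) with ε ~ N(0, noise_sd²); counts are
continuous by default (mirroring density-derived counts; a Poisson option
exists). The arm sizes are the compiled study's; detection fractions are
ordered genetic > trap > camera so that genetic identification is slightly
the most sensitive and a random-movement camera analysis slightly the
least, which reproduces the qualitative pattern of the comparisons; the
spatial multiplier makes spatially analyzed cameras out-detect trapping.
Tissue type, site area, body mass, and realm have no injected effect, so
their driver regressions are null (type-I error checked at 5% ± 2% in the
suite). Species are drawn with replacement from a 20-species
Carnivora/Rodentia-heavy pool (body mass fixed per species), realms are
weighted toward the nearctic and palearctic, and site areas are log-normal.

What the generator does **not** emulate: integer capture histories and
detection-probability structure, between-method dependence beyond the
shared latent abundance (real paired counts share field conditions, so
their noises correlate), heavy-tailed study noise, and the possibility that
one population contributes all three methods (the pipeline supports such
rows — precedence configurable — but the generator never emits them). The
spatial-camera multiplier applies to every camera count, so unlike in a
compilation where analysis choices differ arbitrarily between arms, the
camera–genetic comparison also inherits a (negative) spatial signal.
Passing tests therefore demonstrate correctness of the estimators under
this generative model, not robustness to real-data pathologies.

## Orchestration and determinism

`run_analysis` executes every stage and assembles a JSON-serializable
report. All randomness flows from one user seed, split per named stage via
seed sequences (`stage_seed`), so adding a stage never perturbs another
stage's draws; identical table + seed + options give byte-identical JSON.
Drivers whose covariate is entirely missing, or degenerate (single
category), are skipped with a logged warning rather than failing the run.
Populations holding all three methods contribute their genetic count to the
trapping comparison by default (`trap_precedence="camera"` switches this).

Problem sizes throughout the test suite and the acceptance script are the
study's own (27 and 17 populations; 1000 bootstrap replicates; calibration
studies of 500–1000 simulated tables), chosen to match the structure the
pipeline is built for.
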