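# Methods

## Scope and model

`hruv` addresses normalisation of targeted LC-MS metabolomics studies
acquired in many batches, where run-order drift and inter-batch shifts are
comparable to or larger than the biology. All modelling is on the log2
scale. The working model for a mean-centred measurements × metabolites
matrix is

    Z = X β + W α + ε,

with `W α` the unwanted variation: `k` latent technical factors with
per-measurement scores `W` and per-metabolite loadings `α`. The central
identifying assumption is that technical replicates of a biological sample
share `X β` exactly, so replicate disagreement is evidence about `W α` and
`ε` only.

## Replicate design

A batch is a tray of `rows_per_batch × row_size` injections; the last
position of every row is a pooled QC, and `n_conditioning_qc` pooled-QC
injections precede the grid (row 0) to settle the instrument. From row 2 on,
one position per row re-injects an individual sample from an earlier row of
the same batch not yet re-injected ("short replicate", ≈10 runs after its
first injection). From batch 2 on, `n_batch_replicates` individual samples
of the previous batch that were not short-replicated there are re-injected
in a contiguous block at the start of the tray ("batch replicates"). All
random selection comes from one seeded generator; for a fixed seed the
sheet is reproducible, and across seeds only identities/positions change,
never the counts: `(rows−1)·n_batches` short pairs and
`n_batch_replicates·(n_batches−1)` batch pairs. Options cover scattering
the batch-replicate block across the tray, restricting short-replicate
sources to the immediately preceding row, and stratifying batch-replicate
selection across tray halves (guarding against the chance clustering of
selected positions that purely random choice permits).

## Pre-processing

Raw signals are log2 transformed (non-positive observed values are an
error, never clamped); metabolites observed in under half of all
measurements — pooled across the whole study, zeros counting as missing —
are dropped; remaining gaps are filled by k-nearest-neighbour imputation in
sample space (NaN-aware Euclidean distance, inverse-distance weights,
k = 10). The boolean missing mask is carried through the pipeline so
imputed coordinates can be reset to missing after integration
(`restore_missing`), letting sparse metabolites ride through normalisation
without inventing data for downstream analysis. Conditioning QCs are
screened by a robust z-score: each QC injection is summarised by its median
across metabolites, and a conditioning QC farther than 3.5 MAD-scaled units
from the pooled-QC median is removed. The 3.5 threshold and the
median-summary statistic are package choices (no published criterion
exists); both are configurable. Conditioning QCs are excluded from
normalisation by default.

## Within-batch drift correction

Per metabolite, a smoother is fitted against run index on either all
biological samples or the pooled QCs only, and every measurement is
adjusted by `y + (median − fit-at-its-run)`, preserving the metabolite's
batch median exactly (constants pass through unchanged). Two smoothers are
provided: a local-quadratic loess with tricube weights and span 0.75,
written in-package so the exact dialect is pinned (it reproduces R's
`loess(..., surface="direct")` to ~1e-12 on test fixtures and applies no
robustness iterations), and a Huber-M robust linear fit (statsmodels RLM,
max 100 iterations). Loess evaluation outside the fitted run span is
clamped to the nearest fitted value. The classical QC-ratio method is also
available on raw-scale data: each signal is divided by the bracketing
pooled QC, the earlier QC up to the midpoint of the gap and the later one
beyond it.

An optional second step removes unwanted variation anchored on the
short-replicate pairs alone (pooled-QC repeats are excluded from the
replicate map by default — heterogeneous sample replicates estimate
unwanted variation more robustly than many repeats of one pool, and
QC-anchored estimation measurably over-corrects biology in our simulations
as well). `k` is capped at the replicate-residual rank
(measurements − groups), with a warning (or an error, per `k_policy`).

## Inter-batch integration

Batches are merged pairwise along a binary tree: *balanced* (neighbours,
then neighbouring groups; ceil(log2 n) sequential rounds) or
*concatenating* (left-deep chain; appending m new batches later costs m
adjustments). Both schedules perform exactly n−1 pairwise adjustments. At
each merge the two groups are concatenated, a replicate indicator is built
from every group with ≥2 members in the union (a flag restricts to groups
spanning both sides), and the RUV adjustment is applied: mean-centre per
metabolite, estimate `α̂` from the top-k right singular directions of the
group-mean-residualised matrix, estimate `Ŵ` by least squares of the
control columns of `Z` on those of `α̂`, subtract `Ŵ α̂`, restore the means.
Singular directions with numerically zero singular value are never removed,
so noiseless data with no technical variation pass through untouched. With
controls = all metabolites the subtraction is exactly the orthogonal
projection of each measurement onto the complement of span(`α̂`).

Negative controls default to all metabolites; a data-driven alternative
ranks metabolites by a per-batch two-sample t statistic against a supplied
phenotype (an ordinary t statistic, a deliberate simplification of
moderated variants), averages ranks across batches and keeps the least
associated ones.

## Synthetic studies

The generator lays out samples with the design module and builds each
observed value additively: per-sample biology (baseline ~ N(20, 2²) per
metabolite, between-individual SD 0.5, a binary phenotype in 39% of
individuals adding 0.5 log2 to 10 of 100 metabolites), plus factor-
structured unwanted variation, plus independent noise (SD 0.1). The
unwanted part mirrors the model above: 5 latent technical factors with
fixed, shared metabolite loadings; each measurement's factor scores
decompose into a batch-level mean (batch shift, per-entry SD 1.5), a smooth
within-batch profile (linear, or linear + quadratic + one sinusoid;
per-entry scale ≈1 log2 across a batch) and per-injection jitter (SD 0.2).
This makes every metabolite's drift curve a different mixture of a few
basis profiles — heterogeneous shapes, but low-dimensional batch structure,
which is what principal components of real raw batches show. Replicate
injections share their sample's biology exactly and receive their own
technical terms; the pooled QC's biology is the cohort mixture expectation.
Missing entries are injected completely at random. Setting
`n_unwanted_factors = 0` switches to independent per-metabolite offsets,
curves and jitter.

What the generator does **not** emulate: correlated biology (pathway
structure), intensity-dependent noise, QC degradation over freeze–thaw
cycles, non-random missingness, and retention-time or peak-integration
artefacts. Passing tests therefore demonstrate correct mechanics and
behaviour under the stated variance model, not performance on any
particular real cohort.

`truth_metrics` scores an assay against the ground truth: RMSE to the clean
biological signal after removing per-metabolite mean differences (a
constant shift per metabolite is not informative), mean |correlation| of
residuals with run order, RMS of per-(metabolite, batch) mean residuals
after per-metabolite centring, and the recovered phenotype group difference
on affected metabolites.

## Reference scenario and a known limitation

The 6-batch reference scenario (`standard_config`, seed 0) behaves as
follows under the default `loessAllShort_batch_Hc` pipeline: median
replicate SD falls ~95% (0.457 → 0.021 log2) and the injected effect is
recovered at ~0.76 of its size, but k-means ARI against batch labels falls
only to ~0.42 rather than to chance level. The cause is identifiable and
instructive: a smoother's fitted value at a given run is a fixed linear
combination of the samples' values, identical across metabolites. Because
the five batch replicates sit in one contiguous block at the tray start,
all five linking pairs inherit nearly the same smoother correction — a
coherent biology-mixture vector that contaminates every pair difference
identically. The merge-level RUV consequently estimates (offset +
contamination) instead of the offset; no estimator can separate the two
from those pairs alone, and a residual per-entry offset of ~0.15 log2
survives regardless of noise settings. Scattering the batch replicates
across the tray (`scatter_batch_replicates=True`) or adding the pooled-QC
group to the merge replicate map (`include_qc_replicates=True`) breaks the
coherence and drives the ARI to ~0.01–0.1, the latter at a measurable cost
in retained biology. Both remain off by default to match the reference
design; study planners should weigh scattered batch replicates for this
reason.

## Numerical choices and degenerate inputs

Loess neighbourhoods use `floor(span·n)` points (at least degree+1), weight
`(1−u³)³`, and reduce the polynomial degree when positive-weight points are
scarce; coincident-run ties fall back to the weighted mean. RUV rank
tolerance is `max(S, M)·eps·σ₁`. `k = 0` is the identity everywhere. A
merge union without any multi-member replicate group is an error naming the
merge; `k` above the replicate-residual rank caps with a warning or errors
per configuration. Zero-variance vectors have undefined skewness (NaN, not
an exception). The pipeline is deterministic given inputs, configuration
and seed; the only seeded randomness is design selection, simulation and
k-means initialisation.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 5 | unwanted factors removed per RUV application |
| `controls` | all | negative-control metabolites |
| `loess span` | 0.75 | neighbourhood fraction of the local fit |
| `rlm max_iter` | 100 | Huber IRLS iteration cap |
| `min_presence` | 0.5 | observed fraction required to keep a metabolite |
| `impute_k` | 10 | neighbours for kNN imputation |
| `qc_outlier_z` | 3.5 | robust z threshold for conditioning QCs |
| tray | 8 × 11 | rows × positions, one pooled QC per row |
| `n_batch_replicates` | 5 | inter-batch links per transition |
| `n_conditioning_qc` | 3 | instrument-settling QCs per batch |

Problem sizes used by the test-bed: unit tests run on 2-batch 4×5 trays
with 20 metabolites; the end-to-end scenario uses 6 batches of the full
8×11 geometry with 100 metabolites, chosen to exercise every mechanism of
the method at interactive runtimes.
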