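# Methods

## The datacube and its bookkeeping

All computations operate on a pixels × ions matrix with per-pixel metadata.
Batch labels are integers 1..B in chronological acquisition order, one batch
per slide-day by default (pixel- or section-level batches are expressible:
nothing enforces the batch ⇔ slide equivalence). Acquisition times are
unified onto one study clock: each slide's per-pixel relative times are
shifted by the slide's start offset, with the first acquired slide at
offset 0. Pixel coordinates are 0-based and row-major within a section;
sections are tiled for display only, never for analysis.

imzML is read through pyimzML. Continuous mode maps directly onto the common
axis. Processed mode (per-pixel axes) is accepted only with an explicit
merge tolerance (default recommendation 0.005 Da, a few rebinning widths):
per-pixel bins are merged by single linkage into a common axis and
intensities assigned to the nearest merged bin. imzML carries no study
metadata, so batch/time/tissue fields are initialized to neutral defaults
and must come from the study design. CSV bundles (`matrix.csv`,
`pixels.csv`, `features.csv`, UTF-8, headers mandatory) round-trip all
fields losslessly (`%.17g` floats, `float_precision="round_trip"` parsing).

Ion assignment arithmetic uses CODATA/IUPAC monoisotopic masses (≥ 6
decimals) and includes the electron mass for anions: [M−H]⁻ removes a
proton; [M+Cl]⁻ adds Cl plus an electron. The electron term matters — it is
required to reproduce a chloride-adduct m/z to four decimals. Supported
adducts: deprotonation, chloride adduct, electron attachment (radical
anion, which also covers intrinsic anions such as HSO₄⁻).

## Preprocessing

- **Rebinning**: linear interpolation of each profile spectrum at every node
  of a fixed grid (default 0.0008 Da); outside a spectrum's support the
  value is 0; grid-coincident points are conserved exactly.
- **Peak picking** ("gradient" method): an apex is a + → − sign change of
  the first difference; plateaus resolve to their lowest-index bin;
  boundaries extend downhill to the flanking local minima or the spectrum
  ends. No pre-smoothing by default (an odd-window moving average is
  available). Ranking for top-N selection uses apex height, not area, with
  intensity ties broken toward lower m/z so the selection is deterministic.
- **Segmentation**: cosine k-means (rows L2-normalized, Euclidean k-means,
  3 restarts, best inertia kept), k = 3 default; the background cluster is
  the one whose members have the lowest mean TIC — a rule chosen because
  segmentation needs *some* background criterion and total signal is the
  natural one.
- **Common axis**: peaks chaining within tolerance (single linkage) merge to
  their intensity-weighted mean m/z with summed apex intensity.
- **Peak extraction**: per pixel, profile bins within apex ± half-window are
  summed; overlapping windows assign each bin to its nearest apex (warned).

The tissue "total spectrum" is computed as a mean rather than a sum; top-N
ranking is unaffected by the constant factor.

## Normalizations

TIC divides each pixel by its summed intensity (target: unit sum — the
simplest contract; no median-TIC rescaling). L2 divides by the Euclidean
norm. z-standardization is per ion with the population (divide-by-n) SD;
constant ions become zero columns with a warning, and near-zero SDs (a few
ULPs left by accumulated rounding on constant columns) are treated as
constant via a relative threshold. The generalized logarithm
g(x) = ln((x + √(x² + λ))/2), default λ = 10⁶, has the exact inverse
x = e^y − λ/(4e^y), used when a corrector runs on the g-log scale.

## ComBat (parametric empirical Bayes)

Batch-dummy least squares under Σᵢ nᵢγᵢ = 0 gives the grand mean α_g
(batch-size-weighted mean of batch means) and pooled residual SD σ_g
(divide-by-N). On z = (x − α)/σ: per-batch means γ̂_ig and ddof-1 variances
δ̂²_ig; hyperpriors by method of moments — γ̄ᵢ, τ̄²ᵢ from the ion ensemble
of γ̂, and inverse-gamma (λᵢ, θᵢ) from the mean m and variance s² of δ̂²
via λ = (2s² + m²)/s², θ = (ms² + m³)/s². Posterior conditional means by
fixed-point iteration (tolerance 1e-4 on the max relative change, cap 100;
2 iterations typically suffice), then x* = σ(z − γ*)/δ* + α. Parametric
priors only; no covariates. The feature-ensemble variance s² is floored at
1e-12 so a degenerate ensemble yields a tight prior rather than an
indeterminate one.

The correction is affine per (batch, ion): within-batch Pearson correlation
of any ion pre/post is exactly 1, which is what preserves single-ion image
structure. The implementation matches `sva::ComBat` (Bioconductor) to
~1e-15 relative on shared fixtures; that cross-check runs in the test suite
through Rscript.

Scale choice is exposed (`linear`, `log`, `glog`): the EB normality
assumption is usually more plausible on a log-type scale for MSI
intensities, and recovery tests on the log-normal simulator run on `log`.

Two shrinkage consequences worth knowing: (i) corrected batch means match
only up to the O(1/√n) shrinkage residue, so "means agree within 0.05σ"
needs thousands of pixels per batch under a uniform shift; (ii) the
correction is only *near*-idempotent — a second pass moves values by
~δ²/(nτ̄²) of σ, not by machine epsilon. Both are properties of parametric
EB itself (the reference implementation behaves identically) and both are
asserted at their derived magnitudes in the tests.

## SERRF (QC random-forest regression)

Assumes each batch carries technical replicates of a homogeneous QC
material. QC pixels are split (default 50/50, seeded) into a training half
and a held-out evaluation half. Per batch, means and ddof-1 SDs of the
training QC define the scaling; all features are standardized within batch.
For each ion g, candidate predictors are ranked by |Pearson r| with g on the
scaled training data (the ion never predicts itself; ranking uses QC
correlations only — the original method also consults subject-sample
correlations, a simplification recorded here), and a
`RandomForestRegressor` (defaults k = 10 predictors, 500 trees; per-ion
seeds spawned from the model seed) learns the scaled intensity of g.

Correction: p_jg = ŷ·sd_ig + mean_ig is the predicted raw-scale systematic
level; x* = x · m_g / p with m_g the QC median over positive training
intensities. Predictions are floored at their per-ion 1% quantile (and at
1e-6·m_g) so occasional tiny or negative predictions cannot blow up the
ratio. Pixels with zero raw intensity stay zero; ions whose QC median is
zero pass through unchanged. Because the per-batch scaling constants carry
the batch-mean information, a forest that finds nothing to learn still
yields the classic QC-mean scaling; the forests add correlated within-batch
structure such as drift.

Fitting touches QC pixels only — transfer to heterogeneous tissue is safe
by construction, and a test verifies that perturbing non-QC pixels cannot
change a fitted model. Models pickle with a format/version header and
reload to byte-identical predictions.

## WaveICA (wavelet + ICA)

Pixels are ordered by acquisition time; each ion's series is padded
(edge-replicated) to a multiple of 2^J and decomposed with the undecimated
stationary wavelet transform (Haar default, J = min(10, ⌊log₂ n⌋),
norm-preserving). Per decomposition level, FastICA (c = min(10, G)
components, seeded) runs across ions; a component whose one-way batch
R² = 1 − SS_within/SS_total exceeds the cutoff (default 0.1; a Spearman
association against acquisition order is available instead) is removed by
subtracting its least-squares projection from the level's coefficient
matrix. Inverse transform, trim the padding, restore pixel order, and
reattach each ion's grand mean.

Removal-by-subtraction (rather than re-synthesis from retained components)
makes cutoff = 1 an exact identity up to wavelet round-off (~1e-13).
Whitening is done natively — sample-side SVD with signs canonicalized per
score column — because scikit-learn's internal whitening sign convention
depends on feature order; with well-separated components the corrector is
then exactly equivariant under ion reordering. On noise-dominated detail
levels the SVD basis is near-degenerate and equivariance (like any ICA
result there) is only approximate. The cutoff rule is this package's
documented component-selection criterion; exact default equivalence with
other WaveICA releases is not claimed.

The method's core assumption — batch/drift variation is low-frequency in
acquisition order while biology is high-frequency — holds for randomized
injection sequences but only partially for MSI rasters, where tissue
gradients are themselves slow and batch boundaries can be sharp. The
evaluation suite exists precisely to check, per data set, what a given
cutoff removed and what it kept.

## Evaluation metrics

Percentiles everywhere use linear interpolation (type 7). Between-batch
variance is the population variance of per-batch means (unweighted by
default; a size-weighted option exists). Grand-mean fidelity regresses
ln(corrected ion mean) on ln(raw ion mean) over ions with positive means;
slope ≈ 1 with high R² means the intensity scale survived, slope ≈ 0 flags
collapse onto a constant. PCA is mean-centred with no variance scaling; the
batch silhouette (Euclidean, on the first two scores) quantifies separation
of batch point clouds — near 0 when mixed. This silhouette is this
package's quantification of what is otherwise judged visually from score
plots, and reports label it as such. t-SNE uses the exact algorithm with
the cosine metric, three components min-max scaled to RGB; perplexity is
capped at (n−1)/3 for small inputs. Spatial preservation is the per-section
Pearson correlation between raw and corrected single-ion images; constant
images are excluded (counted), and a correction that leaves no usable ion
anywhere is flagged as collapsed with score 0. A per-ion batch-mean
correlation matrix is available as an optional, non-canonical diagnostic.

## The simulator

`simulate_study` draws x_jg = exp(μ_g + ln f_gr + ln a_bg + d_b·t̃_j + ε),
ε ~ N(0, s_bg): ion base levels μ_g ~ N(5, 1) (natural-log scale, i.e.
typical intensities ~150 arbitrary units); per-batch location factors
a_bg = exp(η_b + ζ_bg) with a shared slide-level component (SD 0.3) and an
ion-specific component (SD 0.3), reproducing both the slide-wide and the
ion-differential character of real batch shifts; noise SDs
s_bg = 0.2·exp(N(0, 0.3)) varying by batch so distribution *spreads* shift
too; drift slopes d_b ~ N(0, 0.1) acting on within-batch normalized time;
and, in heterogeneous sections, a two-region vertical split (random cut
between 35% and 65% of the width) with log-normal fold factors (SD 0.5) on
half the ions. Homogeneous QC sections have no region structure. Timestamps
increase in raster order, sections sequentially within a batch, one second
per pixel with an hour between batches. The default study shape is 10
batches × (one homogeneous + one heterogeneous QC section) × 40×40 pixels
× 100 ions — a desk-scale stand-in for studies with tens of thousands of
pixels and 1000 peaks; tests use smaller draws of the same model where a
scenario calls for specific structure (e.g. a single shared batch factor
for the correlated-ion SERRF setting). A multiplicative model was chosen
because observed batch effects move medians and IQRs jointly; an additive
variant is exposed for robustness checks.

What the simulator does **not** emulate: peak-shape/centroiding artifacts,
mass-calibration drift, matrix-cluster interference, spatially correlated
noise, and inter-ion correlation beyond the shared batch/drift/region
factors. Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated generative model, not performance on any
particular real study.

All randomness flows through explicit integer seeds (`numpy` Generator /
`SeedSequence`); identical seeds give byte-identical cubes, segmentations,
and corrections.

## Degenerate inputs and numerical choices

Zero-TIC/zero-norm pixels are left untouched with a warning; constant ions
z-score to zero columns; ComBat refuses batches with zero variance in every
ion and cubes with fewer than two ions or batches; SERRF refuses k ≥ G and
batches with fewer than two QC training pixels; WaveICA requires finite
times and n ≥ 2^J. Peak lists may be empty. Merged-axis and k-means
tie-breaks are deterministic under fixed seeds.
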