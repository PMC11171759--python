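# Methods

## Model and assumptions

The pipeline treats a single-cell 3D fluorescence stack as a weighted point
cloud: every voxel whose intensity exceeds a background-derived threshold
contributes its excess intensity as weight, and all spatial statistics
(centre of mass, radius of gyration, distance distributions) are moments of
that cloud. The deliberate simplifications are:

- **Spherical cell approximation.** No nucleus or membrane segmentation;
  the "cell centre" is the intensity-weighted centre of mass of the
  suprathreshold signal, and "cell size" is its radius of gyration. This is
  appropriate for roughly isometric cells imaged whole; for strongly
  elongated cells the scaled distance loses its geometric interpretation.
- **Pixel-unit coordinates by default.** Voxel indices are the coordinate
  system unless a physical spacing is supplied, in which case indices are
  scaled per axis before any distance is computed. Confocal stacks with few
  z-slices therefore appear axially compressed in the default analysis —
  consistent with treating the z-index as a coordinate.
- **Background is Gaussian and signal is a right tail.** The background fit
  never models the signal; it only assumes signal pixels are brighter than
  the background mode.

## Background estimation

`estimate_background` pools all z-layers. The mean is the location of the
maximum of the intensity histogram, computed in two stages: a coarse pass
(256 equal-width bins over the full range; integer data gets integer-aligned
bins, which reduces to an exact unit-bin mode for narrow dynamic ranges)
locates the peak and yields a provisional left-tail spread; the histogram is
then re-binned at half that spread around the peak, and the mode is refined
by quadratic interpolation through the log-counts of the three bins around
the maximum. A Gaussian peak is exactly parabolic in log counts, so the
refinement is unbiased there; empirically it reduces the mode error at
detector-like widths (σ ≈ 150 counts, 10⁶ pixels) from ~1.3% to ~0.1%. A
single-pass unit-bin mode was rejected because its sampling jitter at these
widths exceeds 1% of the mean. Ties in the histogram maximum resolve to the
lowest-intensity bin.

The spread σ is the population root mean squared deviation of intensities
below the mode: for any symmetric background law E[(Y−μ)² | Y<μ] = σ², so
bright signal (strictly right-tail) cannot bias it. Degenerate inputs —
constant stacks, stacks with no dispersion below the mode, fewer than 1000
pixels — raise `ValueError` rather than returning numbers.

Thresholds: `compute_threshold` gives θ = μ + n_σ σ (confocal default
n_σ = 10); `sted_threshold` gives θ = mean + n_σ·sd over all pixels
(STED default n_σ = 1). Binarization is strictly `y > θ`; pixels exactly at
θ carry zero excess weight under either convention, so the strictness only
fixes determinism. `background_fraction` is defined as the fraction of
pixels ≤ θ (the definition is configurable in spirit — any monotone variant
can be computed by passing a different θ).

## Geometry and distributions

Weights are normalised to sum to one (the definition is scale-free, so
normalisation just fixes the representation). Distances honour anisotropic
spacing by scaling index offsets per axis. The radius of gyration uses the
same weights, making the scaled distance s = d/R_g invariant under uniform
magnification and under rescaling of all excess intensities — the two
invariances that make populations of differently sized, differently stained
cells comparable.

Scaled histograms live on a fixed common grid, [0, 2.5] × 100 bins, so that
cells can be averaged bin-wise and fed to PCA; mass beyond 2.5 (rare: a
uniform ball ends at s = √(5/3) ≈ 1.29 and membrane shells near s ≈ 1.2–1.5)
is folded into the last bin and reported as an overflow fraction. Bins are
half-open with a closed last bin. Unscaled histograms span [0, max d]. All
histograms are probability densities (∫ = 1 to machine tolerance).

Down-sampling is block-mean over factor×factor tiles per layer (decimation
would discard intensity mass); in-plane spacing is multiplied accordingly,
so physical geometry is preserved. The z-projection QC view averages the
clipped excess over z. Event counting labels 26-connected components of the
suprathreshold mask; per-event intensities integrate the excess over each
component.

## Population statistics

Group mean curves are unweighted means of per-cell densities (R_g scaling
already removes size, so no size weighting is applied). PCA operates on
column-mean-centred density rows without variance scaling (bins share
units); components come from the SVD with a deterministic sign convention
(each component's largest-magnitude entry is positive). No hypothesis tests
are attached — group differences are reported as mean ± SEM and PC1
summaries, reflecting that cohort-level differences of this phenotype are
typically visible but not individually significant.

**Membrane fraction.** The integrated density mass at s > cutoff, default
cutoff 1.2. A cutoff at the gyration radius itself (s = 1) is *not*
discriminating: any homogeneous ball-like distribution already carries the
majority of its mass beyond R_g (1 − (3/5)^{3/2} ≈ 53.5% for a uniform
ball), so membrane arrest barely moves the statistic there. Placing the
cutoff between R_g and the homogeneous support bound √(5/3) ≈ 1.29 — just
below the membrane-shell position R/R_g ≳ 1.2 — makes the statistic
specific to membrane-localised mass while keeping it simple (one number per
cell, exactly integrated including the partial bin at the cutoff).

**Bimodality.** Peaks are local maxima of the 3-bin moving-average-smoothed
curve with prominence at least 5% of the smoothed maximum; the prominence
floor suppresses binning noise without hiding genuine secondary modes. A
cell or group is bimodal when a second peak appears, with the outer peak in
the s ∈ [0.9, 1.6] window characteristic of membrane arrest.

**Outer-peak mass.** For rescue comparisons the membrane population is
quantified as the mass of the *resolved second mode*: density integrated
from the local minimum preceding the outermost peak (when that peak lies in
[0.9, 1.6]) to the end of the grid, and zero for unimodal curves. A
fixed-window integral was rejected: reducing the shell weight shrinks R_g,
which slides the core mode *into* any fixed outer window and masks the
treatment effect the statistic is supposed to expose.

## Synthetic data generator

`generate_cell` emulates a single immunostained cell: vesicle centres are
drawn from one of three spatial models (uniform in the cell volume; uniform
in a thin shell at the cell radius; or a mixture of a truncated-Gaussian
perinuclear core and the shell, with mixing weight `membrane_weight`), each
rendered as a Gaussian spot and overlaid with Gaussian detector background,
then clipped and quantised to 16 bits. The cell is an oblate ellipsoid: the
axial semi-axis is `axial_squash × cell_radius` (default 0.5, reflecting
adherent-cell geometry; squash 1.0 recovers the isotropic sphere where the
closed forms apply). Defaults — stack (64, 160, 160), radius 50 px, 150
vesicles, PSF σ 2.5 px (confocal-like) or 0.6 px (STED-like), spot
amplitude 20 background-sigmas with ±30% uniform brightness jitter,
background 1861.63 ± 147.70 counts — are sized so the cell fits the stack
with margin and a default cell costs ~0.1 s to generate and analyse.
`generate_population` adds ±jitter variation of radius and vesicle count
with per-cell seeds derived from one population seed.

Rendering draws all random numbers (component assignment, positions,
amplitudes, noise) before and independently of the PSF width, so two specs
differing only in `psf_sigma` share identical ground truth — this is what
makes the STED-vs-confocal event-resolution comparison a controlled
experiment.

What the generator does **not** emulate: photon shot noise (background is
additive Gaussian only), realistic PSF shapes (isotropic Gaussian, no axial
elongation, no Gibson–Lanni model), sub-voxel spot placement (centres snap
to the nearest voxel before blurring), autofluorescence gradients,
cell-shape irregularity, or vesicle size variation. Passing tests therefore
demonstrate correctness of the estimators and the qualitative phenotype
logic, not robustness to every artefact of real microscopy.

Deterministic continuum phantoms (`ball_phantom`, `shell_phantom`) realise
the analytic limits exactly — a voxelised uniform ball of radius 30 gives
R_g/R within 0.01% of √(3/5) and mean scaled distance within 10⁻⁴ of
(3/4)√(5/3) — and are used wherever a closed form is the reference.

## Numerical choices

- Histogram mode ties → lowest bin; σ estimators are population (divide by
  n) moments.
- Weights strictly positive, sum checked to 1e-9; empty suprathreshold sets
  and zero radii of gyration raise `QCError`, which batch drivers convert
  into exclusion records (never silent drops).
- SVD sign convention as above; PCA on fewer than 2 cells or on an
  all-identical matrix is an error, not a NaN.
- CSV floats carry ≥ 9 significant digits (histogram files use full
  precision, `%.17g`, and are read back with exact round-trip parsing).
- OME voxel-size metadata is used only when no explicit spacing argument is
  given; default spacing is isotropic 1.0 (pixel units).

## Validation problem sizes

The test suite validates oracle equivalence on fifty 16×32×32 random
stacks; analytic limits on ~1.1×10⁵-voxel phantoms; background recovery on
10⁶-pixel detector simulations over ten seeds; phenotype recovery on
cohorts of 30 + 30 cells (ten seed pairs) and rescue on 40 + 40 (ten seed
pairs); robustness properties on ten generator-default cells. These sizes
were chosen to exercise each property at meaningful statistical resolution
while keeping the default suite in the minutes range on one CPU.

## Known limitations

- Per-cell scaled histograms at the default 150 vesicles/cell and 100 bins
  are granular: at high thresholds each vesicle's suprathreshold blob spans
  only one or two bins, so per-cell L1 distances between histograms
  computed at different n_σ (or before/after down-sampling) can reach
  0.15–0.5 even though the underlying spatial distribution is unchanged.
  The effect vanishes with more vesicles (L1 ≈ 0.09 at 600 vesicles/cell);
  population mean curves are unaffected. Shape comparisons at low event
  counts should therefore be made on group means or with coarser bins.
- In strongly squashed cells the membrane shell is not equidistant from the
  centre, so the outer mode broadens toward lower s; the bimodality window
  [0.9, 1.6] accounts for this, but extreme squash (< 0.2) will blur the
  two modes together.
- The STED-vs-confocal comparison concerns event *counts* under identical
  ground truth; absolute counts still undercount at high vesicle density
  because touching blobs merge at any PSF width.
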