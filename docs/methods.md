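# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `fcdtools`. The package implements a complete analysis chain
for pharmacological resting-state fMRI: denoising, local functional
connectivity density (lFCD) mapping, region-wise repeated-measures
statistics, and imaging-transcriptomic association testing with
spatial-autocorrelation-preserving surrogate maps. Because the kind of study
it targets (within-subject drug challenge, three scanning conditions) rarely
deposits raw scans, the package ships a synthetic-data generator that
produces every input the pipeline needs, with known ground truth.

## Denoising model

A scan enters the pipeline as a 4-D BOLD array already in a common space,
with per-frame nuisance tables. Denoising follows the widely used
36-parameter strategy:

1. **Framewise displacement (FD).** The L1 convention:
   FD(t) = Σ|Δ translations| + r·Σ|Δ rotations|, with r = 50 mm converting
   radians to arc length and FD(1) = 0. Scans with mean FD above 0.3 mm
   (strict inequality) are flagged for exclusion. FD is recomputed from the
   motion parameters rather than read from an upstream table, so the QC is
   self-contained.
2. **Confound regression.** Nine base signals (CSF mean, WM mean, global
   signal, six rigid-body parameters), their backward-difference temporal
   derivatives (first element 0), and the squares of all eighteen — 36
   columns — plus one indicator column per frame with FD > 0.5 mm (spike
   regressors, included in the same single regression rather than used for
   censoring). An intercept is always added; exactly collinear columns are
   dropped with a warning. Residuals are exact least-squares projections,
   orthogonal to every retained column.
3. **Band-pass filtering.** Zero-phase (forward–backward) Butterworth of
   order 4 before doubling, pass band 0.01–0.1 Hz. Zero-phase filtering
   avoids frequency-dependent phase shifts that would bias inter-voxel
   correlations. The high edge is validated against the Nyquist frequency
   of the repetition time.
4. **Spatial smoothing.** Per-frame 3-D Gaussian kernel, FWHM 6 mm,
   σ = FWHM/(2√(2 ln 2)) per axis in voxel units. Smoothing is
   *mask-normalized* (the smoothed data are divided by the smoothed mask)
   so that voxels near the mask edge are not attenuated — important on the
   small grids the generator produces, where most voxels are near an edge.

The stage order is regression → band-pass → smoothing, recorded in each
session's `history` so composition can be asserted.

## Local functional connectivity density

lFCD of a seed voxel is the size of the contiguous cluster grown from the
seed: a voxel joins if it is spatially adjacent to a cluster member *and*
its time series correlates with the **seed** above threshold (r > 0.6,
strictly). Equivalently, lFCD(seed) is the size of the connected component
containing the seed in the seed-specific super-threshold mask. Defaults:
face adjacency (6-connectivity; 18 and 26 available) and correlation against
the seed rather than chained neighbor-to-neighbor correlation. The chained
variant is available as `seed_mode="chained"` for sensitivity analyses; it
produces a partition of the mask (all voxels of a component share one
value) rather than a per-seed count.

Details fixed by convention:

- the seed counts itself, so lFCD ≥ 1 and the logarithm is defined;
- zero-variance voxels are removed from the mask (with a logged count)
  before any correlation is computed;
- the log transform is natural by default (`log10` available);
- regional profiles are unweighted means of in-mask voxel values per
  parcellation region; regions without in-mask voxels are flagged missing.

The production implementation (per-seed thresholded connected-component
labelling) is verified voxel-for-voxel against a brute-force oracle that
materializes the full voxel×voxel correlation matrix and runs breadth-first
search per seed; the oracle is restricted to ≤ 10⁴ in-mask voxels.

A diagnostic (`motion_lfcd_check`) correlates regional log(lFCD) with
per-scan mean FD across all scans and reports both the signed and the
absolute mean coefficient. It gates nothing; it exists to quantify residual
motion contamination.

## Group statistics

- **Repeated-measures ANOVA**, one-way within-subject, per region:
  F = MS_condition / MS_(condition×subject), df = (C−1, (C−1)(S−1)).
  Sphericity is assumed — no Greenhouse–Geisser correction in the default
  inference path, so the reported df match the classical table (e.g.
  (2, 28) for 15 subjects × 3 conditions); the GG epsilon is computed per
  region as a diagnostic column. Regions with exactly zero condition
  variance report F = 0.
- **BH-FDR** across regions (statsmodels' step-up implementation behind the
  package surface; the test suite verifies it against a from-definition
  brute force).
- **Post-hocs**: paired two-sided t-tests per condition pair,
  Bonferroni-multiplied by the number of pairs and capped at 1. A pair with
  zero difference variance but nonzero mean is reported as p = 0 with a
  degeneracy flag.
- **Effect sizes**: Cohen's d, default the paired dz (mean within-subject
  difference / SD of differences, ddof = 1); the pooled-SD variant is
  available and the variant used is recorded in the output table.
- **Behavioral correlation**: Pearson r per region between per-subject
  regional change and a behavioral change score, two-sided p from the t
  transform.
- **Subgroup comparison** (sex, genotype): Welch's t on condition-difference
  scores per region with BH-FDR, the simplest test consistent with a
  two-group comparison of within-subject changes; a full mixed model is
  deliberately out of scope.

## Surrogate-map association testing

Brain maps are spatially autocorrelated, so correlating an effect-size map
with a gene-expression map against an i.i.d. null grossly overstates
significance (the package's own calibration experiment shows the naive
parametric Pearson test rejecting at several times the nominal rate). The
null used here preserves each gene map's spatial autocorrelation via
variogram matching:

1. randomly permute the source map;
2. smooth the permutation over region centroids with a row-normalized
   exponential distance kernel, at each of several candidate scales
   (default: 8 scales geometrically spanning the minimum pair distance to
   a third of the maximum);
3. for each scale, least-squares fit slope β and intercept α mapping the
   smoothed map's binned variogram to the source map's;
4. keep the scale with the smallest residual;
5. surrogate = |β|^½ · (smoothed permutation, standardized) + |α|^½ ·
   independent Gaussian noise.

The variogram is the distance-binned semivariance γ(h) = ½·mean (xᵢ−xⱼ)²,
25 uniform bins spanning (0, max distance]. **The fit in steps 3–4 uses
only bins up to the 25th percentile of pair distances** (configurable via
`fit_percentile`): short lags carry the autocorrelation that determines a
map's effective degrees of freedom, while the sparse long-distance bins of
a single realization are substantially noise, and fitting them destabilizes
scale selection. With this default, the surrogate test's empirical type-I
rate on independent 30 mm-autocorrelated map pairs over a brain-sized
200-region geometry sits near the nominal 5% (the acceptance script
measures it); with a full-range fit it is visibly inflated.

The permutation p-value is two-sided with the add-one correction,
p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_surrogates), so p ≥ 1/(n+1); the
one-sided value in the observed direction is also reported. The default
ensemble size is 5000 surrogates per gene map, with per-surrogate seeds
derived from one master seed so ensemble rows are reproducible
individually. Family-wise results (genes × contrasts; 3 × 2 in the default
pipeline, effect maps restricted to cortical regions) get BH-FDR q-values.

Known limitations of the surrogate generator:

- Inter-region distances are Euclidean between volumetric centroids, not
  geodesic along a cortical surface.
- A surrogate's ability to reproduce the *full-range* binned variogram of
  an arbitrary map is bounded by realization noise: the sample variogram
  of any single smooth random field wobbles at long lags (two independent
  fields drawn from the same covariance correlate only ≈ 0.75 on this
  statistic in our geometry). For canonically smooth maps — monotone
  spatial gradients, or fields whose correlation structure lies within the
  exponential smoothing family at a resolvable scale — mean fidelity is
  ≈ 0.92; for rough fields (correlation length of a few centroid spacings
  or less) it degrades, while the *short-range* autocorrelation relevant
  to inference remains matched.

## Synthetic data: what it emulates and what it does not

The generator reproduces the structure the pipeline is sensitive to, at
desk scale:

- **Parcellation**: Voronoi partition of a voxel grid around random sites
  (contiguous, non-empty regions), with cortical / subcortical / cerebellar
  compartment labels and seven cyclic network labels. Default test grid
  12×12×10 voxels at 3 mm; transcriptomics experiments use 200 cortical
  regions over a brain-sized (144×168×120 mm) grid of 6 mm voxels. These
  sizes preserve every algorithmic property at interactive runtimes.
- **BOLD**: unit-variance AR(1) voxel noise (coefficient 0.3 by default);
  voxels in designated hub regions additionally share a band-limited
  (0.01–0.08 Hz) latent signal with mixing weight h and noise variance
  1−h², so hub pairs correlate at ≈ h². The band-limited latent survives
  the pipeline's own band-pass, enabling end-to-end recovery tests.
  Defaults: TR 2.5 s; 120 frames in desk-scale runs (the emulated
  acquisition has 240).
- **Tissue signals**: two fixed corner blocks of the grid, excluded from
  the brain mask, serve as CSF and WM masks; the confound table contains
  their means plus the in-mask global mean.
- **Motion**: Gaussian random-walk translations/rotations with optional
  sustained step displacements ("spikes") at chosen frames, sized so FD at
  the spiked frame jumps by the spike amplitude.
- **Gene maps**: Gaussian random fields over region centroids with
  covariance exp(−d/L); L = 30 mm by default, matching the correlation
  length regional expression maps typically show.
- **Condition studies**: values = subject intercept + per-condition
  regional effect + i.i.d. noise (subject SD 0.2, noise SD 0.3). The
  optional gene coupling rebuilds the last-vs-first condition contrast as
  slope·z(expression) + √(1−slope²)·(orthogonalized residual), making the
  planted spatial correlation exactly the slope. The emulated design uses
  15 subjects × 3 conditions (baseline, immediately post, 90 min post).

Not emulated: scanner physics, susceptibility and physiological artifacts,
slice timing, registration error, spatial structure of noise beyond the
planted hubs, hemispheric symmetry, and any pharmacokinetics. Passing
tests demonstrate algorithmic correctness and statistical calibration
under these idealized conditions, not robustness to everything real scans
contain.

## Numerical choices and degenerate inputs

- All generators and the surrogate machinery are bit-reproducible given
  (parameters, seed); multi-entity calls derive independent child seeds
  from the master via `SeedSequence` (kept below 2³¹).
- Gene-map covariances are Cholesky-factorized with escalating diagonal
  jitter (up to 1e-4) before failing.
- Voronoi label ties resolve to the lowest site index; variogram bin edges
  are half-open with the maximum distance folded into the last bin.
- Degenerate statistics (zero-variance differences, constant mFD, constant
  maps) are flagged explicitly rather than silently propagated as NaN;
  constant source maps are rejected by the surrogate generator.
- The rm-ANOVA treats condition sums of squares below 1e-12 of the total
  as exactly zero (F = 0) to keep the fully degenerate case finite.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run: oracle equivalence on 100
random 6×6×6×40-frame sessions at 9 threshold/connectivity combinations;
hub recovery on a 12×12×10 grid with 120 frames; surrogate fidelity with
100 surrogates of a 200-region map; type-I calibration with 300 repeats ×
500 surrogates; planted-recovery with 20 runs × 3 genes × 500 surrogates;
brute-force agreement on 500 + 500 random instances. The default ensemble
size for real analyses remains 5000; the experiments use 500 because the
quantities they estimate (rejection rates, recovery rates) are limited by
the number of repeats, not the per-test resolution.
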