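# Methods

## Problem

Whole-body [18F]FDG PET images are reconstructed from a Poisson counting
process, so shortening the acquisition time per bed position raises image
noise roughly as one over the square root of scan time. `petdenoise`
implements a post-reconstruction enhancement approach: a 3D convolutional
network is trained on pairs of short-time (noisy) and long-time (clean)
reconstructions of the *same* acquisition, obtained by splitting one long
frame into sub-intervals, and is then applied to short-time reconstructions
of unseen subjects. The package also implements the quantitative evaluation
battery used to judge such a method — lesion SUVmax/SUVpeak stability,
liver coefficient-of-variation (COV) noise measurements, Bland–Altman
agreement, and the nonparametric omnibus/post-hoc statistics — exercised
end to end on synthetic phantoms with known ground truth.

## Phantom and acquisition model

A phantom is a noiseless activity map in SUV units on a
(slices × rows × cols) grid with voxel size 2.8 × 2.7 × 2.7 mm: a uniform
soft-tissue background (default SUV 0.7), a large uniform liver ellipsoid
(default SUV 2.0, semi-axes 30 × 45 × 45 mm — large enough to host the
three 6-cm noise ROIs the COV protocol requires), and three spherical
hotspot lesions per subject with diameters drawn uniformly in 10–20 mm and
true SUV uniform in 2–8, so the evaluated lesions span a wide uptake range.

Acquisition is emulated statistically, not event-by-event:

- **Counting.** A frame of duration *t* draws independent Poisson counts
  per voxel with mean `activity × t × sensitivity`. The default sensitivity
  (1 count per SUV-unit per minute per voxel) puts the liver COV of a
  1.5-min reconstruction near 0.10–0.12, a realistic clinical level; since
  real scanner count levels are not modelled, absolute noise magnitudes are
  arbitrary and only comparisons across durations/methods are meaningful.
- **List-mode interval extraction.** Splitting a frame into *n* equal
  sub-intervals partitions each voxel's counts by an exact multinomial draw
  (sequential binomial thinning), so sub-frame counts sum exactly to the
  parent frame. Sub-frames of one parent are therefore negatively
  correlated at fixed total — as real sub-intervals are at fixed event
  count — and a short frame shares counts with the long frame derived from
  the same acquisition, which slightly limits how much of the noise is
  removable in principle.
- **Reconstruction.** The penalized iterative reconstruction is emulated by
  a resolution surrogate: counts are converted back to concentration and
  smoothed with a Gaussian whose FWHM combines an intrinsic PSF term
  (default 4.0 mm) in quadrature with a regularization-strength term
  `2.0 + β/250` mm, so β 200/300/500 map to total FWHM ≈ 4.9/5.1/5.7 mm.
  Larger β means stronger noise suppression; only this qualitative
  trade-off, not the true algorithm, is modelled. Smoothing uses reflective
  boundaries with a normalized kernel, so constants are fixed points and
  total activity is conserved.
- **SUV scaling.** SUV = concentration (kBq/mL) × weight (kg) / injected
  activity (MBq), with 1 g/mL tissue density; a subject injected at
  4 MBq/kg with uniform tracer has SUV 1.0. Decay correction is out of
  scope because all comparisons are within-subject at one time point.

The training design mirrors the clinical protocol: each training subject
contributes one 6-min frame (reconstructed at β 200 as the clean target)
that is split into four 1.5-min intervals and, separately, six 1-min
intervals of which the first four are used (reconstructed at β 500 as noisy
inputs). Test subjects are "scanned" for 4 min (β 300 reference); their
1.5-min and 1-min frames are extracted from the same acquisition by
splitting into 0.5-min chunks and summing three (respectively two) of them.

## Training-pair construction

Reconstructions are cropped to the 50 centremost slices (when the discard
count is odd, one more slice is removed from the end than from the start —
a fixed convention), partitioned into ten contiguous 5-slice subsets, and
optionally augmented by random in-plane transforms: uniform scale in
[0.9, 1.1], shear in [−0.1, 0.1], and independent axis flips with
probability 0.5, resampled bilinearly. The identical transform is applied
to both members of a pair — an untransformed target would be spatially
inconsistent with its transformed input. Pair counts follow
`subsets × sources × reconstructions × (1 + augmentations)`; with 72
sources, 4 reconstructions and 5 augmentations this is 17,280 per network.
Two networks are trained from separate pair sets built by the same code
path: one for 1-min and one for 1.5-min inputs.

## Network

A residual denoising CNN adapted to volumetric data: `n_layers` (default
10) same-padded 3×3×3 convolutions with `n_filters` (default 68) channels
in the interior, batch normalization on every interior layer, a rectifier
after every layer except the last, and no pooling. The first layer takes
the single-channel block and the last projects back to one channel (read as
channel counts; a literal one-filter first layer would destroy capacity).
In the default residual mode the network predicts the noise map, which is
subtracted from the input.

Training minimizes mean squared error with stochastic gradient descent
(momentum 0.9). Three standard stabilizers from the denoising-network
lineage are defaults, chosen because plain SGD otherwise either crawls or
collapses to the constant-output solution:

- the output projection is zero-initialized, so residual training starts
  from the identity mapping with loss equal to the residual variance;
- the global gradient norm is clipped (default 0.05) to bound the early
  transient;
- blocks are centered by the training-set mean and scaled by the 99.5th
  percentile of the centered absolute intensities; centering matters
  because the first layer has no batch normalization and a large DC
  component conditions SGD badly. Units are restored after the network, so
  the model is SUV-in/SUV-out.

Whole volumes are denoised by sliding 5-slice windows with stride 1 and
averaging overlapping predictions per slice; inference uses frozen
batch-norm running statistics and is deterministic. All weights, batch
statistics, configuration and the loss history round-trip through a single
checkpoint archive.

The engine is a self-contained numpy implementation (im2col convolutions
routed through BLAS, analytic gradients verified against numerical
differentiation), so training and inference run on a single CPU.

## Quantification and statistics

- **SUVmax**: maximum voxel in the lesion VOI (ground-truth lesion mask
  dilated by one voxel, defined once per subject and reused across all
  image sets).
- **SUVpeak**: maximal mean over a 1 cm³ sphere (radius 6.204 mm,
  voxel-center rasterization, within one voxel volume of 1 cm³) centered at
  any VOI voxel whose sphere fits in the volume; a config switch centers on
  the SUVmax voxel instead.
- **Liver COV**: three 6-cm circles on transaxial slices (i, i+2, i+4),
  voxel centers strictly inside the diameter; per-circle COV uses the
  population SD (configurable) and the three values are averaged.
- **Bland–Altman**: mean difference, 95% limits of agreement with the
  sample SD, least-squares trend of difference against pair mean, and
  t-based LoA confidence limits (the standard approximation
  `Var(LoA) ≈ SD²(1/n + 1.96²/(2(n−1)))`).
- **Statistics**: Friedman omnibus over the five related image sets per
  metric, then all ten pairwise Wilcoxon signed-rank tests at the
  Bonferroni threshold 0.05/10 = 0.005; reader-score tables use
  Kruskal–Wallis followed by pairwise Mann–Whitney U at the same threshold.
  All tests are two-sided. Wilcoxon drops zero differences and uses the
  exact null for n ≤ 25 without ties (normal approximation with continuity
  and tie corrections otherwise); Mann–Whitney uses the exact null for
  min(n) ≤ 8 without ties. Test engines are scipy.stats; every p-value is
  checked against exhaustive enumeration/permutation oracles on small
  instances in the test suite.

## Problem sizes

The default study configuration is desk-scale, chosen so the whole pipeline
(training both networks included) runs on one CPU in minutes: a 71 × 64 ×
64 grid (the 256 × 256 clinical matrix is supported but unnecessary for the
properties under test), three training subjects giving 10 × 3 × 4 × 2 = 240
pairs of 64 × 64 × 5 blocks per network (one augmentation per original),
and a 5-layer, 8-filter network trained for up to 20 epochs at learning
rate 0.3. The full 10-layer, 68-filter architecture is the model default
and is exercised structurally (parameter counts, shapes, determinism) in
the tests; its training cost is out of desk-scale reach and nothing in the
evaluation depends on it.

## What the synthetic data does and does not show

The phantoms emulate the *statistical* structure that matters for the
method — acquisition-time-dependent Poisson noise, shared-count frame
splitting, resolution/regularization trade-offs, lesions of known uptake —
but not patient anatomy, attenuation, scatter, motion, or the true
iterative reconstruction. Passing tests therefore demonstrate that the
pipeline behaves correctly and that the trained networks reduce liver noise
while preserving lesion quantification *under the emulated physics*; they
do not certify clinical image quality, reader preference, or diagnostic
safety. The human reader study is out of scope: its summary
statistics are used only as fixed reference inputs to the ranking reproduction, and
the hotspot add/subtract review is replaced by the lesion-preservation
check against phantom ground truth.

## Known limitations

- Absolute noise levels are arbitrary (scanner sensitivity is not
  reported for the emulated system); only orderings and paired differences
  are meaningful.
- The β→FWHM map is a surrogate; β values are comparable only within this
  package.
- Desk-scale networks are far smaller than the full architecture; the
  denoising effect is qualitatively right (noise down, SUV stable) but its
  magnitude is not comparable to a full-scale clinical study.
- Multinomial splitting reproduces the marginal and joint count structure
  of interval extraction but not detector-level effects (randoms, scatter,
  dead time).
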