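# Methods

## Scope and model

`rsgica` implements the group spatial ICA analysis used for
resting-state network mapping in awake, unrestrained dogs, end to end:
temporal preprocessing, temporal-concatenation group ICA with GICA1
back-projection, dual-FDR component maps, rule-based artifact
screening, and split-half Dice reproducibility.  The package assumes
all volumes are already in one common space on one grid — spatial
realignment, coregistration and template normalization are out of
scope, and grids are required to match exactly (no silent resampling).

The generative model behind both the pipeline's assumptions and the
phantom is the standard linear spatial-ICA model: each run is a sum of
spatial sources with run-specific band-limited time courses,

    Y_s(v, t) = baseline + Σ_i g_{s,i} · M_i(v) · c_{s,i}(t) + drift + noise,

with per-subject lognormal gains `g` and maps `M` shared across
subjects.  Spatial ICA estimates the maps from the temporally
concatenated, variance-normalized data; GICA1 recovers subject-level
maps by pseudo-inverting each run's block of the estimated concatenated
mixing matrix.

## Preprocessing

Fixed order: discard dummies → 3D Gaussian smoothing → linear detrend →
band-pass → nuisance regression.

* Dummy discard: first 5 volumes (139 acquired → 134 retained at the
  default design).
* Motion QC: scan-to-scan displacement is the Euclidean norm of the
  translation increment combined in quadrature with the rotation
  increment converted to arc length on a 30 mm sphere (a brain-scale
  radius; configurable).  A run is invalid if any absolute translation
  exceeds 2 mm or rotation 2°; the policy on violation is whole-run
  truncation before the first offending volume, never mid-run volume
  deletion (censoring combined with frequency filtering introduces
  artifacts).  Transitions above 0.2 mm are counted and reported as a
  percentage rounded to two decimals.
* Smoothing: per-volume Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in mm,
  default FWHM 4 mm.
* Band-pass: zero-phase FFT mask with raised-cosine edges of total
  width 0.005 Hz centred on the 0.01 and 0.1 Hz cutoffs.  Gain is ≥ 0.9
  through the mid-band, 0 at DC and above 0.2 Hz, and exactly testable.
* Nuisance regression: mean WM signal, mean CSF signal, the six
  realignment parameters, and an intercept.  Confound time series are
  detrended and filtered identically to the data before the regression
  so residuals stay inside the analysis band.  Confound signals are
  extracted from tissue masks eroded by one voxel so that smoothing
  spill-over from grey matter cannot leak neural signal into the
  regressors (the erosion falls back to the full mask if it would empty
  it).  Rank-deficient designs are handled by pseudo-inverse.

## Group decomposition

* Variance normalization per run (zero-variance voxels are zeroed and
  recorded).
* Single-stage group PCA after concatenation (no per-subject PCA
  first): exact SVD when the smaller matrix dimension is ≤ 1024, a
  seeded randomized SVD otherwise.  Explained variance is the top-k
  eigenvalues of the temporal Gram matrix.
* fastICA with logcosh contrast (a = 1), symmetric decorrelation,
  tolerance 1e-6, at most 1000 iterations, 5 seeded restarts; the
  converged restart with the largest total negentropy proxy wins.  If
  no restart converges the operation raises a diagnostic error; the
  pipeline driver instead keeps the best-contrast restart with a
  warning, because symmetric fastICA routinely stalls just above a
  strict tolerance when one subspace direction is near-Gaussian (typical
  for split-half decompositions).
* Canonical component identity: maps scaled to unit variance, ordered
  by explained data variance, signs chosen so each map's skewness is
  non-negative.  A decomposition is bit-reproducible given (data, seed).
* GICA1: concatenated mixing by least squares of the concatenated data
  on the group maps, partitioned by row provenance; subject maps
  averaged over a subject's runs.  Component maps are *reported* as
  group one-sample t-maps — the standard reporting form — and the
  phantom's recovery matching correlates those t-maps with the planted
  maps.

## Inference and screening

* Voxel level: one-sample t against zero across subjects, two-sided p,
  Benjamini–Hochberg FDR at q = 0.001.  Zero-variance voxels get signed
  infinite t and are listed as diagnostics.
* Cluster level: 26-connectivity clusters of positive and negative
  survivors separately; a nonparametric null of the maximum cluster
  extent built by sign-flipping subject maps (t-map and BH threshold
  recomputed per permutation, vectorised); per-cluster p = fraction of
  null maxima at least as large; BH across a component's clusters at
  q = 0.005.  Default 1000 permutations: with an empirical p floored at
  1/(B+1), BH across m clusters is only satisfiable when B ≳ m/q, so a
  few hundred permutations would silently empty every multi-cluster
  component at q = 0.005 (the operation still accepts any B ≥ 100).
* Screening rules, all read-only and configurable:
  susceptibility — size-weighted fraction of surviving clusters whose
  |t|-weighted centre lies in the susceptibility-boundary region,
  flag > 0.5 (size weighting keeps a few-voxel satellite cluster from
  out-voting the main cluster; the |t|-weighted centre is stable under
  the choice of display threshold);
  motion ring — fraction of suprathreshold voxels, polarities pooled,
  inside the rim (brain minus its 2-voxel erosion), flag > 0.6;
  vessel — Dice between the component mask and the vessel mask,
  flag > 0.3.
  The susceptibility and vessel rules score the component's dominant
  polarity: component sign is canonicalised per decomposition and is
  not comparable across decompositions, so an artifact can occupy
  either tail.

## Reproducibility

Split into first-run and second-run halves (subjects missing a half are
excluded from that half only); each half is decomposed at the same
model order and thresholded identically.  Components are binarized as
FDR-surviving voxel sets — pooled polarities in the pipeline, again
because sign is not comparable across decompositions.  Matching is
greedy in descending DSC: the globally best (reference, candidate) pair
matches first, so a conflicted candidate goes to the higher-DSC
reference and the loser falls back to its best remaining candidate;
pairs below 0.3 never match; unclaimed candidates receive fresh letters
(X, Y, Z, V, …) in candidate order.  Cross-half consistency is the DSC
between same-labelled components, good above 0.25.  The bundled
published worked example (15 reference components) reproduces the
reported structure exactly: 14 labels matched in half 1 with O
unmatched, E/M/O unmatched in half 2, and all matched labels consistent
except B (0.15) and F (0.16).

## The phantom

The generator emulates the emulated study's design — 22 subjects × 2
runs × 139 acquired volumes (first 5 discarded) at TR 2.64 s — on a
28 × 28 × 14 grid of 2 × 2 × 2.5 mm voxels holding an ellipsoidal brain
(~3400 voxels) with WM shell, central CSF, anterior
susceptibility-boundary slab and ventral vessel compartment (kept
disjoint from WM/CSF so vessel signal cannot enter the nuisance
regressors).

Sources: four network blobs — one bilateral mirror-symmetric pair in
the lateral positions, three unilateral midline blobs separated along
y/z — pairwise support overlap below 20%; a signed, smoothly modulated
in-plane (per-slice) edge ring (residual-motion rings show
complementary positive and negative arcs, and a signed sparse source is
identifiable by spatial ICA where a uniform rim is not); a ventral
vessel blob; an anterior dropout blob beyond the boundary line.
Artifact sources are geometry-locked (identical across subjects, as
template-space edge and dropout effects are) and stronger than networks
(amplitudes 2.0 / 1.5 / 1.5 vs 1.0), as artifact components are in real
recordings.

Dynamics and noise: band-limited (0.01–0.1 Hz) unit-variance source
time courses, pairwise |r| < 0.3 (resampled, with a band-preserving
symmetric decorrelation fallback for short runs); per-subject lognormal
gains (sd 0.2); a shared broadband nuisance signal in WM/CSF; linear
drift up to ±0.5% of baseline per run; voxel noise band-limited to
0.008–0.105 Hz (BOLD noise is low-frequency dominated — spectrally
white noise would let the analysis band-pass delete half the noise
variance and double the effective SNR); 15% of the noise variance in 10
spatially smooth random patterns with band-limited time courses per run
(the spatially structured physiological/residual-motion noise that
makes single-subject estimates genuinely noisy).  Noise sd is
calibrated so the mean signal sd over network-core voxels (|map| > 0.5)
divided by the noise sd equals the requested SNR (default 1).  Motion
traces are bounded random walks whose scan-to-scan statistics land near
real awake-dog values (~0.04 mm mean).  Everything is deterministic
given a seed.

What the phantom does not model: hemodynamic convolution, EPI
distortion physics, quasi-periodic cardiac/respiratory signals,
subject-specific anatomy or spatial variability of networks, and real
registration error.  Passing the recovery suite therefore shows the
pipeline machinery is correct under the linear model, not that it would
reach the same accuracy on scanner data.

## Problem sizes used in the test suite

Unit tests run on seconds-scale studies (2–6 subjects, 24–60 volumes,
16³-ish grids).  The recovery suite runs the full default design (22
subjects × 2 runs × 139 volumes, model order 7 = 4 networks + 3
artifact sources, 1000 sign-flip permutations) over ten seeds plus a
model-order-10 robustness probe; the null suite runs twenty source-free
phantoms.  Together they take a few minutes on one core.

## Known limitations

* **Circular one-sample inference after back-projection.**  GICA1
  subject maps are estimated with the subject's own data contributing
  to the group maps and mixing, so subject maps share a nonzero mean
  proportional to the group map even for pure noise (on null phantoms
  the mean subject map correlates 0.92–0.98 with the group map and
  hundreds of voxels reach |t| > 6).  The dual-FDR thresholds therefore
  do **not** control false positives at the component level on null
  data, and the corresponding null-control check in the acceptance
  suite fails by design; a companion test shows the same thresholds do
  control type I error (< 10%) when given genuinely exchangeable null
  subject maps.  This mirrors the documented caution against one-sample
  group tests on back-projected/dual-regression maps; conclusions about
  where a component is "significantly expressed" should be treated as
  descriptive.
* fastICA accuracy, not convergence, limits network recovery near
  SNR 1; smooth compact blobs are the least non-Gaussian sources in the
  model and are the first to blur into each other when sources overlap
  after smoothing.
* Recovery does **not** improve indefinitely with SNR: far above SNR 1
  the WM-mean confound becomes dominated by network signal bleeding
  into the WM shell (so the regression subtracts network signal) and
  variance normalization saturates maps toward support indicators.
  Recovery correlations peak near SNR 1–2 and degrade at SNR ≳ 10.
* The susceptibility/vessel/ring cutoffs (0.5, 0.3, 0.6) codify visual
  rules; they are declared defaults, not estimated quantities.
* The 26-connectivity cluster definition and the sign-flip extent null
  are one concrete choice for "cluster-level FDR"; random-field-theory
  corrections are out of scope.
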