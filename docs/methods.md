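# Methods

## The similarity model

A DSC perfusion acquisition samples the T2*-weighted signal `S_v(t)` of every
voxel `v` at interval TR while a gadolinium bolus transits the brain. The
working assumption of temporal similarity mapping is that the bolus-passage
curve is, up to a positive affine transform (local blood volume, coil gain,
baseline offset), *common to all normally perfused tissue*, while
under-perfused tissue receives a bolus that is delayed, dispersed and/or
decreased and therefore has a differently *shaped* curve. Pearson's
product-moment correlation is exactly the statistic that ignores affine
differences and scores shape, so the map

    R(v) = corr(S_v, S_ref)

is ≈ 1 in healthy tissue and low in deficits, with no need for an arterial
input function, deconvolution, or per-patient windowing.

Two reference choices are implemented:

* **Seed mode** (`seed_similarity_map`): `S_ref` is one voxel's series,
  chosen interactively. The map recomputes in ~0.1 s at 80×80×20×80 (a
  single centred matrix-vector product over the mask), fast enough to follow
  a cursor.
* **Automated iterative mode** (`automated_tsp`): `S_ref` starts as the
  unweighted mean series of all brain-mask voxels. The full-brain map is
  computed, the reference pool is re-selected as the voxels with
  R > threshold (default 0.6), the reference is re-averaged, and the map
  recomputed; this refinement is repeated twice by default, and the final
  map is the TSP map. Each refinement re-thresholds the *current full-brain
  map*, not the previous pool intersected with it — the alternative is a
  one-line change in `automated_tsp`. No convergence criterion is added:
  the iteration count is the contract, exposed as `refinement_repeats` for
  experimentation. In practice the pool is stable after the first
  refinement on phantom data because healthy voxels score ≈ 1 and lesion
  voxels ≈ 0 with nothing near the threshold.

Degenerate series (zero temporal variance — masked dropout, padded regions)
have no defined correlation. They are flagged undefined (NaN + validity
mask), excluded from every reference average, and never imputed or
silently set to 0. Full-length series are correlated; no bolus sub-window
is selected (the pre-bolus baseline slightly dilutes contrast but keeps the
method parameter-free; a windowed variant would be a preprocessing step,
not a change to the core).

`segment_lesion` converts a map into a binary deficit: defined voxels with
R < cutoff (default 0.6), grouped at 26-connectivity, discarding clusters
below a minimum volume (default 1 cm³) as noise. Undefined voxels are never
lesion. Empty output is a meaningful "no deficit" result, which is what the
imaging-negative (TIA-like) phantom must produce.

## The digital phantom

`phantom.generate_phantom` builds a 4D series whose defaults mirror a
standard stroke-protocol DSC acquisition: 80×80 in-plane matrix, 20 slices,
80 dynamics, TR = 1 s, TE = 24 ms, voxel 0.9375×0.9375×7 mm³.

* **Kinetics.** Contrast concentration follows a peak-normalised
  gamma-variate, `C(t) = A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)` for t > t0,
  the standard first-pass bolus model, with an optional single
  recirculation pass `f·C(t − d)`. Defaults: t0 = 20 s, α = 3, β = 1.5 s
  (signal minimum ≈ 25 s into the scan), recirculation f = 0.12 at d = 20 s.
* **Signal.** Mono-exponential T2* conversion `S = S0·exp(−k·TE·C)` with
  S0 = 1000 a.u. and k = 0.02 (≈ 38% peak signal drop in healthy tissue,
  typical of 3 T DSC).
* **Healthy heterogeneity.** Per-voxel gain (0.85–1.15) and baseline offset
  (±2% of S0) applied *in signal space*, i.e. a positive affine transform of
  one template curve. This is deliberate: it is the exact regime in which
  the similarity model is error-free, so the noise-free phantom provides an
  analytic fixpoint (map ≡ 1.0) that the pipeline must hit to ~1e-9.
  Passing that test shows the machinery is exact under the model's own
  assumption; it does not show robustness to genuinely heterogeneous
  tissue kinetics (grey/white matter differences, partial volume), which
  the phantom does not simulate.
* **Lesion.** An ellipsoid (default ≈ 10 cm³) whose bolus parameters are
  transformed by the lesion model: arrival + delay_shift, β × dispersion
  factor, A × amplitude factor. Defaults delay 5 s, dispersion ×2,
  amplitude ×0.7 — a moderate deficit whose curve correlates at R ≈ 0.02
  with the healthy template, chosen as a plausible severity rather than
  fitted to any dataset. The identity model (0, 1, 1) reproduces healthy
  tissue exactly.
* **Noise.** Gaussian (default σ = 2% of S0) or Rician (magnitude of two
  Gaussian channels); signals are floored at 0.
* **Structure.** Brain = centred ellipsoid; ventricles = small central
  ellipsoid with a flat 0.6·S0 profile (something for mask exclusion to
  exclude); optional near-zero signal-loss region; background empty.
* **Motion.** Optional per-volume rigid transforms (Euler degrees +
  voxel translations) applied by trilinear resampling.

Everything is a pure function of the spec including its `rng_seed`; specs
round-trip through a YAML config.

## Realignment and masking

Realignment registers every dynamic to volume 0 with a rigid 6-DOF
least-squares intensity fit: a subvoxel phase-correlation translation
initialises a Powell search on 2× block-averaged volumes, refined at full
resolution when the coarse fit finds real motion (near-identity coarse fits
are accepted directly, so motion-free volumes are copied through
bit-identically). This minimal registration is adequate for the small
simulated motions it is tested against (≤ 2 voxels; recovery within 0.25
voxel); it is not a substitute for a production registration suite on
patient data with large rotations or through-plane motion.

The brain mask is built from the first (assumed pre-contrast) dynamic:
Otsu foreground → largest connected component → hole fill; then voxels
below `signal_loss_fraction` (default 0.2) × the median foreground signal
are excluded as susceptibility dropout, and an externally supplied
ventricle mask is subtracted. The 20% fraction is a package choice exposed
in the API/CLI. If the first dynamic's mean differs from the first-3-volume
mean by > 5%, a warning notes it may not be pre-contrast. No tissue
segmentation is attempted in-repo.

## TTP comparator and metrics

TTP = TR × argmin_t S_v(t), ties broken to the earliest dynamic, so raw
values are TR-quantised. Optional isotropic Gaussian smoothing (FWHM in mm)
is applied to the *map* under normalised convolution restricted to the
mask; the default is no smoothing, since any specific kernel choice is
arbitrary. Deconvolution-based MTT/CBF is out of scope by design.

CNR uses the sample (n−1) SD over healthy voxels (configurable `ddof`);
effective CNR = CNR·√N holds as an exact algebraic identity. Overlap
percentages are taken relative to the union of the two masks and partition
it. Bland-Altman limits use the conventional 1.96 factor (configurable).
The volume-correlation p-value comes from the t distribution with n−2
degrees of freedom.

## Numerical and design notes

* Computed correlations are clipped to [−1, 1] to absorb float rounding.
* Affine invariance of a voxel's map value is exact (1e-12) in seed mode;
  in iterative mode the rescaled voxel perturbs the reference mean it
  contributes to, so the value is stable (≲1e-3 at realistic mask sizes)
  rather than bitwise-invariant.
* `segment_lesion` accepts cutoff in [−1, 1]; the closed endpoints are
  valid degenerate cases (−1 → always-empty mask).
* Lesion masks are plain boolean arrays on the series grid (voxel
  dimensions passed explicitly); only the brain mask carries provenance
  labels, since that is where exclusions need auditing.
* Test and example problem sizes: module tests run on a 32×32×10 phantom
  with the same physiology as the full grid; the acceptance checks run on
  the full 80×80×20×80 grid (a full pipeline pass is ~1 s), with 20 seeds
  for the lesion-recovery statistics.

## Known limitations

The phantom's healthy tissue is affinely homogeneous, its lesion is a
single uniform ellipsoid, and its noise is spatially white — all kinder
than patient data, where tissue-class kinetic differences, partial-volume
mixing at lesion borders, and physiological fluctuations will lower healthy
R values and blur the lesion margin. Results on the phantom (Dice ≈ 1,
threshold-sweep spread ≈ 0) should be read as verification of the
implementation under the model's assumptions, not as expected clinical
performance. The TTP comparison is against this package's unsmoothed TTP,
not any vendor implementation.
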