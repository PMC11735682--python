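# Methods

## Signal model

The optical EPSP is modeled as a normalized difference of exponentials,

    w(t) = A · [exp(−(t−t0)/τ_d) − exp(−(t−t0)/τ_r)] / peak,   t ≥ t0,

rendered negative-going (depolarization quenches hVOS fluorescence) and
normalized so the peak magnitude equals the amplitude A exactly. The
analytic peak time is t0 + τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r), verified in
the tests against a dense-grid brute-force minimum. Defaults τ_r = 1 ms,
τ_d = 4 ms give a half-width near 5 ms and a decay-time near 3 ms, the
scales seen in PV-interneuron recordings. This is the standard minimal
EPSP shape; no claim is made about biophysical mechanism.

A synthetic scene renders, per trial,

    F(t) = resting_light · (1 + Σ_cells w_c(t) on the cell's footprint) + ε,

with ε ~ N(0, noise_scale²·resting_light) per pixel and frame — a
shot-noise proxy (SD ∝ √intensity). Footprints are hard discs rasterized
to the nearest pixel (default diameter ≤ 3 pixel pitches, matching a PV
soma at 19 μm / 3 px); sub-pixel area weighting is deliberately not
attempted, keeping recovery tests exact. Onset latency is
`latency_offset + distance × conduction_delay` (defaults 1 ms and
0.015 ms/μm, the wild-type distance-normalized latency scale). Optional
multiplicative trial-to-trial amplitude jitter is off by default so the
noiseless round trip is exact to machine precision. The generator does
not model bleaching, optical point-spread, action potentials, or
correlated (non-white) noise; passing tests therefore certify the
pipeline's arithmetic and decision rules, not its behavior under
photobleaching drift or movement artifacts.

## Preprocessing

Fixed order: trial average → ΔF/F → spatial filter → temporal filter,
recorded in a provenance list and asserted by tests. ΔF/F uses each
pixel's own prestimulus mean (window: stim − 20 ms to stim − 2 ms,
configurable) as the baseline rather than a separate resting-light
exposure — self-contained, and the prestimulus mean is zero by
construction; the resting-light image is kept for noise calibration and
display. Both filters use reflection padding, so DC gain is exactly 1
everywhere including borders. All detection maps and kinetic parameters
are computed on the fully filtered movie.

## ROI detection

Per pixel: amplitude = max negative-going |ΔF/F| in the response window
(stimulus to +50 ms by default); SNR = amplitude / prestimulus RMS of the
filtered trace. Pixels with zero RMS are flagged infinite-SNR and
excluded. Candidates are 4-connected groups of pixels above both an
amplitude cutoff and an SNR cutoff (5).

**Amplitude cutoff.** Default 7 × the median per-pixel baseline RMS. The
maximum of filtered noise over a ~100-frame search window has median
≈ 2.4 × RMS and an extreme-value tail reaching ≈ 6.5 × RMS somewhere in
an 80×80 field, so a multiplier near 3 floods the detector with
single-pixel false candidates; 7 sits above the per-field tail while a
cell at the SNR-5 acceptance floor times the detection-quality floor of
10 still clears it comfortably. Exposed in `RunConfig`.

**k-means SNR exclusion.** Exact 1-D k-means (dynamic programming over
contiguous blocks of the sorted values — globally optimal, deterministic,
no seed) with k = 4 by default, applied to all suprathreshold pixel SNRs;
pixels in clusters whose mean SNR < 5 are removed. Each surviving group
is then reduced to the pixels of its own top SNR level (per-group k-means;
clusters whose mean reaches 80% of the top cluster's mean count as the
same level). This "same SNR level" selection is what keeps ROIs smaller
than somata: σ = 1 smoothing bleeds every bright soma into a fringe of
lower-SNR pixels which would otherwise inflate the group past the 3-px /
360 μm² size rule. Without level merging, k-means fragments
noise-jittered near-equal core pixels and ROIs collapse to single
off-center pixels. Detected ROIs average 2.7 pixels on the synthetic
benchmark, matching the ~2.7–2.8 px of real recordings.

**Exclusions** (first rule to fire wins; every candidate carries exactly
one reason, and accepted + rejected = candidates):

* vertex adjacency — two candidate groups in 8-neighbor contact (judged
  at their full pre-shrink extent, the conservative reading) are *both*
  removed;
* size — bounding box > 3 px in either dimension, or area > 360 μm²;
* direct stimulation — centroid < 45 μm from the electrode or latency
  < 1 ms (both strict: exactly 45 μm / 1.0 ms survive);
* noisy waveform — half-maximum crossings cannot be located;
* amplitude outliers — single pass over the pooled dataset (genotypes
  pooled; the stratification is not specified in the source data),
  one-sided: amplitude > mean + 3 sample SD.

## EPSP metrology

The peak is the global negative extremum in the response window (robust
to slow after-waves; the trailing half-maximum search may extend past the
window). Half-maximum crossing times are linearly interpolated between
the bracketing samples, giving sub-frame resolution; latency, rise-time,
decay-time and half-width all derive from the same three time points, so
half-width = rise + decay holds to machine precision identically.
Amplitudes are reported as positive % ΔF/F magnitudes.

Known estimator property: picking the most negative sample of a noisy
trace inflates amplitude by roughly one baseline RMS (relative bias
≈ 1/SNR), and the trailing crossing on the shallow decay limb carries a
timing error ≈ 2 τ_d/SNR. These are intrinsic to the extremum/half-max
definitions, not implementation artifacts; the recovery benchmark reports
them per parameter.

## Benchmarks

The recovery benchmark draws 20 scenes × 5 cells with per-cell detection
SNR uniform on [10, 26] — the accepted-cell SNR span of real recordings
floored at 10 — and scores detection (centroid within 1 px of a true
center) and parameter recovery against a dense-grid (1 μs) brute-force
oracle of the filtered true waveform, with amplitudes corrected by the
kernel-derived spatial × temporal attenuation. Typical results: recall
and precision 0.96–0.98, pooled timing-error median ≈ 0.28 ms,
conduction-delay slope recovered within ~1%.

The statistical benchmarks simulate cohorts directly at the unit level
(55 vs 54 layer-average units; unit SD = printed SE × √n). The bootstrap
type-I benchmark places the common null mean far from zero because the
cohort simulator truncates amplitudes at 0 and, with unequal SDs, a mean
near the boundary would acquire a spurious genotype difference from
truncation alone. Power counts a cohort as detecting the genotype effect
when either the amplitude test (bootstrap branch) or the
distance-normalized-latency test (log-scale F) rejects at α = 0.05 —
the cohort-level reading of an effect that manifests in several
parameters.

## Statistics implementation notes

* Scales: amplitude, half-width, rise-time on the identity scale;
  distance-normalized latency and decay-time on the log scale (their
  distributions are log-normal); the transform is recorded in every
  result.
* Levene uses center = mean; Welch t uses Satterthwaite df.
* The bootstrap ANOVA tests one model term by F = ((RSS_restricted −
  RSS_full)/df₁)/(RSS_full/df₂) with treatment-coded factorial designs;
  the null fit supplies means, design cells supply variances (each cell
  needs ≥ 2 units), p = (1 + #{F_b ≥ F_obs})/(B + 1). B defaults to
  10,000 and a seed is required. Simulation is vectorized (hat-matrix ×
  simulation-matrix products), so 500 calibration replicates at B = 1,000
  run in seconds.
* Tukey HSD runs over the crossed design-cell labels.
* The IQR-based outlier convention affects plotting only; all points
  enter every test.

## Degenerate inputs and tie-breaks

Constant traces and flat windows raise extraction errors rather than
emitting zero-filled records; constant samples raise in the normality
screen; empty design cells raise listing the missing combinations; a
centroid exactly on a layer boundary is assigned to the band above
(toward the pia); k-means ties are resolved by the deterministic DP order;
groups split by pixel pruning keep their highest-mean-SNR connected
component.

## Problem sizes

Default benchmark sizes — 20 scenes × 5 cells, 500 calibration
replicates at B = 1,000, 200 power cohorts — were chosen so the full
self-test completes in well under a minute on one CPU while keeping
Monte-Carlo error a few percent; all are parameters of the benchmark
functions.

## Known limitations

Layer boundaries are inputs (visual identification is out of scope); no
motion/bleach correction; no demixing of overlapping somata or converging
processes (mirroring the acknowledged limitation of the ROI-selection
procedure); the 3-SD outlier pass is single-shot, not iterative; the
synthetic noise is white and Gaussian.
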