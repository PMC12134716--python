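# Methods

This note documents the models, algorithms, parameter choices, and numerical
conventions behind `tfparam`, and what the synthetic-data tests do and do not
establish about real EEG.

## Signal model

Each epoch (trial × channel voltage series, −750 to +1250 ms at 250 Hz by
default) is modeled as the sum of four components:

* **Aperiodic background.** Noise whose one-sided power spectral density is
  `10^b · f^(−χ)` (offset `b` in log₁₀ power, exponent `χ` ≥ 0). The
  generator synthesizes it in the frequency domain: a complex Gaussian
  spectrum is shaped by `√S(f)` and inverse-transformed, so the expected
  Welch periodogram equals the target exactly at every positive frequency
  and the DC bin is zero (exactly zero-mean output). Event-locked broadband
  power changes are realized as a smooth multiplicative gain
  `10^(s(t)/2)` on this background, where `s(t)` is the designed offset time
  course (raised-cosine ramps, 100 ms); a pure gain adds `s(t)` to the
  offset while leaving the exponent untouched, which is the cleanest way to
  emulate broadband condition differences.
* **Oscillatory bursts.** Gaussian-enveloped sinusoids
  (`a · exp(−(t−t₀)²/2σ_t²) · sin(2πf(t−t₀)+φ)`) with phase `φ` drawn
  uniformly per trial, so burst power is *induced* and survives evoked
  subtraction. Sustained oscillations (alpha, beta) run through the whole
  epoch with a smooth post-stimulus amplitude suppression
  (desynchronization).
* **Evoked waveform.** A deterministic Gaussian-windowed sinusoid added with
  identical timing and sign to every trial — the only phase-locked content.
* **Behavior.** One score per subject,
  `intercept + slope · (subject aperiodic offset) + N(0, σ)`, clipped to
  [0, 1] when emulating a choice proportion. The defaults
  (slope 0.4, subject-offset SD 0.25, noise SD 0.1732) give a population
  coupling of r = 0.5 with ~1% of subjects affected by clipping.

Channel structure is limited to per-channel amplitude weights (Gaussian
profiles in chord distance on the unit sphere); there is no forward model,
no channel covariance, and no artifact simulation. Positions come from the
standard 10-20 montage (32-channel subset), recentred on the best-fit
sphere and normalized to unit radius.

Determinism: every random draw descends from `SeedSequence([seed,
subject_index])` in a documented order, so identical designs reproduce
cohorts bit-for-bit, and the per-trial component breakdown is available for
exact additivity checks.

## Time-frequency transform

Hann-tapered STFT, 500-ms (125-sample) windows, 80% overlap (hop = 25
samples = 100 ms), FFT zero-padded to 250 points for 1-Hz spacing, output
restricted to 1–30 Hz. Only fully supported windows are produced, trimming
half a window from each epoch edge; frame centers are
`epoch_start + window/2 + k·hop`, giving −500…+1000 ms for the default
epoch. The Rayleigh resolution of the window is 2 Hz, so the 1-Hz bin exists
only through zero-padding; oscillations below 2 Hz are under-resolved and
delta-band parameterization results should be interpreted with that caveat.

Coefficients are scaled by `2/Σw`, so an on-bin sinusoid of amplitude A
yields coefficient magnitude A regardless of window length. The convention
is arbitrary but fixed; every downstream statistic (log-domain fits,
correlations, t-tests) is invariant to it. One measurable consequence: the
STFT-power "offset" differs from the generator's PSD offset by the constant
`log10(2 fs Σw² / (Σw)²)` (≈ 0.78 under the defaults). Offset *differences*
— the quantities the statistics act on — are unaffected.

Evoked power is removed by subtracting the across-trial mean complex
coefficient from every trial; the residual trial mean is zero to machine
precision. Intertrial phase coherence (magnitude of the across-trial mean
unit phasor; zero-magnitude coefficients are excluded with a logged count)
verifies removal. Note a subtlety: for n *independent* uniform-phase trials
the ITC chance floor is `√(π/4n)` (0.044 at n = 400), but mean subtraction
constrains the residuals to sum to zero, which pushes the expected ITC
*below* that floor (≈ 0.021 at n = 400). The floor is therefore an upper
bound for post-subtraction ITC, which is how the tests treat it.

Condition averages are arithmetic means of single-trial power (µV²,
linear). Percent-change baselining uses the −400 to −200 ms frames by
default — the latest window whose 500-ms support ends before the stimulus —
and is configurable. Baselined power is never parameterized; it exists only
for correlation analyses. Trials exceeding ±500 µV (configurable) are
rejected before transforming. A zero-phase second-order-sections 1–30 Hz
Butterworth bandpass is provided for real recordings; synthetic data are
band-limited by construction and skip it.

## Spectral parameterization

Each (channel, frame) spectrum is fit in log₁₀ power over 1–30 Hz:

1. **Robust aperiodic fit.** Ordinary least-squares line in
   (log₁₀ f, log₁₀ P); then points whose positive residual exceeds the 2.5th
   percentile of positive residuals are masked and the line refit. This
   anchors the aperiodic estimate to the spectrum's lower envelope, away
   from peaks. Fixed (no-knee) mode only.
2. **Iterative peak seeding** on the flattened spectrum: take the global
   maximum (ties break toward the lower frequency); stop when its height
   falls below 2.0 × SD of the current flattened spectrum (the published
   default), or below an optional absolute height, or at an optional peak
   cap. The seed center is refined by a 3-point parabolic interpolation of
   the maximum (sub-bin accuracy keeps the subtracted seed from leaving
   flank residue when the true center is off-grid); the seed width comes
   from the shorter half-height side (robust to overlapping peaks), clipped
   to the width bounds. Seeds within one seeded SD of a band edge are
   discarded. Each seed is subtracted before the next search.
3. **Joint refinement.** All seeds are refit together by bounded
   least squares with analytic Gaussian gradients (centers within ±2 seed
   SDs, amplitudes ≥ 0, SDs within bounds); refined peaks whose center left
   the band are dropped.
4. **Final aperiodic refit** on the peak-removed log spectrum, and model
   assembly. R² is the squared Pearson correlation between modeled and
   observed log power.

Peak widths are reported as `2σ` (the reference tool's bandwidth
convention), so the default width bounds are the familiar (0.5, 12) Hz.
Defaults: threshold 2.0 SD, no peak cap, no minimum height, robust
percentile 2.5, band 1–30 Hz.

**Known behavior at the 2.0-SD default.** The maximum of ~30 spectral noise
values exceeds 2 SD with appreciable probability at *any* noise level (the
trigger rate is scale-invariant), and the lower-envelope robust fit raises
all flattened heights, so small noise-scale peaks are fit in a large
fraction of peak-free spectra. This matches the reference implementation
with identical settings and is why downstream inference relies on condition
contrasts and across-subject statistics, where such overfitting cancels,
rather than on single-fit peak lists. The tests assert the contrast form:
injected theta mass appears only post-stimulus, and baseline-frame theta
amplitudes stay at the noise scale.

Time-resolved operation applies the fit independently to every STFT frame —
no temporal smoothing or peak clustering across frames (clustering is
inappropriate for event-related data, where oscillatory changes are
expected at stimulus latencies). Failed fits are recorded as NaN with a
logged diagnostic; the pipeline zero-fills them (they are rare —
none occur on the default synthetic cohorts).

"Oscillatory power" is the fitted Gaussian sum and "aperiodic power" the
fitted line, both in log₁₀ units on the analysis grid; they sum (with the
residual) to log total power. The unit flag on every surface records this
choice. One consequence worth remembering: because peak amplitude is
measured *above* the background in log units, a subject with a higher
aperiodic offset shows smaller oscillatory amplitudes for the same µV
oscillation, so oscillatory surfaces inherit a negative across-subject
coupling to the aperiodic offset. That is a property of log-domain
parameterization, not an artifact of this implementation.

## TFCE permutation statistics

Channel adjacency: channels are neighbors when their chord distance on the
unit sphere is below a threshold (default 0.6 for the 32-channel montage —
the smallest round value leaving no channel isolated; mean ≈ 3.5
neighbors). Map connectivity adds ±1 frequency bin and ±1 frame. Isolated
channels produce a named warning.

Enhancement: for each sign separately,
`enhanced(p) = Σ_h extent(p,h)^E · h^H · dh` over thresholds
`h = dh, 2dh, … ≤ |stat(p)|`, with E = 0.5, H = 2 (the published
recommendation for EEG) and `dh = max|stat|/100` by default, computed from
the observed map and reused for the null. The production implementation is
a numba union-find sweep over thresholds (activate nodes in descending
order, union with active neighbors, accumulate `size^E · h^H · dh`); an
independent scipy connected-components implementation is kept as a test
oracle and agrees to 1e-15. An isolated suprathreshold point of height h
reproduces the closed form h³/3 as dh → 0.

Paired tests use the one-sample t over subject difference maps with a
sign-flip null (points with zero variance get t = 0; sign flips leave Σd²
invariant, so only the mean is recomputed per permutation). For n ≤ 12 all
2ⁿ sign patterns are enumerated — the identity pattern is included, so
`p = #{null max ≥ obs}/2ⁿ` is exact and never zero. Sampled nulls use
`p = (1 + #{≥})/(B + 1)`. Correlation tests use the Pearson r map with the
behavioral vector permuted; surface-pair correlation tests permute the
subject pairing of the second surface stack. The null maximum of |enhanced|
is always taken over the whole map; band-restricted reporting (delta 1–3,
theta 4–8, alpha 9–14, beta 15–30 Hz — a partition of the 1–30 Hz grid)
happens after correction, never before. Each report row gives the signed
statistic at the band's max-|enhanced| point with its corrected p
(significance cutoff 0.05).

Fisher's z comparison of two correlations uses the independent-samples
formula `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3))` — matching the
study procedure even though compared correlations share the total-power
surface — with Steiger's dependent-correlation variant available separately
as the statistically stricter alternative (it requires the correlation
between the two compared surfaces). Power for a two-sided paired t-test
uses the noncentral t with df = n−1 and noncentrality d√n (normal limit as
a large-df fallback).

## Pipeline

`run_analysis(config)` executes simulate/load → reject → STFT → evoked
subtraction (toggleable, default on; the off position reproduces the
no-subtraction sensitivity analysis) → condition average → parameterize →
percent-change baseline of total power → paired condition tests on
oscillatory and aperiodic surfaces → across-subject correlations of total
(raw and baselined) power with oscillatory and aperiodic surfaces per
condition, with Fisher-z comparison maps → behavior correlations. All
correlations are across subjects, per condition and map point. Per-test
seeds derive from the config seed through a `SeedSequence`, so a config
determines every number in the output; regenerating a report from the same
results is byte-identical. Cohorts and surfaces round-trip through an HDF5
container (one group per subject; surfaces under `/surfaces/<kind>/...`),
and configs through YAML.

## Problem sizes used in tests and the acceptance script

Chosen to put estimator noise well inside the stated tolerances on one CPU:

* Exponent/peak-center recovery: 100 seeds of 120-s simulated series
  (Welch, 500-sample segments). At this duration the per-fit exponent error
  SD is ≈ 0.02, so the 0.1 tolerance holds for every seed, not just on
  average.
* Offset-step recovery: one subject, 2 channels × 600 trials, step read
  from frames whose full 500-ms support lies inside the shifted interval;
  per-frame offset noise at typical trial counts (~0.04 log₁₀) would be
  marginal against the 0.05 tolerance, hence the larger average.
* Evoked-removal check: 400 trials (ITC floor 0.044, point SD 0.023).
* TFCE validity: 200 null cohorts of 8 subjects, 6 × 10 × 8 maps,
  exhaustive 256-pattern nulls.
* End-to-end: 20 subjects × 2 conditions × 100 trials × 32 channels,
  500 permutations.

## What the synthetic tests do not show

The generator omits spatially correlated noise, volume conduction,
artifacts, non-sinusoidal waveform shape, aperiodic "knees", and
trial-to-trial amplitude variability beyond phase randomization. Passing
tests therefore establish the correctness of the numerics and the validity
of the statistics under the stated model, not robustness to real-EEG
pathologies. Known limitations carried over from the method itself:
single-trial parameterization is not offered (condition averages only),
knee fitting is out of scope, sub-2-Hz oscillations are under-resolved, and
peak lists from individual fits overfit noise at the default threshold (see
above).
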