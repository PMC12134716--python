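# tfparam

Time-resolved spectral parameterization of event-related EEG, with
threshold-free cluster enhancement (TFCE) permutation statistics and a
synthetic-cohort generator that makes every stage testable against known
ground truth.

## The problem

Event-related EEG analyses usually express post-stimulus power change
relative to a pre-stimulus baseline and interpret the result as oscillatory
dynamics (mediofrontal theta synchronization, posterior alpha and central
beta desynchronization). But EEG power spectra are dominated by an
**aperiodic** 1/f-like background,

```
log10 P(f) = b − χ · log10 f  +  Σ_k a_k · exp(−(f − c_k)² / (2 σ_k²))
```

with offset `b`, exponent `χ`, and Gaussian oscillatory peaks
(center `c_k` Hz, amplitude `a_k` log₁₀-power above the background, width
`2σ_k` Hz). If the aperiodic background itself shifts after a stimulus,
baseline correction cannot remove it, and "oscillatory" effects may be
aperiodic in origin. This package separates the two contributions frame by
frame:

1. **Transform** — single-trial short-time Fourier spectrograms (500-ms /
   125-sample Hann windows, 80% overlap, zero-padded to 1-Hz spacing; from
   −750…+1250 ms epochs at 250 Hz this yields 1–30 Hz × −500…+1000 ms in
   100-ms frames).
2. **Evoked removal** — the across-trial mean complex coefficient is
   subtracted from every trial, removing phase-locked (evoked) power;
   intertrial phase coherence (ITC) verifies the removal.
3. **Parameterize** — each condition-averaged (channel, frame) spectrum is
   decomposed into the aperiodic line plus Gaussian peaks (robust aperiodic
   fit → iterative peak seeding → joint bounded least squares → aperiodic
   refit), giving total / aperiodic / oscillatory power surfaces and per-fit
   R².
4. **Test** — two-sided TFCE (`extent^E · height^H` integrated over
   thresholds, E=0.5, H=2) with max-statistic permutation null over the full
   channel × frequency × time map: paired condition tests (sign-flip null,
   exhaustive for small n), across-subject correlation tests (shuffle null),
   Fisher-z comparisons of correlation magnitudes, and noncentral-t power
   analysis.

The synthetic generator (`tfparam.synthgen`) builds cohorts from documented
additive parts — 1/f background with event-locked broadband gain, induced
theta bursts, suppressed sustained alpha/beta, a phase-locked evoked
waveform, and a behavioral score coupled to each subject's aperiodic offset
— so recovery of every quantity can be checked exactly.

## Worked example

```python
from tfparam import AnalysisConfig, run_analysis
from tfparam.synthgen import default_design

cfg = AnalysisConfig(
    design=default_design(n_subjects=12, n_trials_per_condition=60, seed=0),
    n_permutations=500, seed=0,
    run_surface_correlations=False, run_behavior_correlations=False)
res = run_analysis(cfg)

print(f"mean model R^2: {res.mean_r_squared:.3f}")
print(f"max ITC before evoked subtraction: {res.itc_max_pre:.2f}")
print(f"max ITC after evoked subtraction:  {res.itc_max_post:.2f}")
print(res.table[res.table.significant].to_string(index=False))
```

prints

```
mean model R^2: 0.986
max ITC before evoked subtraction: 0.99
max ITC after evoked subtraction:  0.23
                      test  band  statistic  channel  frequency_hz  time_ms  p_corrected  significant
  condition_diff_aperiodic alpha  17.799306       17          14.0    300.0     0.000488         True
  condition_diff_aperiodic  beta  17.990636       17          15.0    300.0     0.000488         True
  condition_diff_aperiodic delta  11.160917       17           3.0    500.0     0.000488         True
  condition_diff_aperiodic theta  16.625465       18           8.0    200.0     0.000488         True
condition_diff_oscillatory alpha  23.958249        4           9.0    400.0     0.000488         True
condition_diff_oscillatory  beta -49.780716       13          20.0    200.0     0.000488         True
condition_diff_oscillatory delta  21.894172        4           3.0    400.0     0.000488         True
condition_diff_oscillatory theta  50.152130        4           7.0    400.0     0.000488         True
```

Reading the output: model fits are excellent (R² ≈ 0.99); the phase-locked
evoked component produces near-perfect phase locking (ITC 0.99) that
collapses after complex-domain subtraction; the injected incongruent-minus-
congruent theta burst difference appears as a large positive oscillatory
cluster at 7 Hz / +400 ms on a frontal-midline channel (channel 4 = Fz), and
the injected broadband aperiodic gain difference appears as positive
aperiodic clusters in **every** band over central sensors (channels 17–18),
exactly as designed. Each `p_corrected` is familywise-corrected over the
whole 32 × 30 × 16 map by the max-statistic permutation null.

A thin CLI mirrors the stages:

```bash
tfparam simulate --subjects 20 --trials 100 --seed 1 --out cohort.h5
tfparam tfr --container cohort.h5 --window-ms 500 --overlap 0.8
tfparam parameterize --container cohort.h5 --peak-width 0.5 12 --threshold-sd 2.0
tfparam stats --container cohort.h5 --test paired --kind oscillatory --permutations 1000 --seed 7
tfparam run --out results/          # full pipeline under one config
```

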