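# Methods

`vrcpt` models and analyzes a sustained-attention experiment: a Go/No-go
continuous performance test performed in a virtual classroom, once without
(N-D) and once with (Y-D) visual distractors, with 32-channel EEG recorded
throughout.  Because no raw data are deposited for this design, the package
pairs every analysis stage with a synthetic-cohort generator whose defaults
are calibrated to the published group-level results, so that the entire
chain — filtering, epoching, P300 peak measurement, band power, entropy,
paired statistics — can be validated by parameter recovery.

## Task and cohort model

A block presents 100 target and 50 non-target stimuli in uniformly shuffled
order; each stimulus lasts 500 ms with a 1000 ms inter-stimulus interval,
i.e. a fixed 1500 ms onset-to-onset grid.  A cohort is 66 participants × 2
conditions.  Behavioral summaries per participant × condition are drawn as

* commission, omission, multipress counts ~ Poisson with condition means
  (1.33/3.15, 0.14/1.18, 0.15/0.56 for N-D/Y-D) — the simplest
  non-negative count family matching the published means, which report no
  dispersions;
* mean reaction time ~ Normal(0.367 s / 0.368 s, SD 0.03 s) truncated at
  0.05 s.  The 1 ms condition difference at SD 0.03 makes the reaction-time
  contrast a true (practical) null, mirroring the published non-effect.

## Signal model

Each channel of a recording is the sum of:

1. **1/f background** — spectrally shaped Gaussian noise with power ∝ 1/f,
   SD 2 µV;
2. **narrow-band activity** — Gaussian noise band-limited to δ (0.5–4 Hz),
   θ (4–8), α (8–12), β (12–30), at 0.7/0.6/0.7/0.4 µV RMS.  Narrow-band
   *noise* rather than pure sinusoids is used deliberately: a sinusoid
   whose frequency is near a multiple of the 1/1.5 s stimulus rate would be
   phase-locked across epochs and survive averaging, contaminating ERP
   peaks;
3. **white noise**, 0.8 µV SD; under Y-D an additional white admixture of
   25% of the total background SD is added on frontal, central and parietal
   channels only.  This implements the distraction effect the entropy
   analyses target and leaves occipital/temporal channels as a built-in
   negative control;
4. **evoked P300** — after every target onset, a positive Gaussian bump of
   120 ms FWHM.  A participant's latency is drawn once per condition from
   Normal(published electrode mean, 20 ms); single trials jitter around it
   with SD 25 ms.  Amplitudes are drawn from Normal(published electrode
   mean, published electrode SD where available, else 0.5 µV).

Total background is ≈2.5 µV RMS — clean compared with raw scalp EEG.  This
is a calibration choice, not a realism claim: with 150 target epochs the
per-participant average retains ≈0.2 µV residual noise, small enough that
peak-amplitude recovery is meaningful at the ±0.2 µV level used in
validation.  Recovery tolerances therefore certify the correctness of the
measurement chain, not its robustness to realistic single-trial SNR.
Note also that a windowed maximum is a biased estimator under residual
noise: picking the largest sample in the search window adds a small
positive amplitude offset (up to ≈0.1 µV at the calibrated SNR, largest at
the lowest-amplitude electrode, Oz).  Recovery is therefore asserted at
the calibration bands (±5 ms, ±0.2 µV) rather than at a pure 2-SE radius,
which would presume an unbiased estimator.

**Amplitude calibration.** The configured amplitude is defined as the
*measured* average peak.  Two deterministic attenuations are
pre-compensated at generation time: trial-latency jitter smears the average
waveform (peak gain s/√(s²+σⱼ²) for bump width s), and the zero-phase
0.5–30 Hz Butterworth chain plus baseline correction removes a further ≈2%
(computed once on a noiseless bump train and cached).  Without the
compensation the recovered group means would sit ≈10% + 2% below their
targets by construction.

Sampling rate defaults to 1000 Hz; 250 Hz is supported for fast cohorts.
Recordings are written as 16-bit EDF (physical unit µV) with tab-separated
event files; reading goes through MNE's EDF reader.

## Preprocessing

4th-order Butterworth band-pass 0.5–30 Hz applied forward-backward
(zero-phase, protecting latencies); epochs of [−200, +800) ms around target
onsets; baseline correction by the mean of [−200, 0) ms; peak-to-peak
rejection at 150 µV on analysis channels.  The rejection rule is the
package's reproducible stand-in for manual independent-component screening,
which cannot be automated faithfully; Cohen's kappa (the agreement metric
used for such screening) is provided as a statistics utility.  Epochs whose
window leaves the recording are dropped and logged, so
events = epochs + dropped.

## Feature extraction

**P300.** Features are measured per participant (not on the grand average)
because the downstream contrasts are paired with df = n−1.  Latency and
amplitude are the maximum of the participant's average waveform in a
250–500 ms search window (covering all published latencies,
327.9–382.0 ms), earliest sample on ties.  A global-maximum rule (no
local-peak requirement) is deterministic and robust on noisy averages.

**Band power.** Welch/STFT with 200 ms Hann windows, 50% overlap, windows
zero-padded to a ≈1 Hz grid (a raw 200 ms window has 5 Hz bins and would
leave the delta band empty).  Band power is the mean one-sided PSD over the
half-open band [low, high).  Note the 200 ms Hann mainlobe spans ±10 Hz:
adjacent-band leakage is physical at this window length, so narrow-band
contrasts are qualitative.

**Entropy.** SampEn(m=2, r=0.25·SD) and FuzzyEn(m=2, r=0.2·SD, n=2) on the
post-stimulus 0–800 ms segment of every epoch, with r set per epoch per
channel from that segment's own SD, then averaged per participant ×
condition × electrode (natural log; no cross-channel normalization).
Estimator conventions: templates i, j over 1..N−m at both lengths,
self-matches excluded, per-template denominator N−m−1, strict Chebyshev
criterion d < r (SampEn); local-mean-removed embeddings and membership
exp(−dⁿ/r) (FuzzyEn).  Epochs with no length-m+1 matches make SampEn
undefined; they are excluded from the participant mean and counted, rather
than clipped to an arbitrary cap.  Region values are unweighted electrode
means within lobe per participant.

Two properties worth noting: FuzzyEn with n=2 is *not* invariant to
amplitude rescaling even with SD-relative r (the membership argument dⁿ/r
scales as aⁿ⁻¹); and finite-sample SampEn is not exactly monotone in r.
The tests assert the properties that actually hold (SampEn scale
invariance; FuzzyEn monotonicity in r; decade-scale SampEn decrease).

## Statistics

Paired contrasts screen the differences with Shapiro–Wilk at α=0.05 (an
automated stand-in for visual Q-Q inspection) and use a paired t-test when
normal-looking, otherwise the Wilcoxon signed-rank test — the paired-design
analogue of the rank test (an unpaired rank test would discard the
pairing).  Confidence intervals are bias-corrected percentile bootstrap
(10,000 resamples by default, seeded).  Families of contrasts (electrodes,
region × metric) are Benjamini–Hochberg adjusted and reported alongside raw
p-values.  The a-priori sample size for a two-tailed paired t-test uses the
noncentral t distribution (dz=0.5, α=0.05, power 0.95 → n=54).

## Validation design and problem sizes

* **P300 recovery**: 66 participants, 6 midline electrodes, 150 target
  epochs/condition at 1000 Hz, full chain; group means must land within
  ±5 ms (≈2 SE at the 20 ms between-participant SD) and ±0.2/±0.3 µV of
  the calibrated means.  One cohort takes ≈1 minute on one CPU.
* **Entropy regional pattern**: the validation cohorts hold evoked
  parameters identical across conditions, so the *only* condition
  difference is the broadband admixture — the correct control, since the
  calibrated occipital amplitude difference would otherwise leak a
  systematic occipital entropy effect and defeat the negative control.
  Ten seeds × 66 participants × all 30 analysis electrodes × 16 target
  epochs at 250 Hz; region averaging over full lobar electrode sets is
  what powers the paired tests (a per-recording noise floor makes
  epoch-count scaling saturate).  Entropy kernels are numba-compiled with
  an exactly-matching numpy fallback.
* **Estimator correctness**: brute-force oracle agreement to 1e-10 on
  randomized series (N ≤ 200), the i.i.d. Gaussian closed form
  −ln(2Φ(r/σ√2)−1) at N=5000, and constant-series edge cases.
* **Bootstrap coverage**: 93–97% empirical coverage of a Normal mean over
  500 replications (n=100).

## Known limitations

The generator emulates group-level statistical structure, not
electrophysiology: no artifacts with ICA-separable topographies, no
participant-level entropy traits (conditions differ only through the
admixture), no eye/muscle morphology, volume conduction or cross-channel
correlation (channels are independent), and a background two to ten times
cleaner than raw scalp EEG.  Passing recovery tests therefore demonstrates
the analysis chain is correct and unbiased at calibrated SNR; it does not
certify performance on real recordings.  The reaction-time null is a
design choice inherited from the published means, not an emergent effect.
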