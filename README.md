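# vrcpt

Synthetic cohorts and analysis pipeline for a VR classroom sustained-
attention experiment: a Go/No-go continuous performance test performed
with and without visual distractors (conditions N-D / Y-D) while 32-channel
EEG is recorded.

The package is for researchers who want a fully reproducible, testable
version of this analysis chain — behavioral error scoring, ERP-P300
latency/amplitude extraction, STFT band power, and nonlinear complexity
(sample and fuzzy entropy) with paired condition statistics — together with
a calibrated generator that stands in for the unavailable raw data.

## What it computes

* **Behavior**: commission/omission/multipress counts and mean reaction
  time per participant × condition, contrasted pairwise.
* **P300**: zero-phase 0.5–30 Hz band-pass, −200..800 ms epochs, baseline
  correction over [−200, 0) ms, 150 µV peak-to-peak rejection,
  per-participant average waveforms, peak amplitude (µV) and latency (ms)
  as the maximum in a 250–500 ms window.
* **Band power**: Hann-window STFT (200 ms, 50% overlap); mean PSD over
  δ 0.5–4, θ 4–8, α 8–12, β 12–30 Hz, per electrode and scalp region.
* **Entropy**: per-epoch post-stimulus SampEn(m=2, r=0.25·SD) and
  FuzzyEn(m=2, r=0.2·SD, n=2),

      SampEn = −ln(A(r)/B(r)),   FuzzyEn = ln Φᵐ − ln Φᵐ⁺¹,

  with Chebyshev distances, self-matches excluded, and exponential
  membership exp(−dⁿ/r) for FuzzyEn; averaged per participant × condition
  × electrode and aggregated to frontal/central/parietal/occipital/temporal
  regions.
* **Statistics**: paired t or Wilcoxon signed-rank after Shapiro–Wilk
  screening, bias-corrected bootstrap CIs (10,000 resamples),
  Benjamini–Hochberg adjustment, noncentral-t sample-size computation,
  Cohen's kappa.

The synthetic generator (`vrcpt.synth`) emulates the task's event
structure (blocks of 100 target + 50 non-target stimuli at 1500 ms
spacing), condition-calibrated P300 parameters and behavioral
distributions, 1/f + narrow-band + white background EEG, and a regional
broadband-complexity increase under distraction.  See `docs/methods.md`
for the model and its limitations.

## Worked example

```bash
python analysis/02_behavioral_contrasts.py --seed 0
```

```
  variable  mean_nd  mean_yd                 test  statistic  p_value  ci_low  ci_high
commission   1.4091   3.1667             paired_t     6.0328   0.0000  1.1667   2.3030
  omission   0.0758   1.3636 wilcoxon_signed_rank    31.0000   0.0000  1.0000   1.5606
multipress   0.1061   0.5000 wilcoxon_signed_rank    60.0000   0.0003  0.1970   0.5758
   mean_rt   0.3677   0.3683             paired_t     0.0982   0.9221 -0.0095   0.0104

significant at p < 0.05: commission, omission, multipress
```

A 66-participant cohort shows the expected pattern: all three error counts
rise significantly under visual distraction (e.g. commission 1.41 → 3.17
errors, bootstrap 95% CI of the increase [1.17, 2.30]) while mean reaction
time does not change (0.368 s vs 0.368 s, p = 0.92).

The other drivers follow the same shape — `analysis/01_simulate_cohort.py`
writes a desk-scale EDF cohort, `03_erp_p300.py` recovers P300
latency/amplitude per electrode and contrasts conditions,
`04_band_power.py` produces the regional band-power table (delta-dominant
topography), `05_entropy_contrasts.py` shows the frontal/central/parietal
entropy increase under distraction with occipital/temporal as negative
controls.  Everything is also available as a CLI:

```bash
vrcpt synth --out cohort/ --participants 4 --seed 0
vrcpt run --config myrun.yaml
vrcpt sample-size --effect 0.5 --power 0.95   # -> minimal n = 54
```

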