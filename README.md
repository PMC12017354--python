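# narrafnirs

Event-locked prefrontal fNIRS analysis of trauma narration, with a
calibrated synthetic-cohort generator.

## The problem

When people with post-traumatic stress disorder (PTSD) narrate their
traumatic experience, they use negative emotional vocabulary more often
than trauma-exposed controls (TEC), and their prefrontal hemodynamics
behave differently around those words: controls show a delayed
rise-and-fall oxygenated-hemoglobin (HbO) response at a left anterior
medial prefrontal channel (latency ≈ 3.8 s after word onset, peak
≈ 3.7 s later), while patients show a sustained, plateau-like elevation
with no apparent latency.  Testing that claim requires stitching
together three pipelines — timed speech transcripts, frame-level
prosody, and 48-channel continuous-wave fNIRS — and event-locking the
neural signal to word onsets.

`narrafnirs` implements that full chain for researchers working on
speech-based biomarkers and naturalistic fNIRS paradigms.  Because raw
clinical recordings of this kind cannot be shared, the package includes
a first-class synthetic-cohort generator whose group effects are
calibrated to the published summary statistics, so every stage of the
analysis is runnable, testable and reproducible from a seed.

## What it computes

**fNIRS preprocessing.** Two-wavelength optical-density channels are
motion-corrected (moving-SD + amplitude-deviation detection, spline
interpolation), inverted to chromophore concentration changes by the
modified Beer–Lambert law,

ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · L · DPF(λ),

z-scored per channel against the resting segment, and band-passed
0.01–0.20 Hz (zero-phase Butterworth, order 3).

**Event-locked activation.** For each subject, HbO is windowed 10 s
after every negative-word onset; activation = pooled window mean minus
the mean over the two digit-repetition control blocks.  Channelwise
group differences use two-sided Mann–Whitney U (exact for small groups)
with Benjamini–Hochberg FDR across channels and Cliff's δ effect sizes.
The group-average window is profiled for latency (first sustained
excursion above baseline mean + 2 SD), rise slope, peak, peak − minimum
difference, and Spearman rank correlation against time.

**Language and prosody.** Honoré's lexical richness
R = 100·ln N / (1 − V₁/V), emotional/factual word rates from a
LIWC-style lexicon, and a hierarchical bidirectional RNN
(`BiRnnTagger`, scikit-learn estimator API) with two parallel softmax
heads that tags each token as emotional and/or factual while carrying
its onset marker.  Prosody features: voiced-frame mean pitch, semitone
declination (12·log₂ of last/first voiced-decile median f0), and pause
counts.

**Group statistics.** Shapiro–Wilk-gated t / Mann–Whitney / χ²
comparisons with matched effect sizes (|d|, |δ|, |h|), t-based
confidence intervals from summary statistics, Pearson/Spearman-gated
correlations, and exact noncentral-t a priori power analysis.

## Worked example

```python
from narrafnirs import CohortSpec, analyze_cohort, PTSD, TEC

res = analyze_cohort(CohortSpec(seed=42))   # 35 PTSD-like, 37 TEC-like

at = res["activation_table"]
target = at[at.channel == 27]
print(target.groupby("group").activation.mean())
#  PTSD    0.169
#  TEC     0.047      (windowed, baseline-subtracted HbO, z-units)

q27 = {r.channel: r for r in res["channel_tests"]}[27]
print(q27.q_value, q27.cliffs_delta)
#  1.38e-06 0.79      (BH-FDR q at the target channel; Cliff's delta)

tec, ptsd = res["profiles"][TEC], res["profiles"][PTSD]
print(tec.latency_s, tec.spearman_r)   # 3.55  0.898
print(ptsd.no_latency, ptsd.spearman_r)  # True  0.110

print(res["language"].groupby("group").neg_pct.mean())
#  PTSD    6.14
#  TEC     4.05       (% negative emotional words per narration)
```

The control group's event-locked curve rises only after ~3.5–3.8 s and
correlates strongly with time; the patient group's curve is elevated
throughout the window (no-latency flag set, negligible rank
correlation) and its windowed activation is about 3.5× the control
level, separating the groups at q < 0.001 while the 47 noise-only
channels stay null.

The same analysis runs file-based from the shell:

```
narrafnirs all --seed 42 --outdir run/
narrafnirs validate run/
```

writing `subjects.tsv`, per-subject transcripts/prosody/optical-density
CSVs, `activation_table.tsv`, `channel_tests.tsv`,
`timecourse_profiles.json`, feature tables, a JSON report and a
checksummed run manifest.

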