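# Methods

This note documents the models, parameter choices and known limitations
of `narrafnirs`: what the synthetic cohort emulates, how the analysis
chain is defined, and which numerical decisions were genuinely open.

## Session and cohort model

A session is 540 s at 11 Hz: 300 s rest, 30 s digit repetition
("1-2-3-4-5"), 180 s impromptu trauma narration, 30 s digit repetition.
The default cohort is 35 PTSD-like and 37 TEC-like subjects.  Clinical
scores: PTSD CAPS-5 totals are drawn from N(50.89, 7.57²) truncated at
the diagnostic floor of 45; the criterion-D subscore is generated as a
linear function of the subject's true negative-word rate plus Gaussian
noise whose variance is set so the within-group correlation is 0.349 in
expectation (clipped to the 0–28 scale, which attenuates it slightly).
Demographics come from group-identical distributions, as in a matched
design.

## Transcript generator

Tokens arrive at 2.5/s on a jittered grid (strictly increasing onsets
inside the narration).  Each token's category is multinomial:
negative at the subject's true rate (drawn per subject from
N(5.89, 3.00²) for PTSD, N(4.21, 2.83²) for TEC, clipped at zero —
clipping rather than re-sampling keeps the population mean at ≈ 5.92
instead of ≈ 6.07), positive ≈ 2.2–2.5 %, factual 12 %, the rest
neutral.  Surface forms are drawn from a packaged synthetic lexicon
(Zipf-weighted category vocabularies; neutral tokens mix 20 common
words with a large uniform rare set), so every token is covered by the
lexicon with its generating category and lexicon tagging is exact on
synthetic data.

Lexical richness is controlled through the rare-vocabulary size, solved
by bisection on the expected Honoré statistic
E[V] = Σ_w 1−(1−p_w)^N, E[V1] = Σ_w N·p_w(1−p_w)^{N−1}.  Note a scale
inconsistency in the published group values (≈ 30): with
R = 100·ln N/(1−V₁/V) and N ≈ 450, R cannot be below 100·ln N ≈ 611, so
those values are treated as R/100 and the generator targets R ≈ 3023
(PTSD) and ≈ 3459 (TEC).  The formula itself, with natural log, is used
everywhere and verified against hand counts.

## Prosody generator

f0 tracks at 100 frames/s.  The contour is linear in semitones over
voiced frames (exponential in Hz) with 0.2-semitone frame jitter; the
generated span is the drawn semitone change divided by 0.9 so that the
estimator — 12·log₂ of last/first voiced-decile medians — recovers the
drawn value (the deciles sit at the 5 % and 95 % span points).  The
voiced-frame mean is normalised to equal the drawn mean pitch exactly.
Pauses are unvoiced runs of 60–120 ms inserted at random positions
(count drawn from the group distribution, clipped to [0, 900]); every
generated pause meets the 60 ms detector threshold.

## Hemodynamic generator and calibration

The target channel (27, left anterior medial prefrontal cortex in the
montage table) carries an event-locked HbO signal; all 48 channels get
structured optical-density noise; HbR is tied to HbO by a fixed ratio
of −0.3 (only HbO is analysed downstream).

Response kernels are piecewise linear, because only onset/peak/decline
landmarks are specified for the underlying effect:

* TEC: zero until 3.82 s after word onset, linear rise to peak at
  7.55 s, linear return by 12 s.
* PTSD: a plateau that is already elevated 2 s before each word onset
  (a tonic state is by definition not event-initiated), held through
  the 10 s analysis window with a coherent 0.15 Hz ripple at 0.35
  relative amplitude (the sustained state fluctuates rather than
  trends), declining between 11 and 15 s; plus a narration-long tonic
  pedestal at 0.3 relative amplitude.  The ripple is what makes the
  no-latency flag and a near-zero rank correlation deterministic
  properties of the group-average window instead of coin flips on
  smooth noise.

Noise in OD space per channel and wavelength: two slow drift sinusoids
(0.002–0.006 Hz, ≈ 6·10⁻⁴), cardiac pulsation (1.1 Hz ± 5 %, 2·10⁻³,
amplitude-modulated), respiratory oscillation (0.25 Hz, 4·10⁻⁴), white
noise (10⁻⁴), and sparse triangular motion spikes (0.005/s, 2·10⁻²).
The budget is deliberately dominated by out-of-band components: rest
z-scoring then divides by the full physiological SD, which is what
makes task-evoked z-values of order 0.1 — and per-group activation SDs
of order 0.03–0.1 — come out on the reported scale.

**Amplitude calibration.**  Event amplitudes are not free parameters:
a deterministic pilot (fixed internal seeds, independent of the cohort
seed) pushes a unit-amplitude noise-free signal through the actual
band-pass and windowing code, using irregular onset trains at the
group's mean word rate, and measures the windowed-activation gain per
unit amplitude.  This folds in both response overlap and the reshaping
by the zero-phase 0.01–0.20 Hz filter (a periodic pilot train would be
annihilated by the filter and is explicitly avoided).  Amplitudes are
then set so the pipeline's windowed, baseline-subtracted group means
target 0.153 (PTSD) and 0.047 (TEC) z-units.  Per-subject amplitude
factors (CV 0.45, truncated) and per-event jitter (SD 0.25) supply
realistic between-subject dispersion.

**Latency compensation.**  The zero-phase filter smears the response
foot backwards and overlap wander trips the baseline + 2 SD rule early,
so the threshold-latency estimator reads systematically below the
configured 3.82 s onset.  The pilot therefore also simulates stochastic
signal-only grand averages (16 replicates with per-subject rate draws,
event jitter and amplitude factors) and shifts the generated landmarks
by the median measured bias (+0.46 s at defaults) — the same
estimator-compensation pattern as the semitone 0.9 factor.  The
single-seed latency estimate still has an intrinsic spread of ≈ 0.7 s
(threshold estimated from 22 smooth baseline samples), which is why
seed-ensemble medians, not single seeds, are the unit of evaluation for
time-course recovery.

One consequence of calibrating to the windowed means: the group-average
TEC curve peaks around 0.10–0.12 z rather than at the nominal 0.184
kernel landmark; both cannot hold simultaneously once the band-pass and
overlap act on the superposed train.  The windowed means are the
quantities the group test consumes, so they take precedence.

## Preprocessing chain

Order: motion correction in OD space → Beer–Lambert inversion →
rest-referenced z-scoring → 0.01–0.20 Hz band-pass.

* Motion: a sample is flagged when its 1 s moving SD exceeds 5× the
  series' median moving SD *and* its deviation from the 1 s rolling
  median exceeds 5× that typical SD; flagged runs are spline-
  interpolated and clipped to the clean amplitude range.  >50 %
  flagged passes the series through with a logged warning.
* Inversion: per-sample 2×2 solve with extinction coefficients from a
  standard compilation (0.390/1.1022 at 730 nm, 1.058/0.6913 at 850 nm,
  cm⁻¹·mM⁻¹), DPF 6.0 at both wavelengths, path length = the 3 cm
  source–detector separation.  All values are configuration, not code.
* Z-scoring uses the *unfiltered* concentration series' rest mean/SD
  per channel.  Placing the band-pass after z-scoring is a deliberate
  design choice: if rest statistics were taken from the filtered
  series, the in-band rest noise would be exactly 1 by construction
  and activation values on the 0.05–0.15 z scale (with group SDs of
  0.03–0.1) could not exist.  Zero-rest-SD channels are flagged bad and
  excluded; re-z-scoring raises.
* Filter: Butterworth order 3, `sosfiltfilt` (zero phase); 1.1 Hz is
  attenuated far beyond 20 dB, 0.05 Hz passes within 10 %.

## Event-locked analysis

Windows are 110 samples (10 s at 11 Hz) after each negative-word onset;
onsets with less than a full window of recording remaining are dropped;
overlapping windows are pooled (word spacing is shorter than the
response, so overlap is the norm, not an edge case).  Baseline is the
mean over both pooled digit blocks.  Subjects with no usable onsets
(possible at a clipped-to-zero negative rate) are excluded and logged.

Mann–Whitney U is exact when both groups are ≤ 8 without ties,
otherwise the tie-corrected normal approximation (the approximation
agrees with exact enumeration to ≈ 0.01–0.02 at those sizes; the exact
path is bit-identical to enumeration).  BH-FDR is applied across all 48
channels.  Identical constant groups return p = 1 rather than failing.

Time-course profiling: baseline = first 2 s of the window; latency =
first time the curve stays above baseline mean + 2 SD for ≥ 1 s
continuously, with a "no latency" flag when that happens at t = 0 or
never; slope = least-squares slope between latency and peak, reported
per sample and per second (at 11 Hz a per-sample slope of 0.0067 over a
full rise is consistent with a peak-minus-minimum difference of ≈ 0.27,
which is why both scales are reported); difference defaults to peak −
window minimum (config switch for peak − baseline).  Spearman's rank
correlation is computed over the full window; a constant window returns
r = 0.

## Neural tagger

Vanilla tanh (Elman) cells — the simplest reading of the recursions —
in forward and backward directions; per-token states are concatenated
(2h, default 64) and fed to two parallel 2-way softmax heads (emotional
vs not, factual vs not), keeping the two judgements independent per
token while markers pass through untouched.  Sentence vectors are the
concatenated final states of the same biRNN; an upper Elman cell over
sentence vectors yields the document representation.  Training is
full-batch gradient descent on the summed two-head cross-entropy with a
fixed learning rate and seeded initialisation; gradients are
hand-derived backpropagation-through-time, verified against central
differences to 10⁻⁵.  Words below `min_count` map to a trainable OOV
embedding, which is also the path unseen test words take.  Embeddings
are random-initialised and trained end-to-end at desk scale; no
pretraining corpus is used or needed for lexically separable synthetic
data, where held-out agreement with lexicon tags reaches ≈ 0.97
(residual errors are category words never seen in training —
irreducible for any word-identity model).

## Group statistics

Shapiro–Wilk at α = 0.05 on each group gates t (Welch) vs Mann–Whitney;
either group non-normal → nonparametric.  Categorical variables use
Pearson's χ² without continuity correction.  Effect sizes match the
test family: |Cohen's d|, |Cliff's δ|, |Cohen's h|.  Confidence
intervals are t-based from summary statistics; report rounding is
3 decimals, half away from zero.  `required_n` searches the smallest
integer n whose exact noncentral-t power meets the target (d = 0.7,
α = 0.05, power 0.80 → 34 per group).  The correlation gate applies
Shapiro–Wilk to both margins and picks Pearson or Spearman; on default
cohorts the negative-word-rate × criterion-D correlation is usually
gated to Pearson.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline recovers configured effects
under a physiologically plausible noise model: correct event-locking,
correct channelwise inference with FDR control (false-positive rate at
noise-only channels ≈ nominal), calibrated activation means, and the
qualitative group contrast in time-course shape.  They do not
demonstrate robustness to real-world confounds the generator omits:
superficial/scalp hemodynamics, serially correlated motion, speech
articulation artifacts coupled to word onsets, imperfect transcript
alignment, Mandarin segmentation, or lexicon coverage gaps — on real
data the lexicon tagger and the biRNN would disagree more than the
≈ 5 % seen here.  The time-course latency estimator has an intrinsic
≈ 0.7 s spread at this cohort size; studies leaning on latency should
average over more events or subjects than a single 37-subject group
provides.

## Problem sizes

Default analyses use the full 72-subject cohort at 540 s × 11 Hz × 48
channels.  The test suite evaluates stochastic criteria over a
20-seed ensemble of full-pipeline runs and scaled-down cohorts
elsewhere; the reproduction script uses a 9-seed ensemble and 500
transcripts.  These sizes were chosen so Monte-Carlo error is small
relative to the tolerances being checked.
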