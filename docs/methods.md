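# Methods

`wordbyword` implements the analysis chain for a dyadic "word-by-word"
reading paradigm: two participants jointly read a pair of sentences
(13 words in total) aloud, strictly alternating word by word, while two
wireless 24-channel EEG streams (500 Hz, FCz online reference), one
audio channel per speaker (44.1 kHz) and an online voice-key marker
stream (100 ms resolution) are recorded on a common session clock.
Word 4 of each trial is a homonym; word 8 — the critical word (CW) —
disambiguates it. A silently read prime shown before the sentence fixes
one homonym meaning per participant, so the CW is semantically expected
(congruent) or unexpected (incongruent) independently for each member
of the dyad. The analysis targets the ERP of the *heard* CW (the word
the partner speaks) and the reaction times to speak.

No recordings are distributed with this package; every claim its test
suite makes is measured on data from the built-in session generator,
which plants known effects and keeps their ground truth.

## Trial design

A session has `n_trials` trials (default 240). Per participant, 75% of
trials are congruent and 25% incongruent; a trial is incongruent for at
most one participant. Each participant starts (and therefore perceives
the CW, which sits at an even position) in half of the trials. Each
participant's incongruent trials split 2:1 between perceived-CW and
spoken-CW roles — per 240 trials: 40 incongruent-while-perceiving vs
20 incongruent-while-speaking, i.e. 80:40 expected:unexpected heard CWs
and 100:20 expected:unexpected spoken CWs. `build_trial_plan` solves
these joint constraints exactly (raising a named infeasibility error
when the requested counts cannot be realized with whole trials, e.g.
`n_trials` not divisible by 12 under the default fractions) and
randomizes order and sentence assignment with a seeded generator.
Sentences are drawn without replacement from a lexicon of 240 templates
(two genuine German examples plus structure-matched pseudo-word
placeholders; no full published stimulus list exists).

## Synthetic sessions

`synthetic_session` emulates the statistical structure the downstream
analysis assumes, with these defaults:

- **Timing.** Fixation 0.5 s, prime 2.5 s, 1.5 s inter-trial blank.
  Each word's visual presentation is triggered by the previous word's
  *coarse* (voice-key) offset. Word durations follow a lognormal model
  scaled by letter count (`0.54 * (letters/4.6)^0.3` s, 11% relative
  SD), calibrated to a 0.54 ± 0.07 s grand-average word duration.
  Reaction times come from the gamma model below (grand mean ≈ 0.49 s,
  first word of a sentence markedly slower, ≈ 0.85 s).
- **Audio.** Each word is a harmonic voiced burst (f0 110–180 Hz, six
  harmonics, slight vibrato) under a raised-cosine envelope (30 ms
  attack, 50 ms release). The true onset/offset is defined as the 5%
  envelope crossing. With probability `lip_smack_prob` a 10 ms
  broadband click is planted 50–200 ms before the onset.
- **Voice key.** Coarse markers are the true onsets/offsets rounded up
  to the 100 ms grid (detection always trails the event, error
  < 100 ms).
- **EEG.** Background = 12 spatially smooth AR(1) noise sources
  (lag-1 coefficient 0.985, amplitudes 1.0–2.2 µV) + amplitude-
  modulated 10 Hz alpha (2 µV, occipital) + 0.6 µV sensor noise,
  ≈ 3 µV per-channel SD in the analysis band. The amplitudes were fixed
  once so that planted effects of a few µV are recoverable at the
  session's ~40 trials/condition — the regime the paradigm is designed
  for; they are on the clean side of real post-artifact-removal EEG.
- **ERP components.** Gaussian-windowed half-sine bumps time-locked to
  the *partner's* true speech onsets: N100 (peak 114 ms, SD 25 ms,
  −2.5 µV, Cz; doubled on sentence-initial words), P200 (250 ms, 40 ms,
  +5 µV, Fz), N400 (480 ms, 50 ms, −5 µV, CPz), P600 (600 ms, 55 ms,
  +4 µV, Pz). Topographies are Gaussian on the unit sphere and are
  defined in the *linked-mastoid reference frame* (TP9/TP10 mean
  shifted to zero, center weight kept at exactly 1), so planted peak
  amplitudes are invariant to the pipeline's re-referencing step.
  Incongruent heard CWs receive additive deltas +2 / −3 / +2 µV on
  P200 / N400 / P600.
- **Latency jitter.** Single-trial component latencies jitter: P200 by
  N(0, 20 ms); N400 and P600 jointly by one N(0, 50 ms) draw (they
  form one late cognitive cluster — independent jitters would make the
  late decomposition component ill-defined); the N100 is stimulus-
  locked. This jitter is what makes plain stimulus-locked averaging
  misleading here: the smeared N400 delta leaks into the 500–650 ms
  window and can fully cancel the P600 delta in a plain average.
- **Artifacts.** Blinks (Poisson 8/min, 200 µV, 80 ms Gaussian,
  frontal), jaw EMG during own speech (20 µV, 30–120 Hz, temporal
  emphasis), lip smacks (above). Bluetooth-style packet loss removes
  sample runs while timestamps keep true session time.

`synth_heard_epochs` generates heard-word epochs directly (same kernels
and background, no continuous session) for focused component-recovery
simulations; `synth_rt_study` generates multi-dyad RT tables.

What the generator does **not** emulate: phonetically realistic speech,
coarticulation (the paradigm's alternation prevents it by design),
non-stationary electrode drift, line noise, real Bluetooth transport
beyond sample drops, and between-subject variability in component
topographies or latencies. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the paradigm's assumed
statistical structure, not performance on any real recording.

## Speech-event refinement

The offline onset chain (per coarse marker, per speaker channel):
epoch −0.5..+1.0 s around the marker → 35 Hz FIR highpass (erases
low-frequency room/pop fluctuations) → downsample to 1470 Hz →
three feature traces: amplitude envelope (|x| smoothed with a
300-sample moving average, lowpassed at the configured 730 Hz clamped
to 0.95× Nyquist — effectively pass-through smoothing), the first two
mel-cepstral coefficient traces (128-sample frames, hop 32, 12 mel
filters, interpolated back to the 1470 Hz base, lowpassed likewise at
the clamped 600 Hz), and a running RMS. Abrupt mean changes in the RMS
trace are found by exact penalized segmentation (dynamic programming
over an L2 change-in-mean cost; penalty `3 var log n`, trace decimated
8× first — it is already smooth at the 204 ms moving-average scale).
A candidate is accepted only when, within a ±150 ms validation window,
the envelope rises by ≥ 20% of the epoch's envelope peak *and* at
least one cepstral trace changes by ≥ 20% of its robust range; a
structureless epoch (envelope peak < 3× its median) never validates.
The window matches the feature smoothing scale: change-in-mean points
on a 204 ms-smoothed trace land up to ~150 ms before the voicing edge,
so a much narrower co-occurrence window rejects true onsets wholesale.

Accepted candidates are then *localized*: the onset is the threshold
crossing (5% of the local plateau) of a short 15-sample envelope,
requiring 30 ms of sustained supra-threshold signal — a brief click
cannot sustain it, which is what keeps lip smacks from producing early
onsets. This localization step is this package's own refinement; the
validated changepoint alone has ~100 ms uncertainty, far coarser than
the millisecond onsets an ERP analysis needs. Offsets run the identical
machinery on the time-reversed epoch. On artifact-free synthetic
sessions the median onset error is < 1 ms with zero fallbacks; with lip
smacks on 30% of words the false-early rate (> 30 ms early) is 0%.

## Stream repair

Wireless transport drops sample runs; per-sample timestamps keep true
session time, so a gap is a timestamp delta > 1.5 nominal periods and
loses `round(delta*rate) - 1` samples. Markers map to the nearest-
timestamp sample; markers inside a gap map to the first post-gap sample
and are flagged. Lost samples are never reconstructed — epochs
overlapping a gap are dropped with a logged reason.

## EEG preprocessing

0.1–30 Hz zero-phase Hann-window FIR bandpass (−6 dB at the cutoffs;
kernel long enough for a 0.05 Hz transition) → bad-channel detection
(flat, or correlation < 0.4 with the median of the six nearest
neighbors; needs ≥ 60 s) → burst cleaning → average-mastoid
(TP9/TP10) re-reference → order-4 spherical-spline interpolation
(Perrin-style, 30 Legendre terms, 1e-5 regularization) of removed
channels → epoching −500..1500 ms (half-open, event sample = t0) with
−100..0 ms baseline → one-pass 3-SD rejection (statistic: peak
absolute amplitude across channels, pooled per event type; an
alternative statistic would be epoch-mean global field power) → seeded
subsampling so compared conditions have equal trial counts.

**Burst cleaning** is a deliberately simplified artifact-subspace
method, not a port of the reference implementation: calibration windows
are sampled *uniformly across the session* (robust median/MAD
statistics tolerate a minority of artifact windows, and — critically —
typical event-locked activity stays inside the calibration statistics);
a direction in a sliding 0.5 s window is deviant only when its RMS
exceeds both `median + 12 MAD` and an absolute floor of 3× the
calibration median. Deviant directions are projected out and windows
cross-faded. The floor matters: without it, low-variance directions
with tiny MADs get flagged during ordinary evoked responses, and since
the *incongruent* responses are the largest, the cleaner selectively
shrinks exactly the condition differences under study. With it, planted
200 µV blinks lose ≥ 97% of their variance while evoked amplitudes
change by a few percent.

## Latency-corrected ERPs

The decomposition separates each condition's heard-word epochs into a
stimulus-locked component S (0–250 ms, N100 range) and two cognitive
components C1 (150–350 ms, P200 range) and C2 (300–700 ms, N400/late
range) with single-trial latencies, alternating:

1. *Waveforms:* for each component, subtract the other components at
   their current per-trial latencies, align by this component's
   latencies, take the sample-wise **median** across trials, window
   with 30 ms cosine-tapered edges.
2. *Latencies* (free components): per trial, the lag (±¼ window width,
   2 ms grid, ties toward zero) maximizing the channel-summed
   cross-correlation between the trial residual and the component
   template, computed after **spatial noise-whitening** — the whitening
   matrix comes from the covariance of trial-minus-average residuals
   (eigenvalues shrunk 1% toward their mean, which keeps the
   re-reference null direction harmless). Background EEG is spatially
   low-rank, so whitening sharpens single-trial latency estimates
   dramatically (r ≈ 0.5 → ≈ 0.95 against planted jitter). Temporal
   (AR) pre-whitening is deliberately *not* applied: on band-limited
   EEG the fitted AR coefficient approaches 1 and differencing erases
   the component band. Latencies are centered to median 0.

Iteration stops when waveforms change < 0.05 µV RMS (max 20 sweeps);
non-convergence returns a flagged result with a warning. The
reconstructed ERP is the sum of median-aligned component waveforms; on
zero-jitter data it equals the plain average to < 0.05 µV RMS.

**Condition comparison** (`ride_condition_erps`): latencies are
estimated once on the *pooled* trials of both conditions, then the
waveform partition is re-estimated per condition (mean estimator) with
the latencies held fixed. Two failure modes of naive alternatives
motivated this: independently decomposed conditions anchor to
different median latencies, which distorts difference-wave extrema on
steep component flanks; and subtracting *pooled* components inside
per-condition averages double-counts the condition difference wherever
component windows overlap.

## Statistics

Window means: P200 166–336 ms, N400 350–500 ms, P600 500–650 ms,
N100 window 60–160 ms; midline sites {Fz, Cz, CPz, Pz} or four
quadrant electrode averages (computed per subject before the ANOVA).
The two-way fully-within-subject ANOVA is implemented from the
sum-of-squares definitions; Mauchly's test (α = .05) decides per effect
whether the Greenhouse-Geisser-corrected p (epsilon from the
orthonormal-contrast covariance, reported with original degrees of
freedom) replaces the uncorrected one; effect sizes are partial η².
The implementation agrees with an independent reference implementation
to 1e-8 on F and partial η², and its null rejection rate is ~5%.
Difference-wave component amplitudes are measured as window extrema
after 40 ms smoothing (components are an order of magnitude broader;
the smoothing suppresses the upward bias of taking the extremum of a
noisy curve). No correction is applied across the three component
ANOVAs, mirroring common reporting for this design.

Reaction times: RT = visual presentation → own refined speech onset.
Exclusions: RT < 300 ms or > 1000 ms (strict; boundary values kept) and
words whose preceding spoken word's refined offset exceeds the visual
onset. Models are fitted per spoken-word sequence (CW, CW+2, CW+4 by
the CW producer; CW+1, CW+3, CW+5 by the perceiver): gamma GLMM with
inverse link, fixed congruency (coded ±0.5) + word position (orthogonal
polynomial contrasts for the ordered 3-level factor), random intercepts
for participant and for word length (one level per letter count —
unusual, but followed literally as the design's item-variability
proxy). Fitting delegates to lme4's `glmer` through an R subprocess
(the canonical tool for this model class); log-likelihoods feed
likelihood-ratio tests with df = the actual parameter difference.
Back-transformed condition means are reciprocals of the linear
predictor at the average word position. Null-calibration of the
congruency LRT against χ²(1) holds at the study's design size
(13 dyads × 60 trials per replicate in the reduced-size simulations);
materially smaller replicates make the test visibly conservative.

## Problem sizes and numerical choices

Simulation sizes used by the test-suite and the acceptance script —
60-trial sessions for onset accuracy, one or two 240-trial sessions
(40 trials/condition after matching) for ERP recovery, 20 × 40-trial
epoch sets for amplitude recovery, 500 ANOVA and 60–120 GLMM null
replicates — are the package's chosen working points; they keep every
check reproducible on a single CPU while leaving the measured
quantities' Monte-Carlo error well inside the asserted tolerances.
Milliseconds convert to samples by rounding half away from zero; epoch
windows are half-open `(start, end]`; word positions are 1-based,
sample indices 0-based. Known limitations: the burst cleaner is not a
reference-grade artifact-subspace implementation; the P200-range (C1)
single-trial latencies are estimated much less reliably than the late
component's (smaller, narrower component); and the per-participant
difference-wave extremum at 40 trials/condition carries ±0.5 µV of
sampling noise, which is why condition effects should be read from
grand averages.
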