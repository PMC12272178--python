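# Methods

This note documents the models behind `tagattn`, the parameter choices that
matter, and what the synthetic-data validation does and does not establish.

## The measurement problem

Covert spatial attention is read out here by frequency tagging: display
locations flicker at distinct frame-locked frequencies, each driving a
steady-state visually evoked potential (SSVEP) at its own frequency in
occipitoparietal EEG. Attention to a location is hypothesized to multiply
the amplitude of that location's SSVEP source by a gain g ≥ 0; g = 1 means
no modulation. The pipeline's job is to recover attentional modulation from
the spectrum, as an attention index (ai) that equals 1 under the null.

## Experiment designs

Three designs are generated (`tagattn.design`):

1. **Contrast-probe cueing (Exp 1).** Arc segments (14.7° of polar angle,
   3° gaps, 1.5° off the meridians, 8–14 dva) in the lower visual field;
   narrow / split / broad cue conditions whose cued locations jointly carry
   probe probability 0.75 (narrow 0.75; split 0.375 + 0.375; broad 5 × 0.15),
   with the remaining 0.25 on adjacent uncued locations (narrow/broad 0.125
   each; split 1/12 each, including the intermediate location). Sessions:
   720 trials in 72 blocks of 10, sides alternating, focus balanced per side.
2. **Dimming detection with three tags (Exp 2).** Six segments (25.33°, 4°
   gaps) in the lower hemifield; the task-relevant side's three locations
   flicker at 120/11 ≈ 10.91, 120/10 = 12 and 120/9 ≈ 13.33 Hz
   (innermost → outermost). Dimming events (0.4 s; alpha follows a Gaussian
   peaking at μ = 0.2 s with σ = 1 s, normalized to start and end at
   baseline) are scheduled by rejection sampling under the timing
   constraints: consecutive onsets ≥ 1.1 s apart, none before 0.5 s or
   within 0.7 s of trial end; 1–3 events per 4.5–5 s trial, each
   independently a target with p = 0.5 (a `stratified` flag forces the
   exact-half alternative). Target/nontarget dimming configurations follow
   the condition definitions (split targets = both cued locations
   synchronously; broad targets = any two of three; split nontargets =
   singular or adjacent with equal configuration probability).
3. **RSVP letter conjunctions with six tags (Exp 3).** All six locations
   flicker (adding 120/17 ≈ 7.06, 120/15 = 8, 120/13 ≈ 9.23 Hz); the layout
   mirrors every 3-trial block so each frequency spends half the session on
   each side. Letter streams draw from the 15-consonant alphabet; target
   frames repeat one letter at all cued locations, distractor frames form
   the condition's near-miss conjunction. Letters are re-drawn on collision
   so no unscheduled frame forms a target **or** distractor configuration —
   the emitted schedule is the complete event list. Distractor counts per
   trial are not dictated by the source designs; they are drawn uniformly
   over {0, …, min(2, 3 − n_targets)} so at most three events fit the 1.1 s
   separations (which the RSVP scheduler re-uses so response windows never
   overlap). RSVP switch rates snap to the frame grid and are shifted by one
   frame when they would collide with a tag frequency or harmonic.

Counterbalancing uses balanced random block orders (the "Latin-square"
structure of the originals is not published); sides alternate L/R, except in
Exp 3 where an L/R/R/L pattern keeps the alternating layout flip balanced
within each side. Identical seeds give byte-identical session tables.

## Synthetic EEG

Each trial is

x_c(t) = Σ_s w_c(s) · g(loc_s) · A_s [sin(2πf_s t + φ_s) + Σ_k r_k sin(2πk f_s t + kφ_s)] · 1[t ≥ 0] + n_c(t)

with one source per tagged location, a fixed posterior-weighted topography
w (unit max over occipital channels), and per-channel-independent 1/f^α
noise synthesized in the frequency domain with random phases and normalized
to a target RMS. Defaults: 500 Hz sampling, epochs −0.1 to 4 s around
flicker onset, 30 channels named after the modified 10-20 montage (three
frontocentral electrodes redeployed as I3/Iz/I4), second harmonic at 0.3 of
the fundamental, α = 1.

**Amplitude regime.** Absolute SSVEP amplitudes are not published for these
tasks, so the defaults are conventional: source amplitude 0.25 µV against
10 µV RMS noise. This pair was chosen (once) to put cluster-level peak SNRs
in the 2–6 range typical of reported frequency-tagging data at realistic
trial counts. The regime matters for a subtle reason: the analysis windows
(0.15–4 s → 3.85 s → 0.2597 Hz bins) leave most tag frequencies off the FFT
grid, so a noiseless tag leaks into two adjacent bins and the ±1-bin median
floor would then scale with the tag itself, capping SNR at a
gain-independent constant. With realistic noise the leak sits below the
noise floor and SNR again tracks injected power. Validation at unrealistic,
near-noiseless amplitudes would silently test a different regime than real
recordings occupy.

What the generator does **not** emulate: volume-conducted source mixing from
a head model, ocular/muscle artifacts, inter-channel noise correlation,
non-stationarity, or SSVEP phase differences across locations. Passing
recovery tests therefore show the *analysis* is correct and unbiased under
the stated signal model, not that real-data confounds are handled; the
recording-specific cleaning steps (ICA, channel interpolation) are out of
scope.

## Spectral quantification

Preprocessing order: average reference → zero-phase FIR band filters
(windowed-sinc, 0.1 Hz high-pass, 70 Hz low-pass; forward–backward
application realized as one frequency-domain multiplication by the squared
magnitude response, with odd-reflection padding) → subtraction of the
−0.1–0 s baseline mean → linear detrend. Filter orders follow a
transition-width rule but are capped at a third of the epoch length so
zero-phase filtering of 4.1 s epochs stays well-posed; on epochs this short
the 0.1 Hz high-pass is consequently gentle, which is immaterial after
baselining and detrending. Exact filter order is not contractual.

Trials are averaged **in the time domain** per condition cell before the
FFT, preserving the phase-locked steady-state component while incoherent
activity shrinks as 1/√n. Power is the squared one-sided amplitude spectrum
of the un-tapered, un-padded [0.15, 4.0) s window; the SNR is invariant to
the normalization (asserted by test). The noise floor is a sliding median
over 2h+1 bins (center included; h = 1 default; edges use the shrunken
window), the SNR their elementwise ratio, and the per-frequency statistic is
the maximum SNR within ±0.24 Hz of the tag (the nearest bin serves when the
grid is coarser than the window). Bin width is derived from the data
(0.2597 Hz here) and the ±1-bin kernel is primary; the peak-search
half-width is an independent parameter, and zero-padding to a finer grid is
available (`pad_to`) but off by default since whether the original analyses
padded is not knowable. Cluster averaging (15 named occipitoparietal
electrodes) happens in SNR space after per-channel SNR, making the result
robust to channel-gain differences; `average_power_first` switches to
power-space averaging.

## Attention indices

Both schemes divide an attended-frequency SNR by the mean of an attended
and an unattended SNR of the same frequency:

- **Cross-condition (Exp 2):** the narrow-focus conditions provide the
  baseline for every condition; 13.33 Hz is never cued narrowly and is
  excluded. The narrow conditions' own ai is self-referential by
  construction (its numerator is one of its baseline components).
- **Within-condition (Exp 3):** the baseline's unattended cell is the same
  frequency on the uncued hemifield, after collapsing trials across sides;
  per-frequency ais then collapse to locations by unweighted mean over the
  fixed pairs (9.23/10.91 innermost, 8/12 intermediate, 7.06/13.33
  outermost; trial counts are balanced by design).

Algebraic consequences, enforced by tests: ai ∈ (0, 2);
ai(a,b) + ai(b,a) = 2 exactly; ai is strictly increasing in the attended
SNR; ai = 1 when numerator equals the baseline mean. ai is computed per
participant first and aggregated afterwards, matching subject-level
inference. Whether the Exp 2 "unattended" baseline should pool more cells
than the attend-other-narrow condition is an open reading; the printed
formula is implemented, and the peaks-table interface makes alternatives a
one-line change.

## Behavioral machinery

- **Weibull observer:** P(correct|x) = γ + (1−γ−λ)(1−exp(−(x/θ)^β));
  γ = 0.5 for 2AFC discrimination, ≈ 0 for detection; λ ≤ 0.1.
- **QUEST:** posterior over the target-p intensity on a 200-point log grid
  (0.1%–100% contrast), Gaussian prior in log10 intensity (SD 1), Weibull
  likelihood, placement at the posterior mode after every response. The
  returned estimate is the **posterior mean** in log intensity: the mode
  estimator's occasional lucky-streak posteriors produce a heavy low tail
  (measured skew ≈ −3) that biases realized accuracy ~2 points below
  target, while the mean is unbiased at equal trial counts — consistent
  with the standard recommendation for adaptive methods. The mode is
  available via `estimate="mode"`.
- **3-down-1-up staircase:** intensity steps harder after three consecutive
  correct target responses, easier after any error; with equal step sizes
  accuracy converges to p with p³ = 0.5, i.e. ≈ 0.794. Only target events
  update the staircase; distractors share its current intensity.
- **Response matching:** a response matches an event when its latency lies
  in (0, 1] s (dimming task) or [0.1, 1] s (RSVP task); each response goes
  to the most recent not-yet-consumed matching event (reaction-time
  plausibility; ties cannot error), each event consumes at most one
  response, and unmatched responses are discarded from the rates.
- **d′:** log-linear correction, H = (hits+0.5)/(T+1),
  F = (FA+0.5)/(N+1), d′ = Φ⁻¹(H) − Φ⁻¹(F); finite at ceiling/floor.
- **Exclusions:** a trial is excluded when gaze leaves a 0.75 dva radius
  for more than 0.05 s contiguously (missing samples count as excursions);
  a participant is excluded when more than 25% of trials are excluded
  (strict inequality). Threshold outliers are flagged at |z| > 3 versus the
  sample mean — a reproducible formalization of an originally ad hoc
  judgment — and flagging does not auto-exclude.
- **Within-subject SE:** Cousineau normalization (subtract participant
  mean, add grand mean) with Morey's √(J/(J−1)) correction, on by default
  with a flag to disable (whether the original error bars used the
  correction is not stated).

## Problem sizes and tolerances in the validation suite

The test suite validates numerical primitives against independent oracles
(O(n²) DFT sums, sort-based medians, all-pairs matching) at small n, and
statistical claims by Monte Carlo at sizes chosen for stable verdicts:
staircase convergence over 3000-trial runs (tolerance ±0.02 around 0.794);
QUEST recovery within 15% of the analytically inverted 75% point over 30–40
seeded runs; thresholding-to-accuracy within ±2 percentage points of 75%
for a 27-observer sample; the ai null (g = 1) within three Monte-Carlo
standard errors of 1 over six simulated sessions; and gain recovery
(strictly increasing group-mean ai over g ∈ {1.0, 1.25, 1.5, 2.0}) on
sessions with 60 trials per focus × frequency-band cell, three participants
per gain. Noise-level and amplitude defaults were fixed before these
checks' verdicts and are not per-test knobs.

## Known limitations

- The attention index's (0, 2) range makes group means slightly
  conservative for large gains (ai saturates as g → ∞ at 2·g²/(1+g²) under
  the within-condition scheme's idealization).
- Off-grid tags concede some SNR to spectral leakage by design fidelity;
  the pipeline inherits this property of the original analysis rather than
  repairing it (e.g. by tapering), since SNR comparisons are within-
  frequency and the leak cancels in the ai ratio to first order.
- Exp 1's nine-position thresholding display is represented abstractly
  (position indices) because its full geometry is under-determined; the
  session generator records printed arc values verbatim rather than
  re-deriving them from circle closure, which the printed numbers
  over-constrain.
- The "±1 frame" switch-rate adjustment is implemented as a ±1 change in
  frames per cycle (the quoted per-frame figure is a duration expressed in
  Hz; the cycle-length reading is the realizable one).
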