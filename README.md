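# tagattn

Frequency-tagged SSVEP analysis of covert spatial attention — can visual
attention be split across noncontiguous locations, or does it always cover a
contiguous region? `tagattn` implements the full analysis stack for a family
of cueing experiments that address this question with steady-state visually
evoked potentials (SSVEPs): each display location flickers at its own
frame-locked frequency, so the cortical response to every location is
separable in the EEG spectrum, and attention's effect on a location is read
out as a change in spectral signal-to-noise at its tag frequency.

The package is a library for simulation-based validation of that pipeline.
It contains, as first-class tested code:

- **`tagattn.design`** — generators for the three experiment designs:
  arc-segment geometry, cued-location probability tables (cued locations
  jointly carry P = 0.75 of probe placement), frame-locked flicker
  frequencies (e.g. 120/11 ≈ 10.91 Hz), dimming-event schedules with timing
  constraints (≥ 1.1 s between onsets, none in the first 0.5 s / last
  0.7 s), RSVP letter-conjunction streams, and counterbalanced sessions.
- **`tagattn.synth_eeg`** — synthetic multichannel EEG: sinusoidal
  steady-state sources (+ harmonics) starting at flicker onset, a
  per-location multiplicative attentional gain *g*, and 1/f^α background
  noise; a 30-channel montage whose occipitoparietal 15-electrode analysis
  cluster resolves by name.
- **`tagattn.spectral`** — the quantification chain: average reference,
  zero-phase FIR filters, baseline/detrend, condition-wise evoked averages,
  FFT power over the 0.15–4 s window, a ±1-bin sliding-median noise floor,
  SNR = power/floor, ±0.24 Hz peak search, electrode-cluster averaging.
- **`tagattn.attn_index`** — the attention index

  ai(f) = SNR(f | attended) / mean(SNR(f | attended), SNR(f | unattended))

  under both baselining schemes (a fixed narrow-focus baseline across
  conditions, or a within-condition attended/unattended baseline with
  frequency→location collapsing). ai = 1 means no modulation; ai ∈ (0, 2).
- **`tagattn.behavior`** — Weibull observers, QUEST (Bayesian adaptive
  threshold targeting 75% correct) and 3-down-1-up staircases (convergence
  at 0.5^(1/3) ≈ 79.4% correct), windowed response–event matching,
  log-linear-corrected d′ = Φ⁻¹((H+0.5)/(T+1)) − Φ⁻¹((F+0.5)/(N+1)), and
  gaze-based trial/participant exclusion rules.
- **`tagattn.report`** — group summaries with Cousineau–Morey
  within-subject standard errors.
- **`tagattn.pipeline`** — glue running a session end to end
  (design → synthetic EEG → SNR peaks → attention indices).

## Worked example

Each script in `examples/` demonstrates one capability. For instance:

```sh
python examples/04_psychophysics.py
```

prints

```
QUEST: true 75%-point 0.1072, estimate 0.1087 (1.4% off); accuracy at estimate over 720 trials: 75.8%
3-down-1-up: long-run accuracy 0.796 (theoretical convergence point 0.5^(1/3) = 0.794)
matching: 2 hits, 0 misses, 0 FAs, 1 CRs, 1 unpaired (discarded)
d' (log-linear) for 45/50 hits vs 5/50 FAs: 2.48
d' stays finite even at ceiling: 4.67
```

The first line shows QUEST recovering a simulated observer's 75%-correct
contrast (the estimate is within a few percent, and a 720-trial main session
run at that contrast lands near 75% correct, as the thresholding procedure
intends). The staircase line verifies the 3-down-1-up convergence point;
the matching/d′ lines score a continuous-report trial where responses within
the 1 s window after an event count toward hits or false alarms and
responses matching no event are discarded.

`examples/03_attention_index.py` runs the EEG side end to end: it injects a
known attentional gain (g = 1.5) into synthetic sessions and recovers
attention indices above 1 at attended locations under both baselining
schemes; `examples/05_group_summary.py` aggregates several simulated
participants into condition means ± within-subject SE.

## Scope

The pipeline analyzes synthetic data only; it does not consume real EEG
recordings, and deliberately omits recording-specific steps (ICA artifact
correction, channel interpolation) and the inferential layer (ANOVA, Bayes
factors) — the tidy tables it emits feed any standard stats package. See
`docs/methods.md` for the model, parameter choices and limitations.
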