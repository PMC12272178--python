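"""Synthesize a tagged-EEG session and quantify SSVEP signal-to-noise.

Generates an Experiment 2 session in which attending a location multiplies
its steady-state amplitude by 1.5, runs the spectral chain (average
reference, FIR filters, baseline, detrend, condition averages, FFT power,
median-filter noise floor) and prints the peak SNR at each tag frequency.
An SNR well above 1 at the attended tag and near its unattended level
elsewhere is the frequency-tagging signature the analysis relies on.
"""

import numpy as np

from tagattn.design import build_session
from tagattn.pipeline import default_sources, exp2_peaks
from tagattn.synth_eeg import AttentionProfile, NoiseSpec, synth_session

design = build_session("exp2", 160, seed=3)
sources = default_sources([10.91, 12.0, 13.33], base_amplitude=0.25)
profiles = {
    "narrow_innermost": AttentionProfile({"innermost": 1.5}),
    "narrow_intermediate": AttentionProfile({"intermediate": 1.5}),
    "split": AttentionProfile({"innermost": 1.5, "outermost": 1.5}),
    "broad": AttentionProfile({l: 1.5 for l in ("innermost", "intermediate", "outermost")}),
}
epochs = synth_session(design, sources, profiles, NoiseSpec(alpha=1.0, noise_scale=10.0),
                       seed=3)
print(f"EpochSet: {epochs.n_trials} trials x {len(epochs.ch_names)} channels x "
      f"{epochs.data.shape[2]} samples at {epochs.srate:.0f} Hz")

peaks = exp2_peaks(epochs)
print("\npeak cluster SNR per condition and tag frequency:")
print(peaks.pivot(index="condition", columns="freq", values="snr").round(2).to_string())
print("\nEach row is one cue condition's evoked average; columns are the tag"
      "\nfrequencies (Hz). All tags sit well above the SNR = 1 noise floor;"
      "\nattended-location SNRs are elevated on average, though a single"
      "\n40-trial-per-condition session carries sizeable Monte-Carlo noise.")
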