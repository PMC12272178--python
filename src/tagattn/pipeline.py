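"""End-to-end glue: synthetic session -> SNR peaks -> attention indices.

These helpers wire the module chain together the way the analyses consume
it: condition-wise evoked averages, cluster SNR spectra, per-frequency peak
extraction, and the peaks tables expected by :func:`tagattn.attn_index.ai_exp2`
and :func:`ai_exp3`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .attn_index import ai_exp2, ai_exp3
from .design import build_session
from .spectral import PreprocConfig, snr_peak, spectrum_table
from .synth_eeg import AttentionProfile, NoiseSpec, TagSourceSpec, synth_session

__all__ = [
    "exp2_peaks",
    "exp3_peaks",
    "default_sources",
    "simulate_participant_ai",
]

_EXP2_TAGS = (10.91, 12.0, 13.33)
_LOW_BAND = frozenset({7.06, 8.0, 9.23})
_HIGH_BAND = frozenset({10.91, 12.0, 13.33})


def default_sources(freqs, base_amplitude: float = 1.0,
                    harmonic_ratios=(0.3,)) -> dict:
    """Display-frequency -> TagSourceSpec map with the default topography."""
    return {round(float(f), 2): TagSourceSpec(freq=round(float(f), 2),
                                              base_amplitude=base_amplitude,
                                              harmonic_ratios=tuple(harmonic_ratios))
            for f in freqs}


def exp2_peaks(epochs, cfg: PreprocConfig = None,
               search_halfwidth: float = 0.24, **spectrum_kw) -> pd.DataFrame:
    """Peak cluster SNR per (condition, tag frequency) for an Exp 2 session.

    Conditions are the four cue conditions in the epoch metadata ``focus``
    column; each condition's evoked average yields one SNR spectrum, and the
    peak within +-0.24 Hz of each tag frequency is extracted.
    """
    spec = spectrum_table(epochs, "focus", cfg, **spectrum_kw)
    rows = []
    for cond, g in spec.groupby("focus"):
        freqs, snr = g["freq"].to_numpy(), g["snr"].to_numpy()
        for f in _EXP2_TAGS:
            pk = snr_peak(freqs, snr, f, search_halfwidth)
            rows.append({"condition": cond, "freq": f, "snr": pk.peak_snr,
                         "peak_freq": pk.peak_freq})
    return pd.DataFrame(rows)


def _attended_band(row) -> str:
    return "low" if round(row["freq_innermost"], 2) in _LOW_BAND else "high"


def exp3_peaks(epochs, cfg: PreprocConfig = None,
               search_halfwidth: float = 0.24, **spectrum_kw) -> pd.DataFrame:
    """Peak cluster SNR per (focus, frequency, attended flag) for Exp 3.

    Trials are collapsed across cued sides by grouping on (focus, attended
    frequency band): a trial whose cued hemifield carries the low triplet
    (7.06/8/9.23 Hz) is an attended-low trial regardless of side. Each
    frequency is then "attended" in the cells whose band contains it and
    "unattended" in the complementary cells.
    """
    epochs = epochs.copy()
    epochs.metadata = epochs.metadata.copy()
    epochs.metadata["attended_band"] = epochs.metadata.apply(_attended_band, axis=1)
    spec = spectrum_table(epochs, ["focus", "attended_band"], cfg, **spectrum_kw)
    rows = []
    for (focus, band), g in spec.groupby(["focus", "attended_band"]):
        freqs, snr = g["freq"].to_numpy(), g["snr"].to_numpy()
        members = _LOW_BAND if band == "low" else _HIGH_BAND
        for f in sorted(_LOW_BAND | _HIGH_BAND):
            pk = snr_peak(freqs, snr, f, search_halfwidth)
            rows.append({"focus": focus, "freq": f, "attended": f in members,
                         "snr": pk.peak_snr, "peak_freq": pk.peak_freq})
    return pd.DataFrame(rows)


def simulate_participant_ai(experiment: str, n_trials: int, gain: float,
                            seed, noise_scale: float = 10.0,
                            base_amplitude: float = 0.25,
                            collapse: bool = True) -> pd.DataFrame:
    """One simulated participant, design through attention indices.

    Injects a uniform attentional gain ``gain`` at all attended locations
    (gain 1 = the null), synthesizes the session at the default amplitude
    and 1/f noise level, runs the spectral pipeline and returns the ai table
    for the requested scheme (exp2 or exp3).
    """
    rng = np.random.default_rng(seed)
    design = build_session(experiment, n_trials, rng)
    freq_cols = [c for c in design.trials.columns if c.startswith("freq_")]
    freqs = sorted(set(np.round(design.trials[freq_cols].to_numpy().ravel(), 2)))
    sources = default_sources(freqs, base_amplitude)
    noise = NoiseSpec(alpha=1.0, noise_scale=noise_scale)
    if experiment == "exp2":
        profiles = {
            "narrow_innermost": AttentionProfile({"innermost": gain}),
            "narrow_intermediate": AttentionProfile({"intermediate": gain}),
            "split": AttentionProfile({"innermost": gain, "outermost": gain}),
            "broad": AttentionProfile({l: gain for l in
                                       ("innermost", "intermediate", "outermost")}),
        }
    elif experiment == "exp3":
        profiles = {
            "split": AttentionProfile({"innermost": gain, "outermost": gain}),
            "broad": AttentionProfile({l: gain for l in
                                       ("innermost", "intermediate", "outermost")}),
        }
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    epochs = synth_session(design, sources, profiles, noise, rng)
    if experiment == "exp2":
        return ai_exp2(exp2_peaks(epochs))
    return ai_exp3(exp3_peaks(epochs), collapse=collapse)
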