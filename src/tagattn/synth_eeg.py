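"""Synthetic frequency-tagged EEG for end-to-end pipeline validation.

Each trial is a sum of steady-state sinusoidal sources — one per tagged
display location, at its flicker frequency, optionally with harmonics —
projected to the scalp through a fixed per-channel topography and scaled by a
per-location attentional gain, plus 1/f^alpha background noise synthesized in
the frequency domain. The oscillation starts at flicker onset (t = 0) and is
absent during the pre-stimulus baseline, mimicking evoked steady-state
responses. Absolute amplitudes are conventional (the downstream analysis is
SNR-based and scale-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .design import LOCATIONS, SessionDesign

__all__ = [
    "CHANNELS_30",
    "OCCIPITOPARIETAL_15",
    "TagSourceSpec",
    "AttentionProfile",
    "NoiseSpec",
    "EpochSet",
    "default_topography",
    "pink_noise",
    "synth_trial",
    "synth_session",
]

#: Default 30-channel scalp montage: modified 10-20 with three frontocentral
#: positions re-deployed below the occiput as I3/Iz/I4 for denser posterior
#: sampling.
CHANNELS_30 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8", "CP1", "CP2",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "I3", "Iz", "I4",
)

#: The 15 occipitoparietal electrodes used for SSVEP quantification.
OCCIPITOPARIETAL_15 = (
    "I3", "Iz", "I4", "O2", "Oz", "O1", "PO7", "PO3", "POz", "PO4", "PO8",
    "P8", "P4", "P3", "P7",
)

_POSTERIOR_WEIGHTS = {"I": 1.0, "O": 1.0, "PO": 0.8, "P": 0.5, "CP": 0.2,
                      "C": 0.1, "T": 0.1, "F": 0.05, "Fp": 0.02}


def default_topography(channels=CHANNELS_30) -> np.ndarray:
    """Posterior-weighted unit-max topography, keyed by 10-20 name prefix."""
    w = []
    for ch in channels:
        for prefix in sorted(_POSTERIOR_WEIGHTS, key=len, reverse=True):
            if ch.startswith(prefix):
                w.append(_POSTERIOR_WEIGHTS[prefix])
                break
        else:
            w.append(0.1)
    w = np.asarray(w, float)
    return w / w.max()


@dataclass(frozen=True)
class TagSourceSpec:
    """One tagged location's steady-state source."""

    freq: float  # Hz
    location: str = None  # within-hemifield label the gain profile keys on
    base_amplitude: float = 1.0  # uV at the max-weight channel
    harmonic_ratios: tuple = (0.3,)  # relative amplitudes of harmonics 2..H
    phase: float = 0.0  # radians
    topography: np.ndarray = None  # per-channel weights, unit max

    def __post_init__(self):
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if self.topography is not None:
            w = np.asarray(self.topography, float)
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError("topography weights must lie in [0, 1]")


@dataclass(frozen=True)
class AttentionProfile:
    """Multiplicative amplitude gain per attended location; g = 1 means no
    attentional modulation. Unlisted locations default to 1."""

    gains: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("gains must be >= 0")

    def gain(self, location) -> float:
        return float(self.gains.get(location, 1.0))


@dataclass(frozen=True)
class NoiseSpec:
    """1/f^alpha background-noise parameters."""

    alpha: float = 1.0  # spectral exponent
    noise_scale: float = 1.0  # uV RMS per channel
    per_channel_independent: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


@dataclass
class EpochSet:
    """Trials x channels x samples container with trial metadata.

    ``t0`` is the time of the first sample relative to flicker onset
    (negative: baseline included). Persisted as an HDF5 array with attributes
    plus an embedded TSV of the metadata table (layout version 1).
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples), uV
    srate: float  # Hz
    t0: float  # s relative to flicker onset
    ch_names: tuple
    metadata: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata row count must equal trial count")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.srate

    def copy(self, data=None, metadata=None) -> "EpochSet":
        return EpochSet(
            self.data.copy() if data is None else data, self.srate, self.t0,
            tuple(self.ch_names),
            self.metadata.copy() if metadata is None else metadata.reset_index(drop=True),
        )

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return self.copy(data=self.data[mask],
                         metadata=self.metadata.loc[mask].reset_index(drop=True))

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.attrs["layout_version"] = 1
            f.attrs["srate"] = self.srate
            f.attrs["t0"] = self.t0
            f.attrs["ch_names"] = list(self.ch_names)
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset(
                "metadata_tsv",
                data=self.metadata.to_csv(sep="\t", index=False).encode(),
            )

    @classmethod
    def load(cls, path) -> "EpochSet":
        import io

        with h5py.File(path, "r") as f:
            meta = pd.read_csv(io.BytesIO(f["metadata_tsv"][()]), sep="\t")
            if meta.shape[1] == 0 and f["data"].shape[0] == 0:
                meta = pd.DataFrame(index=range(0))
            return cls(f["data"][()], float(f.attrs["srate"]), float(f.attrs["t0"]),
                       tuple(s if isinstance(s, str) else s.decode()
                             for s in f.attrs["ch_names"]), meta)


# ---------------------------------------------------------------------------
# noise


def pink_noise(n_samples: int, srate: float, spec: NoiseSpec, rng) -> np.ndarray:
    """One channel of 1/f^alpha noise, synthesized in the frequency domain
    with random phases and normalized to the requested RMS."""
    freqs = np.fft.rfftfreq(n_samples, 1 / srate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-spec.alpha / 2)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n_samples)
    sd = x.std()
    return x / sd * spec.noise_scale if sd > 0 else x


# ---------------------------------------------------------------------------
# trial and session synthesis


def synth_trial(sources, profile: AttentionProfile, noise: NoiseSpec,
                duration: float, srate: float = 500.0, seed=None,
                t0: float = -0.1, n_channels: int = None) -> np.ndarray:
    """One synthetic trial: channels x samples.

    The steady-state oscillation of every source starts at t = 0 (flicker
    onset) and is absent before; 1/f noise spans the whole epoch. Each
    source contributes  g * A * [sin(2 pi f t + phi) + sum_k r_k sin(2 pi k f
    t + k phi)]  through its topography, with g the profile gain at the
    source's location.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_channels = n_channels or len(CHANNELS_30)
    n_samples = int(round((duration - t0) * srate))
    t = t0 + np.arange(n_samples) / srate
    active = t >= 0
    out = np.zeros((n_channels, n_samples))
    for src in sources:
        if src.freq >= srate / 2:
            raise ValueError(f"tag frequency {src.freq} Hz at or above Nyquist")
        topo = (np.asarray(src.topography, float) if src.topography is not None
                else default_topography(CHANNELS_30[:n_channels]))
        g = profile.gain(src.location)
        wave = np.sin(2 * np.pi * src.freq * t + src.phase)
        for k, ratio in enumerate(src.harmonic_ratios, start=2):
            wave = wave + ratio * np.sin(2 * np.pi * k * src.freq * t + k * src.phase)
        wave = wave * active
        out += g * src.base_amplitude * topo[:, None] * wave[None, :]
    if noise is not None:
        for ch in range(n_channels):
            out[ch] += pink_noise(n_samples, srate, noise, rng)
    return out


def _trial_sources(row, sources_by_freq, experiment):
    """Per-trial (source, location-for-gain) list from a design row.

    Attended-side sources carry the trial's location labels (so the focus
    condition's gain profile applies); Experiment 3 additionally includes the
    uncued side's three frequencies at gain 1 (location label None).
    """
    out = []
    for loc in LOCATIONS:
        f = row[f"freq_{loc}"]
        src = sources_by_freq.get(f)
        if src is None:
            raise ValueError(f"design frequency {f} Hz missing from sources")
        out.append(replace(src, location=loc))
    if experiment == "exp3":
        for loc in LOCATIONS:
            f = row[f"freq_{loc}_uncued"]
            src = sources_by_freq.get(f)
            if src is None:
                raise ValueError(f"design frequency {f} Hz missing from sources")
            out.append(replace(src, location=None))
    return out


def synth_session(design: SessionDesign, sources_by_freq: dict,
                  profiles: dict, noise: NoiseSpec, seed,
                  srate: float = 500.0, t0: float = -0.1,
                  epoch_end: float = 4.0) -> EpochSet:
    """Synthesize an EpochSet for every trial of a session design.

    ``sources_by_freq`` maps display frequency (2-decimal Hz, as in the
    design table) to a :class:`TagSourceSpec` template; ``profiles`` maps
    focus-condition label to an :class:`AttentionProfile` applied to the
    attended side's locations. Epochs span [t0, epoch_end] s around flicker
    onset regardless of the (jittered) trial duration, matching the analysis
    epoch. Only attended locations receive their condition's gain; in
    Experiment 3 the uncued hemifield flickers too, at gain 1.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_samples = int(round((epoch_end - t0) * srate))
    n_tr = design.n_trials
    data = np.zeros((n_tr, len(CHANNELS_30), n_samples))
    for i, (_, row) in enumerate(design.trials.iterrows()):
        profile = profiles.get(row["focus"], AttentionProfile())
        srcs = _trial_sources(row, sources_by_freq, design.experiment)
        data[i] = synth_trial(srcs, profile, noise, epoch_end, srate, rng, t0=t0)
    return EpochSet(data, srate, t0, CHANNELS_30, design.trials.reset_index(drop=True))
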