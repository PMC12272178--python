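"""Preprocessing and spectral SSVEP quantification.

The analysis chain: average-reference, zero-phase FIR band filtering,
baseline subtraction and linear detrend per trial and channel; time-domain
averaging per condition (preserving the phase-locked steady-state signal);
FFT power over the post-onset analysis window; a sliding-median noise floor
(+-1 bin) whose ratio to the raw power is the spectral SNR; a +-0.24 Hz peak
search around each tag frequency; and averaging of SNR spectra over a fixed
occipitoparietal electrode cluster.

A note on bin width: a [0.15, 4.0) s analysis window at 500 Hz holds 3.85 s
of signal, so the FFT grid spacing is 1/3.85 ~ 0.2597 Hz. The median-filter
kernel is specified in bins (+-1 bin primary); the peak-search half-width is
an independent parameter in Hz (0.24 Hz default). Zero-padding to a finer
grid is available via ``pad_to`` but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .synth_eeg import OCCIPITOPARIETAL_15, EpochSet

__all__ = [
    "PreprocConfig",
    "PeakResult",
    "preprocess",
    "evoked_average",
    "fft_power",
    "noise_floor",
    "snr_spectrum",
    "snr_peak",
    "cluster_average",
    "spectrum_table",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters.

    ``highpass``/``lowpass`` are FIR cutoff frequencies (Hz); the reference
    is the instantaneous average across all channels; baseline is the mean
    over ``baseline_window``; detrending is linear over the whole epoch.
    """

    highpass: float = 0.1
    lowpass: float = 70.0
    reference: str = "average"
    baseline_window: tuple = (-0.1, 0.0)
    detrend: str = "linear"
    analysis_window: tuple = (0.15, 4.0)

    def validate(self, srate):
        if not 0 < self.highpass < self.lowpass < srate / 2:
            raise ValueError("need 0 < highpass < lowpass < Nyquist")


def _window_slice(times, window, half_open=False):
    lo, hi = window
    eps = 1e-9
    if half_open:
        mask = (times >= lo - eps) & (times < hi - eps)
    else:
        mask = (times >= lo - eps) & (times <= hi + eps)
    if not mask.any():
        raise ValueError(f"window {window} outside the epoch span "
                         f"[{times[0]:.3f}, {times[-1]:.3f}]")
    return mask


def _fir_taps(cutoff, srate, n_samples, pass_zero):
    """Windowed-sinc FIR taps with a transition-width rule, capped so
    zero-phase application remains valid on short epochs."""
    trans = max(min(cutoff * 0.25, 2.0), 0.25)  # Hz
    ntaps = int(3.3 * srate / trans) | 1
    cap = (n_samples // 3 - 1) | 1
    ntaps = min(ntaps, max(cap, 5))
    return scipy.signal.firwin(ntaps, cutoff, fs=srate, pass_zero=pass_zero,
                               window="hamming")


def _zero_phase(data: np.ndarray, *tap_sets: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering (squared magnitude response, zero
    phase) of one or more cascaded kernels, applied in the frequency domain.
    Epochs are odd-reflection padded at both ends to tame edge transients."""
    n = data.shape[-1]
    max_taps = max(len(t) for t in tap_sets)
    pad = min(max_taps, n - 1)
    left = 2 * data[..., :1] - data[..., pad:0:-1]
    right = 2 * data[..., -1:] - data[..., -2:-pad - 2:-1]
    ext = np.concatenate([left, data, right], axis=-1)
    nfft = scipy.fft.next_fast_len(ext.shape[-1] + 2 * max_taps)
    resp = np.ones(nfft // 2 + 1)
    for taps in tap_sets:
        resp *= np.abs(np.fft.rfft(taps, nfft)) ** 2
    out = np.fft.irfft(np.fft.rfft(ext, nfft, axis=-1) * resp, nfft, axis=-1)
    return out[..., pad:pad + n]


def preprocess(epochs: EpochSet, cfg: PreprocConfig = PreprocConfig()) -> EpochSet:
    """Average-reference, FIR band filter, baseline-subtract and detrend.

    Steps run in that order, per trial and channel; the filters are
    linear-phase windowed-sinc kernels applied forward-backward (zero phase).
    Metadata is preserved unchanged.
    """
    cfg.validate(epochs.srate)
    times = epochs.times
    bl_mask = _window_slice(times, cfg.baseline_window)
    data = epochs.data.copy()

    if cfg.reference == "average":
        data -= data.mean(axis=1, keepdims=True)
    elif cfg.reference is not None:
        raise ValueError(f"unsupported reference {cfg.reference!r}")

    n = data.shape[2]
    hp = _fir_taps(cfg.highpass, epochs.srate, n, pass_zero=False)
    lp = _fir_taps(cfg.lowpass, epochs.srate, n, pass_zero=True)
    data = _zero_phase(data, hp, lp)

    data -= data[:, :, bl_mask].mean(axis=2, keepdims=True)
    data = scipy.signal.detrend(data, axis=2, type="linear")
    return epochs.copy(data=data)


def evoked_average(epochs: EpochSet, group_by) -> EpochSet:
    """Time-domain average per condition cell (one output epoch per cell).

    Averaging before the FFT preserves the phase-locked steady-state response
    while incoherent activity shrinks ~ 1/sqrt(n). Group sizes are recorded
    in an ``n_trials`` metadata column.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    if epochs.n_trials == 0:
        raise ValueError("cannot average an empty EpochSet")
    meta_rows, out = [], []
    for keys, idx in epochs.metadata.groupby(list(group_by), sort=True).groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty condition cell {keys!r}")
        keys = keys if isinstance(keys, tuple) else (keys,)
        out.append(epochs.data[np.asarray(idx)].mean(axis=0))
        meta_rows.append(dict(zip(group_by, keys), n_trials=len(idx)))
    return EpochSet(np.stack(out), epochs.srate, epochs.t0, tuple(epochs.ch_names),
                    pd.DataFrame(meta_rows))


def fft_power(signal: np.ndarray, srate: float, t0: float = 0.0,
              window: tuple = (0.15, 4.0), pad_to: int = None):
    """FFT power over the analysis window.

    The window is half-open [lo, hi), un-tapered and un-padded by default, so
    the grid spacing is 1/window_length. Power is the squared one-sided
    amplitude spectrum (2|X_k|/n, not doubled at DC/Nyquist); SNR downstream
    is invariant to this normalization.

    Returns (freqs, power); ``signal`` may have any leading shape with time
    last.
    """
    signal = np.asarray(signal, float)
    times = t0 + np.arange(signal.shape[-1]) / srate
    mask = _window_slice(times, window, half_open=True)
    x = signal[..., mask]
    n = x.shape[-1]
    if n == 0:
        raise ValueError("empty analysis window")
    nfft = n if pad_to is None else max(pad_to, n)
    spec = np.fft.rfft(x, n=nfft, axis=-1)
    freqs = np.fft.rfftfreq(nfft, 1 / srate)
    amp = 2 * np.abs(spec) / n
    amp[..., 0] /= 2
    if nfft % 2 == 0:
        amp[..., -1] /= 2
    return freqs, amp ** 2


def noise_floor(power: np.ndarray, halfwidth_bins: int = 1) -> np.ndarray:
    """Sliding-median noise floor across frequency bins.

    Window of 2*halfwidth+1 bins centered on each bin (center included);
    edge bins use the shrunken available window. Because a steady-state
    peak occupies a single bin, the median over 3 bins excludes it — the
    floor tracks broadband background without peak spill-over.
    """
    power = np.asarray(power, float)
    h = int(halfwidth_bins)
    if h < 1:
        raise ValueError("halfwidth_bins must be >= 1")
    n = power.shape[-1]
    if n < 2 * h + 1:
        raise ValueError("spectrum shorter than the median kernel")
    out = np.empty_like(power)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[..., i] = np.median(power[..., lo:hi], axis=-1)
    return out


def snr_spectrum(power: np.ndarray, halfwidth_bins: int = 1):
    """SNR per bin: power divided by the sliding-median noise floor."""
    floor = noise_floor(power, halfwidth_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(floor > 0, power / floor, np.nan)
    return snr, floor


@dataclass(frozen=True)
class PeakResult:
    target_freq: float
    search_halfwidth: float
    peak_freq: float
    peak_snr: float


def snr_peak(freqs: np.ndarray, snr: np.ndarray, target_freq: float,
             search_halfwidth: float = 0.24) -> PeakResult:
    """Maximum SNR within +-search_halfwidth of a tag frequency.

    If no bin center falls inside the window (possible when the grid spacing
    exceeds twice the half-width) the nearest bin is used, provided it lies
    within one bin spacing of the target; otherwise the request is rejected.
    """
    freqs = np.asarray(freqs, float)
    snr = np.asarray(snr, float)
    in_win = np.abs(freqs - target_freq) <= search_halfwidth + 1e-12
    if not in_win.any():
        spacing = np.median(np.diff(freqs))
        nearest = int(np.argmin(np.abs(freqs - target_freq)))
        if abs(freqs[nearest] - target_freq) > spacing:
            raise ValueError(
                f"no frequency bin within {search_halfwidth} Hz of {target_freq} Hz")
        in_win = np.zeros_like(in_win)
        in_win[nearest] = True
    idx = np.flatnonzero(in_win)
    best = idx[np.argmax(snr[idx])]
    return PeakResult(float(target_freq), float(search_halfwidth),
                      float(freqs[best]), float(snr[best]))


def cluster_average(snr_by_channel: np.ndarray, ch_names,
                    cluster=OCCIPITOPARIETAL_15) -> np.ndarray:
    """Mean SNR spectrum over a named electrode cluster.

    SNR is computed per channel first and then averaged (SNR is scale-free
    per channel, so channel-gain differences do not bias the cluster mean).
    """
    ch_names = list(ch_names)
    missing = [c for c in cluster if c not in ch_names]
    if missing:
        raise ValueError(f"cluster channels missing from data: {missing}")
    idx = [ch_names.index(c) for c in cluster]
    return np.asarray(snr_by_channel)[..., idx, :].mean(axis=-2)


def spectrum_table(epochs: EpochSet, group_by, cfg: PreprocConfig = None,
                   cluster=OCCIPITOPARIETAL_15, halfwidth_bins: int = 1,
                   average_power_first: bool = False,
                   preprocessed: bool = False) -> pd.DataFrame:
    """Full chain: (preprocess ->) condition averages -> power -> SNR ->
    cluster mean, as a tidy table.

    One row per condition cell and frequency bin, with columns ``power``
    (cluster-mean power), ``noise_floor``, ``snr`` and the grouping keys.
    ``average_power_first=True`` averages power across the cluster before
    forming SNR instead of averaging per-channel SNR spectra (the default).
    """
    cfg = cfg or PreprocConfig()
    if not preprocessed:
        epochs = preprocess(epochs, cfg)
    ev = evoked_average(epochs, group_by)
    freqs, power = fft_power(ev.data, ev.srate, ev.t0, cfg.analysis_window)
    if average_power_first:
        ch = list(ev.ch_names)
        idx = [ch.index(c) for c in cluster]
        pw = power[:, idx, :].mean(axis=1)
        snr, floor = snr_spectrum(pw, halfwidth_bins)
    else:
        snr_ch, floor_ch = snr_spectrum(power, halfwidth_bins)
        snr = cluster_average(snr_ch, ev.ch_names, cluster)
        floor = cluster_average(floor_ch, ev.ch_names, cluster)
        ch = list(ev.ch_names)
        idx = [ch.index(c) for c in cluster]
        pw = power[:, idx, :].mean(axis=1)
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    rows = []
    for i, (_, meta) in enumerate(ev.metadata.iterrows()):
        cell = {k: meta[k] for k in group_by}
        cell["n_trials"] = meta["n_trials"]
        for j, f in enumerate(freqs):
            rows.append(dict(cell, freq=f, power=pw[i, j],
                             noise_floor=floor[i, j], snr=snr[i, j]))
    out = pd.DataFrame(rows)
    out.attrs["bin_width"] = float(freqs[1] - freqs[0])
    return out
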