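"""Attention indices from peak SSVEP SNRs.

Two baselining schemes quantify the attentional modulation of a tagged
frequency as a dimensionless index (ai), with ai = 1 meaning no modulation:

- Experiment 2 (cross-condition baseline): the narrow-focus condition serves
  as a fixed baseline for every condition. For probe frequency f,

      ai(f | focus) = SNR(f | focus, f attended)
                      / mean(SNR(f | narrow, f attended),
                             SNR(f | narrow, f unattended))

  Only 10.91 and 12 Hz are analyzable — the outermost location (13.33 Hz)
  was never cued narrowly, so it has no baseline.

- Experiment 3 (within-condition baseline): for each focus condition and
  frequency, with trials collapsed across left/right sides,

      ai(f | focus) = SNR_att / mean(SNR_att, SNR_unatt)

  where SNR_unatt is the same frequency measured when it tagged the uncued
  hemifield. Frequency pairs then collapse to locations: 9.23 & 10.91 Hz ->
  innermost, 8 & 12 Hz -> intermediate, 7.06 & 13.33 Hz -> outermost.

Both forms are a ratio of a value to a mean that includes it, so ai is
bounded in (0, 2) and ai(a, b) + ai(b, a) = 2 exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FREQ_TO_LOCATION",
    "attention_index",
    "ai_exp2",
    "ai_exp3",
]

#: Display frequency -> within-hemifield location (Experiment 3 collapse map).
FREQ_TO_LOCATION = {
    9.23: "innermost", 10.91: "innermost",
    8.0: "intermediate", 12.0: "intermediate",
    7.06: "outermost", 13.33: "outermost",
}

#: Experiment 2 narrow-focus condition attending each analyzable frequency.
_NARROW_OF = {10.91: "narrow_innermost", 12.0: "narrow_intermediate"}


def attention_index(snr_attended: float, *baseline_components: float) -> float:
    """ai = attended SNR / mean(baseline components)."""
    base = float(np.mean(baseline_components))
    if base <= 0:
        raise ValueError("baseline SNR must be positive")
    return float(snr_attended) / base


def ai_exp2(peaks: pd.DataFrame) -> pd.DataFrame:
    """Cross-condition (narrow-baseline) attention indices.

    ``peaks`` is tidy with columns ``condition`` (narrow_innermost,
    narrow_intermediate, split, broad), ``freq`` (display Hz) and ``snr``
    (peak SNR of that frequency in that condition), optionally
    ``participant``. Rows for 13.33 Hz are ignored; explicitly requesting it
    is an error. Returns one row per condition x analyzable frequency with
    the ai and the baseline components it was derived from.
    """
    required = {"condition", "freq", "snr"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peaks table needs columns {sorted(required)}")
    if (~np.isin(np.round(peaks["freq"], 2), [10.91, 12.0, 13.33])).any():
        raise ValueError("exp2 peaks may only contain 10.91, 12 and 13.33 Hz")
    groups = [("participant", g) for _, g in peaks.groupby("participant")] \
        if "participant" in peaks.columns else [(None, peaks)]
    rows = []
    for _, g in groups:
        lut = {(r["condition"], round(r["freq"], 2)): r["snr"] for _, r in g.iterrows()}
        for (cond, f), snr_att in sorted(lut.items()):
            f = round(f, 2)
            if f == 13.33:
                continue  # never cued narrowly; no baseline exists
            if cond not in ("split", "broad") and cond != _NARROW_OF[f]:
                continue  # f is unattended in this condition
            own, other = _NARROW_OF[f], _NARROW_OF[12.0 if f == 10.91 else 10.91]
            for c in (own, other):
                if (c, f) not in lut:
                    raise ValueError(f"missing narrow baseline cell ({c}, {f} Hz)")
            b_att, b_unatt = lut[(own, f)], lut[(other, f)]
            row = {
                "condition": cond, "freq": f,
                "location": FREQ_TO_LOCATION[f],
                "snr_attended": snr_att,
                "snr_baseline_attended": b_att,
                "snr_baseline_unattended": b_unatt,
                "ai": attention_index(snr_att, b_att, b_unatt),
            }
            if "participant" in g.columns:
                row["participant"] = g["participant"].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)


def request_exp2_freq(freq: float):
    """Guard for per-frequency queries; 13.33 Hz has no narrow baseline."""
    if round(freq, 2) == 13.33:
        raise ValueError(
            "13.33 Hz (outermost) was never cued in a narrow-focus condition "
            "and is not analyzed further")
    if round(freq, 2) not in _NARROW_OF:
        raise ValueError(f"{freq} Hz is not an Experiment 2 tag frequency")


def ai_exp3(peaks: pd.DataFrame, collapse: bool = True) -> pd.DataFrame:
    """Within-condition attention indices with frequency->location collapse.

    ``peaks`` is tidy with columns ``focus``, ``freq`` (display Hz),
    ``attended`` (bool) and ``snr``, optionally ``participant``; attended and
    unattended cells must both be present for every (focus, freq). Returns
    per-frequency ais and, when ``collapse`` is set, the per-location means
    over the fixed frequency pairs in a second table.
    """
    required = {"focus", "freq", "attended", "snr"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peaks table needs columns {sorted(required)}")
    groups = [g for _, g in peaks.groupby("participant")] \
        if "participant" in peaks.columns else [peaks]
    rows = []
    for g in groups:
        for (focus, f), cell in g.groupby(["focus", "freq"]):
            f = round(float(f), 2)
            att = cell[cell["attended"].astype(bool)]
            unatt = cell[~cell["attended"].astype(bool)]
            if len(att) != 1 or len(unatt) != 1:
                raise ValueError(
                    f"need exactly one attended and one unattended cell for "
                    f"({focus}, {f} Hz); got {len(att)}/{len(unatt)}")
            a, u = float(att["snr"].iloc[0]), float(unatt["snr"].iloc[0])
            row = {
                "focus": focus, "freq": f, "location": FREQ_TO_LOCATION[f],
                "snr_attended": a, "snr_unattended": u,
                "ai": attention_index(a, a, u),
            }
            if "participant" in g.columns:
                row["participant"] = g["participant"].iloc[0]
            rows.append(row)
    per_freq = pd.DataFrame(rows)
    if not collapse:
        return per_freq
    keys = [k for k in ("participant", "focus", "location") if k in per_freq.columns]
    per_loc = (per_freq.groupby(keys, as_index=False)
               .agg(ai=("ai", "mean"), n_freqs=("freq", "nunique")))
    return per_loc
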