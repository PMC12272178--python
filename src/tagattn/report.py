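"""Group-level summaries: condition means, within-subject SE, simple figures.

The error bars appropriate for repeated-measures contrasts remove
between-participant level differences first (Cousineau normalization:
subtract each participant's mean, add back the grand mean) and then rescale
by sqrt(J/(J-1)) for J conditions (Morey's correction for the variance
deflation the normalization induces). The grand mean is untouched by the
normalization, so summary means equal plain participant means.

Inferential statistics are deliberately not re-implemented here; the tidy
tables this module emits feed any standard stats package.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["within_subject_se", "make_summary"]


def _to_wide(df: pd.DataFrame, participant: str, condition, value: str) -> pd.DataFrame:
    condition = [condition] if isinstance(condition, str) else list(condition)
    wide = df.pivot_table(index=participant, columns=condition, values=value,
                          aggfunc="mean")
    if wide.isna().any().any():
        missing = [(p, c) for p in wide.index for c in wide.columns
                   if pd.isna(wide.loc[p, c])]
        raise ValueError(f"missing participant x condition cells: {missing[:5]}")
    return wide


def within_subject_se(df: pd.DataFrame, participant: str = "participant",
                      condition="condition", value: str = "value",
                      morey: bool = True) -> pd.Series:
    """Per-condition within-subject standard error (Cousineau, Morey-corrected).

    Requires a complete participant x condition table with >= 2 participants
    and >= 2 conditions (the correction is undefined for a single condition).
    """
    wide = _to_wide(df, participant, condition, value)
    n, J = wide.shape
    if J < 2:
        raise ValueError("within-subject SE needs >= 2 conditions")
    if n < 2:
        raise ValueError("within-subject SE needs >= 2 participants")
    normalized = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    se = normalized.std(axis=0, ddof=1) / math.sqrt(n)
    if morey:
        se = se * math.sqrt(J / (J - 1))
    se.name = "within_subject_se"
    return se


def make_summary(df: pd.DataFrame, participant: str = "participant",
                 condition="condition", value: str = "value",
                 morey: bool = True, plot_path=None) -> pd.DataFrame:
    """Condition means with within-subject SEs, one row per cell.

    Participants must share the same condition set. When ``plot_path`` is
    given, a bar chart of mean +- 1 within-subject SE is written there
    (deterministic for identical inputs).
    """
    cond_cols = [condition] if isinstance(condition, str) else list(condition)
    sets = df.groupby(participant)[cond_cols].apply(
        lambda g: frozenset(map(tuple, g.drop_duplicates().to_numpy())))
    if sets.nunique() != 1:
        raise ValueError("participants have inconsistent condition sets")
    wide = _to_wide(df, participant, condition, value)
    means = wide.mean(axis=0)
    out = means.rename("mean").reset_index()
    out["n"] = wide.shape[0]
    if wide.shape[1] >= 2 and wide.shape[0] >= 2:
        se = within_subject_se(df, participant, condition, value, morey)
        out = out.merge(se.reset_index(), on=cond_cols)
    else:
        out["within_subject_se"] = np.nan
    if plot_path is not None:
        _plot_summary(out, cond_cols, plot_path)
    return out


def _plot_summary(summary: pd.DataFrame, cond_cols, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = summary[cond_cols].astype(str).agg(" / ".join, axis=1)
    fig, ax = plt.subplots(figsize=(1.2 * len(summary) + 2, 4))
    ax.bar(labels, summary["mean"],
           yerr=summary["within_subject_se"].fillna(0), capsize=4,
           color="#4878A8")
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_ylabel("mean ± 1 within-subject SE")
    fig.autofmt_xdate(rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
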