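"""Minimal diagnostic plots (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_bead_lines(result, ax=None):
    """Running-median smoothed bead intensities vs. time, before and after
    normalization, with the baseline per channel."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    for ch in result.smoothed.columns:
        (line,) = ax.plot(result.smoothed.index, result.smoothed[ch],
                          alpha=0.4, label=f"{ch} (raw)")
        ax.plot(result.smoothed_normed.index, result.smoothed_normed[ch],
                color=line.get_color(), label=f"{ch} (normalized)")
        ax.axhline(result.baseline[ch], color=line.get_color(), ls=":", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("smoothed bead counts")
    ax.legend(fontsize=6, ncol=2)
    return ax


def plot_yields(result, barcode=None, ax=None):
    """Yield-versus-cutoff curves (all barcodes, or one with its cutoff)."""
    if result.yields is None:
        raise ValueError("run compute_yields first")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cols = [barcode] if barcode else result.yields.columns
    for bc in cols:
        ax.plot(result.yields.index, result.yields[bc], lw=1, label=str(bc))
    if barcode and result.sep_cutoffs is not None:
        ax.axvline(result.sep_cutoffs[barcode], color="k", ls="--")
    ax.set_xlabel("separation cutoff")
    ax.set_ylabel("yield")
    if len(cols) <= 16:
        ax.legend(fontsize=6)
    return ax


def qc_boxplot(df: pd.DataFrame, current_label: str = "current", ax=None):
    """Reference distributions as boxes with the current run overlaid as
    crosses (one column per channel/sample)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ref = df.drop(index=current_label, errors="ignore")
    ax.boxplot([ref[c].dropna() for c in ref.columns], tick_labels=list(ref.columns))
    if current_label in df.index:
        ax.scatter(range(1, len(df.columns) + 1), df.loc[current_label],
                   marker="x", color="red", zorder=3, label=current_label)
        ax.legend(fontsize=7)
    ax.tick_params(axis="x", rotation=45)
    return ax
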