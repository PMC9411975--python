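"""Quantile-scaling batch correction and cross-experiment quality control.

Every experiment of a long-running study carries the same set of reference
samples (group ``R``).  Their 98th expression percentiles, recorded for a
set of prior experiments, anchor a per-channel correction factor: the
current run's 98th count percentile over reference events divided by the
across-experiment average (back-transformed to the count scale with the
shared arcsinh cofactor).  Sample counts are divided by these factors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .frame import CytofFrame, arcsinh, inverse_arcsinh

logger = logging.getLogger(__name__)

__all__ = [
    "read_reference_quantiles",
    "correction_factors",
    "apply_correction",
    "qc_cell_counts",
    "qc_marker_levels",
]


def read_reference_quantiles(path: str) -> pd.DataFrame:
    """Read a reference table of 98th expression percentiles (rows = prior
    experiments, columns = targets, arcsinh scale)."""
    ref = pd.read_csv(path)
    if (ref.to_numpy() < 0).any():
        raise ValueError("reference quantiles must be non-negative")
    return ref


def _targets_to_channels(frame: CytofFrame, targets: list[str]) -> dict[str, int]:
    """Map reference-table column labels to channel indices by marker name,
    falling back to channel name."""
    markers = frame.channel_meta["marker_name"].tolist()
    names = frame.channel_names
    out = {}
    for t in targets:
        if t in markers and markers.count(t) == 1:
            out[t] = markers.index(t)
        elif t in names:
            out[t] = names.index(t)
        else:
            logger.warning("target %r not found in panel; dropped", t)
    return out


def correction_factors(
    frame: CytofFrame,
    ref: pd.DataFrame,
    reference_mask: np.ndarray,
    p: float = 0.98,
    assay: str = "compcounts",
) -> pd.Series:
    """Per-channel batch correction factors from pooled reference events.

    For each channel in the reference table the factor is the run's
    p-quantile of compensated counts over reference events divided by the
    mean across prior experiments of the back-transformed reference
    quantile (``sinh(q) * cofactor``).  Channels absent from the table get
    factor 1.  Quantiles use linear interpolation (type-7), so factors are
    reproducible across implementations.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference_mask selects no events")
    if assay not in frame.assays:
        raise KeyError(f"assay {assay!r} not present; have {list(frame.assays)}")
    cf = frame.cofactor
    factors = pd.Series(1.0, index=frame.channel_names, name="factor")
    chan = _targets_to_channels(frame, list(ref.columns))
    counts = frame.assays[assay][reference_mask]
    for target, j in chan.items():
        qs = float(np.mean(inverse_arcsinh(ref[target].to_numpy(), cf)))
        run = float(np.quantile(counts[:, j], p))
        if qs <= 0:
            logger.warning("reference quantile for %r is 0; factor kept at 1", target)
            continue
        factors.iloc[j] = run / qs
    if (factors <= 0).any():
        raise ValueError("non-positive correction factor computed")
    return factors


def apply_correction(
    frame: CytofFrame, factors: pd.Series, assay: str = "compcounts",
    overwrite: bool = False,
) -> CytofFrame:
    """Divide counts by per-channel factors; adds ``bccounts``/``bcexprs``."""
    f = factors.reindex(frame.channel_names).fillna(1.0).to_numpy()
    bccounts = frame.assays[assay] / f[None, :]
    mass = frame.mass_channel_mask
    bcexprs = bccounts.copy()
    bcexprs[:, mass] = arcsinh(bccounts[:, mass], frame.cofactor)
    if overwrite:
        frame.assays["counts"] = bccounts
        frame.assays["exprs"] = bcexprs
    else:
        frame.add_assay("bccounts", bccounts, overwrite=True)
        frame.add_assay("bcexprs", bcexprs, overwrite=True)
    frame.log("apply_correction: batch-corrected counts stored")
    return frame


def qc_cell_counts(
    frame: CytofFrame, grouping: str = "sample", ref_counts_csv: str | None = None
) -> pd.DataFrame:
    """Per-sample (or per-type) event counts, joined with a reference table
    of counts from prior experiments for side-by-side reporting."""
    counts = frame.event_meta.groupby(grouping, observed=True).size()
    out = pd.DataFrame({"count": counts})
    out.index.name = grouping
    if ref_counts_csv is not None:
        ref = pd.read_csv(ref_counts_csv)
        long = ref.melt(var_name=grouping, value_name="count").dropna()
        long["experiment"] = "reference"
        cur = out.reset_index()
        cur["experiment"] = "current"
        out = pd.concat([long, cur], ignore_index=True)
    return out


def qc_marker_levels(
    frame: CytofFrame,
    ref: pd.DataFrame,
    reference_mask: np.ndarray,
    p: float = 0.98,
    assay: str = "compexprs",
) -> pd.DataFrame:
    """p-quantiles of compensated expressions over pooled reference events,
    one row per prior experiment plus one for the current run.

    High quantiles are compared rather than medians so that rare positive
    populations still register in the staining-efficacy check.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    chan = _targets_to_channels(frame, list(ref.columns))
    es = frame.assays[assay][reference_mask]
    run = {t: float(np.quantile(es[:, j], p)) for t, j in chan.items()}
    current = pd.DataFrame([run], index=["current"])
    ref_sub = ref[list(chan)].copy()
    ref_sub.index = [f"reference_{i + 1}" for i in range(len(ref_sub))]
    return pd.concat([ref_sub, current])
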