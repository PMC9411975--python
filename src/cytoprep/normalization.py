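"""Bead-based correction of time-dependent signal drift.

Metal-embedded polystyrene calibration beads are spiked into the sample and
acquired alongside the cells.  Bead events are identified automatically
(including removal of bead-bead and cell-bead doublets), their channel
intensities are smoothed with a running median over acquisition time, and
at each timepoint an intercept-zero least-squares slope maps the smoothed
bead signal onto a baseline (the run's own mean bead signal, or that of a
reference bead set from an earlier run).  All mass channels are then
rescaled by multiplication with the interpolated slopes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .debarcoding import assign_by_key
from .frame import CytofFrame, read_fcs

logger = logging.getLogger(__name__)

__all__ = [
    "BeadConfig",
    "NormalizationResult",
    "BEAD_SETS",
    "identify_beads",
    "compute_baseline",
    "smooth_beads",
    "compute_slopes",
    "normalize",
    "qc_bead_means",
]

#: named commercial bead sets (lanthanide masses)
BEAD_SETS = {
    "dvs": (140, 151, 153, 165, 175),
    "beta": (139, 141, 159, 169, 175),
}

MAD_CONSISTENCY = 1.4826  # consistency constant for normal data


@dataclass
class BeadConfig:
    """Parameters controlling bead identification and drift correction.

    ``trim`` is the half-width (in robust SDs, median +/- trim * MAD) of the
    per-channel window retaining bead singlets; ``window_k`` the running
    median width in bead events; ``sep_cutoff`` the scaled-separation
    threshold removing cell-bead doublets; ``baseline`` is ``None`` for an
    internal baseline or a reference-bead FCS path / CytofFrame.
    """

    bead_masses: tuple[int, ...] | str = "dvs"
    dna_masses: tuple[int, ...] = (191, 193)
    trim: float = 5.0
    window_k: int = 500
    sep_cutoff: float = 0.35
    baseline: object | None = None  # None | path | CytofFrame

    def __post_init__(self) -> None:
        if isinstance(self.bead_masses, str):
            try:
                self.bead_masses = BEAD_SETS[self.bead_masses]
            except KeyError:
                raise ValueError(
                    f"unknown bead set {self.bead_masses!r}; known: {sorted(BEAD_SETS)}"
                ) from None
        self.bead_masses = tuple(int(m) for m in self.bead_masses)
        self.dna_masses = tuple(int(m) for m in self.dna_masses)
        if set(self.bead_masses) & set(self.dna_masses):
            raise ValueError("bead and DNA masses must be disjoint")
        if self.trim <= 0:
            raise ValueError("trim must be > 0")
        if self.window_k < 3:
            raise ValueError("window_k must be >= 3")
        if self.window_k % 2 == 0:
            self.window_k += 1  # running median needs an odd, centered window


@dataclass
class NormalizationResult:
    """Partition of the input events plus fitted drift information.

    ``data`` holds non-bead, non-doublet events with ``normcounts`` /
    ``normexprs`` assays; ``beads`` the bead singlets used for fitting;
    ``removed`` all excluded events (beads and doublets, with ``beads`` a
    subset of ``removed``).
    """

    data: CytofFrame
    beads: CytofFrame
    removed: CytofFrame
    slopes: pd.Series  # per bead event, indexed by acquisition time
    baseline: pd.Series  # per bead channel mean counts
    smoothed: pd.DataFrame = None
    smoothed_normed: pd.DataFrame = None


def identify_beads(frame: CytofFrame, config: BeadConfig) -> tuple[np.ndarray, np.ndarray]:
    """Identify bead singlets and all removable events.

    Returns ``(singlet_mask, removed_mask)``.  Steps: (1) preliminary bead
    tagging with a two-row binary key over DNA and bead channels (cells are
    DNA-positive, beads are positive in every bead channel); (2) tagged
    beads whose scaled separation falls below ``sep_cutoff`` are demoted to
    cell-bead doublets; (3) non-bead events exceeding the lower bound of
    bead-singlet signal in every bead channel are flagged as doublets;
    (4) beads outside median +/- trim * MAD per bead channel (arcsinh scale)
    are dropped from the singlet set.  All tagged beads and doublets end up
    in the removed set.
    """
    dna_idx = frame.channel_indices(config.dna_masses)
    bead_idx = frame.channel_indices(config.bead_masses)
    X = frame.assays["exprs"][:, dna_idx + bead_idx]
    nd, nb = len(dna_idx), len(bead_idx)
    key = np.array([[1] * nd + [0] * nb,      # cells: DNA only
                    [0] * nd + [1] * nb])     # beads: all bead channels
    rows, delta = assign_by_key(X, key)
    is_bead0 = rows == 1
    if not is_bead0.any():
        raise ValueError(
            "no bead events found; check that bead_masses matches the beads "
            "spiked into this acquisition"
        )

    # step 2: cell-bead doublets sit between populations -> low separation
    singlet = is_bead0 & (delta >= config.sep_cutoff)

    # step 4: per-channel median +/- trim * MAD on arcsinh intensities
    B = frame.assays["exprs"][:, bead_idx]
    med = np.median(B[singlet], axis=0)
    mad = MAD_CONSISTENCY * np.median(np.abs(B[singlet] - med), axis=0)
    lo, hi = med - config.trim * mad, med + config.trim * mad
    within = ((B >= lo) & (B <= hi)).all(axis=1)
    singlet = singlet & within

    if not singlet.any():
        raise ValueError("all bead events were trimmed; increase trim or check bead_masses")

    # step 3: events passing the lower bound of bead-singlet signal in every
    # bead channel (bead-bead and bead-cell doublets among non-beads)
    lower = B[singlet].min(axis=0)
    doublet3 = (~is_bead0) & (B > lower).all(axis=1)

    removed = is_bead0 | doublet3
    frame.log(
        f"identify_beads: {int(singlet.sum())} bead singlets, "
        f"{int(removed.sum())} removed of {frame.n_events} events"
    )
    return singlet, removed


def compute_baseline(
    beads: CytofFrame | str | os.PathLike, bead_masses: tuple[int, ...]
) -> pd.Series:
    """Arithmetic mean raw dual count per bead channel (the normalization
    baseline), from a bead CytofFrame or a reference-bead FCS path."""
    if not isinstance(beads, CytofFrame):
        beads = read_fcs(beads)
    if beads.n_events < 1:
        raise ValueError("baseline requires at least one bead event")
    try:
        idx = beads.channel_indices(bead_masses)
    except KeyError as exc:
        raise ValueError(f"reference beads are missing a bead channel: {exc}") from exc
    means = beads.assays["counts"][:, idx].mean(axis=0)
    return pd.Series(means, index=[beads.channel_names[i] for i in idx], name="baseline")


def smooth_beads(bead_counts: np.ndarray, window_k: int = 500) -> np.ndarray:
    """Per-channel running median over bead events ordered by time.

    The window shrinks (is not padded) at the edges; an even ``window_k``
    is incremented to the next odd width.
    """
    bead_counts = np.asarray(bead_counts, dtype=float)
    if bead_counts.shape[0] < 3:
        raise ValueError("need at least 3 bead events to smooth")
    if window_k % 2 == 0:
        window_k += 1
    df = pd.DataFrame(bead_counts)
    return df.rolling(window=window_k, center=True, min_periods=1).median().to_numpy()


def compute_slopes(smoothed: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Intercept-zero least-squares slope mapping smoothed bead signal onto
    the baseline, one slope per bead timepoint:
    ``slope_t = sum_k baseline_k * smoothed_tk / sum_k smoothed_tk^2``."""
    smoothed = np.asarray(smoothed, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    denom = (smoothed**2).sum(axis=1)
    if (denom <= 0).any():
        raise ValueError("degenerate (all-zero) smoothed bead signal at some timepoint")
    return (smoothed * baseline).sum(axis=1) / denom


def _interp_slopes(event_times: np.ndarray, bead_times: np.ndarray,
                   bead_slopes: np.ndarray) -> np.ndarray:
    """Constant interpolation: each event takes the slope of the preceding
    bead event (the first bead's slope before any bead)."""
    pos = np.searchsorted(bead_times, event_times, side="right") - 1
    return bead_slopes[np.clip(pos, 0, len(bead_slopes) - 1)]


def normalize(
    frame: CytofFrame,
    config: BeadConfig | None = None,
    remove_beads: bool = True,
    overwrite: bool = False,
) -> NormalizationResult:
    """Identify beads and rescale all mass channels against the baseline.

    ``normcounts = counts * slope(t)`` for every channel with a parsed mass
    (``Time`` and ``Event_length`` untouched); ``normexprs`` is the arcsinh
    of the normalized counts with the frame's stored cofactor.  With
    ``overwrite=True`` the raw ``counts``/``exprs`` assays are replaced in
    place instead of adding new assays.
    """
    config = config or BeadConfig()
    singlet, removed = identify_beads(frame, config)
    bead_idx = frame.channel_indices(config.bead_masses)
    times = frame.event_meta["time"].to_numpy()

    order = np.argsort(times[singlet], kind="stable")
    singlet_pos = np.flatnonzero(singlet)[order]
    bead_times = times[singlet_pos]
    bead_counts = frame.assays["counts"][singlet_pos][:, bead_idx]

    smoothed = smooth_beads(bead_counts, config.window_k)
    if config.baseline is None:
        baseline = pd.Series(smoothed.mean(axis=0),
                             index=[frame.channel_names[i] for i in bead_idx])
    else:
        baseline = compute_baseline(config.baseline, config.bead_masses)
    slopes = compute_slopes(smoothed, baseline.to_numpy())

    ev_slopes = _interp_slopes(times, bead_times, slopes)
    mass = frame.mass_channel_mask
    normcounts = frame.assays["counts"].copy()
    normcounts[:, mass] = normcounts[:, mass] * ev_slopes[:, None]
    from .frame import arcsinh  # local to avoid cycle at import time

    normexprs = normcounts.copy()
    normexprs[:, mass] = arcsinh(normcounts[:, mass], frame.cofactor)
    if overwrite:
        frame.assays["counts"] = normcounts
        frame.assays["exprs"] = normexprs
    else:
        frame.add_assay("normcounts", normcounts, overwrite=True)
        frame.add_assay("normexprs", normexprs, overwrite=True)
    frame.channel_meta["is_bead"] = [i in bead_idx for i in range(frame.n_channels)]

    data = frame.subset_events(~removed) if remove_beads else frame
    beads = frame.subset_events(singlet)
    removed_frame = frame.subset_events(removed)
    frame.log(
        f"normalize: data {data.n_events} | beads {beads.n_events} | "
        f"removed {removed_frame.n_events} "
        f"({100 * removed_frame.n_events / max(frame.n_events, 1):.2f}% of total)"
    )
    smoothed_df = pd.DataFrame(smoothed, index=bead_times, columns=baseline.index)
    normed_df = smoothed_df.mul(slopes, axis=0)
    return NormalizationResult(
        data=data,
        beads=beads,
        removed=removed_frame,
        slopes=pd.Series(slopes, index=bead_times, name="slope"),
        baseline=baseline,
        smoothed=smoothed_df,
        smoothed_normed=normed_df,
    )


def qc_bead_means(beads: CytofFrame, bead_masses: tuple[int, ...] | str = "dvs",
                  ref_csv: str | None = None) -> pd.DataFrame:
    """Mean raw dual counts per bead channel, optionally joined with a
    reference table (rows = prior experiments) for sensitivity QC."""
    if isinstance(bead_masses, str):
        bead_masses = BEAD_SETS[bead_masses]
    if beads.n_events < 1:
        raise ValueError("no bead events")
    idx = beads.channel_indices(bead_masses)
    names = [beads.channel_names[i] for i in idx]
    means = beads.assays["counts"][:, idx].mean(axis=0)
    current = pd.DataFrame([means], columns=names, index=["current"])
    if ref_csv is None:
        return current
    ref = pd.read_csv(ref_csv)
    ref.index = [f"reference_{i + 1}" for i in range(len(ref))]
    common = [c for c in names if c in ref.columns]
    return pd.concat([ref[common], current[common]])
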