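"""Spillover estimation and compensation for mass cytometry channels.

Spillover between mass channels arises from abundance sensitivity (M +/- 1),
oxide formation (M + 16) and isotopic impurities of the reporter metals.
It is modeled linearly: observed intensities J are the true intensities I
mixed by a spillover matrix, ``J = I . SM`` with unit diagonal.  The true
signal is recovered either exactly (``J . SM^-1``, which can go negative) or
by per-event non-negative least squares (Lawson-Hanson NNLS), which respects
the non-negativity of ion counts.

Spillover is estimated from single-stained controls deconvoluted with the
debarcoding machinery, either from per-cell spill ratios (``default``) or
from population medians (``classic``), restricted to chemically plausible
channel pairs unless ``interactions="all"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls

from .frame import CytofFrame, arcsinh, parse_channel

logger = logging.getLogger(__name__)

__all__ = [
    "SpilloverMatrix",
    "NATURAL_ISOTOPES",
    "interaction_mask",
    "estimate_spillover",
    "compensate",
    "adapt_sm",
]

#: natural isotope masses of metals commonly used as CyTOF reporters;
#: overridable by passing a custom table to :func:`interaction_mask`
NATURAL_ISOTOPES: dict[str, tuple[int, ...]] = {
    "As": (75,),
    "Y": (89,),
    "Rh": (103,),
    "Pd": (102, 104, 105, 106, 108, 110),
    "Cd": (106, 108, 110, 111, 112, 113, 114, 116),
    "In": (113, 115),
    "Sn": (112, 114, 115, 116, 117, 118, 119, 120, 122, 124),
    "Ba": (130, 132, 134, 135, 136, 137, 138),
    "La": (138, 139),
    "Ce": (136, 138, 140, 142),
    "Pr": (141,),
    "Nd": (142, 143, 144, 145, 146, 148, 150),
    "Sm": (144, 147, 148, 149, 150, 152, 154),
    "Eu": (151, 153),
    "Gd": (152, 154, 155, 156, 157, 158, 160),
    "Tb": (159,),
    "Dy": (156, 158, 160, 161, 162, 163, 164),
    "Ho": (165,),
    "Er": (162, 164, 166, 167, 168, 170),
    "Tm": (169,),
    "Yb": (168, 170, 171, 172, 173, 174, 176),
    "Lu": (175, 176),
    "Ir": (191, 193),
    "Pt": (190, 192, 194, 195, 196, 198),
    "Pb": (204, 206, 207, 208),
    "Bi": (209,),
}


@dataclass
class SpilloverMatrix:
    """C x C non-negative spillover matrix with unit diagonal.

    Rows are emitting channels, columns receiving channels; ``sm[i, j]`` is
    the fraction of channel-i signal received by channel j, relative to the
    total signal in i.
    """

    sm: pd.DataFrame  # index = emitting channel names, columns = receiving

    def __post_init__(self) -> None:
        sm = self.sm.astype(float)
        if list(sm.index) != list(sm.columns):
            raise ValueError("spillover matrix must have identical row/column channels")
        vals = sm.to_numpy()
        if (vals < 0).any():
            raise ValueError("spillover entries must be non-negative")
        if not np.allclose(np.diag(vals), 1.0):
            raise ValueError("spillover diagonal must be 1")
        off = vals[~np.eye(len(sm), dtype=bool)]
        if (off >= 1).any():
            raise ValueError("off-diagonal spillover must be < 1")
        self.sm = sm

    @property
    def channels(self) -> list[str]:
        return list(self.sm.index)

    def to_numpy(self) -> np.ndarray:
        return self.sm.to_numpy()

    @classmethod
    def from_csv(cls, path: str) -> "SpilloverMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str) -> None:
        self.sm.to_csv(path)


def interaction_mask(
    channel_names: list[str],
    isotopes: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Boolean mask of chemically plausible spillover interactions.

    ``mask[i, j]`` is True when channel j can receive spill from channel i:
    the diagonal, adjacent masses (M +/- 1, abundance sensitivity), the
    M + 16 oxide, or another natural isotope of channel i's metal.
    """
    isotopes = NATURAL_ISOTOPES if isotopes is None else isotopes
    desc = [parse_channel(c) for c in channel_names]
    n = len(channel_names)
    allowed = np.eye(n, dtype=bool)
    for i, di in enumerate(desc):
        if di.mass is None:
            continue
        if di.metal not in isotopes:
            logger.warning("no isotope table for metal %r; impurity rule skipped", di.metal)
        iso = set(isotopes.get(di.metal, ()))
        for j, dj in enumerate(desc):
            if i == j or dj.mass is None:
                continue
            if dj.mass in (di.mass - 1, di.mass + 1, di.mass + 16):
                allowed[i, j] = True
            elif dj.mass in iso:
                allowed[i, j] = True
    return pd.DataFrame(allowed, index=channel_names, columns=channel_names)


def adapt_sm(sm: SpilloverMatrix, panel_channels: list[str]) -> SpilloverMatrix:
    """Align a spillover matrix to an acquisition panel.

    Panel channels missing from the matrix receive identity rows/columns;
    matrix channels absent from the panel are dropped; rows/columns are
    reordered to the panel order.
    """
    out = pd.DataFrame(np.eye(len(panel_channels)),
                       index=panel_channels, columns=panel_channels)
    common = [c for c in panel_channels if c in sm.sm.index]
    out.loc[common, common] = sm.sm.loc[common, common].to_numpy()
    return SpilloverMatrix(out)


# ---------------------------------------------------------------------------
# estimation


def estimate_spillover(
    frame: CytofFrame,
    bc_to_channel: dict[str, str],
    method: str = "default",
    interactions: str = "default",
    th: float = 1e-5,
    trim: float | None = None,
    assay: str = "counts",
) -> SpilloverMatrix:
    """Estimate a spillover matrix from deconvoluted single-stain controls.

    ``bc_to_channel`` maps each barcode ID (from a debarcoded single-stain
    frame, ``bc_id`` in the event metadata) to the emitting channel it
    stains.  For each emitting channel i and receiving channel j, background
    medians are computed from events negative in i and j, not assigned to
    channels interacting with either, and not unassigned.  The ``default``
    method takes the median over cells c in i+ of
    ``(J_j(c) - m_j^-) / (J_i(c) - m_i^-)``; the ``classic`` method uses
    the ratio of background-subtracted population medians (or trimmed means
    when ``trim`` is given).  Estimates are restricted to the chemistry mask
    unless ``interactions="all"``; entries below ``th`` are zeroed, negative
    estimates clipped to 0, and the diagonal set to 1.
    """
    if method not in ("default", "classic"):
        raise ValueError(f"unknown method {method!r}")
    if interactions not in ("default", "all"):
        raise ValueError(f"unknown interactions mode {interactions!r}")
    mass_idx = np.flatnonzero(frame.mass_channel_mask)
    channels = [frame.channel_names[i] for i in mass_idx]
    X = frame.assays[assay][:, mass_idx]
    bc = frame.event_meta["bc_id"].to_numpy().astype(str)
    mask = interaction_mask(channels)

    col_of = {c: k for k, c in enumerate(channels)}
    pop_channel = {b: bc_to_channel[b] for b in bc_to_channel}
    stained = [c for c in channels if c in pop_channel.values()]
    channel_pop: dict[str, np.ndarray] = {}
    for b, ch in pop_channel.items():
        channel_pop[ch] = (bc == b) if ch not in channel_pop else (channel_pop[ch] | (bc == b))
    assigned = np.isin(bc, list(bc_to_channel))

    n = len(channels)
    sm = np.zeros((n, n))
    np.fill_diagonal(sm, 1.0)
    allowed = mask.to_numpy() if interactions == "default" else ~np.eye(n, dtype=bool)

    for ci in stained:
        i = col_of[ci]
        pos = channel_pop.get(ci, np.zeros(len(bc), dtype=bool))
        if not pos.any():
            logger.warning("no positive events for channel %s; identity row kept", ci)
            continue
        for j in range(n):
            if j == i or not allowed[i, j]:
                continue
            cj = channels[j]
            # background: assigned events not in i+/j+ populations and not
            # assigned to channels interacting with i or j
            interacting = np.zeros(len(bc), dtype=bool)
            for ck, popk in channel_pop.items():
                k = col_of[ck]
                if ck in (ci, cj):
                    interacting |= popk
                elif (mask.iat[k, i] or mask.iat[k, j]
                      or mask.iat[i, k] or mask.iat[j, k]):
                    interacting |= popk
            bg = assigned & ~interacting
            if not bg.any():
                zero = np.zeros(len(bc), dtype=bool)
                bg = assigned & ~(channel_pop.get(ci, zero) | channel_pop.get(cj, zero))
            m_i = np.median(X[bg, i]) if bg.any() else 0.0
            m_j = np.median(X[bg, j]) if bg.any() else 0.0
            if method == "default":
                num = X[pos, j] - m_j
                den = X[pos, i] - m_i
                ok = den > 0
                if not ok.any():
                    continue
                s = float(np.median(num[ok] / den[ok]))
            else:
                if trim is not None:
                    from scipy.stats import trim_mean
                    pj = trim_mean(X[pos, j], trim)
                    pi = trim_mean(X[pos, i], trim)
                else:
                    pj = np.median(X[pos, j])
                    pi = np.median(X[pos, i])
                den = pi - m_i
                if den <= 0:
                    continue
                s = float((pj - m_j) / den)
            sm[i, j] = max(s, 0.0)

    sm[sm < th] = 0.0
    np.fill_diagonal(sm, 1.0)
    sm = np.clip(sm, 0.0, 1.0 - 1e-12)
    np.fill_diagonal(sm, 1.0)
    return SpilloverMatrix(pd.DataFrame(sm, index=channels, columns=channels))


# ---------------------------------------------------------------------------
# compensation


def _nnls_rows(A: np.ndarray, J: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Solve min ||j - i . A||, i >= 0 for each row j of J.

    Row-wise Lawson-Hanson NNLS on A^T; chunking only bounds memory, the
    result is independent of chunk size.
    """
    At = np.ascontiguousarray(A.T)
    out = np.empty_like(J, dtype=float)
    for start in range(0, J.shape[0], chunk):
        block = J[start:start + chunk]
        for r, j in enumerate(block):
            out[start + r], _ = _nnls(At, j)
    return out


def compensate(
    frame: CytofFrame,
    sm: SpilloverMatrix,
    method: str = "nnls",
    assay: str = "counts",
    overwrite: bool = False,
) -> CytofFrame:
    """Compensate an assay for spillover; adds ``compcounts``/``compexprs``.

    ``method="flow"`` applies the exact inverse ``I = J . SM^-1`` (can
    produce negative intensities); ``method="nnls"`` solves a per-event
    non-negative least squares problem.  Only mass channels present in the
    frame are compensated (the matrix is adapted to the panel first);
    ``compexprs`` re-applies the frame's stored arcsinh cofactor.
    """
    if method not in ("nnls", "flow"):
        raise ValueError(f"unknown method {method!r}")
    mass_idx = np.flatnonzero(frame.mass_channel_mask)
    channels = [frame.channel_names[i] for i in mass_idx]
    A = adapt_sm(sm, channels).to_numpy()
    J = frame.assays[assay][:, mass_idx]
    if method == "flow":
        try:
            inv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "spillover matrix is singular; use method='nnls'"
            ) from exc
        I = J @ inv
    else:
        I = _nnls_rows(A, J)
    compcounts = frame.assays[assay].copy()
    compcounts[:, mass_idx] = I
    compexprs = compcounts.copy()
    compexprs[:, mass_idx] = arcsinh(I, frame.cofactor)
    if overwrite:
        frame.assays["counts"] = compcounts
        frame.assays["exprs"] = compexprs
    else:
        frame.add_assay("compcounts", compcounts, overwrite=True)
        frame.add_assay("compexprs", compexprs, overwrite=True)
    frame.log(f"compensate(method={method!r}, assay={assay!r}) on "
              f"{len(channels)} mass channels")
    return frame
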