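"""Events x channels measurement container for mass cytometry data.

A :class:`CytofFrame` bundles one or more assays (dual ion counts and
transforms thereof), per-event metadata, per-channel metadata and
experiment-wide metadata (arcsinh cofactor, separation cutoffs, a
provenance log).  Events are rows, channels are columns, throughout.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fcs import read_fcs_file, write_fcs_file

logger = logging.getLogger(__name__)

__all__ = [
    "CytofFrame",
    "ChannelDescriptor",
    "parse_channel",
    "arcsinh",
    "inverse_arcsinh",
    "read_fcs",
    "write_fcs",
    "concat_frames",
    "filter_time_range",
]

#: channels that carry acquisition bookkeeping rather than ion counts
NON_MASS_CHANNELS = ("Time", "Event_length")

_CHANNEL_RE = re.compile(r"^(?:\d+)?([A-Z][a-z]?)(\d{2,3})(?:Di|Dd)?$")
_CHANNEL_RE_PREFIX = re.compile(r"^(\d{2,3})([A-Z][a-z]?)$")  # e.g. "89Y", "208Pb"


@dataclass(frozen=True)
class ChannelDescriptor:
    """Metal symbol and mass number parsed from a channel name."""

    channel_name: str
    metal: str | None
    mass: int | None


def parse_channel(channel_name: str) -> ChannelDescriptor:
    """Parse a CyTOF channel name such as ``"Pd102Di"`` into metal and mass.

    Non-mass channels (``Time``, ``Event_length``) and unparseable names
    yield ``mass=None``.  Masses outside the instrument's acquisition range
    (75-215 amu) are treated as unparseable.
    """
    name = str(channel_name).strip()
    m = _CHANNEL_RE.match(name)
    if m is not None:
        metal, mass = m.group(1), int(m.group(2))
    else:
        m = _CHANNEL_RE_PREFIX.match(name)
        if m is None:
            return ChannelDescriptor(channel_name, None, None)
        metal, mass = m.group(2), int(m.group(1))
    if not 75 <= mass <= 215:
        return ChannelDescriptor(channel_name, None, None)
    return ChannelDescriptor(channel_name, metal, mass)


def arcsinh(x: np.ndarray, cofactor: float) -> np.ndarray:
    """Variance-stabilizing transform ``asinh(x / cofactor)``."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be > 0, got {cofactor}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def inverse_arcsinh(y: np.ndarray, cofactor: float) -> np.ndarray:
    """Inverse transform ``sinh(y) * cofactor``."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be > 0, got {cofactor}")
    return np.sinh(np.asarray(y, dtype=float)) * cofactor


def _make_channel_meta(channel_names: Sequence[str], marker_names: Sequence[str]) -> pd.DataFrame:
    desc = [parse_channel(c) for c in channel_names]
    return pd.DataFrame(
        {
            "channel_name": list(channel_names),
            "marker_name": [m or c for m, c in zip(marker_names, channel_names)],
            "metal": [d.metal for d in desc],
            "mass": pd.array([d.mass for d in desc], dtype="Int64"),
            "is_bead": False,
            "is_bc": False,
            "use_channel": [d.mass is not None for d in desc],
        }
    )


class CytofFrame:
    """Container of named E x C assays with event/channel/experiment metadata.

    Parameters
    ----------
    assays
        Mapping of assay name to an events x channels matrix; every assay
        must have the same shape.  The conventional names are ``counts``
        (raw dual counts), ``exprs`` (arcsinh counts) and their
        ``norm``/``comp``/``bc``-prefixed stage variants.
    event_meta
        Per-event table (E rows); columns such as ``file_id``, ``time``,
        ``bc_id``, ``delta``, ``mhl``, ``sample``, ``type``, ``group``.
    channel_meta
        Per-channel table (C rows) with at least ``channel_name``.
    experiment_meta
        Free-form dict; recognized keys: ``cofactor``, ``sep_cutoffs``,
        ``log``.
    """

    def __init__(
        self,
        assays: Mapping[str, np.ndarray],
        event_meta: pd.DataFrame,
        channel_meta: pd.DataFrame,
        experiment_meta: dict | None = None,
    ):
        self.assays = {k: np.asarray(v, dtype=float) for k, v in assays.items()}
        self.event_meta = event_meta.reset_index(drop=True)
        self.channel_meta = channel_meta.reset_index(drop=True)
        self.experiment_meta = dict(experiment_meta or {})
        self.experiment_meta.setdefault("log", [])
        self._validate()

    def _validate(self) -> None:
        shapes = {k: v.shape for k, v in self.assays.items()}
        if not shapes:
            raise ValueError("at least one assay is required")
        uniq = set(shapes.values())
        if len(uniq) != 1:
            raise ValueError(f"assay shapes differ: {shapes}")
        e, c = next(iter(uniq))
        if len(self.channel_meta) != c:
            raise ValueError(
                f"channel_meta has {len(self.channel_meta)} rows but assays have {c} channels"
            )
        if len(self.event_meta) != e:
            raise ValueError(
                f"event_meta has {len(self.event_meta)} rows but assays have {e} events"
            )

    # -- basic properties -------------------------------------------------
    @property
    def n_events(self) -> int:
        return next(iter(self.assays.values())).shape[0]

    @property
    def n_channels(self) -> int:
        return next(iter(self.assays.values())).shape[1]

    @property
    def channel_names(self) -> list[str]:
        return self.channel_meta["channel_name"].tolist()

    @property
    def cofactor(self) -> float:
        return float(self.experiment_meta.get("cofactor", 5.0))

    @property
    def mass_channel_mask(self) -> np.ndarray:
        """Boolean mask of channels carrying an ion mass (drift/spill-correctable)."""
        return self.channel_meta["mass"].notna().to_numpy()

    def log(self, message: str) -> None:
        self.experiment_meta["log"].append(message)
        logger.info(message)

    # -- lookups ----------------------------------------------------------
    def channel_index(self, name_or_mass: str | int) -> int:
        if isinstance(name_or_mass, (int, np.integer)):
            hits = np.flatnonzero(self.channel_meta["mass"].to_numpy() == int(name_or_mass))
            if len(hits) != 1:
                raise KeyError(f"mass {name_or_mass} matches {len(hits)} channels")
            return int(hits[0])
        names = self.channel_meta["channel_name"]
        hits = np.flatnonzero((names == name_or_mass).to_numpy())
        if len(hits) != 1:
            raise KeyError(f"channel {name_or_mass!r} matches {len(hits)} channels")
        return int(hits[0])

    def channel_indices(self, names_or_masses: Iterable[str | int]) -> list[int]:
        return [self.channel_index(x) for x in names_or_masses]

    # -- manipulation -----------------------------------------------------
    def copy(self) -> "CytofFrame":
        return CytofFrame(
            {k: v.copy() for k, v in self.assays.items()},
            self.event_meta.copy(),
            self.channel_meta.copy(),
            {**self.experiment_meta, "log": list(self.experiment_meta["log"])},
        )

    def add_assay(self, name: str, matrix: np.ndarray, overwrite: bool = False) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.n_events, self.n_channels):
            raise ValueError(f"assay {name!r} has shape {matrix.shape}, expected "
                             f"{(self.n_events, self.n_channels)}")
        if name in self.assays and not overwrite:
            raise KeyError(f"assay {name!r} exists; pass overwrite=True to replace")
        self.assays[name] = matrix

    def subset_events(self, selector: np.ndarray) -> "CytofFrame":
        """Subset all assays and event metadata by a boolean mask or index array."""
        selector = np.asarray(selector)
        return CytofFrame(
            {k: v[selector] for k, v in self.assays.items()},
            self.event_meta.iloc[selector] if selector.dtype == bool
            else self.event_meta.iloc[np.asarray(selector, dtype=int)],
            self.channel_meta.copy(),
            {**self.experiment_meta, "log": list(self.experiment_meta["log"])},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<CytofFrame {self.n_events} events x {self.n_channels} channels; "
                f"assays={list(self.assays)}>")


# -- I/O -------------------------------------------------------------------

def read_fcs(paths: Sequence[str | os.PathLike] | str | os.PathLike,
             cofactor: float = 5.0) -> CytofFrame:
    """Read and concatenate FCS files into a single :class:`CytofFrame`.

    No transformation or range truncation is applied to the raw values; the
    ``counts`` assay holds the data verbatim and ``exprs`` holds
    cofactor-arcsinh-transformed counts for all mass channels (``Time`` and
    ``Event_length`` are carried through untransformed).  Events are
    concatenated in file order and ``file_id`` records the file of origin.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    if not paths:
        raise ValueError("no FCS files given")
    if cofactor <= 0:
        raise ValueError(f"cofactor must be > 0, got {cofactor}")
    mats, file_ids = [], []
    names0: list[str] | None = None
    stains0: list[str] | None = None
    for p in paths:
        data, names, stains, _ = read_fcs_file(p)
        if names0 is None:
            names0, stains0 = names, stains
        elif set(names) != set(names0):
            diff = sorted(set(names) ^ set(names0))
            raise ValueError(
                f"channel sets differ across FCS files; symmetric difference: {diff}"
            )
        elif names != names0:  # same set, different order: align
            order = [names.index(n) for n in names0]
            data = data[:, order]
        mats.append(data)
        file_ids.extend([Path(p).stem] * data.shape[0])
    counts = np.vstack(mats) if mats else np.empty((0, len(names0)))
    channel_meta = _make_channel_meta(names0, stains0)
    exprs = counts.copy()
    mass = channel_meta["mass"].notna().to_numpy()
    exprs[:, mass] = arcsinh(counts[:, mass], cofactor)
    event_meta = pd.DataFrame({"file_id": pd.Categorical(file_ids)})
    time_hits = [i for i, n in enumerate(names0) if n.lower() == "time"]
    if time_hits:
        event_meta["time"] = counts[:, time_hits[0]]
    frame = CytofFrame(
        {"counts": counts, "exprs": exprs},
        event_meta,
        channel_meta,
        {"cofactor": float(cofactor)},
    )
    frame.log(f"read {len(paths)} FCS file(s), {frame.n_events} events, "
              f"{frame.n_channels} channels, cofactor={cofactor}")
    return frame


def concat_frames(frames: Sequence[CytofFrame]) -> CytofFrame:
    """Concatenate frames with identical channels; total events is preserved."""
    if not frames:
        raise ValueError("no frames to concatenate")
    ref = frames[0]
    for f in frames[1:]:
        if f.channel_names != ref.channel_names:
            diff = sorted(set(f.channel_names) ^ set(ref.channel_names))
            raise ValueError(f"channel sets differ; symmetric difference: {diff}")
    common = set(ref.assays)
    for f in frames[1:]:
        common &= set(f.assays)
    assays = {k: np.vstack([f.assays[k] for f in frames]) for k in common}
    event_meta = pd.concat([f.event_meta for f in frames], ignore_index=True)
    return CytofFrame(assays, event_meta, ref.channel_meta.copy(),
                      {**ref.experiment_meta, "log": list(ref.experiment_meta["log"])})


def filter_time_range(
    frame: CytofFrame, t_min: float, t_max: float, mode: str = "keep"
) -> CytofFrame:
    """Retain (``keep``) or remove (``drop``) events with time in [t_min, t_max].

    Used to programmatically exclude acquisition stretches with unstable
    signal (uneven flow rate, air in the fluidics).
    """
    if t_min >= t_max:
        raise ValueError(f"t_min must be < t_max, got [{t_min}, {t_max}]")
    if mode not in ("keep", "drop"):
        raise ValueError(f"mode must be 'keep' or 'drop', got {mode!r}")
    t = frame.event_meta["time"].to_numpy()
    inside = (t >= t_min) & (t <= t_max)
    mask = inside if mode == "keep" else ~inside
    if not mask.any():
        logger.warning("time filter [%s, %s] mode=%s leaves no events", t_min, t_max, mode)
    out = frame.subset_events(mask)
    out.log(f"time filter [{t_min}, {t_max}] mode={mode}: "
            f"{int(mask.sum())}/{frame.n_events} events retained")
    return out


def write_fcs(
    frame: CytofFrame,
    assay: str = "counts",
    split_by: str | None = None,
    out_dir: str | os.PathLike = ".",
    prefix: str = "cytoprep",
) -> list[str]:
    """Write one assay to FCS 3.0, optionally one file per level of a
    categorical event-metadata column."""
    if assay not in frame.assays:
        raise KeyError(f"assay {assay!r} not present; have {list(frame.assays)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    markers = frame.channel_meta["marker_name"].tolist()
    if split_by is None:
        path = out_dir / f"{prefix}.fcs"
        write_fcs_file(path, frame.assays[assay], frame.channel_names, markers)
        return [str(path)]
    col = frame.event_meta[split_by]
    if pd.api.types.is_numeric_dtype(col):
        raise TypeError(f"split_by column {split_by!r} is numeric; must be categorical")
    paths = []
    for level, idx in frame.event_meta.groupby(col, observed=True).groups.items():
        sub = frame.assays[assay][np.asarray(idx, dtype=int)]
        path = out_dir / f"{prefix}_{level}.fcs"
        write_fcs_file(path, sub, frame.channel_names, markers)
        paths.append(str(path))
    return paths
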