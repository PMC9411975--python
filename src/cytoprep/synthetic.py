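"""Ground-truth generator for multiplexed CyTOF-like experiments.

Emulates the structure of a barcoded acquisition: multiplexed cell events
with a binary palladium barcode pattern, spiked-in lanthanide calibration
beads, multiplicative sensitivity drift over acquisition time, linear
spillover between chemically interacting channels, doublets formed by
event superposition, and dead cells marked by cisplatin uptake.  Per-event
ground truth (class, barcode, dead flag, drift factor) is returned
alongside the measurement frame so that every pipeline stage can be scored
against known labels.

The count model is lognormal signal modulated by Poisson shot noise, which
yields realistic zero inflation at low signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compensation import SpilloverMatrix, interaction_mask
from .debarcoding import BarcodingScheme
from .frame import CytofFrame, arcsinh, parse_channel

__all__ = [
    "SimConfig",
    "default_scheme",
    "default_panel",
    "make_spillover",
    "simulate_experiment",
    "write_metadata_files",
]

BARCODE_MASSES = (102, 104, 105, 106, 108, 110)
BEAD_CHANNELS = ("Ce140Di", "Eu151Di", "Eu153Di", "Ho165Di", "Lu175Di")
DNA_CHANNELS = ("Ir191Di", "Ir193Di")
DEAD_CHANNEL = "Pt194Di"
MARKER_CHANNELS = (
    "Pr141Di", "Nd143Di", "Nd145Di", "Nd146Di", "Sm147Di", "Gd156Di",
    "Tb159Di", "Dy162Di", "Er166Di", "Tm169Di", "Yb172Di", "Yb174Di",
)

SAMPLE_IDS = (
    "CellLine_R1", "CellLine_R2", "CellLine_R3", "CellLine_R4",
    "PBMC_R1", "PBMC_R2", "PBMC_R3", "Tumor_R1", "Tumor_R2",
    "PBMC_S1", "PBMC_S2", "PBMC_S3", "Tumor_S1", "Tumor_S2", "Tumor_S3",
)


def default_scheme(include_empty: bool = False) -> BarcodingScheme:
    """The 6-choose-3 = 20 palladium barcoding scheme over masses
    (102, 104, 105, 106, 108, 110); 15 named samples plus 5 empties."""
    words = list(itertools.combinations(range(6), 3))
    key = np.zeros((20, 6), dtype=int)
    for r, w in enumerate(words):
        key[r, list(w)] = 1
    ids = list(SAMPLE_IDS) + [f"empty_{i}" for i in range(1, 6)]
    df = pd.DataFrame(key, index=ids, columns=list(BARCODE_MASSES))
    scheme = BarcodingScheme(df)
    return scheme if include_empty else scheme.drop_empty()


def default_panel() -> list[str]:
    return (
        ["Time", "Event_length"]
        + [f"Pd{m}Di" for m in BARCODE_MASSES]
        + list(DNA_CHANNELS)
        + [DEAD_CHANNEL]
        + list(BEAD_CHANNELS)
        + list(MARKER_CHANNELS)
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated acquisition.

    Defaults mirror the emulated experimental design: a 15-sample 6-choose-3
    barcode pool, calibration beads spiked in at a fraction comparable to
    the bead share observed in a real run, 2% doublets, 10% dead cells, a
    20% exponential sensitivity decay over the acquisition, and spillover
    magnitudes of up to 4% on chemically allowed channel pairs.
    """

    n_events: int = 50_000
    scheme: BarcodingScheme = field(default_factory=default_scheme)
    panel: list[str] = field(default_factory=default_panel)
    bead_fraction: float = 0.075
    doublet_rate: float = 0.02
    dead_fraction: float = 0.10
    drift_amount: float = 0.20  # total fractional sensitivity loss over the run
    duration: float = 600_000.0  # acquisition time span, ms
    sm_truth: SpilloverMatrix | None = None
    cofactor: float = 5.0
    # lognormal(meanlog, sdlog) signal parameters on the count scale
    bc_pos: tuple[float, float] = (np.log(300.0), 0.30)
    bc_neg: tuple[float, float] = (np.log(1.0), 0.80)
    dna_level: tuple[float, float] = (np.log(350.0), 0.25)
    dead_pos: tuple[float, float] = (np.log(120.0), 0.40)
    dead_neg: tuple[float, float] = (np.log(2.0), 0.80)  # nonspecific background uptake
    marker_pos: tuple[float, float] = (np.log(150.0), 0.50)
    marker_neg: tuple[float, float] = (np.log(1.0), 1.00)
    bead_level: tuple[float, float] = (np.log(2500.0), 0.10)
    bead_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bead_fraction", "doublet_rate", "dead_fraction", "drift_amount"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        missing = [f"Pd{m}Di" for m in self.scheme.channel_masses
                   if f"Pd{m}Di" not in self.panel]
        if missing:
            raise ValueError(f"scheme channels missing from panel: {missing}")


def make_spillover(
    panel: list[str],
    rng: np.random.Generator,
    magnitude: tuple[float, float] = (0.0, 0.04),
    mask: pd.DataFrame | None = None,
) -> SpilloverMatrix:
    """Random ground-truth spillover: entries drawn uniformly in *magnitude*
    on chemically allowed (masked) pairs, unit diagonal."""
    channels = [c for c in panel if parse_channel(c).mass is not None]
    if mask is None:
        mask = interaction_mask(channels)
    n = len(channels)
    sm = np.eye(n)
    allow = mask.loc[channels, channels].to_numpy() & ~np.eye(n, dtype=bool)
    vals = rng.uniform(*magnitude, size=allow.sum())
    sm[allow] = vals
    return SpilloverMatrix(pd.DataFrame(sm, index=channels, columns=channels))


def _drift_factor(t: np.ndarray, amount: float, duration: float) -> np.ndarray:
    """Exponential sensitivity decay reaching (1 - amount) at the end of
    the run."""
    if amount <= 0:
        return np.ones_like(t)
    return np.power(1.0 - amount, t / duration)


def simulate_experiment(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[CytofFrame, pd.DataFrame]:
    """Simulate one acquisition; returns ``(frame, ground_truth)``.

    The frame carries ``counts`` and ``exprs`` assays over the configured
    panel; ground truth is a per-event table with ``true_class``
    (cell/bead/doublet), ``true_bc`` ("" for beads), ``true_dead`` and
    ``true_drift``.  Fully reproducible from the seed.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = list(config.panel)
    C = len(panel)
    col = {c: i for i, c in enumerate(panel)}
    mass_cols = np.array([i for i, c in enumerate(panel) if parse_channel(c).mass is not None])

    n = config.n_events
    is_bead = rng.random(n) < config.bead_fraction
    n_beads, n_cells = int(is_bead.sum()), n - int(is_bead.sum())

    lam = np.full((n, C), 0.2)
    samples = np.array(config.scheme.barcode_ids, dtype=object)
    cell_sample = rng.integers(0, len(samples), size=n_cells)
    key = config.scheme.key.to_numpy()
    cells = np.flatnonzero(~is_bead)
    beads = np.flatnonzero(is_bead)

    def logn(params, size):
        return rng.lognormal(params[0], params[1], size=size)

    # barcode channels
    for j, mass in enumerate(config.scheme.channel_masses):
        cj = col[f"Pd{mass}Di"]
        pos = key[cell_sample, j] == 1
        lam[cells[pos], cj] = logn(config.bc_pos, int(pos.sum()))
        lam[cells[~pos], cj] = logn(config.bc_neg, int((~pos).sum()))
    # DNA
    for c in DNA_CHANNELS:
        lam[cells, col[c]] = logn(config.dna_level, n_cells)
    # dead marker
    dead = np.zeros(n, dtype=bool)
    dead[cells] = rng.random(n_cells) < config.dead_fraction
    lam[cells, col[DEAD_CHANNEL]] = np.where(
        dead[cells], logn(config.dead_pos, n_cells), logn(config.dead_neg, n_cells)
    )
    # markers: each sample positive for a fixed, seed-reproducible half
    marker_design = rng.random((len(samples), len(MARKER_CHANNELS))) < 0.5
    for j, c in enumerate(MARKER_CHANNELS):
        pos = marker_design[cell_sample, j]
        lam[cells[pos], col[c]] = logn(config.marker_pos, int(pos.sum()))
        lam[cells[~pos], col[c]] = logn(config.marker_neg, int((~pos).sum()))
    # beads: high in every bead channel, background elsewhere
    lam[beads] = config.bead_background
    for c in BEAD_CHANNELS:
        lam[beads, col[c]] = logn(config.bead_level, n_beads)

    # acquisition times and multiplicative sensitivity drift
    t = np.sort(rng.uniform(0, config.duration, size=n))
    drift = _drift_factor(t, config.drift_amount, config.duration)
    lam[:, mass_cols] *= drift[:, None]

    # linear spillover on expected counts
    if config.sm_truth is not None:
        sm = config.sm_truth.sm
        sm_cols = [col[c] for c in sm.index if c in col]
        sm_use = sm.loc[[panel[i] for i in sm_cols], [panel[i] for i in sm_cols]].to_numpy()
        lam[:, sm_cols] = lam[:, sm_cols] @ sm_use

    counts = rng.poisson(lam).astype(float)
    counts[:, col["Time"]] = t
    counts[:, col["Event_length"]] = np.round(rng.normal(25, 3, size=n))

    # doublets: superpose a random partner's signal
    n_dbl = int(round(config.doublet_rate * n))
    cls = np.where(is_bead, "bead", "cell").astype(object)
    bc_true = np.full(n, "", dtype=object)
    bc_true[cells] = samples[cell_sample]
    if n_dbl:
        tgt = rng.choice(n, size=n_dbl, replace=False)
        partner = rng.integers(0, n, size=n_dbl)
        counts[np.ix_(tgt, mass_cols)] += counts[np.ix_(partner, mass_cols)]
        counts[tgt, col["Event_length"]] += 10
        cls[tgt] = "doublet"

    exprs = counts.copy()
    mass_mask = np.zeros(C, dtype=bool)
    mass_mask[mass_cols] = True
    exprs[:, mass_mask] = arcsinh(counts[:, mass_mask], config.cofactor)

    channel_meta = pd.DataFrame({
        "channel_name": panel,
        "marker_name": panel,
        "metal": [parse_channel(c).metal for c in panel],
        "mass": pd.array([parse_channel(c).mass for c in panel], dtype="Int64"),
        "is_bead": [c in BEAD_CHANNELS for c in panel],
        "is_bc": [c in {f"Pd{m}Di" for m in config.scheme.channel_masses} for c in panel],
        "use_channel": [parse_channel(c).mass is not None for c in panel],
    })
    event_meta = pd.DataFrame({
        "file_id": pd.Categorical(["sim1"] * n),
        "time": t,
    })
    frame = CytofFrame(
        {"counts": counts, "exprs": exprs},
        event_meta,
        channel_meta,
        {"cofactor": config.cofactor},
    )
    truth = pd.DataFrame({
        "true_class": cls,
        "true_bc": bc_true,
        "true_dead": dead,
        "true_drift": drift,
    })
    frame.log(f"simulated {n} events ({n_beads} beads, {n_dbl} doublets)")
    return frame, truth


def simulate_single_stains(
    channels: list[str] | None = None,
    n_per: int = 500,
    sm_truth: SpilloverMatrix | None = None,
    level: tuple[float, float] = (np.log(500.0), 0.25),
    background: float = 0.3,
    cofactor: float = 5.0,
    seed: int = 0,
) -> tuple[CytofFrame, pd.DataFrame, BarcodingScheme]:
    """Simulate single-stained control populations for spillover estimation.

    Each population is positive (lognormal ``level``) in exactly one channel
    and at Poisson ``background`` elsewhere; expected counts are mixed with
    ``sm_truth`` when given.  Returns the frame, a ground-truth table with
    the stained channel per event, and the identity (k = 1) barcoding
    scheme over the stained masses that deconvolutes the controls.
    """
    rng = np.random.default_rng(seed)
    if channels is None:
        channels = list(MARKER_CHANNELS)
    C = len(channels)
    n = n_per * C
    lam = np.full((n, C), background)
    stain = np.repeat(np.arange(C), n_per)
    lam[np.arange(n), stain] = rng.lognormal(*level, size=n)
    if sm_truth is not None:
        sub = sm_truth.sm.reindex(index=channels, columns=channels).fillna(0.0)
        np.fill_diagonal(sub.values, 1.0)
        lam = lam @ sub.to_numpy()
    counts = rng.poisson(lam).astype(float)
    perm = rng.permutation(n)
    counts, stain = counts[perm], stain[perm]
    exprs = arcsinh(counts, cofactor)
    masses = [parse_channel(c).mass for c in channels]
    channel_meta = pd.DataFrame({
        "channel_name": channels,
        "marker_name": channels,
        "metal": [parse_channel(c).metal for c in channels],
        "mass": pd.array(masses, dtype="Int64"),
        "is_bead": False,
        "is_bc": True,
        "use_channel": True,
    })
    frame = CytofFrame(
        {"counts": counts, "exprs": exprs},
        pd.DataFrame({"file_id": pd.Categorical(["ss"] * n)}),
        channel_meta,
        {"cofactor": cofactor},
    )
    truth = pd.DataFrame({"true_channel": [channels[s] for s in stain]})
    key = pd.DataFrame(np.eye(C, dtype=int), index=[str(m) for m in masses],
                       columns=masses)
    return frame, truth, BarcodingScheme(key)


def write_metadata_files(out_dir: str | Path, config: SimConfig | None = None,
                         seed: int = 0) -> dict[str, str]:
    """Write the study-style metadata CSVs (barcoding scheme, spillover
    matrix, reference bead counts / cell counts / marker levels) plus a
    reference-bead FCS, for integration tests and CLI runs."""
    from .fcs import write_fcs_file

    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    scheme = default_scheme(include_empty=True)
    p = out / "debarcoding_scheme.csv"
    scheme.to_csv(str(p))
    paths["scheme"] = str(p)

    sm = config.sm_truth or make_spillover(config.panel, rng)
    p = out / "spillover_matrix.csv"
    sm.to_csv(str(p))
    paths["spillover"] = str(p)

    # reference beads: stationary draws around the configured bead level
    nb = 2000
    bead_counts = rng.poisson(
        rng.lognormal(config.bead_level[0], config.bead_level[1], size=(nb, len(BEAD_CHANNELS)))
    ).astype(float)
    p = out / "normalization_beads.fcs"
    write_fcs_file(p, bead_counts, list(BEAD_CHANNELS))
    paths["ref_beads"] = str(p)

    ref_bead = pd.DataFrame(
        rng.normal(np.exp(config.bead_level[0]), 100, size=(7, len(BEAD_CHANNELS))),
        columns=list(BEAD_CHANNELS),
    )
    p = out / "ref_bead_counts.csv"
    ref_bead.to_csv(p, index=False)
    paths["ref_bead_counts"] = str(p)

    refs = [s for s in SAMPLE_IDS if "_R" in s]
    soi = [s for s in SAMPLE_IDS if "_S" in s]
    p = out / "ref_cell_counts.csv"
    pd.DataFrame(rng.integers(1500, 4000, size=(7, len(refs))), columns=refs).to_csv(p, index=False)
    paths["ref_cell_counts"] = str(p)
    p = out / "sample_cell_counts.csv"
    df = pd.DataFrame({
        "sample": soi * 7,
        "count": rng.integers(1500, 4000, size=7 * len(soi)),
        "type": [s.split("_")[0] for s in soi] * 7,
    })
    df.to_csv(p, index=False)
    paths["sample_cell_counts"] = str(p)

    # reference marker levels: arcsinh-scale 98th percentiles near the
    # simulated positive marker level
    level = float(np.arcsinh(np.exp(config.marker_pos[0]) * 2.2 / config.cofactor))
    ref_mark = pd.DataFrame(
        rng.normal(level, 0.1, size=(7, len(MARKER_CHANNELS))),
        columns=list(MARKER_CHANNELS),
    ).clip(lower=0)
    p = out / "ref_marker_levels.csv"
    ref_mark.to_csv(p, index=False)
    paths["ref_marker_levels"] = str(p)
    return paths
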