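"""End-to-end pipeline orchestration with a machine-readable run log.

Stages run in acquisition-processing order: read/concatenate -> optional
time filter -> bead normalization -> debarcoding -> compensation -> gating
-> batch correction -> quality control.  Each stage appends its parameters
and summary counts to a JSON-serializable run log keyed by stage name, so
a run is reproducible from its config (plus seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .batch import (apply_correction, correction_factors, qc_cell_counts,
                    qc_marker_levels, read_reference_quantiles)
from .compensation import SpilloverMatrix, compensate
from .debarcoding import (UNASSIGNED, apply_cutoffs, assign_prelim,
                          compute_yields, est_cutoffs, read_scheme)
from .frame import CytofFrame, filter_time_range, read_fcs, write_fcs
from .gating import fit_ellipse_gate, gate_yields, live_gate_polygon, apply_polygon
from .normalization import BeadConfig, normalize, qc_bead_means

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "save_bundle", "load_bundle"]

STAGES = ("prep", "normalize", "debarcode", "compensate", "gate", "batchcorrect", "qc")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_bundle(frame: CytofFrame, out_dir: str | Path, assays: list[str] | None = None) -> None:
    """Persist a frame as text+FCS artifacts (one FCS per assay, CSV metadata,
    JSON experiment metadata) so stages can run standalone."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for assay in assays or list(frame.assays):
        write_fcs(frame, assay=assay, out_dir=out, prefix=f"assay_{assay}")
    frame.event_meta.to_csv(out / "event_meta.csv", index=False)
    frame.channel_meta.to_csv(out / "channel_meta.csv", index=False)
    with open(out / "experiment_meta.json", "w") as fh:
        json.dump(frame.experiment_meta, fh, indent=1, default=str)


def load_bundle(in_dir: str | Path) -> CytofFrame:
    """Load a frame previously written by :func:`save_bundle`."""
    from .fcs import read_fcs_file

    src = Path(in_dir)
    with open(src / "experiment_meta.json") as fh:
        experiment_meta = json.load(fh)
    channel_meta = pd.read_csv(src / "channel_meta.csv")
    channel_meta["mass"] = pd.array(channel_meta["mass"], dtype="Int64")
    event_meta = pd.read_csv(src / "event_meta.csv")
    assays = {}
    for p in sorted(src.glob("assay_*.fcs")):
        name = p.stem.removeprefix("assay_")
        data, names, _, _ = read_fcs_file(p)
        order = [names.index(c) for c in channel_meta["channel_name"]]
        assays[name] = data[:, order]
    return CytofFrame(assays, event_meta, channel_meta, experiment_meta)


def _annotate_samples(frame: CytofFrame) -> None:
    """Derive sample/type/group metadata from barcode IDs of the form
    ``<type>_<group><replicate>`` (e.g. ``PBMC_R2``)."""
    bc = frame.event_meta["bc_id"].astype(str)
    frame.event_meta["sample"] = bc
    frame.event_meta["type"] = bc.str.replace(r"_.*", "", regex=True)
    frame.event_meta["group"] = bc.str.replace(r"[^RS]", "", regex=True).str[:1].fillna("")


def run_pipeline(config: dict, seed: int | None = None) -> tuple[CytofFrame, dict]:
    """Execute the full pipeline from a config mapping; returns the final
    frame and the run log.  Any stage error aborts with the stage name."""
    state: dict = {"stage": "prep"}
    try:
        return _run_pipeline(config, seed, state)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {state['stage']!r} failed: {exc}") from exc


def _run_pipeline(config: dict, seed: int | None, state: dict) -> tuple[CytofFrame, dict]:
    out_dir = Path(config.get("output_dir", "cytoprep_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0) if seed is None else seed
    log: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
    }

    def record(stage: str, params: dict, counts: dict) -> None:
        log["stages"][stage] = {"params": params, "counts": counts}

    # -- prep: read/concat (or simulate) + optional time filter ------------
    cofactor = float(config.get("cofactor", 5.0))
    truth = None
    if "simulate" in config.get("input", {}):
        from .synthetic import SimConfig, simulate_experiment

        sim_kwargs = dict(config["input"]["simulate"] or {})
        sim_kwargs.setdefault("cofactor", cofactor)
        sim_kwargs["seed"] = seed
        sim_config = SimConfig(**sim_kwargs)
        # apply the run's spillover matrix as simulation ground truth so
        # compensation corrects the spill the generator introduced
        sm_path = config.get("compensation", {}).get("spillover")
        if sm_path and sim_config.sm_truth is None:
            sim_config.sm_truth = SpilloverMatrix.from_csv(sm_path)
        frame, truth = simulate_experiment(sim_config)
    else:
        paths = config["input"]["fcs"]
        frame = read_fcs(paths, cofactor=cofactor)
    record("prep", {"cofactor": cofactor}, {"events": frame.n_events,
                                            "channels": frame.n_channels})
    if "time_filter" in config:
        tf = config["time_filter"]
        frame = filter_time_range(frame, tf["t_min"], tf["t_max"], tf.get("mode", "keep"))
        record("time_filter", tf, {"events": frame.n_events})

    # -- normalization -----------------------------------------------------
    state["stage"] = "normalize"
    ncfg = config.get("normalization", {})
    bead_config = BeadConfig(
        bead_masses=ncfg.get("beads", "dvs"),
        dna_masses=tuple(ncfg.get("dna", (191, 193))),
        trim=float(ncfg.get("trim", 5.0)),
        window_k=int(ncfg.get("window_k", 500)),
        sep_cutoff=float(ncfg.get("sep_cutoff", 0.35)),
        baseline=ncfg.get("norm_to"),
    )
    norm = normalize(frame, bead_config)
    record(
        "normalize",
        {"beads": list(bead_config.bead_masses), "dna": list(bead_config.dna_masses),
         "trim": bead_config.trim, "window_k": bead_config.window_k,
         "baseline": "reference" if ncfg.get("norm_to") else "internal"},
        {"data": norm.data.n_events, "beads": norm.beads.n_events,
         "removed": norm.removed.n_events},
    )
    norm.baseline.to_csv(out_dir / "bead_baseline.csv")
    frame = norm.data

    # -- debarcoding -------------------------------------------------------
    state["stage"] = "debarcode"
    dcfg = config.get("debarcoding", {})
    if "scheme" in dcfg:
        scheme = read_scheme(dcfg["scheme"], remove_empty=dcfg.get("remove_empty", True))
    else:
        from .synthetic import default_scheme

        scheme = default_scheme()
    res = assign_prelim(frame, scheme, assay=dcfg.get("assay", "normexprs"))
    n_unassigned_prelim = int((res.bc_id == UNASSIGNED).sum())
    compute_yields(res)
    sep = dcfg.get("sep_cutoffs")
    est = est_cutoffs(res, frame)
    apply_cutoffs(res, frame, sep_cutoffs=sep, mhl_cutoff=float(dcfg.get("mhl_cutoff", 30.0)))
    est.to_csv(out_dir / "sep_cutoffs.csv")
    res.yields.to_csv(out_dir / "yields.csv")
    record(
        "debarcode",
        {"assay": dcfg.get("assay", "normexprs"), "n_barcodes": scheme.n,
         "sep_cutoffs": "global" if sep is not None else "estimated",
         "mhl_cutoff": float(dcfg.get("mhl_cutoff", 30.0))},
        {"events": frame.n_events, "unassigned_prelim": n_unassigned_prelim,
         "unassigned_final": int((res.bc_id == UNASSIGNED).sum())},
    )
    keep = res.bc_id != UNASSIGNED
    frame = frame.subset_events(keep)
    _annotate_samples(frame)

    # -- compensation ------------------------------------------------------
    state["stage"] = "compensate"
    ccfg = config.get("compensation", {})
    if "spillover" in ccfg:
        sm = SpilloverMatrix.from_csv(ccfg["spillover"])
        frame = compensate(frame, sm, method=ccfg.get("method", "nnls"),
                           assay=ccfg.get("assay", "normcounts"))
    else:  # no spillover matrix: pass-through compensation (identity)
        frame.add_assay("compcounts", frame.assays["normcounts"], overwrite=True)
        frame.add_assay("compexprs", frame.assays["normexprs"], overwrite=True)
    record("compensate", {"method": ccfg.get("method", "nnls"),
                          "spillover": ccfg.get("spillover", "identity")},
           {"events": frame.n_events})

    # -- gating ------------------------------------------------------------
    state["stage"] = "gate"
    gcfg = config.get("gating", {})
    dna_ch = gcfg.get("dna_channels", ["Ir191Di", "Ir193Di"])
    live_ch = gcfg.get("live_channels", ["Ir191Di", "Pt194Di"])
    q_cells = float(gcfg.get("quantile", 0.98))
    defaults = {"q": 0.99, "i": 0.9, "s": 0.4}
    defaults.update(gcfg.get("live", {}))
    per_sample = gcfg.get("per_sample", {})
    dna_idx = frame.channel_indices(dna_ch)
    live_idx = frame.channel_indices(live_ch)
    E = frame.assays["compexprs"]
    cells_mask = np.zeros(frame.n_events, dtype=bool)
    live_mask = np.zeros(frame.n_events, dtype=bool)
    parent_counts, cell_counts, live_counts = {}, {}, {}
    for sample, idx in frame.event_meta.groupby("sample", observed=True).groups.items():
        idx = np.asarray(idx, dtype=int)
        parent_counts[sample] = len(idx)
        if len(idx) < 10:
            logger.warning("sample %s has %d events; gating skipped", sample, len(idx))
            continue
        gate = fit_ellipse_gate(E[np.ix_(idx, dna_idx)], q=q_cells)
        cm = gate.mask(E[np.ix_(idx, dna_idx)])
        cells_mask[idx[cm]] = True
        cell_counts[sample] = int(cm.sum())
        params = {**defaults, **per_sample.get(sample, {})}
        sub = idx[cm]
        if len(sub) < 10:
            continue
        try:
            poly = live_gate_polygon(E[np.ix_(sub, live_idx)], **params)
        except ValueError as exc:
            logger.warning("live gate failed for %s: %s", sample, exc)
            continue
        lm = apply_polygon(E[np.ix_(sub, live_idx)], poly)
        live_mask[sub[lm]] = True
        live_counts[sample] = int(lm.sum())
    yields_cells = gate_yields(parent_counts, cell_counts)
    yields_live = gate_yields(cell_counts, {k: live_counts.get(k, 0) for k in cell_counts})
    yields_cells.to_csv(out_dir / "gate_yields_cells.csv")
    yields_live.to_csv(out_dir / "gate_yields_live.csv")
    record("gate", {"dna_channels": dna_ch, "live_channels": live_ch,
                    "quantile": q_cells, "live": defaults},
           {"cells": int(cells_mask.sum()), "live": int(live_mask.sum())})
    frame = frame.subset_events(live_mask)

    # -- batch correction --------------------------------------------------
    state["stage"] = "batchcorrect"
    bcfg = config.get("batch", {})
    ref_mask = (frame.event_meta["group"] == "R").to_numpy()
    if "ref_marker_levels" in bcfg and ref_mask.any():
        ref = read_reference_quantiles(bcfg["ref_marker_levels"])
        factors = correction_factors(frame, ref, ref_mask, p=float(bcfg.get("p", 0.98)))
        apply_correction(frame, factors)
        factors.to_csv(out_dir / "batch_factors.csv")
        record("batchcorrect", {"p": float(bcfg.get("p", 0.98))},
               {"events": frame.n_events,
                "channels_corrected": int((factors != 1).sum())})
    else:
        frame.add_assay("bccounts", frame.assays["compcounts"], overwrite=True)
        frame.add_assay("bcexprs", frame.assays["compexprs"], overwrite=True)
        record("batchcorrect", {"p": None}, {"events": frame.n_events,
                                             "channels_corrected": 0})

    # -- QC ----------------------------------------------------------------
    state["stage"] = "qc"
    qcfg = config.get("qc", {})
    qc_counts = qc_cell_counts(frame, "sample", qcfg.get("ref_cell_counts"))
    qc_counts.to_csv(out_dir / "qc_cell_counts.csv", index=False)
    bead_qc = qc_bead_means(norm.beads, bead_config.bead_masses,
                            qcfg.get("ref_bead_counts"))
    bead_qc.to_csv(out_dir / "qc_bead_means.csv")
    n_tables = 2
    if "ref_marker_levels" in bcfg and ref_mask.any():
        levels = qc_marker_levels(frame, read_reference_quantiles(bcfg["ref_marker_levels"]),
                                  (frame.event_meta["group"] == "R").to_numpy(),
                                  p=float(bcfg.get("p", 0.98)))
        levels.to_csv(out_dir / "qc_marker_levels.csv")
        n_tables += 1
    record("qc", {"tables": n_tables}, {"events": frame.n_events})

    if config.get("write_fcs", False):
        write_fcs(frame, assay="bccounts", split_by="sample", out_dir=out_dir / "fcs")

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return frame, log
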