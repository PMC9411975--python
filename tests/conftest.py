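import numpy as np
import pandas as pd
import pytest

from cytoprep import CytofFrame, SimConfig, simulate_experiment
from cytoprep.synthetic import MARKER_CHANNELS, make_spillover, simulate_single_stains


@pytest.fixture(scope="session")
def sim_default():
    """A default-condition acquisition: 15-plex, 7.5% beads, 2% doublets,
    10% dead, 20% drift."""
    return simulate_experiment(SimConfig(n_events=50_000, seed=11))


@pytest.fixture(scope="session")
def single_stain():
    """Single-stained controls mixed with a known spillover matrix."""
    channels = list(MARKER_CHANNELS)
    rng = np.random.default_rng(7)
    sm_true = make_spillover(channels, rng, magnitude=(0.0, 0.04))
    frame, truth, scheme = simulate_single_stains(
        channels, n_per=600, sm_truth=sm_true, seed=8
    )
    return frame, truth, scheme, sm_true


def make_frame(counts: np.ndarray, channels: list[str], cofactor: float = 5.0,
               **event_cols) -> CytofFrame:
    """Small helper: build a frame from a raw count matrix."""
    from cytoprep.frame import _make_channel_meta, arcsinh

    channel_meta = _make_channel_meta(channels, [""] * len(channels))
    exprs = counts.astype(float).copy()
    mass = channel_meta["mass"].notna().to_numpy()
    exprs[:, mass] = arcsinh(counts[:, mass], cofactor)
    event_meta = pd.DataFrame({"file_id": ["f0"] * len(counts), **event_cols})
    return CytofFrame({"counts": counts.astype(float), "exprs": exprs},
                      event_meta, channel_meta, {"cofactor": cofactor})


def oracle_prelim(X: np.ndarray, scheme) -> np.ndarray:
    """Exhaustive preliminary-assignment oracle: compare every event against
    every candidate word by pairwise channel comparisons (value descending,
    ties broken by channel order)."""
    key = scheme.key.to_numpy()
    ids = scheme.barcode_ids
    out = []
    for x in X:
        if not (x > 0).any():
            out.append("0")
            continue
        match = "0"
        for r, row in enumerate(key):
            pos = np.flatnonzero(row == 1)
            neg = np.flatnonzero(row == 0)
            if all(
                (x[p] > x[q]) or (x[p] == x[q] and p < q)
                for p in pos for q in neg
            ):
                match = ids[r]
                break
        out.append(match)
    return np.array(out, dtype=object)
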