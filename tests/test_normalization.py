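"""Bead identification, smoothing, slope fitting and drift correction."""

import numpy as np
import pandas as pd
import pytest

from cytoprep import BeadConfig, SimConfig, simulate_experiment
from cytoprep.normalization import (compute_baseline, compute_slopes,
                                    identify_beads, normalize, qc_bead_means,
                                    smooth_beads)

from conftest import make_frame


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full((100, 2), 7.0)
        assert (smooth_beads(x, 11) == 7.0).all()

    def test_single_outlier_removed(self):
        x = np.full((600, 1), 10.0)
        x[300] = 1e6
        sm = smooth_beads(x, 499)
        assert (sm == 10.0).all()

    def test_linear_ramp_interior_preserved(self):
        """The median of a symmetric window on a linear ramp is the ramp."""
        x = np.linspace(0, 100, 301).reshape(-1, 1)
        k = 51
        sm = smooth_beads(x, k)
        half = k // 2
        assert np.allclose(sm[half:-half, 0], x[half:-half, 0])

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            smooth_beads(np.ones((2, 1)), 5)


class TestSlopes:
    def test_identity_and_half_signal(self):
        baseline = np.array([10.0, 20.0, 30.0])
        assert np.allclose(compute_slopes(np.tile(baseline, (5, 1)), baseline), 1.0)
        assert np.allclose(compute_slopes(np.tile(baseline / 2, (5, 1)), baseline), 2.0)

    def test_degenerate_row_rejected(self):
        with pytest.raises(ValueError):
            compute_slopes(np.zeros((3, 2)), np.ones(2))


class TestBaseline:
    def test_constant_beads_exact(self):
        f = make_frame(np.full((50, 2), 123.0), ["Ce140Di", "Eu151Di"])
        base = compute_baseline(f, (140, 151))
        assert (base == 123.0).all()

    def test_reference_fcs_equals_column_means(self, tmp_path):
        from cytoprep import write_fcs

        rng = np.random.default_rng(0)
        counts = np.round(rng.lognormal(7, 0.2, size=(500, 2)))
        f = make_frame(counts, ["Ce140Di", "Eu151Di"])
        (path,) = write_fcs(f, out_dir=tmp_path)
        base = compute_baseline(path, (140, 151))
        assert np.allclose(base.to_numpy(), counts.mean(axis=0), rtol=1e-6)

    def test_missing_channel_rejected(self):
        f = make_frame(np.ones((5, 1)), ["Ce140Di"])
        with pytest.raises(ValueError):
            compute_baseline(f, (140, 151))


class TestIdentifyBeads:
    def test_bead_tagging_recall_and_precision(self):
        frame, truth = simulate_experiment(SimConfig(n_events=50_000, seed=2,
                                                     bead_fraction=0.05))
        singlet, removed = identify_beads(frame, BeadConfig())
        true_bead = (truth["true_class"] == "bead").to_numpy()
        recall = (removed & true_bead).sum() / true_bead.sum()
        # every event flagged for removal is a bead or a doublet
        bead_like = true_bead | (truth["true_class"] == "doublet").to_numpy()
        precision = (removed & bead_like).sum() / removed.sum()
        assert recall >= 0.99
        assert precision >= 0.99
        # singlets used for fitting are pure beads
        assert (singlet & ~true_bead).sum() / singlet.sum() <= 0.01
        assert (singlet & ~removed).sum() == 0  # beads subset of removed

    def test_no_beads_errors(self):
        frame, _ = simulate_experiment(SimConfig(n_events=2_000, seed=3,
                                                 bead_fraction=0.0))
        with pytest.raises(ValueError, match="bead"):
            identify_beads(frame, BeadConfig())


@pytest.fixture(scope="module")
def drifted():
    frame, truth = simulate_experiment(SimConfig(n_events=50_000, seed=4))
    return frame, truth, normalize(frame, BeadConfig())


class TestNormalize:
    def test_partition_property(self, drifted):
        frame, _, res = drifted
        assert res.data.n_events + res.removed.n_events == frame.n_events
        assert res.beads.n_events <= res.removed.n_events

    def test_slopes_positive_and_drift_shaped(self, drifted):
        _, _, res = drifted
        assert (res.slopes > 0).all()
        # 20% decay: late slopes must exceed early slopes
        third = len(res.slopes) // 3
        assert res.slopes.iloc[-third:].mean() > res.slopes.iloc[:third].mean()

    def test_multiplicative_and_sign_preserving(self, drifted):
        _, _, res = drifted
        counts = res.data.assays["counts"]
        normed = res.data.assays["normcounts"]
        mass = res.data.mass_channel_mask
        assert ((counts[:, mass] == 0) == (normed[:, mass] == 0)).all()
        assert (normed[:, mass] >= 0).all()

    def test_drift_flattened_within_3pct(self, drifted):
        _, _, res = drifted
        rel = (res.smoothed_normed / res.baseline - 1.0).abs()
        assert rel.to_numpy().max() < 0.03

    def test_no_drift_gives_unit_slopes(self):
        frame, _ = simulate_experiment(SimConfig(n_events=30_000, seed=5,
                                                 drift_amount=0.0))
        res = normalize(frame, BeadConfig())
        assert np.abs(res.slopes.to_numpy() - 1.0).max() < 0.05
        raw = frame.assays["counts"][:, frame.mass_channel_mask]
        normed = frame.assays["normcounts"][:, frame.mass_channel_mask]
        nz = raw > 0
        assert np.abs(normed[nz] / raw[nz] - 1.0).max() < 0.05

    def test_external_reference_centers_at_its_baseline(self, tmp_path):
        """Normalizing to reference beads with higher means recenters the
        smoothed bead signal at the reference level."""
        from cytoprep import write_fcs

        rng = np.random.default_rng(6)
        ref_counts = np.round(rng.lognormal(np.log(5000), 0.1, size=(2000, 5)))
        ref = make_frame(ref_counts, ["Ce140Di", "Eu151Di", "Eu153Di",
                                      "Ho165Di", "Lu175Di"])
        (ref_path,) = write_fcs(ref, out_dir=tmp_path)
        frame, _ = simulate_experiment(SimConfig(n_events=40_000, seed=7))
        res = normalize(frame, BeadConfig(baseline=ref_path))
        assert (res.baseline > 4000).all()  # reference level, not the run's own
        rel = (res.smoothed_normed / res.baseline - 1.0).abs()
        assert rel.to_numpy().max() < 0.03


def test_qc_bead_means_exact_on_constant():
    f = make_frame(np.full((20, 2), 50.0), ["Ce140Di", "Eu151Di"])
    tab = qc_bead_means(f, (140, 151))
    assert (tab.loc["current"] == 50.0).all()


def test_qc_bead_means_close_to_lognormal_mean():
    rng = np.random.default_rng(8)
    mu, sd, n = np.log(2500), 0.1, 20_000
    counts = rng.lognormal(mu, sd, size=(n, 1))
    f = make_frame(counts, ["Ce140Di"])
    analytic = np.exp(mu + sd**2 / 2)
    se = analytic * np.sqrt((np.exp(sd**2) - 1) / n)
    tab = qc_bead_means(f, (140,))
    assert abs(tab.loc["current"].iloc[0] - analytic) < 2 * se
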