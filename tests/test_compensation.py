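"""Interaction mask, spillover estimation, NNLS/flow compensation."""

import numpy as np
import pandas as pd
import pytest

from cytoprep import SpilloverMatrix, adapt_sm, compensate, estimate_spillover, interaction_mask
from cytoprep.compensation import _nnls_rows
from cytoprep.debarcoding import apply_cutoffs, assign_prelim, compute_yields, est_cutoffs
from cytoprep.synthetic import MARKER_CHANNELS, simulate_single_stains

from conftest import make_frame


class TestInteractionMask:
    def test_chemistry_rules(self):
        chs = ["Nd145Di", "Nd146Di", "Nd148Di", "Dy162Di", "Pr141Di"]
        m = interaction_mask(chs)
        assert m.loc["Nd146Di", "Nd145Di"]     # M - 1 (abundance sensitivity)
        assert m.loc["Nd145Di", "Nd146Di"]     # M + 1
        assert m.loc["Nd146Di", "Dy162Di"]     # M + 16 (oxide)
        assert m.loc["Nd146Di", "Nd148Di"]     # isotope impurity
        assert not m.loc["Pr141Di", "Dy162Di"]  # 21 amu apart, different metal
        assert (np.diag(m.to_numpy())).all()   # diagonal allowed

    def test_mass_gap_not_allowed(self):
        m = interaction_mask(["Pr141Di", "Yb171Di"])  # 30 amu apart
        assert not m.loc["Pr141Di", "Yb171Di"]
        assert not m.loc["Yb171Di", "Pr141Di"]


class TestSpilloverMatrix:
    def test_invariants_enforced(self):
        chs = ["Nd145Di", "Nd146Di"]
        with pytest.raises(ValueError):
            SpilloverMatrix(pd.DataFrame([[1.0, -0.1], [0.0, 1.0]], index=chs, columns=chs))
        with pytest.raises(ValueError):
            SpilloverMatrix(pd.DataFrame([[0.9, 0.0], [0.0, 1.0]], index=chs, columns=chs))

    def test_adapt_identity_when_aligned(self):
        chs = ["Nd145Di", "Nd146Di"]
        sm = SpilloverMatrix(pd.DataFrame([[1.0, 0.02], [0.01, 1.0]], index=chs, columns=chs))
        out = adapt_sm(sm, chs)
        assert np.allclose(out.to_numpy(), sm.to_numpy())

    def test_adapt_extra_channel_gets_identity(self):
        chs = ["Nd145Di", "Nd146Di"]
        sm = SpilloverMatrix(pd.DataFrame([[1.0, 0.02], [0.01, 1.0]], index=chs, columns=chs))
        out = adapt_sm(sm, chs + ["Pr141Di"])
        assert out.sm.loc["Pr141Di", "Pr141Di"] == 1.0
        assert out.sm.loc["Pr141Di", chs].sum() == 0.0
        assert out.sm.loc[chs, "Pr141Di"].sum() == 0.0

    def test_adapt_permutation_oracle(self):
        rng = np.random.default_rng(0)
        chs = ["Nd145Di", "Nd146Di", "Pr141Di"]
        base = np.eye(3) + np.triu(rng.uniform(0, 0.03, (3, 3)), 1)
        sm = SpilloverMatrix(pd.DataFrame(base, index=chs, columns=chs))
        perm = ["Pr141Di", "Nd146Di", "Nd145Di"]
        shuffled = SpilloverMatrix(sm.sm.loc[perm, perm])
        out = adapt_sm(shuffled, chs)
        assert np.allclose(out.to_numpy(), sm.to_numpy())


@pytest.fixture(scope="module")
def deconvoluted(single_stain):
    frame, truth, scheme, sm_true = single_stain
    frame = frame.copy()
    res = assign_prelim(frame, scheme, assay="exprs")
    compute_yields(res)
    est_cutoffs(res, frame)
    apply_cutoffs(res, frame)
    bc_to_ch = {bid: list(MARKER_CHANNELS)[i]
                for i, bid in enumerate(scheme.barcode_ids)}
    return frame, bc_to_ch, sm_true


class TestEstimation:
    @pytest.mark.parametrize("method", ["default", "classic"])
    def test_parameter_recovery_within_half_percent(self, deconvoluted, method):
        frame, bc_to_ch, sm_true = deconvoluted
        est = estimate_spillover(frame, bc_to_ch, method=method)
        truth = sm_true.sm.loc[est.channels, est.channels].to_numpy()
        assert np.abs(est.to_numpy() - truth).max() < 0.005

    def test_masked_entries_zero_in_default_mode(self, deconvoluted):
        frame, bc_to_ch, _ = deconvoluted
        est = estimate_spillover(frame, bc_to_ch, interactions="default")
        mask = interaction_mask(est.channels).to_numpy()
        assert (est.to_numpy()[~mask] == 0).all()

    def test_no_spill_gives_near_identity(self):
        frame, truth, scheme = simulate_single_stains(n_per=400, sm_truth=None, seed=9)
        res = assign_prelim(frame, scheme, assay="exprs")
        compute_yields(res)
        est_cutoffs(res, frame)
        apply_cutoffs(res, frame)
        bc_to_ch = {bid: list(MARKER_CHANNELS)[i]
                    for i, bid in enumerate(scheme.barcode_ids)}
        est = estimate_spillover(frame, bc_to_ch)
        off = est.to_numpy()[~np.eye(len(est.channels), dtype=bool)]
        assert off.max() <= 1e-3


class TestCompensate:
    CHS = ["Nd143Di", "Nd145Di", "Nd146Di", "Sm147Di"]

    def _sm(self, s01=0.03, s23=0.04):
        sm = pd.DataFrame(np.eye(4), index=self.CHS, columns=self.CHS)
        sm.iloc[0, 1] = s01
        sm.iloc[2, 3] = s23
        return SpilloverMatrix(sm)

    def test_identity_matrix_is_noop(self):
        rng = np.random.default_rng(1)
        J = rng.lognormal(3, 1, size=(100, 4))
        f = make_frame(J, self.CHS)
        sm = SpilloverMatrix(pd.DataFrame(np.eye(4), index=self.CHS, columns=self.CHS))
        compensate(f, sm, method="nnls")
        assert np.allclose(f.assays["compcounts"], J)

    def test_nnls_recovers_noiseless_mixture(self):
        rng = np.random.default_rng(2)
        I = rng.lognormal(3, 1, size=(300, 4))
        sm = self._sm()
        J = I @ sm.to_numpy()
        f = make_frame(J, self.CHS)
        compensate(f, sm, method="nnls")
        rel = np.abs(f.assays["compcounts"] - I) / I
        assert rel.max() < 1e-6

    def test_nnls_nonnegative_where_flow_goes_negative(self):
        # zero true signal in the receiving channel plus noise makes the
        # exact inverse dip below zero; NNLS must not
        rng = np.random.default_rng(3)
        I = np.zeros((200, 4))
        I[:, 0] = rng.lognormal(4, 0.5, 200)
        sm = self._sm(s01=0.05)
        J = I @ sm.to_numpy()
        J[:, 1] = np.maximum(J[:, 1] - 2.0, 0.0)  # undershoot the spill
        f = make_frame(J, self.CHS)
        compensate(f, sm, method="flow")
        flow = f.assays["compcounts"].copy()
        compensate(f, sm, method="nnls", overwrite=False)
        nnls = f.assays["compcounts"]
        assert (flow < 0).any()
        assert (nnls >= 0).all()

    def test_result_independent_of_chunking(self):
        rng = np.random.default_rng(4)
        A = self._sm().to_numpy()
        J = rng.lognormal(2, 1, size=(50, 4))
        a = _nnls_rows(A, J, chunk=7)
        b = _nnls_rows(A, J, chunk=50)
        assert np.array_equal(a, b)

    def test_flow_matches_exact_inverse(self):
        rng = np.random.default_rng(5)
        I = rng.lognormal(3, 1, size=(100, 4))
        sm = self._sm()
        f = make_frame(I @ sm.to_numpy(), self.CHS)
        compensate(f, sm, method="flow")
        assert np.allclose(f.assays["compcounts"], I, rtol=1e-8)
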