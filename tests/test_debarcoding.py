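"""Barcoding schemes, preliminary assignment, cutoff estimation, filtering."""

import numpy as np
import pandas as pd
import pytest

from cytoprep import BarcodingScheme, assign_prelim, apply_cutoffs, compute_yields, est_cutoffs
from cytoprep.debarcoding import (UNASSIGNED, DebarcodingResult, _log_logistic,
                                  read_scheme)
from cytoprep.synthetic import BARCODE_MASSES, SimConfig, default_scheme, simulate_experiment

from conftest import make_frame, oracle_prelim


class TestScheme:
    def test_complete_weight3_scheme_has_20_barcodes(self):
        scheme = default_scheme(include_empty=True)
        assert scheme.n == 20
        assert (scheme.k_per_row == 3).all()
        # all 6-choose-3 words present exactly once
        assert len(set(map(tuple, scheme.key.to_numpy()))) == 20

    def test_removing_empties_leaves_15_samples(self):
        assert default_scheme(include_empty=True).drop_empty().n == 15

    def test_csv_round_trip(self, tmp_path):
        scheme = default_scheme(include_empty=True)
        p = tmp_path / "scheme.csv"
        scheme.to_csv(str(p))
        assert read_scheme(p).n == 20
        assert read_scheme(p, remove_empty=True).n == 15

    @pytest.mark.parametrize(
        "rows",
        [
            [[0, 0, 0], [1, 0, 1]],          # all-zero row
            [[1, 0, 1], [1, 0, 1]],          # duplicate rows
            [[1, 2, 0], [0, 1, 1]],          # non-binary entry
        ],
    )
    def test_invalid_keys_rejected(self, rows):
        key = pd.DataFrame(rows, index=["a", "b"], columns=[102, 104, 105])
        with pytest.raises(ValueError):
            BarcodingScheme(key)

    def test_mixed_k_rejected_by_assignment(self):
        key = pd.DataFrame([[1, 0, 0], [1, 1, 0]], index=["a", "b"],
                           columns=[102, 104, 105])
        scheme = BarcodingScheme(key)
        frame = make_frame(np.ones((5, 3)), ["Pd102Di", "Pd104Di", "Pd105Di"])
        with pytest.raises(ValueError, match="mixed-k"):
            assign_prelim(frame, scheme)


class TestPrelim:
    def test_known_intensity_pattern(self):
        """(9,0,9,0,9,0) must map to the barcode positive for masses 102/105/108."""
        scheme = default_scheme(include_empty=True)
        chs = [f"Pd{m}Di" for m in BARCODE_MASSES]
        x = np.array([[9.0, 0, 9, 0, 9, 0]] * 5)
        frame = make_frame(x, chs)
        res = assign_prelim(frame, scheme, assay="exprs")
        expected = scheme.key[(scheme.key[102] == 1) & (scheme.key[105] == 1)
                              & (scheme.key[108] == 1)].index[0]
        assert (res.bc_id == str(expected)).all()

    def test_word_absent_from_key_is_unassigned(self):
        scheme = default_scheme()  # 15 rows: some weight-3 words removed
        chs = [f"Pd{m}Di" for m in BARCODE_MASSES]
        empties = default_scheme(include_empty=True).key.filter(like="empty", axis=0)
        word = empties.iloc[0].to_numpy().astype(float) * 9
        frame = make_frame(np.tile(word, (4, 1)), chs)
        res = assign_prelim(frame, scheme, assay="exprs")
        assert (res.bc_id == UNASSIGNED).all()

    def test_all_zero_events_unassigned_with_zero_delta(self):
        scheme = default_scheme()
        chs = [f"Pd{m}Di" for m in BARCODE_MASSES]
        frame = make_frame(np.zeros((3, 6)), chs)
        res = assign_prelim(frame, scheme, assay="exprs")
        assert (res.bc_id == UNASSIGNED).all()
        assert (res.delta == 0).all()

    def test_agrees_with_brute_force_oracle(self, sim_default):
        frame, _ = sim_default
        scheme = default_scheme()
        res = assign_prelim(frame.copy(), scheme, assay="exprs")
        rng = np.random.default_rng(0)
        idx = rng.choice(frame.n_events, 1000, replace=False)
        cols = frame.channel_indices(scheme.channel_masses)
        expected = oracle_prelim(frame.assays["exprs"][np.ix_(idx, cols)], scheme)
        assert (res.bc_id[idx] == expected.astype(str)).all()

    def test_delta_bounded(self, sim_default):
        frame, _ = sim_default
        res = assign_prelim(frame.copy(), default_scheme(), assay="exprs")
        assert ((res.delta >= 0) & (res.delta <= 1)).all()


def _result_with_yields(yields: pd.DataFrame) -> DebarcodingResult:
    key = pd.DataFrame(np.eye(len(yields.columns), dtype=int),
                       index=list(yields.columns),
                       columns=list(range(102, 102 + len(yields.columns))))
    res = DebarcodingResult(
        scheme=BarcodingScheme(key), assay="exprs",
        bc_id=np.array([], dtype=str), delta=np.array([]),
        scaled=np.empty((0, len(yields.columns))),
    )
    res.yields = yields
    return res


class TestYieldsAndCutoffs:
    def test_yield_curve_endpoints_and_midpoint(self):
        key = pd.DataFrame([[1]], index=["a"], columns=[102])
        res = DebarcodingResult(
            scheme=BarcodingScheme(key), assay="exprs",
            bc_id=np.array(["a", "a"], dtype=object),
            delta=np.array([0.2, 0.8]),
            scaled=np.zeros((2, 1)),
        )
        y = compute_yields(res)
        assert y["a"].iloc[0] == 1.0           # cutoff 0: everything passes
        assert y["a"].loc[0.5] == 0.5          # between the two deltas
        assert y["a"].iloc[-1] <= 0.5          # at 1.0 only delta >= 1 passes
        assert (np.diff(y["a"].to_numpy()) <= 1e-12).all()  # non-increasing

    def test_linear_yields_give_half_initial_cutoff(self):
        grid = np.round(np.arange(0, 1.01, 0.01), 2)
        res = _result_with_yields(pd.DataFrame({"a": 1.0 - grid}, index=grid))
        est_cutoffs(res)
        assert res.cutoff_fits.loc["a", "c_linear"] == pytest.approx(0.5, abs=1e-8)

    def test_perfect_log_logistic_yields_weight_zero(self):
        grid = np.round(np.arange(0, 1.01, 0.01), 2)
        y = _log_logistic(grid, b=6.0, e=0.35, d=0.95)
        res = _result_with_yields(pd.DataFrame({"a": y}, index=grid))
        cut = est_cutoffs(res)
        fits = res.cutoff_fits.loc["a"]
        assert fits["w"] == pytest.approx(0.0, abs=1e-4)
        assert cut["a"] == pytest.approx(fits["c_log_logistic"], abs=1e-3)


@pytest.fixture(scope="module")
def assigned(sim_default):
    frame, _ = sim_default
    frame = frame.copy()
    res = assign_prelim(frame, default_scheme(), assay="exprs")
    compute_yields(res)
    return frame, res


class TestApplyCutoffs:
    def test_zero_cutoff_and_infinite_mhl_is_identity(self, assigned):
        _, res = assigned
        ids = apply_cutoffs(res, sep_cutoffs=0.0, mhl_cutoff=np.inf)
        assert (ids == res.prelim_id).all()

    def test_zero_delta_events_always_unassigned(self, assigned):
        _, res = assigned
        ids = apply_cutoffs(res, sep_cutoffs=0.05, mhl_cutoff=np.inf)
        assert (ids[res.delta == 0] == UNASSIGNED).all()

    def test_global_equals_uniform_per_barcode(self, assigned):
        _, res = assigned
        ids_global = apply_cutoffs(res, sep_cutoffs=0.3, mhl_cutoff=np.inf).copy()
        per_bc = {bc: 0.3 for bc in res.scheme.barcode_ids}
        ids_specific = apply_cutoffs(res, sep_cutoffs=per_bc, mhl_cutoff=np.inf)
        assert (ids_global == ids_specific).all()

    def test_raising_cutoff_shrinks_assigned_set(self, assigned):
        _, res = assigned
        low = apply_cutoffs(res, sep_cutoffs=0.2, mhl_cutoff=np.inf).copy()
        high = apply_cutoffs(res, sep_cutoffs=0.5, mhl_cutoff=np.inf)
        for bc in res.scheme.barcode_ids:
            assert set(np.flatnonzero(high == bc)) <= set(np.flatnonzero(low == bc))

    def test_unassigned_fraction_tracks_contamination(self, sim_default):
        """At high SNR the unassigned fraction approximates the bead+doublet
        contamination rate (within 2 percentage points)."""
        frame, truth = sim_default
        frame = frame.copy()
        res = assign_prelim(frame, default_scheme(), assay="exprs")
        compute_yields(res)
        est_cutoffs(res, frame)
        ids = apply_cutoffs(res, frame)
        unassigned = (ids == UNASSIGNED).mean()
        contamination = (truth["true_class"] != "cell").mean()
        assert abs(unassigned - contamination) < 0.02
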