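"""Filtering, per-batch centering, replicate merging and presence flags."""

import numpy as np
import pandas as pd
import pytest

from dipscreen.preprocess import (
    assign_presence,
    control_center_batch,
    filter_instances,
    mean_center_batch,
    merge_replicates,
    select_highest_concentration,
)
from conftest import make_instances, make_matrix


def _batch(n, batch="b1", prefix="i", cell="MCF7", control_ids=()):
    rows = [(f"{prefix}{k}", f"d{k}", cell, batch, 10.0, False) for k in range(n)]
    rows += [(c, "CTRL", cell, batch, 0.0, True) for c in control_ids]
    return make_instances(rows)


class TestFilterInstances:
    def test_batch_of_exactly_25_is_excluded(self):
        assert filter_instances(_batch(25), min_batch_size=25).empty

    def test_batch_of_26_is_retained(self):
        assert len(filter_instances(_batch(26), min_batch_size=25)) == 26

    def test_controls_are_dropped_and_dont_count(self):
        inst = _batch(26, control_ids=["c1", "c2"])
        out = filter_instances(inst, min_batch_size=25)
        assert len(out) == 26 and not out.is_control.any()

    def test_all_controls_gives_empty_with_warning(self):
        inst = _batch(0, control_ids=["c1", "c2"])
        with pytest.warns(UserWarning):
            assert filter_instances(inst, min_batch_size=0).empty

    def test_platform_allowlist_is_per_cell_line(self):
        inst = _batch(3)
        out = filter_instances(inst, 0, {"MCF7": {"HT_HG-U133A"}})
        assert len(out) == 3
        assert filter_instances(inst, 0, {"MCF7": {"HG-U133A"}}).empty


class TestHighestConcentration:
    def test_lower_concentrations_are_dropped(self):
        inst = make_instances([
            ("i1", "d1", "MCF7", "b1", 0.1, False),
            ("i2", "d1", "MCF7", "b1", 10.0, False),
            ("i3", "d1", "MCF7", "b2", 10.0, False),
        ])
        out = select_highest_concentration(inst)
        assert sorted(out.instance_id) == ["i2", "i3"]

    def test_single_concentration_unchanged(self):
        inst = make_instances([("i1", "d1", "MCF7", "b1", 1.0, False)])
        pd.testing.assert_frame_equal(select_highest_concentration(inst), inst)

    def test_selection_is_per_cell_line(self):
        inst = make_instances([
            ("i1", "d1", "MCF7", "b1", 10.0, False),
            ("i2", "d1", "PC3", "b2", 1.0, False),
        ])
        assert len(select_highest_concentration(inst)) == 2

    def test_mixed_units_rejected(self):
        inst = make_instances([
            ("i1", "d1", "MCF7", "b1", 100.0, False),
            ("i2", "d1", "MCF7", "b1", 10.0, False),
        ])
        inst.loc[0, "concentration_unit"] = "nM"
        with pytest.raises(ValueError, match="units"):
            select_highest_concentration(inst)

    def test_commutes_with_batch_filter(self):
        # batch b1: 28 drugs at top dose plus 4 low-dose duplicates (32 rows,
        # 28 after dose selection, above the >25 cut either way);
        # batch b2: 10 treatments, below the cut either way.
        rows = [(f"i{k}", f"d{k}", "MCF7", "b1", 10.0, False) for k in range(28)]
        rows += [(f"lo{k}", f"d{k}", "MCF7", "b1", 1.0, False) for k in range(4)]
        rows += [(f"j{k}", f"d{k}", "MCF7", "b2", 10.0, False) for k in range(10)]
        inst = make_instances(rows)
        a = select_highest_concentration(filter_instances(inst, 25))
        b = filter_instances(select_highest_concentration(inst), 25)
        assert sorted(a.instance_id) == sorted(b.instance_id)


class TestMeanCenterBatch:
    def test_two_treatment_arithmetic(self):
        inst = _batch(2)
        mat = make_matrix({"p1": [2.0, 4.0]}, ["i0", "i1"])
        out = mean_center_batch(mat, inst)
        assert out.loc["p1"].tolist() == [-1.0, 1.0]

    def test_three_treatment_arithmetic(self):
        inst = _batch(3)
        mat = make_matrix({"p1": [1.0, 2.0, 6.0]}, ["i0", "i1", "i2"])
        assert mean_center_batch(mat, inst).loc["p1"].tolist() == [-2.0, -1.0, 3.0]

    def test_constant_probe_row_goes_to_zero(self):
        inst = _batch(4)
        mat = make_matrix({"p1": [3.0] * 4}, [f"i{k}" for k in range(4)])
        assert (mean_center_batch(mat, inst).loc["p1"] == 0.0).all()

    def test_idempotent_and_batch_means_vanish(self, rng):
        inst = pd.concat([_batch(10, "b1", "a"), _batch(12, "b2", "b")],
                         ignore_index=True)
        mat = pd.DataFrame(rng.normal(7, 2, (50, 22)),
                           index=[f"p{i}" for i in range(50)],
                           columns=list(inst.instance_id))
        once = mean_center_batch(mat, inst)
        twice = mean_center_batch(once, inst)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12
        for _, group in inst.groupby("batch_id"):
            means = once[list(group.instance_id)].mean(axis=1)
            assert np.abs(means).max() < 1e-9

    def test_single_treatment_batch_rejected(self):
        inst = _batch(1)
        mat = make_matrix({"p1": [2.0]}, ["i0"])
        with pytest.raises(ValueError, match="single treatment"):
            mean_center_batch(mat, inst)

    def test_nan_rejected(self):
        inst = _batch(2)
        mat = make_matrix({"p1": [np.nan, 1.0]}, ["i0", "i1"])
        with pytest.raises(ValueError, match="NaN"):
            mean_center_batch(mat, inst)


class TestControlCenterBatch:
    def test_single_control_baseline(self):
        inst = _batch(1, control_ids=["c1"])
        mat = make_matrix({"p1": [5.0, 4.0]}, ["i0", "c1"])
        assert control_center_batch(mat, inst).loc["p1", "i0"] == 1.0

    def test_treatment_equal_to_control_mean_is_zero(self):
        inst = _batch(1, control_ids=["c1", "c2"])
        mat = make_matrix({"p1": [4.0, 3.0, 5.0]}, ["i0", "c1", "c2"])
        assert control_center_batch(mat, inst).loc["p1", "i0"] == 0.0

    def test_batch_without_controls_rejected(self):
        inst = _batch(3)
        mat = make_matrix({"p1": [1.0, 2.0, 3.0]}, ["i0", "i1", "i2"])
        with pytest.raises(ValueError, match="no control"):
            control_center_batch(mat, inst)


class TestMergeReplicates:
    def test_replicates_average(self):
        inst = make_instances([
            ("i1", "d1", "MCF7", "b1", 10.0, False),
            ("i2", "d1", "MCF7", "b2", 10.0, False),
        ])
        mat = make_matrix({"p1": [1.0, 3.0], "p2": [-1.0, 1.0]}, ["i1", "i2"])
        prof = merge_replicates(mat, inst)["MCF7"]
        assert prof["d1"].tolist() == [2.0, 0.0]

    def test_single_instance_identity(self):
        inst = make_instances([("i1", "d1", "MCF7", "b1", 10.0, False)])
        mat = make_matrix({"p1": [1.5]}, ["i1"])
        assert merge_replicates(mat, inst)["MCF7"]["d1"].tolist() == [1.5]

    def test_cell_lines_stay_separate(self):
        inst = make_instances([
            ("i1", "d1", "MCF7", "b1", 10.0, False),
            ("i2", "d1", "PC3", "b2", 10.0, False),
        ])
        mat = make_matrix({"p1": [1.0, 9.0]}, ["i1", "i2"])
        prof = merge_replicates(mat, inst)
        assert prof["MCF7"]["d1"].iloc[0] == 1.0
        assert prof["PC3"]["d1"].iloc[0] == 9.0

    def test_platforms_not_merged(self):
        inst = make_instances([
            ("i1", "d1", "HL60", "b1", 10.0, False),
            ("i2", "d2", "HL60", "b2", 10.0, False),
        ])
        inst.loc[1, "platform"] = "HG-U133A"
        mat = make_matrix({"p1": [1.0, 2.0]}, ["i1", "i2"])
        prof = merge_replicates(mat, inst)
        assert set(prof) == {"HL60|HT_HG-U133A", "HL60|HG-U133A"}


class TestAssignPresence:
    def _setup(self, calls_per_probe):
        n = len(next(iter(calls_per_probe.values())))
        inst = _batch(n)
        calls = pd.DataFrame(calls_per_probe, index=[f"i{k}" for k in range(n)]).T
        return calls, inst

    def test_half_threshold_is_inclusive(self):
        calls, inst = self._setup({"p1": ["P"] * 5 + ["A"] * 5})
        pres = assign_presence(calls, inst, 0.5, "MCF7")
        assert "p1" in pres

    def test_one_tenth_threshold_is_inclusive(self):
        calls, inst = self._setup({"p1": ["P"] + ["A"] * 9})
        assert "p1" in assign_presence(calls, inst, 0.1, "MCF7")

    def test_below_threshold_excluded_and_marginal_not_present(self):
        calls, inst = self._setup({
            "p1": ["P"] * 4 + ["A"] * 6,
            "p2": ["P"] * 4 + ["M"] * 6,
            "p3": ["A"] * 10,
        })
        pres = assign_presence(calls, inst, 0.5, "MCF7")
        assert len(pres) == 0
        assert "p3" not in assign_presence(calls, inst, 0.01, "MCF7")

    def test_unknown_cell_line_rejected(self):
        calls, inst = self._setup({"p1": ["P", "P"]})
        with pytest.raises(ValueError, match="no treatment instances"):
            assign_presence(calls, inst, 0.5, "HL60")
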