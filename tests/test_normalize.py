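"""Weighted-mean reference, dCt/ddCt chain, and fold-change closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vitremir as v
from vitremir.errors import AnalysisError


def make_ct_matrix(values, samples=None, mirs=None):
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    mirs = mirs or [f"m{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(samples, name="sample_id"),
                        columns=pd.Index(mirs, name="mir_id"))


class TestCtMatrix:
    def test_replicates_collapsed_by_mean(self):
        recs = pd.DataFrame(
            {
                "sample_id": ["S1"] * 3,
                "mir_id": ["miR-16"] * 3,
                "replicate": [1, 2, 3],
                "ct": [20.0, 21.0, 22.0],
            }
        )
        assert v.ct_matrix(recs).loc["S1", "miR-16"] == pytest.approx(21.0)
        recs.loc[2, "ct"] = 40.0
        assert v.ct_matrix(recs, collapse="median").loc["S1", "miR-16"] == pytest.approx(21.0)

    def test_all_undetected_cell_is_nan(self):
        recs = pd.DataFrame(
            {"sample_id": ["S1", "S1"], "mir_id": ["miR-106b"] * 2,
             "replicate": [1, 2], "ct": [np.nan, np.nan]}
        )
        assert np.isnan(v.ct_matrix(recs).loc["S1", "miR-106b"])


class TestWeightedReference:
    def test_equal_sds_reduce_to_plain_mean(self):
        # columns are shifted copies of one pattern -> identical SDs
        base = np.array([20.0, 21.0, 23.0, 19.5])
        mat = make_ct_matrix(np.column_stack([base, base + 3, base - 2]))
        ct0, model, _ = v.weighted_reference(mat, ["m0", "m1", "m2"], wmp=1.0)
        np.testing.assert_allclose(ct0.to_numpy(), mat.mean(axis=1).to_numpy(), atol=1e-12)
        np.testing.assert_allclose(list(model.weights.values()), 1 / 3, atol=1e-12)

    def test_hand_weights_for_sds_one_and_two(self, rng):
        # SDs {1, 2} at wmp 1 -> weights {2/3, 1/3}
        a = np.array([0.0, 1.0, 2.0]) * 1.0 + 20  # SD 1
        b = np.array([0.0, 2.0, 4.0]) * 1.0 + 25  # SD 2
        mat = make_ct_matrix(np.column_stack([a, b]))
        ct0, model, _ = v.weighted_reference(mat, ["m0", "m1"], wmp=1.0)
        assert model.weights["m0"] == pytest.approx(2 / 3)
        assert model.weights["m1"] == pytest.approx(1 / 3)
        np.testing.assert_allclose(ct0.to_numpy(), (2 * a + b) / 3, atol=1e-12)

    def test_wmp_zero_ignores_sds(self, rng):
        mat = make_ct_matrix(rng.normal(25, [1.0, 4.0, 0.2], size=(8, 3)))
        ct0, model, _ = v.weighted_reference(mat, list(mat.columns), wmp=0.0)
        np.testing.assert_allclose(list(model.weights.values()), 1 / 3, atol=1e-12)
        np.testing.assert_allclose(ct0.to_numpy(), mat.mean(axis=1).to_numpy(), atol=1e-12)

    @given(wmp=st.floats(min_value=0.0, max_value=4.0))
    @settings(max_examples=25, deadline=None)
    def test_weights_always_sum_to_one(self, wmp):
        rng = np.random.default_rng(0)
        mat = make_ct_matrix(rng.normal(25, [0.5, 1.0, 2.0, 3.0], size=(10, 4)))
        _, model, _ = v.weighted_reference(mat, list(mat.columns), wmp=wmp)
        assert sum(model.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_member_undetected_flags_sample(self, rng):
        mat = make_ct_matrix(rng.normal(25, 1, size=(5, 2)))
        mat.iloc[2, 0] = np.nan
        ct0, _, flagged = v.weighted_reference(mat, list(mat.columns))
        assert flagged == ["S2"]
        assert "S2" not in ct0.index

    def test_single_member_equals_single_reference(self, rng):
        mat = make_ct_matrix(rng.normal(25, 1, size=(6, 2)), mirs=["miR-16", "miR-146a"])
        w_ct0, _, _ = v.weighted_reference(mat, ["miR-16"], wmp=1.0)
        s_ct0, model, _ = v.single_reference(mat, "miR-16")
        np.testing.assert_allclose(w_ct0.to_numpy(), s_ct0.to_numpy(), atol=1e-12)
        assert model.mode == "single_mir"
        # dCt against a constant-20 reference is Ct - 20
        mat["miR-16"] = 20.0
        ct0, _, _ = v.single_reference(mat, "miR-16")
        dct = v.delta_ct(mat, ct0)
        np.testing.assert_allclose(dct["miR-146a"], mat["miR-146a"] - 20.0)

    def test_missing_member_raises(self, rng):
        mat = make_ct_matrix(rng.normal(25, 1, size=(4, 2)))
        with pytest.raises(AnalysisError):
            v.weighted_reference(mat, ["m0", "ghost"])


class TestFoldChange:
    def _groups(self, n_ctrl, n_case):
        labels = ["control"] * n_ctrl + ["case"] * n_case
        return pd.Series(labels, index=[f"S{i}" for i in range(n_ctrl + n_case)])

    def test_closed_forms(self):
        # ddCt 0 -> FC 1; base 2 at ddCt -1 -> 2; base 1.75 at ddCt -2 -> 3.0625
        dct = make_ct_matrix([[0.0], [0.0], [-1.0], [-2.0]], mirs=["m0"])
        groups = self._groups(2, 2)
        fc2 = v.fold_change(dct, groups, base=2.0)
        assert fc2.loc[fc2["sample_id"] == "S0", "fc"].iloc[0] == pytest.approx(1.0)
        assert fc2.loc[fc2["sample_id"] == "S2", "fc"].iloc[0] == pytest.approx(2.0)
        fc175 = v.fold_change(dct, groups, base=1.75)
        assert fc175.loc[fc175["sample_id"] == "S3", "fc"].iloc[0] == pytest.approx(1.75**2)
        assert (1.75**2) == pytest.approx(3.0625)

    def test_log2fc_consistent_with_fc(self, rng):
        dct = make_ct_matrix(rng.normal(0, 1, size=(6, 2)))
        fc = v.fold_change(dct, self._groups(3, 3), base=1.75)
        np.testing.assert_allclose(fc["log2fc"], np.log2(fc["fc"]), atol=1e-12)
        assert (fc["fc"] > 0).all()

    def test_mir_without_controls_dropped(self):
        dct = make_ct_matrix([[0.0, np.nan], [0.1, np.nan], [1.0, 2.0]], mirs=["m0", "m1"])
        fc = v.fold_change(dct, self._groups(2, 1), base=2.0)
        assert set(fc["mir_id"]) == {"m0"}

    def test_no_controls_at_all_raises(self):
        dct = make_ct_matrix([[0.0], [1.0]], mirs=["m0"])
        groups = pd.Series(["case", "case"], index=["S0", "S1"])
        with pytest.raises(AnalysisError):
            v.fold_change(dct, groups, base=2.0)


class TestLog2Center:
    def test_control_mean_zero_after_centering(self, rng):
        dct = make_ct_matrix(rng.normal(0, 1, size=(10, 3)))
        groups = pd.Series(["control"] * 5 + ["case"] * 5, index=dct.index)
        fc = v.log2_center(v.fold_change(dct, groups, base=1.75))
        for _, sub in fc.groupby("mir_id"):
            ctrl = sub.loc[sub["group"] == "control", "centered_log2fc"]
            assert ctrl.mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_case(self):
        fc = pd.DataFrame(
            {
                "sample_id": ["S0", "S1", "S2", "S3"],
                "mir_id": "m0",
                "group": ["control"] * 3 + ["case"],
                "fc": [2.0, 2.0, 2.0, 4.0],
                "log2fc": [1.0, 1.0, 1.0, 2.0],
            }
        )
        out = v.log2_center(fc)
        assert list(out["centered_log2fc"]) == pytest.approx([0.0, 0.0, 0.0, 1.0])

    def test_idempotent_on_centered_data(self, rng):
        dct = make_ct_matrix(rng.normal(0, 1, size=(8, 2)))
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=dct.index)
        fc = v.log2_center(v.fold_change(dct, groups, base=2.0))
        fc2 = fc.drop(columns="centered_log2fc").assign(log2fc=fc["centered_log2fc"])
        again = v.log2_center(fc2)
        np.testing.assert_allclose(again["centered_log2fc"], fc["centered_log2fc"], atol=1e-12)

    def test_centered_consistency_with_geometric_mean(self, rng):
        dct = make_ct_matrix(rng.normal(0, 1, size=(8, 1)), mirs=["m0"])
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=dct.index)
        fc = v.log2_center(v.fold_change(dct, groups, base=1.75))
        ctrl_fc = fc.loc[fc["group"] == "control", "fc"]
        geo = np.exp(np.log(ctrl_fc).mean())
        np.testing.assert_allclose(2.0 ** fc["centered_log2fc"], fc["fc"] / geo, atol=1e-10)


class TestPipelineEquivariance:
    def test_sample_wide_ct_shift_leaves_dct_unchanged(self, rng):
        # wmp = 0 keeps the weights fixed, so the reference absorbs the
        # shift exactly (with SD-derived weights the shift also perturbs
        # the weights, and absorption holds only to first order)
        mat = make_ct_matrix(rng.normal(25, 1, size=(6, 4)))
        ct0, _, _ = v.weighted_reference(mat, list(mat.columns), wmp=0.0)
        dct = v.delta_ct(mat, ct0)
        shifted = mat.copy()
        shifted.iloc[2] += 3.7  # whole-sample shift: reference absorbs it
        ct0s, _, _ = v.weighted_reference(shifted, list(shifted.columns), wmp=0.0)
        dcts = v.delta_ct(shifted, ct0s)
        np.testing.assert_allclose(dcts.iloc[2], dct.iloc[2], atol=1e-9)

    def test_noise_free_roundtrip_recovers_fold_effects(self, noisefree_cohort):
        cfg, records, meta, _ = noisefree_cohort
        mat = v.ct_matrix(records)
        ct0, _, _ = v.single_reference(mat, "miR-16")
        dct = v.delta_ct(mat, ct0)
        groups = meta.set_index("sample_id")["group"]
        fc = v.fold_change(dct, groups, base=1.75)
        for mir, effect in cfg.fold_effects.items():
            case_fc = fc.loc[(fc["mir_id"] == mir) & (fc["group"] == "case"), "fc"]
            np.testing.assert_allclose(case_fc, effect, rtol=1e-10)
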