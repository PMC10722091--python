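"""Spot-to-consensus QC: net intensity, CV gate, control scaling, NCF, PSA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abarray import qc
from abarray.core import AntigenMatrix, ArrayLayout, ValidationError
from oracles import cv_percent


class TestNetIntensity:
    @pytest.mark.parametrize(
        "fg,bg,expected",
        [(500.0, 120.0, 380.0), (100.0, 150.0, 1.0), (7.0, 0.0, 7.0), (1.0, 0.0, 1.0)],
    )
    def test_subtraction_with_floor(self, fg, bg, expected):
        assert qc.net_intensity(fg, bg) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            qc.net_intensity(-1.0, 0.0)


class TestReplicateConsensus:
    def test_low_cv_no_removal(self):
        cons, cv, removed, masked = qc.replicate_consensus([100, 102, 98, 100])
        assert cons == pytest.approx(100.0)
        assert cv == pytest.approx(cv_percent([100, 102, 98, 100]), abs=1e-9)
        assert cv == pytest.approx(1.632993, abs=1e-5)
        assert removed == 0 and not masked

    def test_outlier_removed_iteratively(self):
        cons, cv, removed, masked = qc.replicate_consensus([10, 10, 10, 100])
        assert cv_percent([10, 10, 10, 100]) > 100  # triggers the gate
        assert cons == pytest.approx(10.0)
        assert removed == 1 and not masked
        assert cv == pytest.approx(0.0)

    def test_zero_variance(self):
        cons, cv, removed, masked = qc.replicate_consensus([50, 50, 50, 50])
        assert (cons, cv, removed, masked) == (50.0, 0.0, 0, False)

    def test_irreducible_cv_masks_at_two_spots(self):
        # two wildly different survivors: CV cannot reach 20% with 2 left
        cons, cv, removed, masked = qc.replicate_consensus([10, 1000, 500, 20])
        assert masked
        assert removed <= 2

    def test_all_invalid_masks_without_consensus(self):
        cons, cv, removed, masked = qc.replicate_consensus(
            [10, 10, 10, 10], valid=[False] * 4
        )
        assert masked and np.isnan(cons)

    def test_single_valid_spot_is_masked(self):
        cons, cv, removed, masked = qc.replicate_consensus(
            [10, 10, 10, 40], valid=[True, False, False, False]
        )
        assert masked and cons == 10.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=6),
        c=st.floats(0.01, 100.0),
    )
    def test_cv_scale_invariance(self, vals, c):
        _, cv1, r1, m1 = qc.replicate_consensus(vals)
        _, cv2, r2, m2 = qc.replicate_consensus([v * c for v in vals])
        if np.isfinite(cv1):
            assert cv2 == pytest.approx(cv1, rel=1e-6, abs=1e-9)
        assert (r1, m1) == (r2, m2)


def _matrix(values: np.ndarray, antigens, samples, stage="consensus"):
    vals = pd.DataFrame(values, index=antigens, columns=samples)
    return AntigenMatrix(vals, pd.DataFrame(True, index=vals.index, columns=vals.columns), stage)


@pytest.fixture()
def layout_with_controls():
    classes = {f"AG{i:02d}": "analyte" for i in range(1, 21)}
    classes.update({f"NEG{i}": "negative" for i in range(1, 4)})
    classes.update({f"CY3{i}": "cy3_bsa" for i in range(1, 3)})
    return ArrayLayout.from_classes(classes, 4)


class TestControlScale:
    def test_identical_control_medians_leave_matrix_unchanged(self, layout_with_controls):
        ids = list(layout_with_controls.antigen_ids)
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, (len(ids), 5))
        vals[[ids.index("CY31"), ids.index("CY32")], :] = 12.0
        m = _matrix(vals, ids, [f"S{i}" for i in range(5)])
        out = qc.control_scale(m, layout_with_controls)
        np.testing.assert_allclose(out.values.to_numpy(), vals)
        assert out.stage == "scaled"

    def test_doubled_control_sample_shifted_down_one_log2(self, layout_with_controls):
        ids = list(layout_with_controls.antigen_ids)
        vals = np.full((len(ids), 3), 8.0)
        cy_rows = [ids.index("CY31"), ids.index("CY32")]
        vals[cy_rows, :] = 12.0
        vals[cy_rows, 0] = 13.0  # 2x on the raw scale
        m = _matrix(vals, ids, ["S0", "S1", "S2"])
        out = qc.control_scale(m, layout_with_controls)
        np.testing.assert_allclose(out.values["S0"].to_numpy()[: len(ids) - 5], 7.0)
        np.testing.assert_allclose(out.values["S1"].to_numpy()[: len(ids) - 5], 8.0)

    def test_missing_controls_flag_qc_fail(self, layout_with_controls):
        ids = list(layout_with_controls.antigen_ids)
        vals = np.full((len(ids), 3), 8.0)
        m = _matrix(vals, ids, ["S0", "S1", "S2"])
        cy = ["CY31", "CY32"]
        m.valid.loc[cy, "S2"] = False
        report = qc.QCReport.empty(ids, ["S0", "S1", "S2"])
        qc.control_scale(m, layout_with_controls, report)
        assert bool(report.samples.loc["S2", "qc_fail"])
        assert "cy3" in report.samples.loc["S2", "qc_fail_reason"]

    def test_generator_gain_equalizes_control_medians(self, cohort):
        m, report = qc.spots_to_matrix(cohort.spots, cohort.layout)
        out = qc.control_scale(m, cohort.layout, report)
        sub = out.masked_values().loc[cohort.layout.cy3_bsa_ids]
        med = sub.median(axis=0, skipna=True).dropna()
        assert med.max() - med.min() < 1e-9


class TestNegativeControlFilter:
    def test_profile_clone_removed_and_controls_dropped(self, layout_with_controls):
        ids = list(layout_with_controls.antigen_ids)
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(12)]
        vals = rng.normal(8, 0.5, (len(ids), 12))
        neg_rows = [ids.index(f"NEG{i}") for i in range(1, 4)]
        profile = rng.normal(0, 1, 12)
        vals[neg_rows] = 5.0 + profile
        vals[ids.index("AG01")] = 9.0 + profile  # clone of the reference, r = 1
        m = _matrix(vals, ids, samples, stage="scaled")
        out, removed = qc.negative_control_filter(m, layout_with_controls)
        assert removed == ["AG01"]
        assert out.stage == "ncf"
        # reference/control features are not analytes and leave the matrix
        assert not set(out.antigen_ids) & set(
            layout_with_controls.negative_control_ids
        )
        assert not set(out.antigen_ids) & set(layout_with_controls.cy3_bsa_ids)

    def test_independent_noise_retained(self, layout_with_controls):
        # 40 samples of independent noise: P(r > 0.7) is astronomically small
        ids = list(layout_with_controls.antigen_ids)
        rng = np.random.default_rng(2)
        vals = rng.normal(8, 0.5, (len(ids), 40))
        m = _matrix(vals, ids, [f"S{i}" for i in range(40)], stage="scaled")
        out, removed = qc.negative_control_filter(m, layout_with_controls)
        assert removed == []
        assert len(out.antigen_ids) == 20

    def test_too_few_samples_error(self, layout_with_controls):
        ids = list(layout_with_controls.antigen_ids)
        m = _matrix(np.zeros((len(ids), 2)), ids, ["S0", "S1"], stage="scaled")
        with pytest.raises(ValidationError, match="3 samples"):
            qc.negative_control_filter(m, layout_with_controls)


class TestDetectPsa:
    def test_median_sample_scores_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 1, (50, 21))
        vals[:, 0] = np.median(vals[:, 1:], axis=1)
        m = _matrix(vals, [f"A{i}" for i in range(50)], [f"S{i}" for i in range(21)])
        out = qc.detect_psa(m)
        assert out.loc["S0", "psa_score"] < 0.05
        assert not out.loc["S0", "psa_flag"]

    def test_identical_samples_never_flagged(self):
        vals = np.tile(np.arange(50, dtype=float)[:, None], (1, 8))
        m = _matrix(vals, [f"A{i}" for i in range(50)], [f"S{i}" for i in range(8)])
        out = qc.detect_psa(m)
        assert (out["psa_score"] == 0).all()
        assert not out["psa_flag"].any()

    def test_needs_ten_antigens(self):
        vals = np.zeros((5, 8))
        m = _matrix(vals, [f"A{i}" for i in range(5)], [f"S{i}" for i in range(8)])
        with pytest.raises(ValidationError):
            qc.detect_psa(m)


class TestSampleAccounting:
    def _manifest(self, n):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "group": ["control", "MCI", "dementia"][0] if n < 3 else
                         [["control", "MCI", "dementia"][i % 3] for i in range(n)],
            }
        ).set_index("sample_id", drop=False)

    def test_study_accounting_127_to_98(self):
        manifest = self._manifest(127)
        report = qc.QCReport.empty(["A1"], manifest.index)
        report.samples.iloc[:23, report.samples.columns.get_loc("psa_flag")] = True
        for s in manifest.index[23:29]:
            report.fail_sample(s, "control_failure")
        retained, exclusions, counts = qc.sample_accounting(manifest, report)
        assert len(retained) == 98
        assert len(exclusions) == 29
        assert counts["retained"].sum() == 98

    def test_no_flags_keeps_everything(self):
        manifest = self._manifest(10)
        report = qc.QCReport.empty(["A1"], manifest.index)
        retained, exclusions, _ = qc.sample_accounting(manifest, report)
        assert len(retained) == 10 and len(exclusions) == 0

    def test_overlapping_flags_counted_once_with_reason_both(self):
        manifest = self._manifest(10)
        report = qc.QCReport.empty(["A1"], manifest.index)
        report.samples.loc["S0", "psa_flag"] = True
        report.fail_sample("S0", "control_failure")
        retained, exclusions, _ = qc.sample_accounting(manifest, report)
        assert len(retained) == 9
        assert exclusions["reason"].tolist() == ["both"]

    def test_counts_conserved(self, pipeline_result):
        rep = pipeline_result.report["samples"]
        assert rep["retained"] + rep["psa_flagged"] + rep["qc_failed"] == rep["total"]
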