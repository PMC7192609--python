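"""Calibration line, LOD/LOQ, quantification, normalization, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dntpkin.calibration import (
    CalibrationModel,
    accuracy_percent,
    assay_statistics,
    build_calibration,
    cv_percent,
    estimate_lod_loq,
    normalize_amount,
    quantify_well,
    recovery_percent,
)
from dntpkin.curves_io import PlateLayout, WellInfo
from dntpkin.kinetics import ExpFitResult
from dntpkin.plate_qc import Checkpoint, QcFlags


def make_fit(A1: float, **overrides) -> ExpFitResult:
    params = dict(
        model="double", A1=A1, k1obs=2.5e-3, A2=29878.0 - A1, k2obs=1.1e-4,
        F0=35540.0, se_A1=0.02 * A1, raw_A1=A1, converged=True,
    )
    params.update(overrides)
    return ExpFitResult(**params)


def exact_linear_plate(amounts=(1, 2, 3, 4, 5, 6, 7, 8), slope=1000.0, intercept=50.0):
    wells = {}
    fits = {}
    for i, amount in enumerate(amounts):
        well = f"A{i + 1}"
        wells[well] = WellInfo(role="calibration", amount_pmol=float(amount))
        fits[well] = make_fit(slope * amount + intercept)
    return fits, PlateLayout(wells=wells)


class TestBuildCalibration:
    def test_exact_linear_data(self):
        fits, layout = exact_linear_plate()
        calib = build_calibration(fits, layout)
        assert calib.slope == pytest.approx(1000.0)
        assert calib.intercept == pytest.approx(50.0)
        assert calib.r_squared == pytest.approx(1.0)
        assert calib.fitted_range == (1.0, 8.0)

    def test_qc_flagged_well_excluded_but_recorded(self):
        fits, layout = exact_linear_plate()
        qc = {"A3": QcFlags(flags={Checkpoint.K2_TOO_SLOW: "k2obs below 1e-5 s^-1"})}
        calib = build_calibration(fits, layout, qc)
        point = next(p for p in calib.points if p.well_id == "A3")
        assert not point.included and "QC failed" in point.reason
        assert calib.slope == pytest.approx(1000.0)

    def test_unfittable_low_point_recorded_under_detection_limit(self):
        fits, layout = exact_linear_plate()
        fits["A1"] = ExpFitResult(model="single", A1=28000.0, k1obs=2e-4, F0=36000.0)
        calib = build_calibration(fits, layout)
        point = next(p for p in calib.points if p.well_id == "A1")
        assert not point.included and "detection limit" in point.reason
        assert calib.fitted_range[0] == 2.0

    def test_user_refinement_excludes_outliers(self):
        fits, layout = exact_linear_plate()
        fits["A5"] = make_fit(20000.0)  # gross outlier at 5 pmol
        refined = build_calibration(fits, layout, exclude_wells=("A5",))
        assert refined.slope == pytest.approx(1000.0)
        assert not next(p for p in refined.points if p.well_id == "A5").included

    def test_noisy_duplicates_recover_slope(self, rng):
        amounts = [0.5, 1, 2, 4, 8, 12]
        wells, fits = {}, {}
        i = 1
        for amount in amounts:
            for _ in range(2):
                well = f"B{i}"
                a1 = 2100.0 * amount
                wells[well] = WellInfo(role="calibration", amount_pmol=float(amount))
                fits[well] = make_fit(a1 * (1 + rng.normal(0, 0.02)))
                i += 1
        calib = build_calibration(fits, PlateLayout(wells=wells))
        assert calib.slope == pytest.approx(2100.0, rel=0.05)

    def test_single_amount_rejected(self):
        fits, layout = exact_linear_plate(amounts=(2, 2, 2))
        with pytest.raises(ValueError, match="one amount"):
            build_calibration(fits, layout)


class TestLodLoq:
    @pytest.fixture
    def calib(self):
        fits, layout = exact_linear_plate()
        return build_calibration(fits, layout)

    def test_three_and_five_sd_rule(self, calib):
        lod, loq = estimate_lod_loq(calib, [1000.0, 1100.0, 1200.0])
        sd = np.std([1000.0, 1100.0, 1200.0], ddof=1)
        assert lod == pytest.approx(max(3 * sd / 1000.0, 1.0))
        assert loq == pytest.approx(max(5 * sd / 1000.0, 1.0))

    def test_zero_sd_falls_back_to_lowest_point(self, calib):
        # mathematically LOD would be 0; the lowest resolvable point rules
        lod, loq = estimate_lod_loq(calib, [1050.0, 1050.0])
        assert lod == 1.0 and loq == 1.0

    def test_known_arithmetic(self, calib):
        # slope 1000/pmol, SD 100 -> 0.3 and 0.5 pmol before the floor
        reps = [1000.0 - 100.0, 1000.0 + 100.0]
        sd = np.std(reps, ddof=1)
        assert sd == pytest.approx(141.42, rel=1e-3)
        lod, loq = estimate_lod_loq(calib, reps)
        assert lod == pytest.approx(max(3 * sd / 1000, 1.0))
        assert loq == pytest.approx(max(5 * sd / 1000, 1.0))

    def test_missing_replicates_warns_and_uses_method_a(self, calib):
        with pytest.warns(UserWarning, match="replicates"):
            lod, loq = estimate_lod_loq(calib, [1000.0])
        assert lod == loq == 1.0

    @given(sd=st.floats(0.0, 5000.0))
    def test_lod_never_exceeds_loq_and_monotone(self, sd):
        calib = CalibrationModel(
            dntp_species="dGTP", slope=1000.0, intercept=0.0, r_squared=1.0,
            fitted_range=(1.0, 8.0),
        )
        from dntpkin.calibration import CalibrationPoint

        calib.points = [
            CalibrationPoint("A1", 1.0, 1000.0, True),
            CalibrationPoint("A2", 1.0, 1000.0, True),
        ]
        lod, loq = estimate_lod_loq(calib, [1000.0 - sd, 1000.0 + sd])
        assert lod <= loq


class TestQuantifyWell:
    @pytest.fixture
    def calib(self):
        fits, layout = exact_linear_plate()
        model = build_calibration(fits, layout)
        estimate_lod_loq(model, [1040.0, 1060.0])
        return model

    def test_a1_at_intercept_is_zero_and_below_lod(self, calib):
        q = quantify_well(make_fit(calib.intercept), calib)
        assert q.pmol_in_reaction == pytest.approx(0.0)
        assert q.flag == "BELOW_LOD"

    def test_calibration_well_roundtrip(self, calib):
        for amount in (1.0, 4.0, 8.0):
            q = quantify_well(make_fit(calib.A1_from_amount(amount)), calib)
            assert abs(q.pmol_in_reaction - amount) < 1e-6

    def test_above_range_flagged(self, calib):
        q = quantify_well(make_fit(calib.A1_from_amount(9.5)), calib)
        assert q.flag == "ABOVE_RANGE"

    def test_qc_failure_propagates_explanation(self, calib):
        qc = QcFlags(flags={Checkpoint.K2_TOO_SLOW: "k2obs below 1e-5 s^-1"})
        q = quantify_well(make_fit(3000.0), calib, qc=qc)
        assert q.pmol_in_reaction is None
        assert q.flag == "QC_FAILED" and "k2obs" in q.explanation

    def test_normalization_applied_with_complete_metadata(self, calib):
        info = WellInfo(
            role="sample", sample_id="S1", extract_volume_ul=50.0,
            assayed_volume_ul=10.0, cells_extracted=5e5, basis="per_1e6_cells",
        )
        q = quantify_well(make_fit(calib.A1_from_amount(2.0)), calib, info=info)
        assert q.normalized_amount == pytest.approx(2.0 * 5 * 2, rel=1e-6)

    def test_yaml_roundtrip(self, calib, tmp_path):
        p = tmp_path / "calib.yaml"
        calib.to_yaml(p)
        back = CalibrationModel.from_yaml(p)
        assert back.slope == calib.slope
        assert back.lod_pmol == calib.lod_pmol
        assert len(back.points) == len(calib.points)


class TestNormalizeAmount:
    def test_human_cell_basis(self):
        out = normalize_amount(
            2.0, extract_volume_ul=50.0, assayed_volume_ul=10.0,
            cells_extracted=5e5, basis="per_1e6_cells",
        )
        assert out == pytest.approx(20.0)

    def test_identity_when_volumes_and_counts_match_basis(self):
        out = normalize_amount(
            3.7, extract_volume_ul=10.0, assayed_volume_ul=10.0,
            cells_extracted=1e6, basis="per_1e6_cells",
        )
        assert out == pytest.approx(3.7)

    def test_bacterial_cfu_basis_with_dilution(self):
        out = normalize_amount(
            1.0, dilution_factor=2.0, extract_volume_ul=50.0,
            assayed_volume_ul=5.0, cells_extracted=1e8, basis="per_1e8_cfu",
        )
        assert out == pytest.approx(20.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_amount(
                1.0, extract_volume_ul=50.0, assayed_volume_ul=10.0,
                cells_extracted=0.0, basis="per_1e6_cells",
            )


class TestAssayStatistics:
    def test_identical_replicates_zero_cv(self):
        df = pd.DataFrame({
            "plate": [1, 1, 2, 2],
            "nominal_pmol": [2.0, 2.0, 2.0, 2.0],
            "measured_pmol": [2.1, 2.1, 2.1, 2.1],
        })
        stats = assay_statistics(df)
        assert stats["intra_cv"] == pytest.approx(0.0)
        assert stats["inter_cv"] == pytest.approx(0.0)

    def test_perfect_measurement_gives_100s(self):
        df = pd.DataFrame({
            "plate": [1, 1, 1, 1, 2, 2, 2, 2],
            "nominal_pmol": [1.0, 1.0, 8.0, 8.0] * 2,
            "measured_pmol": [1.0, 1.0, 8.0, 8.0] * 2,
        })
        spiked = pd.DataFrame({
            "measured_spiked": [5.0], "measured_unspiked": [3.0], "added_pmol": [2.0],
        })
        stats = assay_statistics(df, spiked)
        assert stats["accuracy_low"] == pytest.approx(100.0)
        assert stats["accuracy_high"] == pytest.approx(100.0)
        assert stats["recovery"] == pytest.approx(100.0)

    def test_cv_formula_on_known_pair(self):
        assert cv_percent([9.0, 11.0]) == pytest.approx(14.142, rel=1e-3)

    def test_cv_needs_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            cv_percent([5.0])

    def test_accuracy_and_recovery_formulas(self):
        assert accuracy_percent([1.9, 2.1], 2.0) == pytest.approx(100.0)
        assert recovery_percent(4.7, 3.0, 2.0) == pytest.approx(85.0)
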