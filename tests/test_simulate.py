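"""Phantom construction, scenario trajectories and the simple dose engine."""

import math

import numpy as np
import pytest

from artqa.core import MarginSpec
from artqa.flagging import FlagProtocol, apply_flag
from artqa.simulate import (
    BeamModel,
    ScenarioConfig,
    _fraction_anatomy,
    build_phantom,
    central_axis_dose_change,
    default_grid,
    simulate_cohort,
    simulate_course,
)


class TestCentralAxisDoseChange:
    def test_zero_depth_reduction(self):
        assert central_axis_dose_change(0.0) == 0.0

    def test_cylinder_worked_example(self):
        # 1.5 cm radius loss at 6 MV (mu = 0.035/cm) -> ~5%
        change = central_axis_dose_change(1.5, mu=0.035)
        assert change == pytest.approx(math.exp(0.0525) - 1.0)
        assert round(100 * change) == 5

    def test_first_order_limit(self):
        mu = 0.035
        for delta in (1e-3, 1e-5):
            ratio = central_axis_dose_change(delta, mu) / (mu * delta)
            assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_requires_positive_mu(self):
        with pytest.raises(ValueError):
            central_axis_dose_change(1.0, mu=0.0)


class TestPhantom:
    def test_high_dose_target_coverage(self, phantom):
        # >= 95% of high-dose PTV voxels receive >= 95% of 70 Gy
        ptv = phantom.structures["ptv_high"]
        frac = (phantom.dose[ptv] >= 0.95 * 70.0).mean()
        assert frac >= 0.95

    def test_cord_outside_violation_isodose(self, phantom):
        cord = phantom.structures["spinal_cord"]
        assert phantom.dose[cord].max() < 49.44

    def test_planned_parameters_satisfy_criteria(self, phantom, phantom_criteria):
        from artqa.criteria import grade_fraction
        from artqa.core import FractionRecord
        from artqa.dosimetry import extract_fraction_parameters

        specs = [c.parameter_spec() for c in phantom_criteria]
        planned = extract_fraction_parameters(phantom.structures, phantom.dose, specs)
        record = FractionRecord(1, assessed=True, parameters=planned)
        report = grade_fraction(record, planned, phantom_criteria)
        assert set(report.statuses.values()) == {"none"}

    def test_zero_margins_collapse_high_dose_targets(self):
        ph = build_phantom(
            margins=MarginSpec(ctv_from_gtv=0.0, ptv_from_ctv=0.0),
            grid=default_grid(0.4),
        )
        s = ph.structures
        assert np.array_equal(s["gtv_high"], s["ctv_high"])
        assert np.array_equal(s["ctv_high"], s["ptv_high"])

    def test_structure_set_is_complete_and_valid(self, phantom):
        phantom.structures.validate(require_all=True)


class TestIdentityCourse:
    def test_no_change_course_is_clean(self, phantom, phantom_specs, phantom_criteria):
        from artqa.criteria import grade_fraction

        course = simulate_course(
            phantom, ScenarioConfig.none(noise_sigma=0.0, schedule=(1, 15, 30)),
            phantom_specs,
        )
        flagged = apply_flag(course, FlagProtocol())
        for fr in flagged.assessed_fractions:
            assert fr.contour_change == 0.0
            assert not fr.flagged
            assert fr.parameters == pytest.approx(course.planned_parameters)
            report = grade_fraction(fr, course.planned_parameters, phantom_criteria)
            assert not report.any_minor()


class TestWeightLoss:
    def test_contour_change_tracks_erosion_depth(self, phantom, phantom_specs):
        rate = 0.06
        course = simulate_course(
            phantom,
            ScenarioConfig.weight_loss(shrink_rate=rate, noise_sigma=0.0),
            phantom_specs,
        )
        voxel_diag = math.hypot(0.2, 0.2)
        for fr in course.assessed_fractions:
            assert fr.contour_change == pytest.approx(
                rate * fr.fraction_index, abs=voxel_diag
            )

    def test_first_flag_at_first_assessed_fraction_over_threshold(self, phantom, phantom_specs):
        course = simulate_course(
            phantom, ScenarioConfig.weight_loss(shrink_rate=0.06, noise_sigma=0.0),
            phantom_specs,
        )
        flagged = apply_flag(course, FlagProtocol(threshold=1.5))
        flags = {fr.fraction_index: fr.flagged for fr in flagged.assessed_fractions}
        changes = {fr.fraction_index: fr.contour_change for fr in flagged.assessed_fractions}
        expected_first = min((f for f, c in changes.items() if c > 1.5), default=None)
        assert expected_first is not None
        for f, is_flagged in flags.items():
            assert is_flagged == (f >= expected_first)

    def test_pure_shrink_without_advection_monotonically_heats_dmax(
        self, phantom, phantom_specs
    ):
        course = simulate_course(
            phantom,
            ScenarioConfig.weight_loss(
                shrink_rate=0.06, noise_sigma=0.0, advect_soft_tissue=False,
                schedule=(5, 15, 25),
            ),
            phantom_specs,
        )
        dmax = [fr.parameters["ptv_high_dmax_gy"] for fr in course.assessed_fractions]
        assert dmax[0] < dmax[1] < dmax[2]
        cord = [fr.parameters["spinal_cord_dmax_gy"] for fr in course.assessed_fractions]
        assert cord[0] < cord[1] < cord[2]


class TestLocalizedEdema:
    def test_volume_trajectory_hits_calibration_ratios(self, phantom):
        sc = ScenarioConfig.localized_edema(noise_sigma=0.0)
        v0 = phantom.structures.volume_cc("ctv_high")
        peak, _ = _fraction_anatomy(phantom, sc, sc.edema_peak_fraction)
        end, _ = _fraction_anatomy(phantom, sc, 33)
        assert peak.volume_cc("ctv_high") / v0 == pytest.approx(1.256, rel=0.02)
        assert end.volume_cc("ctv_high") / v0 == pytest.approx(0.598, rel=0.02)

    def test_contour_change_peaks_at_changepoint(self, phantom, phantom_specs):
        course = simulate_course(
            phantom,
            ScenarioConfig.localized_edema(noise_sigma=0.0, schedule=(4, 8, 14)),
            phantom_specs,
        )
        changes = {fr.fraction_index: fr.contour_change for fr in course.assessed_fractions}
        assert changes[8] > changes[4]
        assert changes[8] > changes[14]

    def test_anatomy_valid_at_every_phase(self, phantom):
        sc = ScenarioConfig.localized_edema(noise_sigma=0.0)
        for f in (1, 8, 20, 33):
            anatomy, _ = _fraction_anatomy(phantom, sc, f)
            anatomy.validate(require_all=True)


class TestTargetShift:
    @pytest.mark.parametrize("shift", [0.5, 1.0])
    def test_lateral_target_shift_degrades_coverage(self, phantom, phantom_specs, shift):
        # fixed dose field + shifted target -> D95 below plan
        sc = ScenarioConfig(kind="none", target_drift=(shift, 0.0),
                            noise_sigma=0.0, schedule=(1,))
        course = simulate_course(phantom, sc, phantom_specs)
        fr = course.assessed_fractions[0]
        assert (
            fr.parameters["ptv_high_d95_gy"]
            < course.planned_parameters["ptv_high_d95_gy"]
        )


class TestShoulderShift:
    def test_flags_without_dose_change(self, phantom, phantom_specs):
        course = simulate_course(
            phantom,
            ScenarioConfig.shoulder_shift(shift=(2.0, 0.0), noise_sigma=0.0,
                                          schedule=(5,)),
            phantom_specs,
        )
        fr = course.assessed_fractions[0]
        assert fr.contour_change == pytest.approx(2.0, abs=math.hypot(0.2, 0.2))
        assert fr.parameters == pytest.approx(course.planned_parameters)


class TestCohort:
    def test_same_seed_reproduces_csv_byte_identically(self, tmp_path, phantom_specs):
        from artqa.io import write_course_csv

        ph = build_phantom(grid=default_grid(0.4))
        paths = []
        for name in ("a.csv", "b.csv"):
            courses = simulate_cohort(3, phantom_specs, seed=42, phantom=ph)
            p = tmp_path / name
            write_course_csv(courses, p, seed=42)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_all_quiet_mix_has_no_flags_or_violations(self, phantom, phantom_specs, phantom_criteria):
        from artqa.criteria import grade_fraction

        courses = simulate_cohort(
            2, phantom_specs, mix={"none": 1.0}, seed=7, phantom=phantom
        )
        for course in courses:
            flagged = apply_flag(course)
            for fr in flagged.assessed_fractions:
                assert not fr.flagged
                report = grade_fraction(fr, course.planned_parameters, phantom_criteria)
                assert not report.any_major()

    def test_scenario_mix_is_drawn_from_given_kinds(self, phantom_specs):
        ph = build_phantom(grid=default_grid(0.4))
        courses = simulate_cohort(
            4, phantom_specs, mix={"shoulder_shift": 0.5, "none": 0.5},
            seed=3, phantom=ph,
        )
        assert len(courses) == 4
        assert len({c.patient_id for c in courses}) == 4
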