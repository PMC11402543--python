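import numpy as np
import pytest

from gtvfusion import (
    BinaryMask,
    DelineationSet,
    SearchSettings,
    VoxelGrid,
    apply_calibrated_shift,
    calibrate_penalty_weight,
    dice,
    evaluate_case,
    expand_margin,
    optimize_translation,
    shift_mask,
)
from gtvfusion.alignment import CalibrationResult

from conftest import box_mask, random_mask
from reference import brute_force_expand


class TestExpandMargin:
    def test_radius_zero_is_identity(self, small_grid, rng):
        m = random_mask(small_grid, rng)
        assert expand_margin(m, 0.0).same_values(m)

    def test_single_voxel_isotropic_radius_one(self, iso_grid):
        m = box_mask(iso_grid, (4, 4, 4), (5, 5, 5))
        out = expand_margin(m, 1.0)
        assert out.count == 7  # center + 6-neighbour cross
        assert out.values[4, 4, 4] and out.values[3, 4, 4] and out.values[4, 4, 5]

    def test_thick_slices_confine_small_margins_in_plane(self):
        grid = VoxelGrid(shape=(5, 9, 9), spacing_mm=(5.0, 1.0, 1.0))
        m = box_mask(grid, (2, 4, 4), (3, 5, 5))
        out = expand_margin(m, 3.0)
        assert out.values[2].sum() > 1
        assert not out.values[1].any() and not out.values[3].any()

    def test_matches_brute_force_distance_oracle(self, rng):
        grid = VoxelGrid(shape=(4, 6, 6), spacing_mm=(2.5, 1.0, 1.0))
        for radius in (1.0, 2.0, 2.5, 3.0):
            m = random_mask(grid, rng, 0.1)
            out = expand_margin(m, radius)
            assert np.array_equal(out.values, brute_force_expand(m, radius))

    def test_extensive_and_monotone(self, small_grid, rng):
        m = random_mask(small_grid, rng, 0.15)
        prev = m
        for radius in (0.0, 1.0, 2.0, 3.0):
            out = expand_margin(m, radius)
            assert not np.any(m.values & ~out.values)  # extensive
            assert not np.any(prev.values & ~out.values)  # monotone in radius
            prev = out

    def test_negative_radius_rejected(self, small_grid):
        with pytest.raises(ValueError):
            expand_margin(BinaryMask.empty(small_grid), -1.0)


def blob(grid, center, radius_mm):
    z = grid.voxel_centers(0)[:, None, None]
    y = grid.voxel_centers(1)[None, :, None]
    x = grid.voxel_centers(2)[None, None, :]
    d2 = (
        ((z - center[0]) / radius_mm[0]) ** 2
        + ((y - center[1]) / radius_mm[1]) ** 2
        + ((x - center[2]) / radius_mm[2]) ** 2
    )
    return BinaryMask(grid, d2 <= 1.0)


class TestOptimizeTranslation:
    def test_already_aligned_stays_put(self, rng):
        grid = VoxelGrid(shape=(8, 24, 24), spacing_mm=(2.5, 1, 1))
        lesion = blob(grid, (10, 12, 12), (5, 6, 6))
        for lam in (0.0, 0.05, 1.0):
            res = optimize_translation(lesion, lesion, lam)
            assert res.translation_mm == (0.0, 0.0)
            assert res.dsc_after == 1.0 and res.dsc_before == 1.0

    def test_recovers_constructed_integer_shift_exactly(self):
        grid = VoxelGrid(shape=(8, 32, 32), spacing_mm=(2.5, 1, 1))
        lesion = blob(grid, (10, 16, 16), (6, 7, 7))
        gtv = shift_mask(lesion, (3.0, -2.0))
        res = optimize_translation(gtv, lesion, 0.0)
        assert res.dsc_after == 1.0
        # any translation inside the optimal voxel cell undoes the shift; the
        # minimum-norm tie-break pulls toward zero by at most half a voxel
        assert abs(res.translation_mm[0] - (-3.0)) <= 0.5
        assert abs(res.translation_mm[1] - 2.0) <= 0.5
        undone = shift_mask(gtv, res.translation_mm)
        assert dice(undone, lesion) == 1.0

    def test_fine_grid_recovers_subvoxel_shift_tightly(self):
        # on a 0.125 mm in-plane grid the (2.0, -1.5) mm shift is an exact
        # voxel multiple and the optimal plateau is narrower than 0.1 mm
        grid = VoxelGrid(shape=(3, 128, 128), spacing_mm=(2.5, 0.125, 0.125))
        lesion = blob(grid, (2.5, 8.0, 8.0), (4, 3.0, 3.0))
        gtv = shift_mask(lesion, (2.0, -1.5))
        res = optimize_translation(
            gtv, lesion, 0.0, search=SearchSettings(radius_mm=4.0)
        )
        assert res.dsc_after == 1.0
        assert abs(res.translation_mm[0] - (-2.0)) <= 0.1
        assert abs(res.translation_mm[1] - 1.5) <= 0.1

    def test_huge_penalty_forces_zero_shift(self):
        grid = VoxelGrid(shape=(6, 20, 20), spacing_mm=(2.5, 1, 1))
        lesion = blob(grid, (7.5, 10, 10), (4, 5, 5))
        gtv = shift_mask(lesion, (3.0, 0.0))
        res = optimize_translation(gtv, lesion, 1e3)
        assert res.translation_mm == (0.0, 0.0)
        assert res.dsc_after == res.dsc_before

    def test_dsc_never_decreases(self, rng):
        grid = VoxelGrid(shape=(6, 24, 24), spacing_mm=(2.5, 1, 1))
        lesion = blob(grid, (7.5, 12, 12), (4, 5, 5))
        for lam in (0.0, 0.01, 0.1, 1.0):
            gtv = random_mask(grid, rng, 0.1)
            if gtv.count == 0:
                continue
            res = optimize_translation(gtv, lesion, lam)
            assert res.dsc_after >= res.dsc_before
            assert res.distance_mm <= 10.0 + 1e-9

    def test_empty_inputs_rejected(self, small_grid):
        m = box_mask(small_grid, (0, 0, 0), (1, 2, 2))
        with pytest.raises(ValueError):
            optimize_translation(BinaryMask.empty(small_grid), m, 0.0)
        with pytest.raises(ValueError):
            optimize_translation(m, m, -0.5)


def _mini_cohort(n, seed, shift_scale=3.0):
    rng = np.random.default_rng(seed)
    grid = VoxelGrid(shape=(8, 40, 40), spacing_mm=(2.5, 1, 1))
    cases = []
    for i in range(n):
        lesion = blob(grid, (10, 20, 20), (5, rng.uniform(4, 7), rng.uniform(4, 7)))
        t = rng.normal(0, shift_scale, size=2)
        gtv = shift_mask(lesion, tuple(t))
        cases.append((f"P{i}", gtv, lesion))
    return cases


class TestCalibration:
    def test_aligned_cohort_with_zero_target(self):
        cases = [(pid, lesion.copy(), lesion) for pid, _, lesion in _mini_cohort(3, 5, 0.0)]
        res = calibrate_penalty_weight(cases, target_mean_mm=0.0, tolerance_mm=0.01)
        assert res.lambda_star == 0.0
        assert res.mean_distance_mm == 0.0
        assert res.converged and not res.boundary

    def test_unreachable_target_reports_boundary(self):
        cases = _mini_cohort(3, 6, 0.5)
        res = calibrate_penalty_weight(cases, target_mean_mm=50.0, tolerance_mm=0.01)
        assert res.lambda_star == 0.0
        assert res.boundary and not res.converged

    def test_mean_distance_nonincreasing_in_lambda(self):
        from gtvfusion.alignment import _ShiftDiceTable

        cases = _mini_cohort(4, 7)
        tables = [(pid, _ShiftDiceTable(g, l)) for pid, g, l in cases]
        means = []
        for lam in (0.0, 0.005, 0.02, 0.08, 0.3, 1.0):
            dists = [
                optimize_translation(t.gtv, t.lesion, lam, _table=t).distance_mm
                for _, t in tables
            ]
            means.append(np.mean(dists))
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_penalty_drives_mean_toward_target(self):
        cases = _mini_cohort(6, 8, shift_scale=4.0)
        res = calibrate_penalty_weight(cases, target_mean_mm=1.7, tolerance_mm=0.2)
        assert res.mean_distance_mm <= np.mean(
            [optimize_translation(g, l, 0.0).distance_mm for _, g, l in cases]
        )
        assert abs(res.mean_distance_mm - 1.7) <= 0.2

    def test_per_patient_results_at_lambda_star(self):
        cases = _mini_cohort(3, 9)
        res = calibrate_penalty_weight(cases, target_mean_mm=1.0, tolerance_mm=0.5)
        assert set(res.per_patient) == {pid for pid, _, _ in cases}
        for r in res.per_patient.values():
            assert r.penalty_weight == res.lambda_star
            assert r.dsc_after >= r.dsc_before


class TestApplyCalibratedShift:
    @pytest.fixture
    def patient_setup(self):
        grid = VoxelGrid(shape=(8, 40, 40), spacing_mm=(2.5, 1, 1))
        lesion = blob(grid, (10, 20, 20), (5, 6, 6))
        gtv = shift_mask(lesion, (3.0, -2.0))
        patient = DelineationSet(
            patient_id="P1",
            masks={("obs1", "T2w"): gtv},
            histo_lesion=lesion,
            histo_support=BinaryMask.full(grid),
        )
        return patient, gtv, lesion

    def test_zero_translation_reproduces_unshifted_records(self, patient_setup):
        patient, gtv, lesion = patient_setup
        calibration = CalibrationResult(
            lambda_star=0.0,
            mean_distance_mm=0.0,
            per_patient={
                "P1": optimize_translation(lesion, lesion, 0.0, patient_id="P1")
            },
            target_mean_mm=0.0,
            tolerance_mm=0.01,
            converged=True,
        )
        base = evaluate_case(patient, {"T2w": gtv}, lesion, [0.0, 2.0])
        shifted = apply_calibrated_shift([patient], {"P1": {"T2w": gtv}}, calibration, [0.0, 2.0])
        assert [(r.dsc, r.coverage) for r in base] == [(r.dsc, r.coverage) for r in shifted]

    def test_calibrated_shift_improves_dsc(self, patient_setup):
        patient, gtv, lesion = patient_setup
        res = optimize_translation(gtv, lesion, 0.0, patient_id="P1")
        calibration = CalibrationResult(
            lambda_star=0.0,
            mean_distance_mm=res.distance_mm,
            per_patient={"P1": res},
            target_mean_mm=res.distance_mm,
            tolerance_mm=0.01,
            converged=True,
        )
        base = evaluate_case(patient, {"T2w": gtv}, lesion, [0.0])
        shifted = apply_calibrated_shift([patient], {"P1": {"T2w": gtv}}, calibration, [0.0])
        assert shifted[0].dsc >= base[0].dsc
        assert shifted[0].dsc == 1.0

    def test_missing_patient_raises(self, patient_setup):
        patient, gtv, _ = patient_setup
        calibration = CalibrationResult(
            lambda_star=0.0,
            mean_distance_mm=0.0,
            per_patient={},
            target_mean_mm=0.0,
            tolerance_mm=0.01,
            converged=True,
        )
        with pytest.raises(KeyError):
            apply_calibrated_shift([patient], {"P1": {"T2w": gtv}}, calibration, [0.0])
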