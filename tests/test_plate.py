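"""Plate geometry: cortical centre, normals, displacement, split, statistics."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from blastovol import plate
from blastovol.capmodel import cap_volumes
from blastovol.plate import (ChromatinTrack, cortical_center, displacement_stats,
                             division_normal, extrapolate_shift,
                             plate_displacement, split_by_plate, surface_sample)
from blastovol.synthetic import DisplacementSample, sample_displacements

from conftest import digitized_sphere


def fibonacci_sphere(n, radius=10.0):
    """Deterministic, nearly uniform points on a sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5 ** 0.5) * i
    return radius * np.stack([np.cos(phi),
                              np.sin(phi) * np.sin(theta),
                              np.sin(phi) * np.cos(theta)], axis=1)


class TestCorticalCenter:
    def test_sphere_center_is_fixed_point(self):
        pts = fibonacci_sphere(3000) + np.array([5.0, -2.0, 7.0])
        c = cortical_center(pts)
        assert np.linalg.norm(c - [5.0, -2.0, 7.0]) < 0.05

    def test_ellipsoid_center_is_fixed_point(self):
        pts = fibonacci_sphere(3000, radius=1.0) * np.array([15.0, 8.0, 8.0])
        c = cortical_center(pts)
        assert np.linalg.norm(c) < 0.05

    def test_hemisphere_equilibrium_matches_geometric_median(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((6000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        hemi = v[v[:, 2] < 0] * 10.0
        c = cortical_center(hemi, eps=0.01, tol=5e-5)
        ref = minimize(lambda x: np.linalg.norm(hemi - x, axis=1).sum(),
                       hemi.mean(axis=0), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8}).x
        assert np.linalg.norm(c - ref) < 0.15
        # the equilibrium departs from the centroid toward the open side
        assert abs(c[2] - hemi[:, 2].mean()) > 0.5

    def test_coplanar_points_rejected(self):
        pts = np.zeros((100, 3))
        pts[:, :2] = np.random.default_rng(1).normal(size=(100, 2))
        with pytest.raises(ValueError, match="coplanar"):
            cortical_center(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cortical_center(np.zeros((3, 3)))


class TestSurfaceSample:
    def test_sphere_sample_lies_on_the_digitized_surface(self):
        lm, center = digitized_sphere(10.0)
        pts = surface_sample(lm, 1, n_points=1500, seed=0)
        assert len(pts) == 1500
        radii = np.linalg.norm(pts - center, axis=1)
        lz = lm.spacing[0]
        assert radii.max() <= 10.0 + 1e-6
        assert radii.min() >= 10.0 - 1.5 * lz

    def test_requesting_more_points_than_boundary_returns_all(self):
        lm, _ = digitized_sphere(1.5)
        with pytest.warns(UserWarning, match="boundary voxels"):
            pts = surface_sample(lm, 1, n_points=100_000)
        boundary_count = len(pts)
        assert boundary_count < 100_000

    def test_adjacent_cells_share_interface_points(self):
        labels = np.zeros((6, 10, 20), dtype=np.int32)
        labels[1:5, 1:9, 1:10] = 1
        labels[1:5, 1:9, 10:19] = 2
        from blastovol.stacks import LabelMap
        lm = LabelMap(labels, spacing=(1.0, 1.0, 1.0))
        for lab, iface_x in ((1, 9.0), (2, 10.0)):
            pts = surface_sample(lm, lab, n_points=200, seed=1)
            assert np.any(np.isclose(pts[:, 2], iface_x))


class TestDivisionNormal:
    def test_single_pair(self):
        track = ChromatinTrack(r1=[[0, 0, 0]], r2=[[0, 0, 2]])
        assert np.allclose(division_normal(track), [0, 0, 1])

    def test_symmetric_pairs_average_exactly(self):
        r1 = np.zeros((3, 3))
        r2 = np.array([[0.0, 0.3, 1.0], [0.0, -0.3, 1.0], [0.0, 0.0, 1.0]])
        d = division_normal(ChromatinTrack(r1=r1, r2=r2))
        assert d == pytest.approx(np.array([0.0, 0.0, 1.0]), abs=1e-12)

    def test_averaging_reduces_angular_error(self):
        rng = np.random.default_rng(2)
        s = math.tan(math.radians(5.0))
        single_err, avg_err = [], []
        for _ in range(1000):
            noisy = np.stack([rng.normal(0, s, 3), rng.normal(0, s, 3),
                              np.ones(3)], axis=1)
            track = ChromatinTrack(r1=np.zeros((3, 3)), r2=noisy)
            d = division_normal(track)
            avg_err.append(math.acos(min(1.0, d[2])))
            d1 = noisy[0] / np.linalg.norm(noisy[0])
            single_err.append(math.acos(min(1.0, d1[2])))
        assert np.mean(avg_err) < np.mean(single_err)

    def test_coincident_positions_rejected(self):
        with pytest.raises(ValueError):
            division_normal(ChromatinTrack(r1=[[1, 1, 1]], r2=[[1, 1, 1]]))


class TestPlateDisplacement:
    def test_arithmetic_example(self):
        assert plate_displacement([0, 0, 0], [-1, 0, 0], [1, 0, 0]) == \
            pytest.approx(1.0)

    def test_zero_at_coincidence(self):
        assert plate_displacement([2, 3, 4], [2, 3, 4], [0, 0, 1]) == 0.0

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError, match="unit vector"):
            plate_displacement([0, 0, 0], [1, 0, 0], [0, 0, 2])


class TestSplitByPlate:
    def test_center_plane_halves_within_discretisation(self):
        lm, center = digitized_sphere(10.0)
        d = np.array([0.0, 0.0, 1.0])
        v1, v2 = split_by_plate(lm, 1, center, d)
        total = v1 + v2
        # the tie layer is one in-plane voxel sheet through the sphere
        sheet = math.pi * 100.0 * lm.spacing[2]
        assert abs(v1 - v2) <= 2 * sheet
        assert total == pytest.approx(4 / 3 * math.pi * 1000, rel=0.02)

    def test_sum_is_exact_for_any_plane(self):
        lm, center = digitized_sphere(6.0)
        rng = np.random.default_rng(8)
        total = np.count_nonzero(lm.labels) * np.prod(lm.spacing)
        for _ in range(5):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            v1, v2 = split_by_plate(lm, 1, center + rng.normal(0, 1, 3), d)
            assert v1 + v2 == pytest.approx(total, rel=1e-12)

    def test_offset_plane_matches_caps_after_alignment_average(self):
        # sub-voxel alignment averaging removes the grid quantisation bias
        d = np.array([0.0, 0.0, 1.0])
        ratios = []
        for frac in np.linspace(0.0, 0.8, 5):
            lm, center = digitized_sphere(10.0, sub_voxel=frac)
            v1, v2 = split_by_plate(lm, 1, center + 1.75 * d, d)
            ratios.append(v2 / v1)  # larger over smaller
            c1, c2 = cap_volumes(10.0, 1.75)
            assert v2 / v1 == pytest.approx(c1 / c2, rel=0.035)
        c1, c2 = cap_volumes(10.0, 1.75)
        assert np.mean(ratios) == pytest.approx(c1 / c2, rel=0.02)

    def test_extra_shift_adds_to_plate_offset(self):
        d = np.array([0.0, 0.0, 1.0])
        ratios = []
        for frac in np.linspace(0.0, 0.8, 5):
            lm, center = digitized_sphere(10.0, sub_voxel=frac)
            v1, v2 = split_by_plate(lm, 1, center + 1.75 * d, d,
                                    extra_shift=0.45)
            ratios.append(v2 / v1)
        c1, c2 = cap_volumes(10.0, 2.20)
        assert np.mean(ratios) == pytest.approx(c1 / c2, rel=0.02)

    def test_plane_outside_cell_warns_and_returns_empty_part(self):
        lm, center = digitized_sphere(4.0)
        d = np.array([0.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="outside the cell"):
            v1, v2 = split_by_plate(lm, 1, center + 20.0 * d, d)
        assert v1 == 0.0 and v2 > 0.0


class TestExtrapolateShift:
    def test_printed_lag_correction(self):
        assert extrapolate_shift(1.36, 0.030, 15.0) == pytest.approx(1.81)
        assert 0.030 * 15.0 == pytest.approx(0.45)

    def test_zero_velocity_is_identity(self):
        assert extrapolate_shift(1.2, 0.0, 100.0) == 1.2

    def test_arithmetic(self):
        assert extrapolate_shift(0.0, 0.040, 10.0) == pytest.approx(0.40)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_shift(-1.0, 0.03, 15.0)


class TestDisplacementStats:
    def test_degenerate_separation(self):
        samples = [DisplacementSample(f"s{i}", "somatic", 0.0) for i in range(5)]
        samples += [DisplacementSample(f"g{i}", "germline", 1.36)
                    for i in range(5)]
        st = displacement_stats(samples)
        assert st.somatic_mean == 0.0
        assert st.germline_median == pytest.approx(1.36)
        assert st.ks_p < 0.05

    def test_large_sample_parameter_recovery(self):
        samples = sample_displacements(10_000, 100, seed=21)
        st = displacement_stats(samples)
        assert st.somatic_sd == pytest.approx(0.56, abs=0.02)
        assert st.somatic_mean == pytest.approx(-0.1, abs=0.02)
        assert st.jarque_bera_p > 0.01  # data really are normal

    def test_ks_type_one_error_calibrated(self):
        rng = np.random.default_rng(31)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(0, 1, 1000)
            y = rng.normal(0, 1, 1000)
            if stats.ks_2samp(x, y).pvalue < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.10

    def test_jarque_bera_type_one_error_calibrated(self):
        rng = np.random.default_rng(37)
        rejections = 0
        reps = 200
        for _ in range(reps):
            samples = [DisplacementSample(str(i), "somatic", v)
                       for i, v in enumerate(rng.normal(0, 0.56, 500))]
            if displacement_stats(samples).jarque_bera_p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.10

    def test_correlation_with_volume_ratios(self):
        rng = np.random.default_rng(41)
        disp = rng.normal(0, 0.5, 200)
        samples = [DisplacementSample(f"c{i}", "somatic", d)
                   for i, d in enumerate(disp)]
        vr = {f"c{i}": 1.0 + 0.5 * d for i, d in enumerate(disp)}
        st = displacement_stats(samples, vr_by_cell=vr)
        assert st.corr_displacement_vr == pytest.approx(1.0, abs=1e-9)

    def test_small_groups_skip_tests_with_flags(self):
        samples = [DisplacementSample("a", "somatic", 0.1)]
        st = displacement_stats(samples)
        assert st.jarque_bera_p is None and st.ks_p is None
        assert len(st.flags) == 2


class TestMeasuredGeometryOnSyntheticCells:
    def test_median_displacement_recovers_ground_truth(
            self, germline_plate_measurements):
        dxs = [r["geometry"].dx_measured for r in germline_plate_measurements]
        assert np.median(dxs) == pytest.approx(1.36, abs=0.1)

    def test_sign_positive_toward_smaller_daughter(
            self, germline_plate_measurements):
        # the plate is offset toward the new germline (smaller) daughter in
        # every synthetic cell, so every measured displacement is positive
        for r in germline_plate_measurements:
            assert r["geometry"].dx_measured > 0
        # swapping the daughter roles flips the sign
        r = germline_plate_measurements[0]
        swapped = ChromatinTrack(r1=r["track"].r2, r2=r["track"].r1)
        geom = plate.measure_plate_geometry(r["labelmap"], 1, swapped, seed=0)
        assert geom.dx_measured < 0

    def test_displacement_independent_of_cell_radius(
            self, germline_plate_measurements):
        radii = [r["radius"] for r in germline_plate_measurements]
        dxs = [r["geometry"].dx_measured for r in germline_plate_measurements]
        fit = stats.linregress(radii, dxs)
        # zero slope within the 95% confidence band
        assert abs(fit.slope) <= 1.96 * fit.stderr + 1e-12

    def test_oriented_normal_points_toward_larger_daughter(
            self, germline_plate_measurements):
        r = germline_plate_measurements[0]
        d = r["geometry"].d
        axis = r["cell"].division_axis  # toward the smaller daughter
        assert float(d @ axis) == pytest.approx(-1.0, abs=1e-9)
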