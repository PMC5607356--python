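"""FOD reorientation, ROI/profile statistics and cross-modality correlation."""

import numpy as np
import pytest

from fibredisp.compare import (
    DeformationField2D,
    cc_profile,
    correlate_profiles,
    fod_correlation_map,
    local_rotations,
    profile_regression,
    reorient_fod,
    roi_mean,
)
from fibredisp.fod import AxialFOD2D
from fibredisp.synthetic import gen_deformation, global_rotation_field


class TestLocalRotations:
    def test_identity_field_zero_rotation(self):
        rot = local_rotations(DeformationField2D(np.zeros((20, 30, 2))))
        assert np.allclose(rot, 0.0)

    def test_global_rotation_exact_in_interior(self):
        u = global_rotation_field((50, 60), 25.0)
        rot = local_rotations(DeformationField2D(u))
        assert np.allclose(rot[3:-3, 3:-3], 25.0, atol=1e-6)

    def test_smooth_field_matches_neighbourhood_affine_oracle(self):
        """Central-difference Jacobian rotations vs a least-squares affine
        fitted to each 5x5 neighbourhood of displaced coordinates."""
        field, _ = gen_deformation((40, 50), max_rotation_deg=12,
                                   smoothness=10, seed=3)
        rot = local_rotations(field)
        u = field.displacement
        r, c = np.mgrid[0:40, 0:50].astype(float)
        x, y = c + u[..., 1], -(r + u[..., 0])  # displaced, display coords
        for rr in range(5, 35, 7):
            for cc in range(5, 45, 7):
                sl = (slice(rr - 2, rr + 3), slice(cc - 2, cc + 3))
                src = np.column_stack([
                    (c[sl] - cc).ravel(), (-(r[sl] - rr)).ravel(),
                    np.ones(25)])
                a_x, *_ = np.linalg.lstsq(src, x[sl].ravel(), rcond=None)
                a_y, *_ = np.linalg.lstsq(src, y[sl].ravel(), rcond=None)
                jac = np.array([[a_x[0], a_x[1]], [a_y[0], a_y[1]]])
                ang = np.rad2deg(np.arctan2(jac[1, 0] - jac[0, 1],
                                            jac[0, 0] + jac[1, 1]))
                assert abs(ang - rot[rr, cc]) < 1.0

    def test_folding_masked_with_warning(self):
        u = np.zeros((10, 10, 2))
        u[5, 5] = [-3.0, 0.0]  # local flip
        u[4, 5] = [3.0, 0.0]
        with pytest.warns(RuntimeWarning):
            rot = local_rotations(DeformationField2D(u))
        assert np.isnan(rot).any()


class TestReorientFod:
    def test_zero_angle_identity(self, rng):
        f = AxialFOD2D.from_samples(rng.uniform(0, 180, 300))
        out = reorient_fod(f, 0.0)
        assert np.allclose(out.mass, f.mass)

    def test_delta_shifts_by_right_angle(self):
        out = reorient_fod(AxialFOD2D.delta(30.0), 90.0)
        assert out.bin_centers[np.argmax(out.mass)] == pytest.approx(120.5)

    def test_fractional_shift_conserves_mass_and_moves_mean(self, rng):
        f = AxialFOD2D.from_samples(rng.vonmises(0.6, 8, 20000) * 90 / np.pi)
        out = reorient_fod(f, 7.5)
        assert out.mass.sum() == pytest.approx(1.0, abs=1e-9)
        shift = (out.circular_mean_deg() - f.circular_mean_deg()) % 180
        assert shift == pytest.approx(7.5, abs=0.1)

    def test_roundtrip_exact_for_bin_multiples(self, rng):
        f = AxialFOD2D.from_samples(rng.uniform(0, 180, 500))
        out = reorient_fod(reorient_fod(f, 13.0), -13.0)
        assert np.max(np.abs(out.mass - f.mass)) < 1e-6


class TestRoiAndProfiles:
    def test_roi_mean_constant_map(self):
        m = np.full((6, 8), 0.2)
        mask = np.zeros((6, 8), bool)
        mask[2:4, 3:6] = True
        mean, n = roi_mean(m, mask)
        assert mean == pytest.approx(0.2)
        assert n == 6

    def test_roi_single_voxel(self):
        m = np.arange(12.0).reshape(3, 4)
        mask = np.zeros((3, 4), bool)
        mask[1, 2] = True
        assert roi_mean(m, mask)[0] == 6.0

    def test_roi_empty_overlap_raises(self):
        m = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            roi_mean(m, np.ones((3, 3), bool))

    def test_flat_map_gives_flat_profile(self):
        m = np.full((5, 10), 0.3)
        prof = cc_profile(m, np.ones((5, 10), bool))
        assert np.allclose(prof.odi_mean, 0.3)
        assert prof.positions.size == 10

    def test_midline_bump_peaks_at_midline(self):
        cols = np.arange(16)
        bump = 0.05 + 0.25 * np.exp(-((cols - 7.5) / 3) ** 2)
        m = np.tile(bump, (4, 1))
        prof = cc_profile(m, np.ones((4, 16), bool))
        assert prof.positions[np.argmax(prof.odi_mean)] in (7, 8)

    def test_single_column_mask(self):
        m = np.random.default_rng(0).uniform(size=(6, 9))
        mask = np.zeros((6, 9), bool)
        mask[:, 4] = True
        prof = cc_profile(m, mask)
        assert prof.positions.tolist() == [4]

    def test_min_count_drops_sparse_positions(self):
        m = np.ones((4, 3))
        mask = np.zeros((4, 3), bool)
        mask[0, 0] = True          # 1 voxel -> dropped
        mask[:2, 1] = True         # 2 voxels -> kept
        prof = cc_profile(m, mask, min_count=2)
        assert prof.positions.tolist() == [1]


class TestCorrelateProfiles:
    def test_affine_relation_perfect_correlation(self):
        a = np.linspace(0.05, 0.4, 12)
        assert correlate_profiles(a, 2 * a + 1)["r"] == pytest.approx(1.0)
        assert correlate_profiles(a, -a)["r"] == pytest.approx(-1.0)

    def test_noisy_copies_stay_strongly_correlated(self, rng):
        prof = 0.05 + 0.25 * np.exp(-((np.arange(20) - 9.5) / 4) ** 2)
        sigma = 0.1 * np.ptp(prof)
        r = correlate_profiles(prof + rng.normal(0, sigma, 20),
                               prof + rng.normal(0, sigma, 20))["r"]
        assert r > 0.9

    def test_subset_below_cutoff(self):
        a = np.array([0.02, 0.05, 0.08, 0.2, 0.3, 0.06, 0.04])
        out = correlate_profiles(a, a * 1.5, subset_max=0.1)
        assert out["n_subset"] == 5
        assert out["r_subset"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        out = correlate_profiles(np.ones(5), np.arange(5.0))
        assert out["degenerate"] and np.isnan(out["r"])

    def test_affine_rescaling_invariance(self, rng):
        a = rng.uniform(0, 1, 15)
        b = rng.uniform(0, 1, 15)
        r1 = correlate_profiles(a, b)["r"]
        r2 = correlate_profiles(3 * a - 0.2, 0.5 * b + 4)["r"]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestFodCorrelationMap:
    def _grid(self, fods):
        arr = np.empty((1, len(fods)), dtype=object)
        arr[0, :] = fods
        return arr

    def test_identical_fods_r_one(self, rng):
        f = AxialFOD2D.from_samples(rng.uniform(0, 90, 400))
        r = fod_correlation_map(self._grid([f]), self._grid([f]))
        assert r[0, 0] == pytest.approx(1.0)

    def test_antialigned_smoothed_deltas_anticorrelate(self):
        from scipy.ndimage import gaussian_filter1d

        def smooth_delta(angle):
            f = AxialFOD2D.delta(angle)
            m = gaussian_filter1d(f.mass, 5.0, mode="wrap")
            return AxialFOD2D(f.bin_edges, m / m.sum())

        r = fod_correlation_map(self._grid([smooth_delta(0.0)]),
                                self._grid([smooth_delta(90.0)]))
        assert r[0, 0] < 0

    def test_missing_or_flat_fod_gives_nan(self, rng):
        f = AxialFOD2D.from_samples(rng.uniform(0, 90, 400))
        r = fod_correlation_map(self._grid([f, None, AxialFOD2D.uniform()]),
                                self._grid([f, f, f]))
        assert np.isfinite(r[0, 0])
        assert np.isnan(r[0, 1]) and np.isnan(r[0, 2])


class TestProfileRegression:
    def test_pure_myelin_profile(self, rng):
        m = rng.uniform(0.05, 0.4, 20)
        a = rng.uniform(0.2, 0.6, 20)
        out = profile_regression(m, m, a)
        assert out["params"]["myelin"] == pytest.approx(1.0, abs=1e-9)
        assert out["params"]["astro"] == pytest.approx(0.0, abs=1e-9)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_even_mixture_recovered_exactly(self, rng):
        m = rng.uniform(0.05, 0.4, 20)
        a = rng.uniform(0.2, 0.6, 20)
        out = profile_regression(0.5 * m + 0.5 * a, m, a)
        assert out["params"]["myelin"] == pytest.approx(0.5, abs=1e-9)
        assert out["params"]["astro"] == pytest.approx(0.5, abs=1e-9)

    def test_null_astro_contribution_inside_ci(self, rng):
        """When the target is myelin-driven plus noise, the astrocyte
        coefficient's confidence interval covers zero."""
        m = rng.uniform(0.05, 0.4, 40)
        a = rng.uniform(0.2, 0.6, 40)
        y = m + rng.normal(0, 0.02, 40)
        out = profile_regression(y, m, a)
        lo, hi = out["conf_int"][2]
        assert lo <= 0.0 <= hi

    def test_collinear_predictors_flagged(self):
        m = np.linspace(0, 1, 10)
        out = profile_regression(m, m, 2 * m + 1e-12)
        assert out["collinear"]
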