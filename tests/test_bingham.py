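"""Bingham densities, the dispersion index, plane restriction and ML fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special

from fibredisp import (
    AxialFOD2D,
    Bingham2,
    Bingham3,
    K_MAX,
    bingham3_density,
    fit_bingham2,
    k_from_odi,
    odi_from_k,
    restrict_to_plane,
)
from fibredisp.bingham import DegenerateOrientationError, sample_bingham3
from fibredisp.quadrature import sphere_grid


def random_unit_vectors(n, rng):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestDensity:
    def test_uniform_limit_is_sphere_density(self):
        b = Bingham3(np.eye(3), 0.0, 0.0)
        d = bingham3_density(b, [[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        assert np.allclose(d, 1.0 / (4 * np.pi), atol=1e-10)

    def test_watson_equivalence_against_closed_form(self, rng):
        """k1 = k2 = kappa is the Watson law; check against the analytic
        Watson normalization 4*pi*M(1/2, 3/2, kappa) (Kummer function)."""
        kappa = 5.0
        b = Bingham3(np.eye(3), kappa, kappa)
        v = random_unit_vectors(100, rng)
        ours = bingham3_density(b, v)
        watson = np.exp(kappa * (v @ b.mu0) ** 2) / (
            4 * np.pi * special.hyp1f1(0.5, 1.5, kappa)
        )
        assert np.max(np.abs(ours - watson) / watson) < 1e-6

    @pytest.mark.parametrize("k1,k2", [(0, 0), (5, 5), (8, 3), (128, 64), (128, 128)])
    def test_quadrature_normalization(self, k1, k2):
        b = Bingham3(np.eye(3), float(k1), float(k2))
        pts, wts = sphere_grid()
        assert abs(np.sum(wts * bingham3_density(b, pts)) - 1.0) < 1e-4

    def test_antipodal_symmetry_and_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        b = Bingham3(np.eye(3), 9.0, 2.0)
        v = random_unit_vectors(50, rng)
        assert np.allclose(bingham3_density(b, v), bingham3_density(b, -v))
        r = Rotation.random(random_state=3).as_matrix()
        b_rot = Bingham3(r @ b.axes, b.k1, b.k2)
        assert np.allclose(
            bingham3_density(b_rot, v @ r.T), bingham3_density(b, v), rtol=1e-9
        )

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            Bingham3(np.eye(3) * 1.1, 1.0, 0.5)
        with pytest.raises(ValueError):
            Bingham3(np.eye(3), 1.0, 2.0)  # k1 < k2
        b = Bingham3(np.eye(3), 1.0, 0.5)
        with pytest.raises(ValueError):
            bingham3_density(b, [[0.0, 0.0, 2.0]])


class TestODI:
    def test_limits(self):
        assert odi_from_k(1e9) == pytest.approx(0.0, abs=1e-8)
        assert odi_from_k(0.0) == 1.0
        assert odi_from_k(1.0) == pytest.approx(0.5, abs=1e-12)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            odi_from_k(-0.1)

    @given(st.floats(min_value=0.0, max_value=1e6),
           st.floats(min_value=1e-9, max_value=1e6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_decreasing(self, k, dk):
        assert odi_from_k(k + dk) < odi_from_k(k)

    def test_inverse_roundtrip(self):
        for odi in [0.01, 0.1, 0.5, 0.99]:
            assert odi_from_k(k_from_odi(odi)) == pytest.approx(odi, rel=1e-12)


class TestRestrictToPlane:
    def test_inplane_axis_selects_inplane_concentration(self):
        mu0 = np.array([1.0, 0.0, 0.0])
        mu1 = np.array([0.0, 0.0, 1.0])  # out-of-plane dispersion axis
        mu2 = np.array([0.0, 1.0, 0.0])
        b = Bingham3(np.column_stack([mu0, mu1, mu2]), 8.0, 3.0)
        r = restrict_to_plane(b, [0, 0, 1.0])
        assert r.k2d == pytest.approx(3.0, abs=1e-9)
        assert r.mu == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_restricts_to_zero_concentration(self):
        r = restrict_to_plane(Bingham3(np.eye(3), 0.0, 0.0), [0, 0, 1.0])
        assert r.k2d == 0.0

    def test_degenerate_axis_raises(self):
        b = Bingham3.from_principal_axis([0.0, 0.0, 1.0], 5.0, 2.0)
        with pytest.raises(DegenerateOrientationError):
            restrict_to_plane(b, [0, 0, 1.0])

    def test_against_great_circle_ml_oracle(self, rng):
        """The restricted law must match an ML Bingham2 fit to the 3D density
        evaluated directly on the great circle."""
        for _ in range(5):
            mu0 = np.array([np.cos(a := rng.uniform(0, np.pi)), np.sin(a), 0.0])
            roll = rng.uniform(0, 180)
            k1, k2 = sorted(rng.uniform(0.5, 20, 2))[::-1]
            b = Bingham3.from_principal_axis(mu0, k1, k2, roll_deg=roll)
            got = restrict_to_plane(b, [0, 0, 1.0])

            theta = np.deg2rad(np.linspace(0, 180, 3600, endpoint=False))
            circle = np.column_stack(
                [np.cos(theta), np.sin(theta), np.zeros_like(theta)]
            )
            dens = bingham3_density(b, circle)
            w = dens / dens.sum()
            tdeg = np.rad2deg(theta)

            def nll(params):
                mu, k = params
                d = np.deg2rad(tdeg - mu)
                return float(np.sum(w * (k * np.sin(d) ** 2))
                             + np.log(np.pi * special.i0e(k / 2.0)))

            res = optimize.minimize(nll, x0=[got.mu, max(got.k2d, 0.1)],
                                    method="Nelder-Mead")
            k_oracle = res.x[1]
            assert abs(got.k2d - k_oracle) / max(k_oracle, 1e-9) < 0.05

    def test_restriction_matches_projected_sampling(self, rng):
        """ODI from the analytic restriction equals the ODI from sampling the
        3D law, projecting axial angles into the plane, and refitting —
        in the mostly-in-plane regime (out-of-plane axis strongly
        concentrated), which is where the in-plane restriction is the right
        summary of the 3D law."""
        # roll 90 puts the k1 = 10 axis out of plane, k2 = 3 in plane
        b = Bingham3.from_principal_axis([1.0, 0.0, 0.0], 10.0, 3.0, roll_deg=90.0)
        analytic = restrict_to_plane(b, [0, 0, 1.0]).odi
        v = sample_bingham3(b, 1_000_000, rng)
        ang = np.rad2deg(np.arctan2(v[:, 1], v[:, 0]))
        fod = AxialFOD2D.from_samples(ang, 180)
        sampled = fit_bingham2(fod).odi
        assert abs(analytic - sampled) < 0.03


class TestFitBingham2:
    def test_uniform_fod_fits_zero_concentration(self):
        fit = fit_bingham2(AxialFOD2D.uniform(180))
        assert fit.k2d == 0.0
        assert fit.odi == 1.0

    def test_delta_fod_saturates_at_cap(self):
        fit = fit_bingham2(AxialFOD2D.delta(30.0))
        assert fit.k2d == K_MAX
        assert fit.odi < 0.01
        assert abs(fit.mu - 30.5) < 1.0  # bin centre of the delta

    def test_all_zero_fod_rejected(self):
        fod = AxialFOD2D.uniform(180)
        fod.mass = np.zeros_like(fod.mass)
        with pytest.raises(ValueError):
            fit_bingham2(fod)

    def test_recovery_against_grid_search_oracle(self, rng):
        """1e5 samples from Bingham2(40 deg, k=10): mu within 1 degree and k
        within 5% of a dense grid-search ML oracle."""
        truth = Bingham2(40.0, 10.0)
        fod = AxialFOD2D.from_samples(truth.sample(100_000, rng), 180)
        fit = fit_bingham2(fod)
        assert min(abs(fit.mu - 40.0), 180 - abs(fit.mu - 40.0)) < 1.0
        assert abs(fit.k2d - 10.0) / 10.0 < 0.05

        # independent oracle: exhaustive scan over k with mu fixed at the fit
        ks = np.arange(0.01, 100.0, 0.01)
        d = np.deg2rad(fod.bin_centers - fit.mu)
        w_sin2 = fod.mass @ (np.sin(d) ** 2)
        nll = ks * w_sin2 + np.log(np.pi * special.i0e(ks / 2.0))
        k_oracle = ks[np.argmin(nll)]
        assert abs(fit.k2d - k_oracle) < 0.02

    def test_odi_monotone_in_planted_concentration(self, rng):
        odis = []
        for k in [0.5, 1, 2, 4, 8, 16]:
            fod = AxialFOD2D.from_samples(Bingham2(70.0, k).sample(100_000, rng))
            odis.append(fit_bingham2(fod).odi)
        assert all(a > b for a, b in zip(odis, odis[1:]))


class TestAxialFOD:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_from_samples_normalized(self, seed):
        rng = np.random.default_rng(seed)
        fod = AxialFOD2D.from_samples(rng.uniform(-400, 400, 500))
        assert fod.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_csv_roundtrip(self, tmp_path, rng):
        fod = AxialFOD2D.from_samples(rng.uniform(0, 180, 1000), 90)
        p = tmp_path / "fod.csv"
        fod.to_csv(p)
        back = AxialFOD2D.from_csv(p)
        assert np.allclose(back.mass, fod.mass)
        assert np.allclose(back.bin_edges, fod.bin_edges)

    def test_bingham2_json_export(self, tmp_path):
        import json

        Bingham2(33.0, 4.0).to_json(tmp_path / "b.json")
        d = json.loads((tmp_path / "b.json").read_text())
        assert d["mu_deg"] == pytest.approx(33.0)
        assert d["odi"] == pytest.approx(odi_from_k(4.0))
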