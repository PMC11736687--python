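"""Geometry builders, point-dipole couplings, and the OU disorder generator."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

import mcfret as mc
from mcfret.errors import GeometryError, ParameterError


class TestChainGeometry:
    def test_no_slip_interchain_distance(self):
        s = mc.build_parallel_chains(2, 0.95, 1.5, 0.0)
        d = np.linalg.norm(s.positions[2] - s.positions[0])
        assert d == pytest.approx(1.5)

    def test_half_slip_interchain_distance(self):
        s = mc.build_parallel_chains(2, 0.95, 1.5, 0.5)
        d = np.linalg.norm(s.positions[2] - s.positions[0])
        assert d == pytest.approx(np.hypot(1.5, 0.475))

    def test_lattice_spacing(self):
        s = mc.build_parallel_chains(200, 0.95, 1.5, 0.0)
        gaps = np.linalg.norm(np.diff(s.positions[:200], axis=0), axis=1)
        assert np.allclose(gaps, 0.95)

    def test_dipoles_along_axis(self):
        s = mc.build_parallel_chains(5, 0.95, 1.5, 0.3, dipole_magnitude=11.4)
        assert np.allclose(s.dipoles[:, 1:], 0.0)
        assert np.allclose(np.abs(s.dipoles[:, 0]), 11.4)

    @pytest.mark.parametrize("kwargs", [
        dict(spacing=-1.0, chain_separation=1.5),
        dict(spacing=0.95, chain_separation=0.0),
        dict(spacing=0.95, chain_separation=1.5, slip=1.0),
    ])
    def test_invalid_geometry(self, kwargs):
        with pytest.raises(GeometryError):
            mc.build_parallel_chains(3, **{"slip": 0.0, **kwargs})


class TestRingGeometry:
    def test_sites_on_circle(self):
        s = mc.build_ring(18, 3.0, 6.3)
        assert np.allclose(np.linalg.norm(s.positions, axis=1), 3.0)
        # neighbor arc angle 2 pi / 18
        ang = np.arctan2(s.positions[:, 1], s.positions[:, 0])
        steps = np.diff(np.unwrap(ang))
        assert np.allclose(steps, 2 * np.pi / 18)

    def test_antipodal_antiparallel(self):
        s = mc.build_ring(2, 1.0, 5.0)
        assert np.allclose(s.positions[0], -s.positions[1])
        assert np.allclose(s.dipoles[0], -s.dipoles[1])

    def test_two_ring_min_distance(self):
        r1 = mc.build_ring(18, 3.0, 6.3)
        r2 = mc.build_ring(18, 3.0, 6.3, center=(20.0, 0.0, 0.0))
        d = np.linalg.norm(
            r1.positions[:, None, :] - r2.positions[None, :, :], axis=-1
        )
        assert d.min() == pytest.approx(20.0 - 2 * 3.0, abs=1e-9)

    def test_too_few_sites(self):
        with pytest.raises(GeometryError):
            mc.build_ring(1, 3.0, 6.3)


class TestPointDipoleCouplings:
    def test_printed_aggregate_couplings(self):
        """Collinear, broadside, and slipped couplings of the 11.4 D chain pair."""
        s = mc.build_parallel_chains(3, 0.95, 1.5, 0.0)
        J = mc.point_dipole_couplings(s)
        assert J[0, 1] == pytest.approx(-1526.1, abs=0.05)
        assert J[3, 0] == pytest.approx(193.8, abs=0.05)
        s5 = mc.build_parallel_chains(3, 0.95, 1.5, 0.5)
        J5 = mc.point_dipole_couplings(s5)
        assert np.abs(J5[3:, :3]).max() == pytest.approx(122.0, abs=0.05)

    def test_magic_angle_vanishes(self):
        # parallel dipoles with (mu.r)^2 = 1/3 -> orientation factor zero
        ct = 1.0 / np.sqrt(3.0)
        st = np.sqrt(1.0 - ct**2)
        system = mc.SiteSystem(
            positions=[[0, 0, 0], [2.0 * ct, 2.0 * st, 0.0]],
            dipoles=[[5.0, 0, 0], [5.0, 0, 0]],
            mean_energies=[0.0, 0.0],
        )
        J = mc.point_dipole_couplings(system)
        assert abs(J[0, 1]) < 1e-9

    def test_inverse_cube_distance(self):
        def pair(r):
            system = mc.SiteSystem(
                positions=[[0, 0, 0], [0, r, 0]],
                dipoles=[[7.0, 0, 0], [7.0, 0, 0]],
                mean_energies=[0, 0],
            )
            return mc.point_dipole_couplings(system)[0, 1]

        assert pair(2.0) / pair(1.0) == pytest.approx(1.0 / 8.0, rel=1e-12)

    def test_dipole_scale_quadratic(self):
        s1 = mc.build_parallel_chains(4, 0.95, 1.5, 0.2, dipole_magnitude=11.4)
        s2 = mc.build_parallel_chains(4, 0.95, 1.5, 0.2, dipole_magnitude=22.8)
        J1 = mc.point_dipole_couplings(s1)
        J2 = mc.point_dipole_couplings(s2)
        assert np.allclose(J2, 4.0 * J1, rtol=1e-12)

    def test_symmetry_and_zero_diagonal(self):
        s = mc.build_ring(7, 2.0, 4.0)
        J = mc.point_dipole_couplings(s)
        assert np.array_equal(J, J.T)
        assert np.all(np.diag(J) == 0.0)

    def test_coincident_positions_error(self):
        system = mc.SiteSystem(
            positions=[[0, 0, 0], [0, 0, 0]],
            dipoles=[[1, 0, 0], [1, 0, 0]],
            mean_energies=[0, 0],
        )
        with pytest.raises(GeometryError, match="sites 0 and 1"):
            mc.point_dipole_couplings(system)

    def test_screening_scales_couplings(self):
        r = mc.build_ring(6, 2.0, 4.0, screening=0.55)
        r_full = mc.build_ring(6, 2.0, 4.0, screening=1.0)
        assert np.allclose(
            mc.point_dipole_couplings(r), 0.55 * mc.point_dipole_couplings(r_full)
        )


class TestOUGenerator:
    def test_stationary_moments(self):
        model = mc.DisorderModel([(1500.0, 6.0)])
        e = mc.generate_ou_trajectory(model, 1, 1_000_000, 3.0,
                                      mean_energies=11955.0, seed=11)
        x = e[:, 0]
        se = 1500.0 / np.sqrt(1e6 / (2 * 6.0 / 3.0))  # crude effective-N s.e.
        assert x.mean() == pytest.approx(11955.0, abs=3 * se)
        assert x.var() == pytest.approx(1500.0**2, rel=0.02)

    def test_autocorrelation_at_tau(self):
        sigma, tau, dt = 1500.0, 6.0, 3.0
        model = mc.DisorderModel([(sigma, tau)])
        x = mc.generate_ou_trajectory(model, 1, 1_000_000, dt, seed=12)[:, 0]
        lag = int(tau / dt)
        acf = np.mean(x[:-lag] * x[lag:])
        assert acf == pytest.approx(sigma**2 / np.e, rel=0.03)

    def test_seed_reproducibility(self):
        model = mc.DisorderModel([(500.0, 10.0)])
        a = mc.generate_ou_trajectory(model, 3, 1000, 2.0, seed=5)
        b = mc.generate_ou_trajectory(model, 3, 1000, 2.0, seed=5)
        c = mc.generate_ou_trajectory(model, 3, 1000, 2.0, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_adding_sites_preserves_existing_streams(self):
        model = mc.DisorderModel([(500.0, 10.0)])
        a = mc.generate_ou_trajectory(model, 2, 500, 2.0, seed=5)
        b = mc.generate_ou_trajectory(model, 4, 500, 2.0, seed=5)
        assert np.array_equal(a, b[:, :2])

    def test_two_component_autocovariance(self):
        """Sum of two OU components has the sum of their autocovariances."""
        s1, t1, s2, t2 = 800.0, 5.0, 400.0, 60.0
        dt = 2.0
        model = mc.DisorderModel([(s1, t1), (s2, t2)])
        x = mc.generate_ou_trajectory(model, 1, 1_000_000, dt, seed=21)[:, 0]
        lags = np.arange(0, 40)
        acf = np.array([np.mean(x[: len(x) - L or None] * x[L:]) for L in lags])

        def model_acf(t, a1, a2):
            return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)

        popt, _ = curve_fit(model_acf, lags * dt, acf, p0=[s1**2, s2**2])
        assert popt[0] == pytest.approx(s1**2, rel=0.05)
        assert popt[1] == pytest.approx(s2**2, rel=0.05)

    @pytest.mark.parametrize("bad", [
        dict(components=[(-1.0, 5.0)]),
        dict(components=[(100.0, 0.0)]),
    ])
    def test_invalid_disorder(self, bad):
        with pytest.raises(ParameterError):
            mc.DisorderModel(**bad)

    def test_bad_dt(self):
        with pytest.raises(ParameterError):
            mc.generate_ou_trajectory(mc.DisorderModel([(1.0, 1.0)]), 1, 10, 0.0)
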