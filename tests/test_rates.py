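"""Absorption/emission matrices, rate response, rate integral, decoherence."""

import warnings

import numpy as np
import pytest

import mcfret as mc
from mcfret.constants import U_CM_FS
from mcfret.errors import ParameterError
from mcfret.rates import QuadratureWarning


class TestEquilibriumDensity:
    def test_high_temperature_limit_flat(self, random_symmetric_h):
        H = random_symmetric_h(5)
        rho = mc.equilibrium_density(H, mc.ThermalSpec(mode="ht"))
        assert np.allclose(rho, np.eye(5) / 5)

    def test_low_temperature_projector(self, random_symmetric_h):
        H = random_symmetric_h(4, scale=500.0)
        rho = mc.equilibrium_density(H, mc.ThermalSpec(temperature=1e-3))
        w, V = np.linalg.eigh(H)
        proj = np.outer(V[:, 0], V[:, 0])
        assert np.allclose(rho, proj, atol=1e-10)

    def test_boltzmann_ratio_two_level(self):
        kT = mc.KB_CM * 200.0
        gap = kT * np.log(2.0)
        H = np.diag([0.0, gap])
        rho = mc.equilibrium_density(H, mc.ThermalSpec(temperature=200.0))
        assert np.diag(rho) == pytest.approx([2.0 / 3.0, 1.0 / 3.0])

    def test_properties(self, random_symmetric_h):
        H = random_symmetric_h(6)
        rho = mc.equilibrium_density(H, mc.ThermalSpec(temperature=300.0))
        assert np.trace(rho) == pytest.approx(1.0)
        assert np.allclose(rho, rho.T)
        assert np.all(np.linalg.eigvalsh(rho) > -1e-12)

    def test_bad_temperature(self):
        with pytest.raises(ParameterError):
            mc.ThermalSpec(temperature=-5.0)


class TestAbsorptionEmission:
    def test_absorption_t0_identity(self, dimer_trajectory):
        I = mc.absorption_matrix(dimer_trajectory, [0], 30.0, mc.SamplingSpec(50, 40))
        assert np.allclose(I.values[0], np.eye(1))

    def test_zero_disorder_static_equals_propagator(self):
        H = np.array([[100.0, 40.0], [40.0, -50.0]])
        traj = mc.HamiltonianTrajectory(
            np.tile(np.diag(H), (30, 1)), H - np.diag(np.diag(H)), 3.0
        )
        I = mc.absorption_matrix(traj, [0, 1], 60.0, mc.SamplingSpec(3, 2))
        from mcfret.propagation import window_propagators
        U = window_propagators(traj, np.array([0, 1]), 0, 20)
        assert np.allclose(I.values, U, atol=1e-12)

    def test_single_site_kubo_decay(self):
        """|I_11(t)| follows the Kubo dephasing function for OU noise."""
        sigma, tau, dt = 300.0, 20.0, 3.0
        t_c, nw, interval = 90.0, 10_000, 40
        model = mc.DisorderModel([(sigma, tau)])
        nf = (nw - 1) * interval + int(t_c / dt) + 1
        e = mc.generate_ou_trajectory(model, 1, nf, dt, seed=9)
        traj = mc.HamiltonianTrajectory(e, np.zeros((1, 1)), dt)
        I = mc.absorption_matrix(traj, [0], t_c, mc.SamplingSpec(nw, interval))
        t = I.times
        g = (sigma * U_CM_FS * tau) ** 2 * (np.exp(-t / tau) - 1 + t / tau)
        assert np.max(np.abs(np.abs(I.values[:, 0, 0]) - np.exp(-g))) < 0.03

    def test_emission_t0_trace_one_ht(self, dimer_trajectory):
        E = mc.emission_matrix(
            dimer_trajectory, [0, 1], 30.0, mc.ThermalSpec(mode="ht"),
            mc.SamplingSpec(20, 40),
        )
        assert np.allclose(E.values[0], np.eye(2) / 2)

    def test_single_site_emission_matches_absorption_modulus(self, dimer_trajectory):
        samp = mc.SamplingSpec(2000, 40)
        I = mc.absorption_matrix(dimer_trajectory, [0], 60.0, samp)
        E = mc.emission_matrix(
            dimer_trajectory, [0], 60.0, mc.ThermalSpec(temperature=300.0), samp
        )
        assert np.allclose(np.abs(E.values), np.abs(I.values), atol=1e-12)

    def test_static_zero_t_projector_modulus_constant(self):
        H = np.array([[0.0, 60.0], [60.0, 80.0]])
        traj = mc.HamiltonianTrajectory(
            np.tile(np.diag(H), (40, 1)), H - np.diag(np.diag(H)), 3.0
        )
        E = mc.emission_matrix(
            traj, [0, 1], 60.0, mc.ThermalSpec(temperature=1e-3),
            mc.SamplingSpec(2, 10),
        )
        mods = np.abs(E.values)
        assert np.allclose(mods, mods[0], atol=1e-10)

    def test_insufficient_frames(self, dimer_trajectory):
        with pytest.raises(mc.SamplingError, match="frames"):
            mc.absorption_matrix(
                dimer_trajectory, [0], 30.0,
                mc.SamplingSpec(10**7, 40),
            )


class TestRateResponse:
    def test_zero_coupling_zero_response(self, dimer_trajectory):
        samp = mc.SamplingSpec(50, 40)
        I = mc.absorption_matrix(dimer_trajectory, [1], 30.0, samp)
        E = mc.emission_matrix(
            dimer_trajectory, [0], 30.0, mc.ThermalSpec(mode="ht"), samp
        )
        R = mc.rate_response(I, E, np.zeros((1, 1)))
        assert np.all(R.values == 0)

    def test_static_two_site_phase_rotation(self):
        """Two static single-site segments with gap D: |R| constant, phase u*D*t."""
        gap, J = 250.0, 10.0
        traj = mc.HamiltonianTrajectory(
            np.tile([0.0, gap], (40, 1)), np.array([[0.0, J], [J, 0.0]]), 3.0
        )
        samp = mc.SamplingSpec(2, 10)
        I = mc.absorption_matrix(traj, [1], 60.0, samp)
        E = mc.emission_matrix(traj, [0], 60.0, mc.ThermalSpec(mode="ht"), samp)
        R = mc.rate_response(I, E, np.array([[J]]))
        assert np.allclose(np.abs(R.values), J * J, atol=1e-10)
        expected = J * J * np.exp(-1j * U_CM_FS * gap * R.times)
        assert np.allclose(R.values, expected, atol=1e-10)

    def test_r0_real_nonnegative(self, dimer_trajectory):
        samp = mc.SamplingSpec(100, 40)
        I = mc.absorption_matrix(dimer_trajectory, [1], 30.0, samp)
        E = mc.emission_matrix(
            dimer_trajectory, [0], 30.0, mc.ThermalSpec(temperature=300.0), samp
        )
        R = mc.rate_response(I, E, np.array([[10.0]]))
        assert abs(R.values[0].imag) < 1e-10
        assert R.values[0].real >= 0

    def test_dimension_mismatch(self, dimer_trajectory):
        samp = mc.SamplingSpec(10, 40)
        I = mc.absorption_matrix(dimer_trajectory, [1], 30.0, samp)
        E = mc.emission_matrix(
            dimer_trajectory, [0], 30.0, mc.ThermalSpec(mode="ht"), samp
        )
        with pytest.raises(ParameterError, match="coupling block"):
            mc.rate_response(I, E, np.zeros((2, 2)))


class TestIntegration:
    def test_gaussian_cosine_integral(self):
        """Trapezium quadrature of exp(-t^2) cos t against the closed form."""
        t = np.arange(0.0, 6.0 + 1e-12, 0.05)
        y = np.exp(-t * t) * np.cos(t)
        exact = 0.5 * np.sqrt(np.pi) * np.exp(-0.25)
        assert mc.trapezium_end_weighted(y, 0.05) == pytest.approx(exact, abs=1e-3)

    def test_zero_response_zero_rate(self):
        R = mc.ResponseFunction(np.zeros(25, dtype=complex), 3.0)
        res = mc.integrate_rate(R)
        assert res.rate == 0.0
        assert not res.quadrature_warning

    def test_quadrature_warning_on_coarse_sampling(self):
        # narrow peak under-resolved by the grid: trapezium and Simpson split
        t = np.arange(5) * 1.0
        y = np.zeros(5, dtype=complex)
        y[0] = 1.0
        with pytest.warns(QuadratureWarning, match="time step"):
            res = mc.integrate_rate(mc.ResponseFunction(y, 1.0))
        assert res.quadrature_warning

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            mc.integrate_rate(mc.ResponseFunction(np.ones(2, dtype=complex), 1.0))

    def test_rate_scales_with_coupling_squared(self, dimer_trajectory):
        samp = mc.SamplingSpec(500, 40)
        I = mc.absorption_matrix(dimer_trajectory, [1], 60.0, samp)
        E = mc.emission_matrix(
            dimer_trajectory, [0], 60.0, mc.ThermalSpec(temperature=300.0), samp
        )
        k1 = mc.integrate_rate(mc.rate_response(I, E, np.array([[10.0]]))).rate
        k2 = mc.integrate_rate(mc.rate_response(I, E, np.array([[30.0]]))).rate
        assert k2 == pytest.approx(9.0 * k1, rel=1e-12)


class TestDecoherence:
    def test_exponential_decay_rate(self):
        tau = 40.0  # fs
        t = np.arange(0.0, 2000.0, 1.0)
        R = mc.ResponseFunction(np.exp(-t / tau).astype(complex), 1.0)
        assert mc.decoherence_rate(R) == pytest.approx(1e3 / tau, rel=0.01)

    def test_scale_invariance(self):
        t = np.arange(0.0, 500.0, 2.0)
        base = (np.exp(-t / 30.0) * np.exp(-1j * 0.05 * t)).astype(complex)
        g1 = mc.decoherence_rate(mc.ResponseFunction(base, 2.0))
        g2 = mc.decoherence_rate(mc.ResponseFunction(137.0 * base, 2.0))
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_zero_response_undefined(self):
        with pytest.raises(ParameterError, match="zero"):
            mc.decoherence_rate(mc.ResponseFunction(np.zeros(10, dtype=complex), 1.0))


class TestCouplingSumSq:
    def test_uniform_block(self):
        J = np.full((4, 3), 2.0)
        per_donor, avg = mc.coupling_sum_sq(J)
        assert np.allclose(per_donor, 4 * 4.0)
        assert avg == pytest.approx(16.0)

    def test_matches_brute_force_on_chain_pair(self):
        n = 30
        s = mc.build_parallel_chains(n, 0.95, 1.5, 0.0)
        J = mc.point_dipole_couplings(s)[n:, :n]
        per_donor, avg = mc.coupling_sum_sq(J)
        brute = np.array([sum(J[a, d] ** 2 for a in range(n)) for d in range(n)])
        assert np.allclose(per_donor, brute)
        assert avg == pytest.approx(brute.mean())

    def test_empty_block_rejected(self):
        with pytest.raises(ParameterError):
            mc.coupling_sum_sq(np.zeros((0, 0)))


def test_coupling_fluctuation_freeze_warning(rng):
    n_frames = 60
    J0 = np.array([[0.0, 20.0], [20.0, 0.0]])
    Jt = np.tile(J0, (n_frames, 1, 1))
    Jt[:, 0, 1] += rng.standard_normal(n_frames)
    Jt[:, 1, 0] = Jt[:, 0, 1]
    traj = mc.HamiltonianTrajectory(rng.standard_normal((n_frames, 2)) * 100, Jt, 3.0)
    with pytest.warns(mc.rates.CouplingFluctuationWarning):
        mc.segment_pair_rate(
            traj, [0], [1], 30.0, mc.ThermalSpec(mode="ht"), mc.SamplingSpec(5, 10)
        )
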