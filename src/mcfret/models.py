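"""Model systems and fluctuating-Hamiltonian trajectories.

Builds the geometric model systems used throughout (parallel J-aggregate
chains, chromophore rings), evaluates point-dipole resonance couplings, and
generates stochastic site-energy trajectories as sums of independent
Ornstein-Uhlenbeck (overdamped Brownian oscillator) components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .constants import DIPOLE_COUPLING_CM_A3_D2, NM_TO_ANGSTROM, U_CM_FS
from .errors import GeometryError, ParameterError


@dataclass
class SiteSystem:
    """A set of chromophore sites with positions, transition dipoles and
    mean transition energies.

    Parameters
    ----------
    positions : (n, 3) array, nm
    dipoles : (n, 3) array, Debye
    mean_energies : (n,) array, cm^-1
    screening : float
        Dimensionless coupling scale factor 1/eps_r applied to all
        point-dipole couplings; in (0, 1].
    """

    positions: np.ndarray
    dipoles: np.ndarray
    mean_energies: np.ndarray
    screening: float = 1.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.dipoles = np.atleast_2d(np.asarray(self.dipoles, dtype=float))
        self.mean_energies = np.asarray(self.mean_energies, dtype=float).ravel()
        if self.positions.shape != self.dipoles.shape or self.positions.shape[1] != 3:
            raise GeometryError("positions and dipoles must both be (n, 3)")
        if self.mean_energies.shape[0] != self.positions.shape[0]:
            raise GeometryError("mean_energies length must match site count")
        if not np.all(np.isfinite(self.positions)):
            raise GeometryError("non-finite site positions")
        if not (0.0 < self.screening <= 1.0):
            raise ParameterError(f"screening must be in (0, 1], got {self.screening}")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @staticmethod
    def concatenate(systems: Sequence["SiteSystem"]) -> "SiteSystem":
        """Join several site systems into one (shared screening required)."""
        screenings = {s.screening for s in systems}
        if len(screenings) != 1:
            raise ParameterError("cannot concatenate systems with different screening")
        return SiteSystem(
            positions=np.vstack([s.positions for s in systems]),
            dipoles=np.vstack([s.dipoles for s in systems]),
            mean_energies=np.concatenate([s.mean_energies for s in systems]),
            screening=systems[0].screening,
        )


@dataclass
class DisorderModel:
    """Site-energy fluctuation model: a sum of independent stationary
    Gaussian components, each with exponential autocorrelation
    sigma^2 exp(-t/tau).

    components : list of (sigma [cm^-1], tau [fs]) pairs, shared by all sites
        (every site gets an independent realization of each component).
    """

    components: Sequence[tuple[float, float]]
    seed: int | None = None

    def __post_init__(self):
        comps = [(float(s), float(t)) for s, t in self.components]
        for s, t in comps:
            if s < 0:
                raise ParameterError(f"sigma must be >= 0, got {s}")
            if t <= 0:
                raise ParameterError(f"tau must be > 0, got {t}")
        self.components = comps

    @property
    def total_variance(self) -> float:
        return float(sum(s * s for s, _ in self.components))


@dataclass
class HamiltonianTrajectory:
    """Time-resolved Frenkel-exciton Hamiltonian.

    energies : (n_frames, n_sites) array, cm^-1 — per-frame site energies.
    couplings : (n_sites, n_sites) static symmetric matrix, or
        (n_frames, n_sites, n_sites) per-frame matrices, cm^-1.
    dt : frame spacing, fs.
    """

    energies: np.ndarray
    couplings: np.ndarray
    dt: float

    def __post_init__(self):
        self.energies = np.atleast_2d(np.asarray(self.energies, dtype=float))
        self.couplings = np.asarray(self.couplings, dtype=float)
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        n = self.energies.shape[1]
        if self.couplings.ndim not in (2, 3) or self.couplings.shape[-2:] != (n, n):
            raise ParameterError("couplings must be (n, n) or (n_frames, n, n)")
        if self.couplings.ndim == 3 and self.couplings.shape[0] != self.n_frames:
            raise ParameterError("per-frame couplings must match n_frames")
        if not np.all(np.isfinite(self.energies)) or not np.all(
            np.isfinite(self.couplings)
        ):
            raise ParameterError("trajectory contains non-finite entries")
        check = self.couplings if self.couplings.ndim == 2 else self.couplings[0]
        if not np.allclose(check, check.T, atol=1e-9):
            raise ParameterError("coupling matrix must be symmetric")

    @property
    def n_sites(self) -> int:
        return self.energies.shape[1]

    @property
    def n_frames(self) -> int:
        return self.energies.shape[0]

    @property
    def has_fluctuating_couplings(self) -> bool:
        return self.couplings.ndim == 3

    def static_couplings(self) -> np.ndarray:
        """Static coupling matrix; time mean when couplings fluctuate."""
        if self.couplings.ndim == 2:
            return self.couplings
        return self.couplings.mean(axis=0)

    def frame_hamiltonian(self, k: int, sites: np.ndarray | None = None) -> np.ndarray:
        """Dense symmetric Hamiltonian of frame ``k`` restricted to ``sites``."""
        J = self.couplings[k] if self.couplings.ndim == 3 else self.couplings
        if sites is None:
            H = J.copy()
            H[np.diag_indices_from(H)] = self.energies[k]
            return H
        sites = np.asarray(sites, dtype=int)
        H = J[np.ix_(sites, sites)].copy()
        H[np.diag_indices_from(H)] = self.energies[k, sites]
        return H


# ---------------------------------------------------------------------------
# Geometry builders
# ---------------------------------------------------------------------------

def build_parallel_chains(
    n_per_chain: int,
    spacing: float,
    chain_separation: float,
    slip: float = 0.0,
    dipole_magnitude: float = 11.4,
    mean_energy: float = 0.0,
    screening: float = 1.0,
) -> SiteSystem:
    """Two parallel linear aggregates along x, separated along y.

    Chain 2 is displaced by ``chain_separation`` perpendicular to the chain
    axis and by ``slip * spacing`` along it.  All transition dipoles point
    along the chain axis (head-to-tail J-aggregate arrangement).

    Units: nm for spacing/separation, Debye for the dipole magnitude,
    ``slip`` is a fraction of the lattice spacing in [0, 1).
    """
    if n_per_chain < 1:
        raise GeometryError("n_per_chain must be >= 1")
    if spacing <= 0 or chain_separation <= 0:
        raise GeometryError("spacing and chain_separation must be > 0")
    if not (0.0 <= slip < 1.0):
        raise GeometryError(f"slip must be in [0, 1), got {slip}")
    x = np.arange(n_per_chain) * spacing
    pos1 = np.column_stack([x, np.zeros(n_per_chain), np.zeros(n_per_chain)])
    pos2 = np.column_stack(
        [x + slip * spacing, np.full(n_per_chain, chain_separation), np.zeros(n_per_chain)]
    )
    dip = np.tile([dipole_magnitude, 0.0, 0.0], (2 * n_per_chain, 1))
    return SiteSystem(
        positions=np.vstack([pos1, pos2]),
        dipoles=dip,
        mean_energies=np.full(2 * n_per_chain, mean_energy),
        screening=screening,
    )


def build_ring(
    n_sites: int,
    radius: float,
    dipole_magnitude: float,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    mean_energy: float = 0.0,
    screening: float = 1.0,
    phase: float = 0.0,
) -> SiteSystem:
    """A ring of ``n_sites`` chromophores with tangential transition dipoles.

    Sites are equally spaced on a circle of the given ``radius`` (nm) in the
    xy plane around ``center``; dipoles are tangent to the circle.  Two rings
    at a given center-to-center distance are obtained by two calls.
    """
    if n_sites < 2:
        raise GeometryError("a ring needs at least 2 sites")
    if radius <= 0:
        raise GeometryError("radius must be > 0")
    ang = 2.0 * np.pi * np.arange(n_sites) / n_sites + phase
    center = np.asarray(center, dtype=float)
    pos = center + radius * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(n_sites)]
    )
    dip = dipole_magnitude * np.column_stack(
        [-np.sin(ang), np.cos(ang), np.zeros(n_sites)]
    )
    return SiteSystem(
        positions=pos,
        dipoles=dip,
        mean_energies=np.full(n_sites, mean_energy),
        screening=screening,
    )


def point_dipole_couplings(system: SiteSystem) -> np.ndarray:
    """Resonance couplings in the point-dipole approximation.

    J_nm = screening * C * [mu_n.mu_m - 3 (mu_n.r)(mu_m.r)] / r^3 with the
    unit vectors along the dipoles and the intersite separation, C the
    Debye^2/Angstrom^3 -> cm^-1 constant, r in Angstrom.  Returns a symmetric
    matrix (cm^-1) with zero diagonal.
    """
    n = system.n_sites
    if n < 2:
        raise GeometryError("need at least 2 sites for couplings")
    pos_a = system.positions * NM_TO_ANGSTROM
    rvec = pos_a[None, :, :] - pos_a[:, None, :]
    r = np.linalg.norm(rvec, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] == 0.0):
        i, j = np.argwhere((r == 0.0) & off)[0]
        raise GeometryError(f"coincident positions for sites {i} and {j}")
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = rvec / r[..., None]
    mu_dot = system.dipoles @ system.dipoles.T
    # both dipoles projected on the same separation unit vector r_nm
    mu_r_n = np.einsum("nd,nmd->nm", system.dipoles, rhat)
    mu_r_m = np.einsum("md,nmd->nm", system.dipoles, rhat)
    kappa_mu2 = mu_dot - 3.0 * mu_r_n * mu_r_m
    J = np.zeros((n, n))
    J[off] = (
        system.screening
        * DIPOLE_COUPLING_CM_A3_D2
        * kappa_mu2[off]
        / r[off] ** 3
    )
    J = 0.5 * (J + J.T)  # exact symmetry against rounding
    return J


def intersegment_coupling_block(
    couplings: np.ndarray, acceptor_sites: Sequence[int], donor_sites: Sequence[int]
) -> np.ndarray:
    """Static coupling block J[a, d] between acceptor and donor sites."""
    a = np.asarray(acceptor_sites, dtype=int)
    d = np.asarray(donor_sites, dtype=int)
    return np.asarray(couplings, dtype=float)[np.ix_(a, d)]


# ---------------------------------------------------------------------------
# Stochastic site energies
# ---------------------------------------------------------------------------

def generate_ou_trajectory(
    model: DisorderModel,
    n_sites: int,
    n_frames: int,
    dt: float,
    mean_energies: np.ndarray | float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Sample stationary site-energy fluctuations, (n_frames, n_sites) in cm^-1.

    Each site receives an independent realization of every disorder
    component.  The update uses the exact discrete OU solution
    ``x_{k+1} = x_k exp(-dt/tau) + sigma sqrt(1 - exp(-2 dt/tau)) xi_k``
    with ``x_0 ~ N(0, sigma)``, so the process is unbiased at any dt.

    Random streams are spawned per (site, component) from the seed, so adding
    sites or components never perturbs earlier streams.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if n_frames < 1 or n_sites < 1:
        raise ParameterError("n_frames and n_sites must be >= 1")
    if seed is None:
        seed = model.seed
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_sites)
    energies = np.zeros((n_frames, n_sites))
    for i, ss in enumerate(streams):
        comp_streams = ss.spawn(len(model.components))
        for (sigma, tau), cs in zip(model.components, comp_streams):
            if sigma == 0.0:
                continue
            rng = np.random.default_rng(cs)
            a = np.exp(-dt / tau)
            noise = rng.standard_normal(n_frames)
            x0 = sigma * noise[0]
            drive = sigma * np.sqrt(1.0 - a * a) * noise[1:]
            # exact recursion via an IIR filter: x_k = a x_{k-1} + drive_k
            x, _ = lfilter([1.0], [1.0, -a], drive, zi=np.array([a * x0]))
            energies[0, i] += x0
            energies[1:, i] += x
    return energies + np.asarray(mean_energies, dtype=float)


def build_trajectory(
    system: SiteSystem,
    model: DisorderModel,
    n_frames: int,
    dt: float,
    seed: int | None = None,
    couplings: np.ndarray | None = None,
) -> HamiltonianTrajectory:
    """Convenience: OU site energies + point-dipole couplings for a system."""
    if couplings is None:
        couplings = point_dipole_couplings(system)
    energies = generate_ou_trajectory(
        model, system.n_sites, n_frames, dt, system.mean_energies, seed=seed
    )
    return HamiltonianTrajectory(energies=energies, couplings=couplings, dt=dt)


def pure_dephasing_rate(sigma: float, tau: float) -> float:
    """Motional-narrowing pure-dephasing rate 2*pi*c*sigma^2*tau in cm^-1.

    Valid in the fast-modulation (motional narrowing) limit u*sigma*tau << 1;
    sigma in cm^-1, tau in fs.
    """
    return U_CM_FS * sigma * sigma * tau
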