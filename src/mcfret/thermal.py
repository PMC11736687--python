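"""Detailed-balance thermal correction of raw TD-MCFRET rates.

The trajectory-based rates are built on a classical bath and do not obey
detailed balance by themselves.  The correction rescales every segment pair
(i, j) so that (a) the pairwise equilibration rate k_ji + k_ij is preserved
and (b) the corrected ratio obeys the Boltzmann factor of the segment
energies, k'_ji / k'_ij = exp(-(E_j - E_i)/k_B T).  These two constraints
determine the corrected pair uniquely.  Segment energies default to the
thermal expectation of the segment Hamiltonian averaged along the
trajectory, optionally shifted by the population adjustment
dE_j = k_B T ln(N P_j / D_j) that prevents double counting of thermal
effects already present in the lineshapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import KB_CM
from .errors import ParameterError
from .kinetics import NegativeRateWarning
from .models import HamiltonianTrajectory
from .rates import ThermalSpec, equilibrium_density


@dataclass
class SegmentEnergies:
    """Per-segment expectation energies (cm^-1), site counts, and an
    optional per-segment adjustment dE (cm^-1)."""

    energies: np.ndarray
    site_counts: np.ndarray
    delta_e: np.ndarray | None = None

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float).ravel()
        self.site_counts = np.asarray(self.site_counts, dtype=int).ravel()
        if self.energies.shape != self.site_counts.shape:
            raise ParameterError("energies and site_counts must have equal length")
        if not np.all(np.isfinite(self.energies)):
            raise ParameterError("segment energies must be finite")
        if self.delta_e is not None:
            self.delta_e = np.asarray(self.delta_e, dtype=float).ravel()
            if self.delta_e.shape != self.energies.shape:
                raise ParameterError("delta_e length must match energies")

    @property
    def total_sites(self) -> int:
        return int(self.site_counts.sum())

    def effective(self) -> np.ndarray:
        """Energies plus adjustment (if set)."""
        if self.delta_e is None:
            return self.energies
        return self.energies + self.delta_e


def segment_energy(
    trajectory: HamiltonianTrajectory,
    segment: np.ndarray,
    thermal: ThermalSpec,
    stride: int = 1,
    mode: str = "thermal",
) -> float:
    """Expectation energy of a segment, time-averaged along the trajectory.

    mode "thermal" (default) evaluates Tr[H(t) rho_eq(H(t))] per sampled
    frame; mode "flat" averages the instantaneous eigenvalues uniformly
    (this is also what "thermal" reduces to in the high-temperature limit).
    ``stride`` subsamples frames for long trajectories.
    """
    segment = np.asarray(segment, dtype=int)
    if segment.size == 0:
        raise ParameterError("empty segment")
    if mode not in ("thermal", "flat"):
        raise ParameterError(f"unknown mode {mode!r}")
    total = 0.0
    count = 0
    for k in range(0, trajectory.n_frames, stride):
        H = trajectory.frame_hamiltonian(k, segment)
        if mode == "flat" or thermal.mode == "ht":
            total += float(np.trace(H)) / H.shape[0]
        else:
            rho = equilibrium_density(H, thermal)
            total += float(np.trace(H @ rho))
        count += 1
    return total / count


def delta_e_adjustment(
    P_raw: np.ndarray, D: np.ndarray, thermal: ThermalSpec
) -> np.ndarray:
    """Population adjustment dE_j = k_B T ln(N P_j / D_j) per segment (cm^-1).

    ``P_raw`` are the equilibrium populations predicted by the uncorrected
    rate matrix and ``D`` the per-segment site counts; by construction the
    adjustment vanishes when P_j = D_j / N (the high-temperature result).
    """
    P = np.asarray(P_raw, dtype=float).ravel()
    D = np.asarray(D, dtype=int).ravel()
    if P.shape != D.shape:
        raise ParameterError("P_raw and D must have equal length")
    if np.any(P < 0) or abs(P.sum() - 1.0) > 1e-8:
        raise ParameterError("P_raw must be a probability vector summing to 1")
    if np.any(D <= 0):
        raise ParameterError("site counts must be positive")
    if np.any(P == 0):
        raise ParameterError(
            "zero equilibrium population encountered; the log-adjustment "
            "diverges — increase sampling or disable the dE adjustment"
        )
    if thermal.mode == "ht":
        return np.zeros_like(P)
    N = D.sum()
    return KB_CM * thermal.temperature * np.log(N * P / D)


def thermal_correction(
    K: np.ndarray, energies: SegmentEnergies, thermal: ThermalSpec
) -> np.ndarray:
    """Detailed-balance correction of a segment rate matrix (K[to, from]).

    Each off-diagonal pair is rescaled so the pair sum is preserved and the
    ratio equals the Boltzmann factor of the effective segment energies;
    the diagonal is rebuilt as minus the column sums.  In the
    high-temperature limit (or for equal energies) the matrix is unchanged.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ParameterError("rate matrix must be square")
    if energies.energies.shape[0] != n:
        raise ParameterError("segment energies length must match rate matrix")
    off = K[~np.eye(n, dtype=bool)]
    if np.any(off < 0):
        warnings.warn(
            "negative off-diagonal rate(s) in the matrix being corrected "
            f"(most negative {off.min():.3g} ps^-1); usually sampling noise — "
            "increase the number of windows",
            NegativeRateWarning,
            stacklevel=2,
        )
    E = energies.effective()
    beta = thermal.beta
    Kc = np.zeros_like(K)
    for i in range(n):
        for j in range(i + 1, n):
            s = K[j, i] + K[i, j]  # pairwise equilibration rate, preserved
            if s == 0.0:
                continue
            b = np.exp(-beta * (E[j] - E[i]))  # k'_ji / k'_ij
            Kc[j, i] = s * b / (1.0 + b)
            Kc[i, j] = s / (1.0 + b)
    Kc[np.diag_indices(n)] = -Kc.sum(axis=0)
    return Kc
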