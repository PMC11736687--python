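"""Time-evolution operators for segment wave functions.

Each trajectory frame defines a constant Hamiltonian over its time step
(left-edge convention); the step propagator is the exact matrix exponential
``exp(-i u H dt)`` evaluated by eigendecomposition, and longer evolutions
are products of consecutive step propagators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import U_CM_FS
from .errors import ParameterError, SamplingError
from .models import HamiltonianTrajectory


@dataclass
class Propagator:
    """Unitary time-evolution matrix between two trajectory times (fs)."""

    matrix: np.ndarray
    t_start: float
    t_end: float


def _step_u(H: np.ndarray, dt: float) -> np.ndarray:
    """exp(-i * u * H * dt) for a real symmetric H (cm^-1), dt in fs."""
    w, V = np.linalg.eigh(H)
    phase = np.exp(-1j * U_CM_FS * w * dt)
    return (V * phase) @ V.T


def step_propagator(H_frame: np.ndarray, dt: float, t_start: float = 0.0) -> Propagator:
    """Single-step propagator for one Hamiltonian frame.

    Raises on a non-symmetric Hamiltonian or non-positive step.
    """
    H = np.atleast_2d(np.asarray(H_frame, dtype=float))
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if not np.all(np.isfinite(H)):
        raise ParameterError("Hamiltonian contains non-finite entries")
    if not np.allclose(H, H.T, atol=1e-9):
        raise ParameterError("Hamiltonian frame must be symmetric")
    return Propagator(matrix=_step_u(H, dt), t_start=t_start, t_end=t_start + dt)


def window_propagators(
    trajectory: HamiltonianTrajectory,
    sites: np.ndarray | None,
    start_frame: int,
    n_steps: int,
) -> np.ndarray:
    """Cumulative propagators over a sampling window.

    Returns a complex array ``U`` of shape (n_steps + 1, n, n) where
    ``U[k]`` evolves the segment state from the window start over ``k``
    steps; ``U[0]`` is the identity.  The segment Hamiltonian of each frame
    is used at the step's left edge.
    """
    if n_steps < 0:
        raise ParameterError("n_steps must be >= 0")
    if start_frame < 0 or start_frame + n_steps > trajectory.n_frames:
        raise SamplingError(
            f"window [{start_frame}, {start_frame + n_steps}] overruns trajectory "
            f"of {trajectory.n_frames} frames"
        )
    sites = None if sites is None else np.asarray(sites, dtype=int)
    n = trajectory.n_sites if sites is None else len(sites)

    if n == 1:
        # single-site segment: pure phase from the prefix sum of the energy
        idx = 0 if sites is None else sites[0]
        eps = trajectory.energies[start_frame : start_frame + n_steps, idx]
        phases = np.concatenate([[0.0], np.cumsum(eps)]) * (
            -1j * U_CM_FS * trajectory.dt
        )
        return np.exp(phases)[:, None, None]

    out = np.empty((n_steps + 1, n, n), dtype=complex)
    out[0] = np.eye(n)
    acc = np.eye(n, dtype=complex)
    for k in range(n_steps):
        H = trajectory.frame_hamiltonian(start_frame + k, sites)
        acc = _step_u(H, trajectory.dt) @ acc
        out[k + 1] = acc
    return out


def propagate_window(
    trajectory: HamiltonianTrajectory,
    sites: np.ndarray | None,
    start_frame: int,
    n_steps: int,
) -> list[Propagator]:
    """As :func:`window_propagators`, wrapped with window times attached."""
    mats = window_propagators(trajectory, sites, start_frame, n_steps)
    t0 = start_frame * trajectory.dt
    return [
        Propagator(matrix=m, t_start=t0, t_end=t0 + k * trajectory.dt)
        for k, m in enumerate(mats)
    ]
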