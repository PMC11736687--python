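"""File formats: energy trajectories, couplings, geometries, segmentations.

Binary trajectory container (``.traj``): magic ``b"MCFT"``, n_sites:int64,
n_frames:int64, dt:float64, then the frame-major float64 little-endian
payload.  Text trajectory (``.txt``): a ``# n_sites n_frames dt`` header and
one whitespace-separated frame per line.  Both are lossless within their
printed precision and diff-able in the text case.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import TrajectoryFormatError
from .models import HamiltonianTrajectory, SiteSystem

_MAGIC = b"MCFT"


def write_trajectory(path, trajectory: HamiltonianTrajectory) -> None:
    """Write site energies to a ``.traj`` binary or ``.txt`` text file.

    Couplings are stored separately (see :func:`write_couplings`).
    """
    path = Path(path)
    e = np.ascontiguousarray(trajectory.energies, dtype="<f8")
    n_frames, n_sites = e.shape
    if path.suffix == ".traj":
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<qqd", n_sites, n_frames, trajectory.dt))
            fh.write(e.tobytes())
    else:
        header = f"# {n_sites} {n_frames} {trajectory.dt!r}"
        np.savetxt(path, e, fmt="%.10g", header=header, comments="")


def read_trajectory(path, couplings: np.ndarray) -> HamiltonianTrajectory:
    """Read a trajectory file written by :func:`write_trajectory`."""
    path = Path(path)
    if path.suffix == ".traj":
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != _MAGIC:
                raise TrajectoryFormatError(f"{path}: bad magic bytes {magic!r}")
            n_sites, n_frames, dt = struct.unpack("<qqd", fh.read(24))
            payload = np.frombuffer(fh.read(), dtype="<f8")
    else:
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 4 or header[0] != "#":
                raise TrajectoryFormatError(f"{path}: missing '# n_sites n_frames dt' header")
            n_sites, n_frames, dt = int(header[1]), int(header[2]), float(header[3])
            payload = np.loadtxt(fh).ravel()
    if dt <= 0:
        raise TrajectoryFormatError(f"{path}: non-positive dt {dt} in header")
    expected = n_sites * n_frames
    if payload.size != expected:
        frame = payload.size // max(n_sites, 1)
        raise TrajectoryFormatError(
            f"{path}: expected {expected} values ({n_frames} frames x {n_sites} "
            f"sites), found {payload.size} (short at frame {frame})"
        )
    energies = payload.reshape(n_frames, n_sites)
    if np.any(~np.isfinite(energies)):
        frame = int(np.argwhere(~np.isfinite(energies))[0][0])
        raise TrajectoryFormatError(f"{path}: non-finite value at frame {frame}")
    return HamiltonianTrajectory(energies=energies, couplings=couplings, dt=dt)


def write_couplings(path, couplings: np.ndarray) -> None:
    """Write a static n x n coupling matrix, or per-frame stacked matrices
    flagged by a ``# frames <count>`` header line, in cm^-1."""
    J = np.asarray(couplings, dtype=float)
    if J.ndim == 2:
        np.savetxt(path, J, fmt="%.10g", header=f"static {J.shape[0]}", comments="# ")
    else:
        nf, n, _ = J.shape
        np.savetxt(
            path, J.reshape(nf * n, n), fmt="%.10g", header=f"frames {nf} {n}", comments="# "
        )


def read_couplings(path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        body = np.loadtxt(fh)
    if len(header) >= 2 and header[1] == "static":
        n = int(header[2])
        if body.shape != (n, n):
            raise TrajectoryFormatError(f"{path}: expected {n}x{n} matrix, got {body.shape}")
        return body
    if len(header) >= 2 and header[1] == "frames":
        nf, n = int(header[2]), int(header[3])
        if body.shape != (nf * n, n):
            raise TrajectoryFormatError(
                f"{path}: expected {nf} stacked {n}x{n} matrices, got {body.shape}"
            )
        return body.reshape(nf, n, n)
    raise TrajectoryFormatError(f"{path}: unrecognized coupling header {header}")


def write_geometry(path, system: SiteSystem) -> None:
    """One site per line: x y z mux muy muz mean_energy (nm, D, cm^-1)."""
    data = np.column_stack(
        [system.positions, system.dipoles, system.mean_energies]
    )
    np.savetxt(
        path, data, fmt="%.10g",
        header=f"screening {system.screening!r}", comments="# ",
    )


def read_geometry(path) -> SiteSystem:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        data = np.atleast_2d(np.loadtxt(fh))
    screening = float(header[2]) if len(header) >= 3 and header[1] == "screening" else 1.0
    if data.shape[1] != 7:
        raise TrajectoryFormatError(
            f"{path}: expected 7 columns (x y z mux muy muz energy), got {data.shape[1]}"
        )
    return SiteSystem(
        positions=data[:, :3],
        dipoles=data[:, 3:6],
        mean_energies=data[:, 6],
        screening=screening,
    )


def write_segmentation(path, assignment: dict[int, int]) -> None:
    """Text map ``site_id segment_id`` with 1-based site ids."""
    with open(path, "w") as fh:
        fh.write("# site_id segment_id\n")
        for site in sorted(assignment):
            fh.write(f"{site + 1} {assignment[site]}\n")


def read_segmentation(path) -> dict[int, int]:
    data = np.atleast_2d(np.loadtxt(path, dtype=int))
    return {int(s) - 1: int(g) for s, g in data}


def segments_from_assignment(assignment: dict[int, int]) -> list[np.ndarray]:
    """Ordered list of site-index arrays, one per segment id (ascending)."""
    ids = sorted(set(assignment.values()))
    return [
        np.array(sorted(s for s, g in assignment.items() if g == gid), dtype=int)
        for gid in ids
    ]
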