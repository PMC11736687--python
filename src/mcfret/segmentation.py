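"""Automatic segmentation from the absolute value density matrix (ADM).

Diagonalizing the full-system Hamiltonian along the trajectory gives
exciton eigenvectors c_a; the ADM element Sum_a |c_na||c_ma|, averaged over
frames, measures how strongly sites n and m share eigenstates.  Taking the
absolute values kills the interference that averages ordinary coherences to
zero.  Sites are clustered by single linkage on the distance
d_nm = -ln(ADM_nm) and segments are the connected components of the graph
with edges d_nm < eps_p — equivalent to cutting the single-linkage
dendrogram at eps_p, since the pairwise criterion is transitively closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .constants import KB_CM
from .errors import ParameterError
from .models import HamiltonianTrajectory


class SamplingDepthWarning(UserWarning):
    """Too few frames averaged for a stable ADM."""


@dataclass
class ADMatrix:
    """Frame-averaged absolute value density matrix, diagonal-normalized.

    ``site_energies`` carries the per-site mean exciton energy
    Sum_a |c_na|^2 E_a averaged over the same frames; it is used to order
    segments by ascending energy.
    """

    values: np.ndarray
    n_frames_averaged: int
    site_energies: np.ndarray | None = None


@dataclass
class Segmentation:
    """Partition of sites into segments, ordered by mean exciton energy."""

    assignment: dict[int, int]  # site index -> 1-based segment id
    cutoff: float
    linkage: np.ndarray | None = None
    segment_energies: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(set(self.assignment.values()))

    def segments(self) -> list[np.ndarray]:
        ids = sorted(set(self.assignment.values()))
        return [
            np.array(
                sorted(s for s, g in self.assignment.items() if g == gid), dtype=int
            )
            for gid in ids
        ]


def _frame_indices(n_frames: int, stride: int) -> np.ndarray:
    return np.arange(0, n_frames, stride)


def adm_matrix(
    trajectory: HamiltonianTrajectory,
    stride: int = 1,
    boltzmann_temperature: float | None = None,
) -> ADMatrix:
    """Compute the ADM over the full system.

    By default every eigenstate enters with unit weight, which makes the
    raw diagonal exactly one (eigenvector completeness); a
    Boltzmann-weighted variant is available via ``boltzmann_temperature``
    (K), in which case the matrix is renormalized to its diagonal.
    """
    frames = _frame_indices(trajectory.n_frames, stride)
    if len(frames) < 10:
        warnings.warn(
            f"ADM averaged over only {len(frames)} frames; consider more sampling",
            SamplingDepthWarning,
            stacklevel=2,
        )
    n = trajectory.n_sites
    acc = np.zeros((n, n))
    e_acc = np.zeros(n)
    for k in frames:
        w, V = np.linalg.eigh(trajectory.frame_hamiltonian(int(k)))
        A = np.abs(V)
        if boltzmann_temperature is not None:
            p = np.exp(-(w - w.min()) / (KB_CM * boltzmann_temperature))
            acc += (A * p) @ A.T
        else:
            acc += A @ A.T
        e_acc += (V * V) @ w
    acc /= len(frames)
    e_acc /= len(frames)
    d = np.sqrt(np.diag(acc))
    norm = acc / np.outer(d, d)
    return ADMatrix(values=norm, n_frames_averaged=len(frames), site_energies=e_acc)


def pr_matrix(trajectory: HamiltonianTrajectory, stride: int = 1) -> np.ndarray:
    """Frame-averaged participation-ratio matrix
    PR_nm = Sum_a |c_na|^2 |c_ma|^2, an alternative clustering input."""
    frames = _frame_indices(trajectory.n_frames, stride)
    n = trajectory.n_sites
    acc = np.zeros((n, n))
    for k in frames:
        _, V = np.linalg.eigh(trajectory.frame_hamiltonian(int(k)))
        P = V * V
        acc += P @ P.T
    return acc / len(frames)


def cluster_segments(adm: ADMatrix, epsilon_p: float) -> Segmentation:
    """Cut the ADM into segments at coherence distance eps_p.

    Pairwise distance d_nm = -ln(ADM_nm); sites with d_nm strictly below
    ``epsilon_p`` join the same segment (transitive closure = connected
    components = single-linkage dendrogram cut).  Segments are numbered from
    1 by ascending mean exciton energy.
    """
    if epsilon_p <= 0:
        raise ParameterError("epsilon_p must be > 0")
    A = np.asarray(adm.values, dtype=float)
    n = A.shape[0]
    with np.errstate(divide="ignore"):
        dist = -np.log(np.clip(A, 0.0, None))
    np.fill_diagonal(dist, 0.0)

    adjacency = (dist < epsilon_p) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(
        csr_matrix(adjacency), directed=False
    )

    # order segments by ascending mean exciton energy of their sites
    if adm.site_energies is not None:
        seg_e = np.array(
            [adm.site_energies[labels == c].mean() for c in range(n_comp)]
        )
    else:
        seg_e = np.array(
            [float(np.min(np.where(labels == c)[0])) for c in range(n_comp)]
        )
    order = np.argsort(seg_e, kind="stable")
    rank = {int(c): i + 1 for i, c in enumerate(order)}
    assignment = {i: rank[int(labels[i])] for i in range(n)}

    Z = None
    if n > 1:
        finite = np.isfinite(dist)
        big = 2.0 * (dist[finite].max() + epsilon_p + 1.0)
        dist_f = np.where(np.isfinite(dist), dist, big)
        dist_f = 0.5 * (dist_f + dist_f.T)
        Z = linkage(squareform(dist_f, checks=False), method="single")
    return Segmentation(
        assignment=assignment,
        cutoff=epsilon_p,
        linkage=Z,
        segment_energies=seg_e[order] if adm.site_energies is not None else None,
    )
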