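"""Segment rate-matrix kinetics: population propagation, eigen-analysis,
and the incoherence (Gamma vs k) diagnostic.

The rate matrix is oriented K[to, from]; the diagonal holds minus the sum
of the rates leaving each segment, so every column sums to zero and total
population is conserved under dP/dt = K P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import ParameterError


class ComplexEigenvalueWarning(UserWarning):
    """Rate matrix has complex eigenvalues (unphysical circular current)."""


class NegativeRateWarning(UserWarning):
    """Negative off-diagonal transfer rate encountered."""


@dataclass
class RateMatrix:
    """Segment-to-segment rate matrix in ps^-1, K[to, from]."""

    K: np.ndarray
    negative_rate_flag: bool = False

    @property
    def n_segments(self) -> int:
        return self.K.shape[0]


def build_rate_matrix(pairwise_rates: dict[tuple[int, int], float] | np.ndarray) -> RateMatrix:
    """Assemble K from pairwise rates.

    ``pairwise_rates`` is either a map (donor, acceptor) -> rate (0-based
    segment indices; missing pairs are zero) or a full matrix whose
    [to, from] off-diagonal entries are the transfer rates (its diagonal is
    ignored and rebuilt).
    """
    if isinstance(pairwise_rates, dict):
        n = 1 + max(max(i, j) for i, j in pairwise_rates)
        K = np.zeros((n, n))
        for (donor, acceptor), k in pairwise_rates.items():
            if donor == acceptor:
                continue
            K[acceptor, donor] = k
    else:
        K = np.array(pairwise_rates, dtype=float)
        np.fill_diagonal(K, 0.0)
    if np.any(~np.isfinite(K)):
        raise ParameterError("rate matrix contains non-finite entries")
    neg = bool(np.any(K < 0))
    if neg:
        warnings.warn(
            "negative off-diagonal transfer rate(s) present; increase sampling",
            NegativeRateWarning,
            stacklevel=2,
        )
    np.fill_diagonal(K, 0.0)
    K[np.diag_indices_from(K)] = -K.sum(axis=0)
    return RateMatrix(K=K, negative_rate_flag=neg)


def propagate_populations(
    rate_matrix: RateMatrix | np.ndarray, P0: np.ndarray, times_fs: np.ndarray
) -> np.ndarray:
    """Populations P(t) = exp(K t) P0 at the requested times (fs), K in ps^-1.

    Uses the eigendecomposition of K, falling back to scaling-and-squaring
    when the eigenbasis is (near-)defective.  Returns (n_times, n_segments).
    """
    K = rate_matrix.K if isinstance(rate_matrix, RateMatrix) else np.asarray(rate_matrix)
    P0 = np.asarray(P0, dtype=float).ravel()
    if np.any(P0 < -1e-12) or abs(P0.sum() - 1.0) > 1e-8:
        raise ParameterError("P0 must be a probability vector summing to 1")
    t_ps = np.asarray(times_fs, dtype=float).ravel() * 1e-3
    lam, V = np.linalg.eig(K)
    if np.linalg.cond(V) < 1e12:
        c = np.linalg.solve(V, P0.astype(complex))
        out = np.real((V[None, :, :] * np.exp(np.outer(t_ps, lam))[:, None, :]) @ c)
    else:
        # defective eigenbasis: fall back to scaling-and-squaring per time
        out = np.stack([expm(K * t) @ P0 for t in t_ps])
    return out


@dataclass
class KineticsReport:
    """Eigen-analysis of a segment rate matrix."""

    eigenvalues: np.ndarray  # sorted by |value| ascending, ps^-1
    eigenvectors: np.ndarray  # columns matching eigenvalues, max-norm 1
    equilibrium: np.ndarray  # zero-eigenvalue vector normalized to sum 1
    relaxation_rates: np.ndarray  # -Re(nonzero eigenvalues), ps^-1
    complex_flag: bool = False


def eigen_analysis(
    rate_matrix: RateMatrix | np.ndarray, imag_tolerance: float = 1e-8
) -> KineticsReport:
    """Diagonalize K: the near-zero eigenvalue's eigenvector holds the
    equilibrium populations; the remaining eigenpairs are the relaxation
    processes with rates -lambda.

    Imaginary eigenvalue parts below ``imag_tolerance * max|Re lambda|`` are
    treated as numerical noise; larger ones raise a
    :class:`ComplexEigenvalueWarning` (circular current; average over more
    samples) and the report carries a caution flag.
    """
    K = rate_matrix.K if isinstance(rate_matrix, RateMatrix) else np.asarray(rate_matrix)
    lam, V = np.linalg.eig(K)
    scale = max(np.abs(lam.real).max(), 1e-300)
    complex_flag = bool(np.abs(lam.imag).max() > imag_tolerance * scale)
    if complex_flag:
        warnings.warn(
            "rate matrix has complex eigenvalues (unphysical circular "
            "current); averaging over more samples typically solves this — "
            "use the results with caution",
            ComplexEigenvalueWarning,
            stacklevel=2,
        )
    order = np.argsort(np.abs(lam))
    lam = lam[order]
    V = V[:, order]
    V = V / np.abs(V).max(axis=0)
    eq = np.real(V[:, 0])
    if eq.sum() == 0:
        raise ParameterError("degenerate equilibrium eigenvector")
    eq = eq / eq.sum()
    return KineticsReport(
        eigenvalues=lam if complex_flag else lam.real,
        eigenvectors=V if complex_flag else np.real(V),
        equilibrium=eq,
        relaxation_rates=-np.real(lam[1:]),
        complex_flag=complex_flag,
    )


@dataclass
class CoherencePair:
    donor: int
    acceptor: int
    rate: float
    gamma: float
    ratio: float  # gamma / rate
    label: str  # incoherent-ok | borderline | coherent-flagged


def incoherence_check(
    rate_matrix: RateMatrix | np.ndarray,
    gammas: np.ndarray,
    borderline_factor: float = 3.0,
) -> list[CoherencePair]:
    """Classify every ordered segment pair by the decoherence-to-transfer
    ratio Gamma/k.

    Transfer is safely incoherent when the rate response loses coherence
    much faster than the transfer proceeds.  Defaults: coherent-flagged
    when k >= Gamma, borderline when Gamma/k is below ``borderline_factor``.
    """
    K = rate_matrix.K if isinstance(rate_matrix, RateMatrix) else np.asarray(rate_matrix)
    G = np.asarray(gammas, dtype=float)
    if G.shape != K.shape:
        raise ParameterError("gamma matrix shape must match rate matrix")
    out: list[CoherencePair] = []
    n = K.shape[0]
    for donor in range(n):
        for acceptor in range(n):
            if donor == acceptor:
                continue
            k = K[acceptor, donor]
            g = G[acceptor, donor]
            if k <= 0:
                ratio, label = np.inf, "incoherent-ok"
            else:
                ratio = g / k
                if ratio <= 1.0:
                    label = "coherent-flagged"
                elif ratio < borderline_factor:
                    label = "borderline"
                else:
                    label = "incoherent-ok"
            out.append(CoherencePair(donor, acceptor, k, g, ratio, label))
    return out
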