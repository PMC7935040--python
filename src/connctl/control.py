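"""Linear network control metrics for discrete-time systems x(t+1) = A x(t) + B u(t).

Average controllability of node k is the trace of the controllability Gramian
W_k = sum_{i>=0} A^i e_k e_kᵀ (Aᵀ)^i, obtained here by solving the stationary
discrete Lyapunov equation W = A W Aᵀ + e_k e_kᵀ. Modal controllability of
node k is phi_k = sum_j (1 - xi_j²) v_kj² over the orthonormal eigenmodes
(xi_j, v_j) of the (symmetric) system matrix. Both require spectral radius
below one, which ``normalize_adjacency`` guarantees by dividing the raw
adjacency by one plus its largest singular value (or spectral radius).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import scipy.linalg

from .connectome import ConnectivityMatrix, node_strength

__all__ = [
    "NormalizedSystem",
    "ControlProfile",
    "KalmanRank",
    "normalize_adjacency",
    "controllability_gramian",
    "average_controllability",
    "modal_controllability",
    "kalman_rank",
    "control_profile",
    "profiles_to_frame",
]

SCHEMES = ("singular_value", "spectral_radius", "none")


@dataclass(frozen=True)
class NormalizedSystem:
    """Stabilized system matrix A_norm = A / normalization_factor."""

    A_norm: np.ndarray
    normalization_factor: float
    scheme: str

    @property
    def n(self) -> int:
        return self.A_norm.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A_norm))))


@dataclass(frozen=True)
class ControlProfile:
    """Per-node controllability summary for one subject."""

    subject_id: str
    region_names: tuple[str, ...]
    ac: np.ndarray
    mc: np.ndarray
    strength: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "region_name": list(self.region_names),
                "ac": self.ac,
                "mc": self.mc,
                "strength": self.strength,
            }
        )


class KalmanRank(NamedTuple):
    rank: int
    full_rank: bool


def normalize_adjacency(
    C: ConnectivityMatrix | np.ndarray, scheme: str = "singular_value"
) -> NormalizedSystem:
    """Scale an adjacency matrix so the infinite Gramian sum converges.

    ``singular_value`` divides by (1 + largest singular value);
    ``spectral_radius`` by (1 + spectral radius); ``none`` passes the matrix
    through with factor 1 (downstream operations must then check stability).
    """
    A = C.weights if isinstance(C, ConnectivityMatrix) else np.asarray(C, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("adjacency contains non-finite entries")
    if scheme == "singular_value":
        factor = 1.0 + float(np.linalg.norm(A, 2))
    elif scheme == "spectral_radius":
        factor = 1.0 + float(np.max(np.abs(np.linalg.eigvals(A))))
    elif scheme == "none":
        factor = 1.0
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return NormalizedSystem(A_norm=A / factor, normalization_factor=factor, scheme=scheme)


def _check_stable(S: NormalizedSystem) -> None:
    rho = S.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"spectral radius {rho:.6g} >= 1: controllability Gramian diverges"
        )


def controllability_gramian(S: NormalizedSystem, control_node: int) -> np.ndarray:
    """Infinite-horizon Gramian for a single control node, via Lyapunov solve."""
    n = S.n
    if not 0 <= control_node < n:
        raise IndexError(f"control node {control_node} outside 0..{n - 1}")
    _check_stable(S)
    q = np.zeros((n, n))
    q[control_node, control_node] = 1.0
    W = scipy.linalg.solve_discrete_lyapunov(S.A_norm, q)
    return (W + W.T) / 2.0


def average_controllability(S: NormalizedSystem) -> np.ndarray:
    """Trace of the single-node controllability Gramian, for every node.

    For symmetric A the stationary equation W = A W Aᵀ + e_k e_kᵀ has the
    exact spectral solution Tr(W_k) = sum_j v_kj² / (1 - xi_j²), evaluated
    from one eigendecomposition; otherwise each node's Gramian is solved
    individually. Both routes are the exact stationary solution, not a
    truncation.
    """
    _check_stable(S)
    A = S.A_norm
    n = S.n
    if np.allclose(A, A.T, rtol=0, atol=1e-12 * max(1.0, np.abs(A).max())):
        xi, V = np.linalg.eigh(A)
        return (V**2) @ (1.0 / (1.0 - xi**2))
    ac = np.empty(n)
    for k in range(n):
        q = np.zeros((n, n))
        q[k, k] = 1.0
        W = scipy.linalg.solve_discrete_lyapunov(A, q)
        ac[k] = np.trace(W)
    return ac


def modal_controllability(S: NormalizedSystem) -> np.ndarray:
    """phi_k = sum_j (1 - xi_j²) v_kj² over orthonormal eigenmodes.

    Requires a symmetric system matrix (real spectrum, orthonormal
    eigenvectors); complex modes are unsupported.
    """
    A = S.A_norm
    if not np.allclose(A, A.T, rtol=0, atol=1e-10 * max(1.0, np.abs(A).max())):
        raise ValueError("modal controllability requires a symmetric matrix")
    xi, V = np.linalg.eigh(A)
    return (V**2) @ (1.0 - xi**2)


def kalman_rank(S: NormalizedSystem, control_nodes: Iterable[int]) -> KalmanRank:
    """Numerical rank of the controllability matrix [B, AB, ..., A^{n-1}B].

    B holds one indicator column per control node. Rank uses an SVD with
    tolerance max(n, n·|B|) · eps · sigma_max.
    """
    nodes = sorted(set(int(k) for k in control_nodes))
    if not nodes:
        raise ValueError("control node set must be non-empty")
    n = S.n
    if nodes[0] < 0 or nodes[-1] >= n:
        raise IndexError(f"control nodes {nodes} outside 0..{n - 1}")
    B = np.zeros((n, len(nodes)))
    for col, k in enumerate(nodes):
        B[k, col] = 1.0
    blocks = [B]
    for _ in range(n - 1):
        blocks.append(S.A_norm @ blocks[-1])
    ctrb = np.hstack(blocks)
    s = np.linalg.svd(ctrb, compute_uv=False)
    tol = max(ctrb.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    return KalmanRank(rank=rank, full_rank=rank == n)


def control_profile(
    C: ConnectivityMatrix, scheme: str = "singular_value"
) -> ControlProfile:
    """AC, MC and strength for every region of one subject's connectome."""
    S = normalize_adjacency(C, scheme=scheme)
    return ControlProfile(
        subject_id=C.subject_id,
        region_names=tuple(C.atlas.names),
        ac=average_controllability(S),
        mc=modal_controllability(S),
        strength=node_strength(C),
    )


def profiles_to_frame(profiles: Iterable[ControlProfile]) -> pd.DataFrame:
    """Tidy table (subject_id, region_name, ac, mc, strength)."""
    frames = [p.to_frame() for p in profiles]
    if not frames:
        raise ValueError("no control profiles given")
    return pd.concat(frames, ignore_index=True)
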