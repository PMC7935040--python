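"""Weighted structural connectivity matrices: I/O, validation, thresholding.

A connectome here is an undirected, non-negative, zero-diagonal weighted
adjacency matrix of streamline counts (or derived weights) between atlas
regions. Proportional thresholding retains a fixed fraction of the strongest
upper-triangle edges; node strength is the weighted row sum (the quantity
usually reported as "nodal degree" for weighted connectomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

__all__ = [
    "ConnectivityMatrix",
    "read_connectome",
    "write_connectome",
    "threshold_proportional",
    "node_strength",
]

logger = logging.getLogger(__name__)

#: relative asymmetry tolerated (and silently symmetrized) on ingestion
ASYMMETRY_RTOL = 1e-9


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Validated undirected weighted adjacency bound to a region atlas."""

    weights: np.ndarray
    atlas: RegionAtlas
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] != self.atlas.n_regions:
            raise ValueError(
                f"matrix size {w.shape[0]} does not match atlas size "
                f"{self.atlas.n_regions}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain NaN or infinite entries")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        scale = w.max() if w.size and w.max() > 0 else 1.0
        if np.abs(w - w.T).max() > ASYMMETRY_RTOL * scale:
            raise ValueError("weights must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            weights=weights, atlas=self.atlas, subject_id=self.subject_id
        )


def _parse_matrix_frame(path: str | Path) -> np.ndarray:
    """Load a delimited numeric matrix, tolerating header row/column."""
    raw = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    # header row: any non-numeric cell in the first row
    def _numeric(cell: object) -> bool:
        try:
            float(cell)  # type: ignore[arg-type]
            return True
        except (TypeError, ValueError):
            return False

    start_row = 0 if all(_numeric(c) for c in raw.iloc[0]) else 1
    body = raw.iloc[start_row:]
    start_col = 0 if all(_numeric(c) for c in body.iloc[:, 0]) else 1
    body = body.iloc[:, start_col:]
    try:
        return body.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric matrix entries in {path}: {exc}") from exc


def read_connectome(
    path: str | Path, atlas: RegionAtlas, subject_id: str | None = None
) -> ConnectivityMatrix:
    """Read and validate a delimited connectivity matrix.

    Accepts comma- or tab-delimited files with an optional header row and/or
    first column of region names. Near-symmetric input (relative asymmetry
    below 1e-9) is symmetrized as (W + Wᵀ)/2; a nonzero diagonal is forced to
    zero with a warning.
    """
    w = _parse_matrix_frame(path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is not square (shape {w.shape})")
    if w.shape[0] != atlas.n_regions:
        raise ValueError(
            f"{path}: matrix size {w.shape[0]} does not match atlas size "
            f"{atlas.n_regions}"
        )
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{path}: NaN or infinite entries")
    if np.any(w < 0):
        raise ValueError(f"{path}: negative entries")
    scale = w.max() if w.max() > 0 else 1.0
    asym = np.abs(w - w.T).max()
    if asym > ASYMMETRY_RTOL * scale:
        raise ValueError(
            f"{path}: asymmetry {asym:.3g} exceeds tolerance "
            f"{ASYMMETRY_RTOL * scale:.3g}"
        )
    w = (w + w.T) / 2.0
    if np.any(np.diag(w) != 0):
        logger.warning("%s: nonzero diagonal forced to zero", path)
        np.fill_diagonal(w, 0.0)
    sid = subject_id if subject_id is not None else Path(path).stem
    return ConnectivityMatrix(weights=w, atlas=atlas, subject_id=sid)


def write_connectome(C: ConnectivityMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with a region-name header row and column."""
    df = pd.DataFrame(C.weights, index=C.atlas.names, columns=C.atlas.names)
    df.to_csv(path, sep="\t")


def threshold_proportional(
    C: ConnectivityMatrix, proportion: float
) -> ConnectivityMatrix:
    """Keep the ``round(proportion * n(n-1)/2)`` strongest undirected edges.

    The retained count is computed over all *possible* upper-triangle edges
    (round half up). Ties at the cutoff are broken by ascending (i, j) index
    so the result is deterministic; surviving weights are unchanged and the
    matrix stays symmetric with zero diagonal.
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    w = C.weights
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    m = iu.size
    k = int(np.floor(proportion * m + 0.5))
    vals = w[iu, ju]
    # sort by (-weight, i, j): descending weight, ties by stable edge index
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    return C.with_weights(out)


def node_strength(C: ConnectivityMatrix) -> np.ndarray:
    """Weighted degree: row sums of the adjacency matrix."""
    return C.weights.sum(axis=1)
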