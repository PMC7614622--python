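"""Spatial weight matrices for simultaneous-autoregressive modelling.

A weight matrix ``W`` encodes the neighbourhood structure of ``R`` regions:
``w_ij > 0`` when region *j* is a neighbour of region *i*.  Throughout the
package ``W`` is required to be row-stochastic with a zero diagonal, which
guarantees a spectral radius of at most one and hence that the spatial
filter ``I - rho * W`` is invertible for every ``|rho| < 1``.

For brain-imaging panels the natural neighbourhood combines anatomy and
geometry: the weight of region *j* for region *i* grows with the number of
white-matter fibers connecting them and shrinks with the Euclidean distance
between their centroids (:func:`build_weight_matrix`).  Synthetic
rook-contiguity lattices are provided for simulation studies
(:func:`lattice_weights`).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpatialWeights",
    "StructuralInputs",
    "WeightDiagnostics",
    "build_weight_matrix",
    "row_normalize",
    "lattice_weights",
    "validate_weights",
    "read_weights_csv",
    "write_weights_csv",
]

_ROW_SUM_TOL = 1e-10
_EIG_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class SpatialWeights:
    """A validated row-stochastic spatial weight matrix.

    Parameters
    ----------
    W
        ``R x R`` nonnegative matrix with zero diagonal whose rows each sum
        to one.
    region_labels
        Optional region names, length ``R``.
    """

    W: np.ndarray
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        diag = validate_weights(W)
        if not diag.ok:
            raise ValueError(f"invalid spatial weight matrix: {diag.summary()}")
        if self.region_labels is not None:
            labels = tuple(str(s) for s in self.region_labels)
            if len(labels) != W.shape[0]:
                raise ValueError(
                    f"{len(labels)} region labels for {W.shape[0]} regions"
                )
            object.__setattr__(self, "region_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]


@dataclasses.dataclass(frozen=True)
class StructuralInputs:
    """Fiber-count and centroid-distance matrices for one subject.

    ``F`` holds nonnegative white-matter fiber counts (zero diagonal,
    symmetry not assumed); ``D`` holds pairwise distances, symmetric with a
    zero diagonal and strictly positive off-diagonal entries.
    """

    F: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        D = np.asarray(self.D, dtype=float)
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise ValueError("F must be square")
        if D.shape != F.shape:
            raise ValueError(f"shape mismatch: F {F.shape} vs D {D.shape}")
        if np.any(F < 0):
            raise ValueError("fiber counts must be nonnegative")
        if np.any(np.diag(F) != 0):
            raise ValueError("F must have a zero diagonal")
        if not np.allclose(D, D.T):
            raise ValueError("D must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("D must have a zero diagonal")
        off = ~np.eye(D.shape[0], dtype=bool)
        if np.any(D[off] <= 0):
            raise ValueError("off-diagonal distances must be strictly positive")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "D", D)


@dataclasses.dataclass(frozen=True)
class WeightDiagnostics:
    """Result of :func:`validate_weights`."""

    ok: bool
    row_sum_deviation: float
    diagonal_violation: float
    min_entry: float
    spectral_radius: float

    def summary(self) -> str:
        parts = []
        if self.row_sum_deviation > _ROW_SUM_TOL:
            parts.append(f"row-sum deviation {self.row_sum_deviation:.3g}")
        if self.diagonal_violation != 0.0:
            parts.append(f"nonzero diagonal (max {self.diagonal_violation:.3g})")
        if self.min_entry < 0:
            parts.append(f"negative entry {self.min_entry:.3g}")
        if self.spectral_radius > 1 + _EIG_TOL:
            parts.append(f"spectral radius {self.spectral_radius:.6g} > 1")
        return "; ".join(parts) if parts else "ok"


def validate_weights(W: np.ndarray) -> WeightDiagnostics:
    """Diagnose whether ``W`` is a valid row-stochastic weight matrix.

    Never raises: reports row-sum deviations, diagonal violations,
    negativity and the spectral radius, plus an overall pass flag.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    row_dev = float(np.max(np.abs(W.sum(axis=1) - 1.0)))
    diag_viol = float(np.max(np.abs(np.diag(W)))) if W.shape[0] else 0.0
    min_entry = float(W.min())
    rho = float(np.max(np.abs(np.linalg.eigvals(W))))
    ok = (
        row_dev <= _ROW_SUM_TOL
        and diag_viol == 0.0
        and min_entry >= 0.0
        and rho <= 1.0 + _EIG_TOL
    )
    return WeightDiagnostics(ok, row_dev, diag_viol, min_entry, rho)


def row_normalize(A: np.ndarray) -> np.ndarray:
    """Divide each row of a nonnegative matrix by its sum.

    Idempotent on already row-stochastic input.  Raises on negative
    entries or an all-zero row.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("matrix must be nonnegative")
    sums = A.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(sums.ravel() == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero row(s) at index {zero_rows.tolist()}")
    return A / sums


def build_weight_matrix(
    F: np.ndarray | StructuralInputs,
    D: np.ndarray | None = None,
    zero_row_policy: str = "error",
    region_labels: Sequence[str] | None = None,
) -> SpatialWeights:
    """Combine fiber counts and distances into a row-stochastic weight matrix.

    The raw affinity between regions *i* and *j* is ``g_ij = f_ij / d_ij``
    (zero on the diagonal): proportional to the white-matter fiber count and
    inversely proportional to the centroid distance.  Each row is then
    normalised to sum to one, so the result is scale-free in both ``F`` and
    ``D``.

    Parameters
    ----------
    F, D
        Fiber-count and distance matrices (or a single
        :class:`StructuralInputs`).
    zero_row_policy
        What to do when a region has no fibers to any other region (an
        all-zero raw row): ``"error"`` (default) raises, flagging an
        isolated region; ``"inverse_distance"`` fills the row with
        normalised ``1/d_ij`` weights instead.
    """
    if isinstance(F, StructuralInputs):
        inputs = F
    else:
        if D is None:
            raise TypeError("D is required when F is a plain matrix")
        inputs = StructuralInputs(F, D)
    if zero_row_policy not in ("error", "inverse_distance"):
        raise ValueError(f"unknown zero_row_policy {zero_row_policy!r}")

    R = inputs.F.shape[0]
    off = ~np.eye(R, dtype=bool)
    G = np.zeros((R, R))
    G[off] = inputs.F[off] / inputs.D[off]
    zero_rows = np.flatnonzero(G.sum(axis=1) == 0)
    if zero_rows.size:
        if zero_row_policy == "error":
            raise ValueError(
                f"isolated region(s) with no fiber connections: {zero_rows.tolist()}"
            )
        for i in zero_rows:
            G[i, off[i]] = 1.0 / inputs.D[i, off[i]]
    return SpatialWeights(row_normalize(G), region_labels=region_labels)


def lattice_weights(nrows: int, ncols: int) -> SpatialWeights:
    """Row-normalised rook-contiguity weights on an ``nrows x ncols`` grid.

    Cells are neighbours when they share an edge.  Used as the synthetic
    spatial structure in simulation studies.
    """
    R = nrows * ncols
    if nrows < 1 or ncols < 1 or R < 2:
        raise ValueError("lattice needs at least 2 cells")
    A = np.zeros((R, R))
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c
            if r + 1 < nrows:
                j = (r + 1) * ncols + c
                A[i, j] = A[j, i] = 1.0
            if c + 1 < ncols:
                j = r * ncols + (c + 1)
                A[i, j] = A[j, i] = 1.0
    return SpatialWeights(row_normalize(A))


def read_weights_csv(path, validate: bool = True) -> SpatialWeights | np.ndarray:
    """Read a weight matrix from CSV (optional header row of region labels)."""
    df = pd.read_csv(path, header=None, float_precision="round_trip")
    labels = None
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        labels = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:].astype(float)
    W = df.to_numpy(dtype=float)
    if not validate:
        return W
    return SpatialWeights(W, region_labels=labels)


def write_weights_csv(weights: SpatialWeights | np.ndarray, path) -> None:
    """Write a weight matrix to CSV at full precision (17 significant digits)."""
    W = weights.W if isinstance(weights, SpatialWeights) else np.asarray(weights)
    labels = weights.region_labels if isinstance(weights, SpatialWeights) else None
    with open(path, "w") as fh:
        if labels is not None:
            fh.write(",".join(labels) + "\n")
        for row in W:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def inverse_distance_weights(D: np.ndarray) -> SpatialWeights:
    """Pure inverse-distance weights: ``w_ij`` proportional to ``1/d_ij``."""
    D = np.asarray(D, dtype=float)
    R = D.shape[0]
    off = ~np.eye(R, dtype=bool)
    G = np.zeros((R, R))
    G[off] = 1.0 / D[off]
    return SpatialWeights(row_normalize(G))
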