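"""Graph-Laplacian spatial prior over a voxel mask.

A first-order graph Laplacian ``D`` over the masked voxels encodes the prior
belief that neighbouring voxels of a parameter map should not differ
substantially.  Off-diagonal entries of ``D`` are 1 for face-adjacent
(6-connected) masked voxel pairs and each diagonal entry is minus the voxel's
neighbour count, so ``-D`` is positive semidefinite and
``theta^T (-D) theta = sum over adjacent pairs (theta_i - theta_j)^2``.

The spatial log-density for a v-voxel map is

    (v/2) * log(alpha) - (alpha/2) * theta^T (-D) theta

with a single precision ``alpha`` per map that is itself optimised.  The
Laplacian is singular, so this is an improper prior; the per-map
normalisation constant ``(v/2) log alpha`` is what makes optimising ``alpha``
trade data fit against smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["VoxelGrid", "build_laplacian", "spatial_logpdf", "normal_logpdf"]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D boolean mask plus the raster-order masked-voxel index."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "VoxelGrid":
        return cls(np.ones(shape, dtype=bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_index(self) -> np.ndarray:
        """Grid-shaped array mapping masked voxels to 0..v-1, else -1."""
        idx = np.full(self.mask.shape, -1, dtype=np.int64)
        idx[self.mask] = np.arange(self.n_voxels)
        return idx

    def unravel(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a length-v vector back onto the grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError("values length does not match mask voxel count")
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out


def build_laplacian(grid: VoxelGrid) -> sparse.csr_matrix:
    """First-order graph Laplacian D over the masked voxels (sparse v x v).

    Adjacency is 6-connectivity (face neighbours) restricted to the mask;
    an interior voxel of a fully-masked grid has diagonal -6, mask-boundary
    voxels simply have fewer neighbours.  Rows sum to zero and the matrix
    is symmetric.
    """
    mask = grid.mask
    idx = grid.voxel_index
    rows, cols = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        i = idx[tuple(sl_a)][pair]
        j = idx[tuple(sl_b)][pair]
        rows.extend((i, j))
        cols.extend((j, i))
    v = grid.n_voxels
    if not rows:
        return sparse.csr_matrix((v, v), dtype=np.int64)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    off = sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int64), (rows, cols)), shape=(v, v)
    ).tocsr()
    degree = np.asarray(off.sum(axis=1)).ravel()
    return (off - sparse.diags(degree, format="csr", dtype=np.int64)).tocsr()


def spatial_logpdf(theta_map: np.ndarray, alpha: float,
                   laplacian: sparse.spmatrix) -> float:
    """Improper spatial-prior log-density of one parameter map.

    Evaluates ``(v/2) log(alpha) - (alpha/2) theta^T (-D) theta``; the
    quadratic form is the sum of squared differences over adjacent masked
    voxel pairs, so smoother maps score higher and the constant map scores
    highest.
    """
    theta = np.asarray(theta_map, dtype=float)
    v = laplacian.shape[0]
    if theta.shape != (v,):
        raise ValueError(
            f"theta_map has shape {theta.shape}, Laplacian is {v}x{v}"
        )
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    roughness = float(theta @ (-(laplacian @ theta)))
    return 0.5 * v * math.log(alpha) - 0.5 * alpha * roughness


def normal_logpdf(x, mean, variance):
    """Gaussian log-density (full constant included), vectorised."""
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variance must be positive")
    x = np.asarray(x, dtype=float)
    out = -0.5 * (np.log(2.0 * np.pi * variance) + (x - mean) ** 2 / variance)
    return float(out) if out.ndim == 0 else out
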