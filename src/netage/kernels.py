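"""Vectorized network images and linear-kernel similarity matrices.

Each subject's network image is flattened (C-order over the voxel grid) into
one row of a subjects x voxels feature matrix; the linear kernel is then the
Gram matrix of pairwise dot products between rows.  Columns outside the
network mask are identically zero and contribute nothing to the dot
products, so the feature matrix may equivalently be restricted to the mask
support (useful at realistic voxel counts).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .parcellation import NetworkImage, NetworkMask


def build_feature_matrix(
    images: Sequence[NetworkImage] | Sequence[np.ndarray],
    mask: NetworkMask | None = None,
) -> np.ndarray:
    """Stack network images into a subjects x voxels feature matrix.

    Row i is subject i's volume flattened in C order.  If ``mask`` is given,
    columns are restricted to the mask's support; the resulting Gram matrix
    is unchanged because off-support voxels are zero.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    arrays = [
        im.values if isinstance(im, NetworkImage) else np.asarray(im)
        for im in images
    ]
    dims = arrays[0].shape
    for a in arrays:
        if a.shape != dims:
            raise ValueError(f"mixed image dims: {a.shape} vs {dims}")
    if mask is not None:
        if mask.dims != dims:
            raise ValueError(f"mask dims {mask.dims} != image dims {dims}")
        support = mask.values.ravel().astype(bool)
        rows = [a.ravel()[support] for a in arrays]
    else:
        rows = [a.ravel() for a in arrays]
    f = np.asarray(rows, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("feature matrix contains NaN or infinite values")
    return f


def linear_similarity(f_a: np.ndarray, f_b: np.ndarray | None = None) -> np.ndarray:
    """Linear-kernel (cross-)similarity: entry (i, j) = <row_i(a), row_j(b)>.

    With ``f_b`` omitted or identical to ``f_a`` the result is the symmetric
    positive semi-definite Gram matrix K = F F^T; symmetry is enforced
    exactly by averaging with the transpose (guards against BLAS rounding).
    """
    f_a = np.asarray(f_a, dtype=np.float64)
    symmetric = f_b is None
    f_b = f_a if f_b is None else np.asarray(f_b, dtype=np.float64)
    if f_a.ndim != 2 or f_b.ndim != 2:
        raise ValueError("feature matrices must be 2D")
    if f_a.shape[1] != f_b.shape[1]:
        raise ValueError(
            f"column mismatch: {f_a.shape[1]} vs {f_b.shape[1]} voxels"
        )
    k = f_a @ f_b.T
    if symmetric:
        k = 0.5 * (k + k.T)
    return k


def validate_similarity(k: np.ndarray, tol_scale: float = 1e-8) -> np.ndarray:
    """Check K is square, symmetric and PSD up to a trace-relative jitter."""
    k = np.asarray(k, dtype=np.float64)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {k.shape}")
    if not np.allclose(k, k.T, rtol=0, atol=tol_scale * max(1.0, np.abs(k).max())):
        raise ValueError("similarity matrix is not symmetric")
    evals = np.linalg.eigvalsh(k)
    if evals.min() < -tol_scale * max(np.trace(k), 1.0):
        raise ValueError(
            f"similarity matrix is not PSD (min eigenvalue {evals.min():.3g})"
        )
    return k


def trace_normalize(k: np.ndarray) -> np.ndarray:
    """Scale K so its mean diagonal entry is 1 (conditioning aid only)."""
    k = np.asarray(k, dtype=np.float64)
    scale = np.trace(k) / k.shape[0]
    if scale <= 0:
        raise ValueError("cannot trace-normalize a zero or negative-trace kernel")
    return k / scale
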