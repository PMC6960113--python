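"""Network parcellation of gray-matter volumes and GMV-age correlation.

A subject's preprocessed gray-matter map (modulated, smoothed density on a
shared voxel grid) is intersected with binary structural-network masks; the
network gray-matter volume (GMV) is the sum of density over the network's
voxels.  The association between network GMV and chronological age is
summarized by Pearson's r; min-max normalized volumes v* are produced for
reporting only (Pearson r is invariant to that affine rescaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical seven-network labels (frontoparietal, dorsal attention, default
#: mode, somatomotor, ventral attention, visual, limbic).
NETWORK_LABELS = ("FPN", "DAN", "DMN", "SMN", "VAN", "VN", "LN")


class DimensionMismatchError(ValueError):
    """Image and mask grids do not share the same voxel dimensions."""


class DegenerateInputError(ValueError):
    """Input is constant (or otherwise degenerate) where variation is required."""


@dataclass(frozen=True)
class GrayMatterImage:
    """One subject's 3D gray-matter density grid.

    Parameters
    ----------
    values
        Non-negative 3D array of gray-matter density (arbitrary density
        units; modulated VBM outputs are unitless tissue fractions scaled
        by the Jacobian of the normalization).
    voxel_size
        Isotropic voxel edge length in mm.  Metadata only; no operation
        resamples the grid.
    """

    values: np.ndarray
    voxel_size: float = 1.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"gray-matter image must be 3D, got ndim={v.ndim}")
        if not np.isfinite(v).all():
            raise ValueError("gray-matter image contains NaN or infinite voxels")
        if (v < 0).any():
            raise ValueError("gray-matter image contains negative voxels")
        object.__setattr__(self, "values", v)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class NetworkMask:
    """Binary 3D parcel defining one structural network on the shared grid."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={v.ndim}")
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask voxels must be 0 or 1")
        if not v.any():
            raise ValueError(f"mask {self.label!r} has no nonzero voxel")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class NetworkImage:
    """A gray-matter image restricted to one network (zero outside the mask)."""

    label: str
    values: np.ndarray

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class VolumeSeries:
    """Per-subject network GMV v and its min-max normalization v*."""

    label: str
    v: np.ndarray
    v_star: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "v_star", minmax_normalize(self.v))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of network GMV with chronological age."""

    label: str
    r: float
    n: int


def apply_mask(gm: GrayMatterImage, mask: NetworkMask) -> NetworkImage:
    """Intersect a gray-matter image with a network mask.

    The overlap of the subject's gray-matter image with the network parcel
    defines the structural network map: a voxelwise product that keeps the
    full grid, with zeros outside the mask.
    """
    if gm.dims != mask.dims:
        raise DimensionMismatchError(
            f"image dims {gm.dims} != mask dims {mask.dims}"
        )
    return NetworkImage(label=mask.label, values=gm.values * mask.values)


def network_gmv(net: NetworkImage) -> float:
    """Total gray-matter volume of a network: the sum over all voxels."""
    return float(net.values.sum(dtype=np.float64))


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Min-max normalize volumes to v* = (v - min) / (max - min) in [0, 1]."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateInputError("constant input: max == min, range is degenerate")
    return (v - lo) / (hi - lo)


def gmv_age_correlation(
    v: np.ndarray, ages: np.ndarray, label: str = ""
) -> CorrelationResult:
    """Pearson correlation between network gray-matter volumes and ages."""
    v = np.asarray(v, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if v.shape != ages.shape or v.ndim != 1:
        raise ValueError("v and ages must be 1D arrays of equal length")
    if v.size < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if np.ptp(v) == 0 or np.ptp(ages) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    r = float(np.corrcoef(v, ages)[0, 1])
    return CorrelationResult(label=label, r=r, n=v.size)
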