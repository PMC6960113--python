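"""Synthetic aging gray-matter cohorts with calibrated network-age coupling.

Emulates the output of a VBM pipeline (modulated, smoothed gray-matter
density volumes on one voxel grid) for a cohort spanning adulthood: within
each structural-network mask the mean voxel density declines linearly with
age, and the per-subject network gray-matter volume (GMV, the sum of density
over the mask) correlates negatively with age at a prescribed Pearson r.

The generator is calibrated analytically.  Each network's GMV noise has two
parts: an iid voxel noise field shared with the rest of the grid, and a
network-coherent per-subject intensity shift.  Because Gaussian smoothing is
linear, its effect on the GMV sum is computed exactly from the smoothed mask
indicator: with weights ``w = smooth(mask)``, the masked sum of a smoothed
volume equals ``w . raw``, so the age slope and coherent noise scale by
``c = sum(w[mask])`` while the iid noise contributes ``sd * ||w||``.  The
coherent noise sd is then solved in closed form so the total GMV noise gives
the requested correlation with age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .parcellation import NETWORK_LABELS, GrayMatterImage, NetworkMask

#: GMV-age Pearson correlations reported for the seven cortical networks
#: (FPN, DAN, DMN, SMN, VAN, VN, LN), used as the generator's default targets.
DEFAULT_TARGET_R = (-0.78, -0.70, -0.74, -0.75, -0.75, -0.60, -0.57)


class SizingError(ValueError):
    """Grid too small to host the requested masks or network layout."""


class CalibrationError(ValueError):
    """Requested correlation unreachable under the noise configuration."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_subjects
        Cohort size (>= 2).
    age_low, age_high
        Age range in years; ages are drawn uniformly on this interval.
    sex_ratio
        Fraction of male subjects in [0, 1].
    grid_dims
        Voxel grid, three positive integers.
    n_networks
        Number of structural networks; must equal ``len(target_r)``.
    target_r
        Per-network target Pearson correlation of network GMV with age,
        each in (-1, 0].  A target of exactly 0 means no age signal for
        that network (zero slope, zero coherent noise).
    baseline_intensity
        Mean gray-matter density per voxel at the midpoint age (density
        units, VBM-like tissue fraction scale).
    voxel_noise_sd
        SD of the iid per-voxel noise field (density units).
    smooth_sigma
        Isotropic Gaussian smoothing in voxel units (0 disables).
    age_slope
        Per-voxel density loss per year inside a network mask
        (density units / year); the GMV slope is this times the
        (smoothing-adjusted) mask volume.
    seed
        RNG seed; identical (spec, masks) reproduce bit-identical output.
    """

    n_subjects: int
    age_low: float = 18.0
    age_high: float = 90.0
    sex_ratio: float = 0.5
    grid_dims: tuple[int, int, int] = (32, 32, 32)
    n_networks: int = 7
    target_r: tuple[float, ...] = DEFAULT_TARGET_R
    baseline_intensity: float = 0.6
    voxel_noise_sd: float = 0.1
    smooth_sigma: float = 1.0
    age_slope: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.age_low < self.age_high:
            raise ValueError("need age_low < age_high")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if len(self.grid_dims) != 3 or any(d < 2 for d in self.grid_dims):
            raise ValueError("grid_dims must be three integers >= 2")
        if len(self.target_r) != self.n_networks:
            raise ValueError("target_r must have one entry per network")
        for r in self.target_r:
            if not -1.0 < r <= 0.0:
                raise ValueError(f"each target r must lie in (-1, 0], got {r}")
        if self.voxel_noise_sd < 0 or self.smooth_sigma < 0:
            raise ValueError("noise sd and smoothing sigma must be >= 0")
        if self.age_slope <= 0:
            raise ValueError("age_slope must be positive")

    @property
    def age_sd(self) -> float:
        """SD of the uniform age distribution, (high - low) / sqrt(12)."""
        return (self.age_high - self.age_low) / math.sqrt(12.0)

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_low + self.age_high)


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated subject: id, phenotype, and gray-matter volume."""

    subject_id: str
    age: float
    sex: str
    gm: GrayMatterImage


def noise_sd_for_target_r(slope: float, age_sd: float, target_r: float) -> float:
    """Noise sd giving Pearson r = target for a linear-in-age signal.

    For ``v = const - slope * age + eps`` with ``eps ~ N(0, sigma^2)``,
    ``r = -slope * age_sd / sqrt(slope^2 age_sd^2 + sigma^2)``; inverting
    gives ``sigma = slope * age_sd * sqrt(1 / r^2 - 1)``.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if age_sd <= 0:
        raise ValueError("age_sd must be positive")
    if not 0.0 < abs(target_r) < 1.0:
        raise ValueError(
            f"|target_r| must lie strictly in (0, 1), got {target_r}: "
            "r = 0 needs infinite noise, |r| = 1 needs zero noise"
        )
    return slope * age_sd * math.sqrt(1.0 / target_r**2 - 1.0)


def _auto_lattice(n: int) -> tuple[int, int, int]:
    """Smallest near-cubic cell lattice with at least n cells."""
    best: tuple[int, int, int] | None = None
    for a in range(1, n + 1):
        for b in range(a, n + 1):
            c = math.ceil(n / (a * b))
            if c < b:
                c = b
            if a * b * c >= n:
                cand = tuple(sorted((a, b, c)))
                # prefer balanced lattices (small longest axis) over tight fits
                if best is None or (max(cand), math.prod(cand)) < (
                    max(best),
                    math.prod(best),
                ):
                    best = cand  # type: ignore[assignment]
    assert best is not None
    return best  # type: ignore[return-value]


def make_masks(
    grid_dims: Sequence[int],
    n_networks: int,
    seed: int,
    allow_overlap: bool = False,
    min_voxels: int = 8,
    margin: int = 3,
) -> list[NetworkMask]:
    """Place one rectangular network parcel per network on the grid.

    Stands in for a cortical-network atlas: each mask is a single connected
    box of at least ``min_voxels`` voxels.  Without overlap the boxes live in
    disjoint lattice cells separated by ``margin`` voxels (so smoothing leaks
    negligibly between networks); with overlap they are placed freely.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if len(grid_dims) != 3:
        raise ValueError("grid_dims must have three entries")
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(seed)
    min_side = max(2, round(min_voxels ** (1 / 3)))

    masks: list[NetworkMask] = []
    if allow_overlap:
        for k in range(n_networks):
            sides = []
            starts = []
            for d in grid_dims:
                hi = max(min_side, d // 2)
                if d < min_side:
                    raise SizingError(f"grid {grid_dims} too small for a mask")
                s = int(rng.integers(min_side, hi + 1))
                sides.append(s)
                starts.append(int(rng.integers(0, d - s + 1)))
            m = np.zeros(grid_dims, dtype=np.uint8)
            m[
                starts[0] : starts[0] + sides[0],
                starts[1] : starts[1] + sides[1],
                starts[2] : starts[2] + sides[2],
            ] = 1
            masks.append(NetworkMask(label=_label(k), values=m))
        return masks

    lat = _auto_lattice(n_networks)
    # assign lattice axes to grid axes, largest cell count to largest dim
    order = np.argsort(grid_dims)[::-1]
    lat_sorted = sorted(lat, reverse=True)
    n_cells = [0, 0, 0]
    for ax, nc in zip(order, lat_sorted):
        n_cells[ax] = nc
    cell = [grid_dims[i] // n_cells[i] for i in range(3)]
    avail = [c - margin for c in cell]
    if any(a < min_side for a in avail):
        raise SizingError(
            f"grid {grid_dims} too small for {n_networks} masks of >= "
            f"{min_voxels} voxels with margin {margin} (cell {cell})"
        )
    cells = [
        (i, j, k)
        for i in range(n_cells[0])
        for j in range(n_cells[1])
        for k in range(n_cells[2])
    ][:n_networks]
    for idx, cidx in enumerate(cells):
        sides = []
        starts = []
        for ax in range(3):
            lo_side = max(min_side, (2 * avail[ax]) // 3)
            s = int(rng.integers(lo_side, avail[ax] + 1))
            off = int(rng.integers(0, avail[ax] - s + 1))
            sides.append(s)
            starts.append(cidx[ax] * cell[ax] + margin // 2 + off)
        m = np.zeros(grid_dims, dtype=np.uint8)
        m[
            starts[0] : starts[0] + sides[0],
            starts[1] : starts[1] + sides[1],
            starts[2] : starts[2] + sides[2],
        ] = 1
        if int(m.sum()) < min_voxels:
            raise SizingError("placed mask smaller than min_voxels")
        masks.append(NetworkMask(label=_label(idx), values=m))
    return masks


def _label(k: int) -> str:
    return NETWORK_LABELS[k] if k < len(NETWORK_LABELS) else f"NET{k + 1}"


def _mask_weights(
    mask: NetworkMask, sigma: float
) -> tuple[np.ndarray, float, float]:
    """Smoothing-adjusted mask weights (w, c, ||w||).

    ``w = smooth(indicator)`` gives, for each raw voxel, its total weight in
    the post-smoothing masked sum; ``c = sum(w[mask])`` scales any pattern
    added uniformly inside the mask, and ``||w||`` scales iid voxel noise.
    Without smoothing, w is the indicator, c the voxel count, ||w|| = sqrt(c).
    """
    ind = mask.values.astype(np.float64)
    if sigma > 0:
        w = gaussian_filter(ind, sigma=sigma, mode="constant", cval=0.0)
    else:
        w = ind
    c = float((w * ind).sum())
    l2 = float(np.sqrt((w**2).sum()))
    return w, c, l2


@dataclass(frozen=True)
class _NetworkPlan:
    """Calibrated per-network generation parameters."""

    slope_per_voxel: float
    coherent_sd: float
    gmv_slope: float  # expected d(GMV)/d(age), post smoothing


def _calibrate(spec: CohortSpec, masks: Sequence[NetworkMask]) -> list[_NetworkPlan]:
    plans = []
    for k, mask in enumerate(masks):
        r = spec.target_r[k]
        if r == 0.0:
            plans.append(_NetworkPlan(0.0, 0.0, 0.0))
            continue
        _, c, l2 = _mask_weights(mask, spec.smooth_sigma)
        gmv_slope = spec.age_slope * c
        total_sd = noise_sd_for_target_r(gmv_slope, spec.age_sd, r)
        iid_part = spec.voxel_noise_sd * l2
        if total_sd**2 <= iid_part**2:
            raise CalibrationError(
                f"network {mask.label}: voxel noise alone (GMV sd {iid_part:.3g}) "
                f"exceeds the total noise {total_sd:.3g} required for r={r}; "
                "lower voxel_noise_sd or raise age_slope"
            )
        coherent_sd = math.sqrt(total_sd**2 - iid_part**2) / c
        plans.append(_NetworkPlan(spec.age_slope, coherent_sd, gmv_slope))
    return plans


def make_cohort(
    spec: CohortSpec, masks: Sequence[NetworkMask]
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate a calibrated synthetic cohort.

    Returns the subjects (each holding a full gray-matter volume) and a
    phenotype table with columns subject_id, age, sex, path (path is filled
    by :func:`write_cohort`).
    """
    if len(masks) == 0:
        raise ValueError("need at least one network mask")
    if len(masks) != spec.n_networks:
        raise ValueError(
            f"got {len(masks)} masks for spec.n_networks={spec.n_networks}"
        )
    for m in masks:
        if m.dims != tuple(spec.grid_dims):
            raise ValueError(
                f"mask {m.label} dims {m.dims} != grid {spec.grid_dims}"
            )
    plans = _calibrate(spec, masks)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ages = rng.uniform(spec.age_low, spec.age_high, size=n)
    sexes = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    # per-subject, per-network coherent intensity shifts
    shifts = rng.standard_normal((n, len(masks)))

    mask_bool = [m.values.astype(bool) for m in masks]
    subjects: list[SyntheticSubject] = []
    for i in range(n):
        vol = rng.standard_normal(spec.grid_dims).astype(np.float32)
        vol *= np.float32(spec.voxel_noise_sd)
        vol += np.float32(spec.baseline_intensity)
        dage = ages[i] - spec.age_mid
        for k, plan in enumerate(plans):
            delta = -plan.slope_per_voxel * dage + plan.coherent_sd * shifts[i, k]
            if delta != 0.0:
                vol[mask_bool[k]] += np.float32(delta)
        if spec.smooth_sigma > 0:
            vol = gaussian_filter(vol, sigma=spec.smooth_sigma, mode="constant")
        np.clip(vol, 0.0, None, out=vol)
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:04d}",
                age=float(ages[i]),
                sex=str(sexes[i]),
                gm=GrayMatterImage(values=vol),
            )
        )
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "path": ["" for _ in subjects],
        }
    )
    return subjects, table


def _nifti(values: np.ndarray, voxel_size: float) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(values), affine=np.eye(4))
    img.header.set_zooms((voxel_size,) * 3)
    return img


def write_cohort(
    cohort: Sequence[SyntheticSubject],
    table: pd.DataFrame,
    out_dir: str | Path,
    masks: Sequence[NetworkMask] = (),
) -> list[Path]:
    """Write subject volumes, masks and the phenotype table to ``out_dir``.

    One NIfTI-1 file per subject and per mask (shared grid, voxel size in the
    header), plus ``phenotype.csv`` with columns subject_id, age, sex, path.
    Returns the manifest of files written.  Validates dims and voxel values
    before touching the disk.
    """
    if len(cohort) == 0:
        raise ValueError("cannot write an empty cohort")
    dims = cohort[0].gm.dims
    for s in cohort:
        if s.gm.dims != dims:
            raise ValueError(f"subject {s.subject_id} dims {s.gm.dims} != {dims}")
        if not np.isfinite(s.gm.values).all() or (s.gm.values < 0).any():
            raise ValueError(f"subject {s.subject_id} has invalid voxels")
    for m in masks:
        if m.dims != dims:
            raise ValueError(f"mask {m.label} dims {m.dims} != cohort dims {dims}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    paths = []
    for s in cohort:
        p = out / f"{s.subject_id}_gm.nii.gz"
        nib.save(_nifti(s.gm.values, s.gm.voxel_size), p)
        manifest.append(p)
        paths.append(p.name)
    for m in masks:
        p = out / f"mask-{m.label}.nii.gz"
        nib.save(_nifti(m.values, 1.5), p)
        manifest.append(p)
    table = table.copy()
    table["path"] = paths
    csv_path = out / "phenotype.csv"
    table.to_csv(csv_path, index=False)
    manifest.append(csv_path)
    return manifest


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[SyntheticSubject], pd.DataFrame, list[NetworkMask]]:
    """Read back a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "phenotype.csv")
    subjects = []
    for row in table.itertuples():
        img = nib.load(in_dir / row.path)
        vs = float(img.header.get_zooms()[0])
        subjects.append(
            SyntheticSubject(
                subject_id=row.subject_id,
                age=float(row.age),
                sex=row.sex,
                gm=GrayMatterImage(
                    values=np.asarray(img.dataobj, dtype=np.float32),
                    voxel_size=vs,
                ),
            )
        )
    masks = []
    for p in sorted(in_dir.glob("mask-*.nii.gz")):
        label = p.name[len("mask-") : -len(".nii.gz")]
        img = nib.load(p)
        masks.append(
            NetworkMask(label=label, values=np.asarray(img.dataobj).astype(np.uint8))
        )
    return subjects, table, masks


def expected_gmv_slope(spec: CohortSpec, mask: NetworkMask, target_r: float) -> float:
    """Expected GMV-per-year slope for one network (diagnostic helper)."""
    if target_r == 0.0:
        return 0.0
    _, c, _ = _mask_weights(mask, spec.smooth_sigma)
    return -spec.age_slope * c
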