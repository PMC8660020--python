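"""Radial cell-position metrics, thresholding operators, and 3D mask
colocalization.

Positions along the CA1 radial axis are signed distances from the stratum
pyramidale / stratum radiatum border (positive toward stratum oriens),
optionally normalized to the local pyramidal-layer thickness, so 0 is the
SP/SR border and 1 the SO/SP border; ectopic cells may fall outside [0, 1].

Image operators cover the two classical histogram thresholds used for
nuclear segmentation (minimum cross-entropy and robust background), binary
mask overlap in physical units with per-z-step normalization, object-level
colocalization via 3D connected components of the mask product, and the
polyline approximation of primary-dendrite length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "CellPosition",
    "PositionSummary",
    "LabelVolume3D",
    "OverlapResult",
    "ColocObject",
    "radial_position",
    "position_summary",
    "li_min_cross_entropy_threshold",
    "robust_background_threshold",
    "mask_overlap_volume",
    "colocalize_objects",
    "colabel_fraction",
    "polyline_length",
]


@dataclass(frozen=True)
class CellPosition:
    """Signed distance (µm) from the SP/SR border and its normalized value
    (distance / local SP thickness)."""

    distance_um: float
    sp_thickness_um: float
    normalized: float


def radial_position(distance_um: float, sp_thickness_um: float) -> CellPosition:
    """Normalize a soma's distance from the SP/SR border by the SP thickness.

    No clamping: ectopic cells yield values outside [0, 1] (negative toward
    stratum radiatum).
    """
    if sp_thickness_um <= 0:
        raise ValueError("SP thickness must be positive")
    return CellPosition(distance_um=float(distance_um),
                        sp_thickness_um=float(sp_thickness_um),
                        normalized=float(distance_um) / float(sp_thickness_um))


@dataclass(frozen=True)
class PositionSummary:
    """Empirical CDF support/values plus median and interquartile range."""

    xs: np.ndarray
    cdf: np.ndarray
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def position_summary(distances_um) -> PositionSummary:
    """Cumulative fraction curve, median and IQR of soma positions.

    Quantiles use linear interpolation between order statistics.
    """
    d = np.asarray(distances_um, dtype=float)
    if d.size == 0:
        raise ValueError("no distances given")
    xs = np.sort(d)
    cdf = np.arange(1, xs.size + 1) / xs.size
    q1, med, q3 = np.quantile(d, [0.25, 0.5, 0.75])
    return PositionSummary(xs=xs, cdf=cdf, median=float(med), q1=float(q1), q3=float(q3))


def _cross_entropy(counts: np.ndarray, values: np.ndarray, split: int) -> float:
    """Li cross-entropy objective for background = values[:split]."""
    m0 = counts[:split].sum()
    m1 = counts[split:].sum()
    term = 0.0
    for m, c, v in ((m0, counts[:split], values[:split]),
                    (m1, counts[split:], values[split:])):
        if m == 0:
            continue
        mu = float((c * v).sum() / m)
        if mu > 0:
            term -= m * mu * math.log(mu)
    return term


def li_min_cross_entropy_threshold(counts, values=None) -> float:
    """Minimum-cross-entropy (Li) threshold of an intensity histogram.

    Minimizes the cross-entropy between the image and its two-level
    reconstruction exhaustively over all split points between distinct
    intensity levels; the returned threshold is the midpoint between the two
    boundary levels (pixels strictly above it are foreground).  Invariant to
    rescaling all counts by a constant.
    """
    counts = np.asarray(counts, dtype=float)
    if values is None:
        values = np.arange(counts.size, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = counts > 0
    counts, values = counts[keep], values[keep]
    order = np.argsort(values)
    counts, values = counts[order], values[order]
    if values.size < 2:
        raise ValueError("need at least two distinct intensity levels")
    best_split, best_obj = None, math.inf
    for split in range(1, values.size):
        obj = _cross_entropy(counts, values, split)
        if obj < best_obj:
            best_obj, best_split = obj, split
    return float(0.5 * (values[best_split - 1] + values[best_split]))


def robust_background_threshold(
    image, trim: tuple[float, float] = (0.05, 0.05), k: float = 2.0
) -> float:
    """Robust-background threshold: trimmed mean + k * trimmed sd.

    The lowest and highest ``trim`` fractions of pixel intensities are
    discarded before computing mean and (population) sd, which suppresses
    bright outliers so the threshold tracks the background.
    """
    x = np.sort(np.asarray(image, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty image")
    lo = int(math.floor(trim[0] * x.size))
    hi = x.size - int(math.floor(trim[1] * x.size))
    if hi <= lo:
        raise ValueError("all pixels trimmed")
    core = x[lo:hi]
    return float(core.mean() + k * core.std())


@dataclass(frozen=True)
class LabelVolume3D:
    """Binary voxel grid (nz, ny, nx) with anisotropic voxel size (dx, dy, dz) µm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("volume must be 3-D (nz, ny, nx)")
        object.__setattr__(self, "data", arr.astype(bool))

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass(frozen=True)
class OverlapResult:
    voxel_count: int
    overlap_um3: float
    overlap_per_z_um3: float


@dataclass(frozen=True)
class ColocObject:
    centroid: tuple[float, float, float]
    voxel_count: int
    bbox: tuple[int, ...]


def _check_grids(a: LabelVolume3D, b: LabelVolume3D) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.voxel_size, b.voxel_size):
        raise ValueError("voxel size mismatch")


def mask_overlap_volume(a: LabelVolume3D, b: LabelVolume3D) -> OverlapResult:
    """Physical overlap volume of two masks, normalized by z-step count.

    overlap_um3 = |A ∧ B| voxels x voxel volume; the per-z normalization
    divides by the stack's z-extent to control for object-size differences.
    """
    _check_grids(a, b)
    count = int(np.logical_and(a.data, b.data).sum())
    vol = count * a.voxel_volume_um3
    return OverlapResult(voxel_count=count, overlap_um3=vol,
                         overlap_per_z_um3=vol / a.n_z)


def colocalize_objects(
    a: LabelVolume3D, b: LabelVolume3D, connectivity: int = 26, min_size: int = 0
) -> list[ColocObject]:
    """Connected components of the mask product (putative colocalized cells).

    ``connectivity`` is 26 (vertex) or 6 (face); components smaller than
    ``min_size`` voxels are discarded.  All surviving candidates are
    returned; confirmation of individual objects is left to the caller.
    """
    _check_grids(a, b)
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    inter = np.logical_and(a.data, b.data)
    labels = measure.label(inter, connectivity=3 if connectivity == 26 else 1)
    objects = []
    for region in measure.regionprops(labels):
        if region.area < min_size:
            continue
        objects.append(ColocObject(centroid=tuple(float(c) for c in region.centroid),
                                   voxel_count=int(region.area),
                                   bbox=tuple(int(v) for v in region.bbox)))
    return objects


def colabel_fraction(
    objects_total: int,
    coloc: int,
    animal_id: str = "",
    birthdate: str = "",
    factor2: str = "",
):
    """Co-labeled fraction plus the per-animal count vector for pooling.

    Returns ``(fraction, AnimalVector)``; the vector feeds the bootstrap
    group comparisons.
    """
    from natalmap.resampling import AnimalVector

    if objects_total < 1:
        raise ValueError("total object count must be >= 1")
    if not 0 <= coloc <= objects_total:
        raise ValueError("need 0 <= coloc <= total")
    vec = AnimalVector(animal_id=animal_id, birthdate=birthdate, factor2=factor2,
                       n_total=objects_total, n_pos=coloc)
    return coloc / objects_total, vec


def polyline_length(points, max_segments: int = 3) -> float:
    """Primary-dendrite length as the sum of 1-3 linear segments (µm)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or not 2 <= pts.shape[0] <= max_segments + 1:
        raise ValueError(f"need 2 to {max_segments + 1} points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
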