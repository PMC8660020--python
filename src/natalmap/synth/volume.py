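"""Synthetic 3D label volumes with planted overlaps.

Two binary channels (e.g. presynaptic puncta vs somata, or two nuclear
markers) are rasterized as ellipsoids on an anisotropic voxel grid.  Ground
truth records per-object voxel counts, the voxel count of every planted
A-B overlap, and the planted number of overlapping object pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from natalmap.anatomy import LabelVolume3D
from natalmap.seeding import child_rng

__all__ = ["Ellipsoid", "VolumeSimParams", "simulate_label_volume"]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in physical coordinates: center (x, y, z) µm,
    radii (rx, ry, rz) µm.  A sphere has equal radii."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("all radii must be positive")

    @classmethod
    def sphere(cls, center: tuple[float, float, float], r: float) -> "Ellipsoid":
        return cls(center=center, radii=(r, r, r))


@dataclass(frozen=True)
class VolumeSimParams:
    """Grid shape is (nx, ny, nz) voxels; voxel_size (dx, dy, dz) µm.

    Give explicit ``objects_a`` / ``objects_b`` lists, or leave them empty
    and set ``planted_overlaps`` (plus ``extra_a`` / ``extra_b`` disjoint
    objects) for seeded random placement with guaranteed separation.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.06, 0.06, 0.41)
    objects_a: tuple[Ellipsoid, ...] = ()
    objects_b: tuple[Ellipsoid, ...] = ()
    planted_overlaps: int = 0
    extra_a: int = 0
    extra_b: int = 0
    radius_um: float = 1.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(d <= 0 for d in self.voxel_size):
            raise ValueError("degenerate grid: shape and voxel_size must be positive")
        object.__setattr__(self, "objects_a", tuple(self.objects_a))
        object.__setattr__(self, "objects_b", tuple(self.objects_b))
        ext = self.extent_um
        for obj in self.objects_a + self.objects_b:
            for c, r, e in zip(obj.center, obj.radii, ext):
                if c - r < 0 or c + r > e:
                    raise ValueError(f"object {obj} does not fit in volume extent {ext}")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape
        dx, dy, dz = self.voxel_size
        return (nx * dx, ny * dy, nz * dz)


def _rasterize(objects: tuple[Ellipsoid, ...], shape, voxel_size) -> tuple[np.ndarray, list[int]]:
    """Binary (nz, ny, nx) mask of the ellipsoid union + per-object voxel counts.

    Voxel centers sit at (i + 0.5) * d along each axis.
    """
    nx, ny, nz = shape
    dx, dy, dz = voxel_size
    mask = np.zeros((nz, ny, nx), dtype=bool)
    counts = []
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    zs = (np.arange(nz) + 0.5) * dz
    for obj in objects:
        cx, cy, cz = obj.center
        rx, ry, rz = obj.radii
        ix = np.flatnonzero(np.abs(xs - cx) <= rx)
        iy = np.flatnonzero(np.abs(ys - cy) <= ry)
        iz = np.flatnonzero(np.abs(zs - cz) <= rz)
        if ix.size == 0 or iy.size == 0 or iz.size == 0:
            counts.append(0)
            continue
        u = ((xs[ix] - cx) / rx) ** 2
        v = ((ys[iy] - cy) / ry) ** 2
        w = ((zs[iz] - cz) / rz) ** 2
        inside = (w[:, None, None] + v[None, :, None] + u[None, None, :]) <= 1.0
        counts.append(int(inside.sum()))
        sub = mask[np.ix_(iz, iy, ix)]
        mask[np.ix_(iz, iy, ix)] = sub | inside
    return mask, counts


def _random_objects(params: VolumeSimParams, seed: int | None):
    """Plant k overlapping A-B pairs plus disjoint extras on a coarse lattice."""
    rng = child_rng(0 if seed is None else seed, "volume")
    r = params.radius_um
    ext = params.extent_um
    pitch = 4.0 * r + 2.0 * max(params.voxel_size)
    sites = []
    for x in np.arange(pitch, ext[0] - pitch / 2, pitch):
        for y in np.arange(pitch, ext[1] - pitch / 2, pitch):
            for z in np.arange(pitch, ext[2] - pitch / 2, pitch):
                sites.append((float(x), float(y), float(z)))
    need = params.planted_overlaps + params.extra_a + params.extra_b
    if len(sites) < need:
        raise ValueError(f"volume too small: {len(sites)} sites for {need} objects")
    picks = rng.permutation(len(sites))[:need]
    objs_a, objs_b = [], []
    k = params.planted_overlaps
    for j, idx in enumerate(picks):
        c = sites[idx]
        if j < k:
            # B shifted by half a radius along x: guaranteed intersection
            objs_a.append(Ellipsoid.sphere(c, r))
            objs_b.append(Ellipsoid.sphere((c[0] + 0.5 * r, c[1], c[2]), r))
        elif j < k + params.extra_a:
            objs_a.append(Ellipsoid.sphere(c, r))
        else:
            objs_b.append(Ellipsoid.sphere(c, r))
    return tuple(objs_a), tuple(objs_b)


def simulate_label_volume(
    params: VolumeSimParams, seed: int | None = None
) -> tuple[LabelVolume3D, LabelVolume3D, dict]:
    """Rasterize the two channels and report ground truth.

    Ground truth keys: ``voxel_counts_a``/``_b`` (per object), ``overlap_voxels``
    (total A∧B voxel count), ``pair_overlap_voxels`` (per planted pair, random
    mode), and ``n_overlap_objects`` (planted count of intersecting pairs).
    """
    objs_a, objs_b = params.objects_a, params.objects_b
    pair_overlaps = None
    n_overlap = None
    if not objs_a and not objs_b:
        if params.planted_overlaps + params.extra_a + params.extra_b == 0:
            raise ValueError("no objects specified")
        objs_a, objs_b = _random_objects(params, seed)
        n_overlap = params.planted_overlaps
        pair_overlaps = []
        for i in range(params.planted_overlaps):
            ma, _ = _rasterize((objs_a[i],), params.shape, params.voxel_size)
            mb, _ = _rasterize((objs_b[i],), params.shape, params.voxel_size)
            pair_overlaps.append(int(np.logical_and(ma, mb).sum()))

    mask_a, counts_a = _rasterize(objs_a, params.shape, params.voxel_size)
    mask_b, counts_b = _rasterize(objs_b, params.shape, params.voxel_size)

    gt = {
        "objects_a": objs_a,
        "objects_b": objs_b,
        "voxel_counts_a": counts_a,
        "voxel_counts_b": counts_b,
        "overlap_voxels": int(np.logical_and(mask_a, mask_b).sum()),
        "pair_overlap_voxels": pair_overlaps,
        "n_overlap_objects": n_overlap,
    }
    vol_a = LabelVolume3D(data=mask_a, voxel_size=params.voxel_size)
    vol_b = LabelVolume3D(data=mask_b, voxel_size=params.voxel_size)
    return vol_a, vol_b, gt
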