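"""Tract lesion burden by streamline filtering.

A white-matter bundle is a set of streamlines (polylines in world mm). A
streamline is *injured* when any point along its trajectory falls inside a
lesion voxel. The tract's lesion burden is the volume occupied by injured
streamlines divided by the volume occupied by the whole (canonical) bundle,
with left/right hemisphere volumes averaged before the ratio is taken, so the
burden is dimensionless in [0, 1].

Geometry conventions (fixed for bit-reproducibility):

* voxel centers sit at integer indices; a world point belongs to the voxel
  whose continuous index is nearest, with exact halves rounded away from zero;
* polylines are resampled so consecutive samples are at most half the smallest
  voxel edge apart, which guarantees no voxel is skipped on straight segments;
* streamline volume is the volume of the set-union of traversed voxels, not a
  per-streamline sum, which makes burden <= 1 provable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "TractBundle",
    "LesionMask",
    "BurdenResult",
    "world_to_voxel",
    "resample_polyline",
    "voxelize",
    "filter_injured",
    "tract_burden",
    "total_lesion_volume",
]


class FrameMismatchError(ValueError):
    """Bundle and mask do not share a world frame."""


class UndefinedBurdenError(ValueError):
    """Canonical tract volume is zero on both sides."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with a voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "affine", _check_affine(self.affine))
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        object.__setattr__(self, "shape", shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_size_mm(self) -> float:
        """Smallest voxel edge length (column norm of the affine)."""
        return float(np.linalg.norm(self.affine[:3, :3], axis=0).min())

    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class TractBundle:
    """Named set of streamlines (polylines, world mm) for one tract side."""

    name: str
    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.streamlines:
            raise ValueError(f"bundle {self.name!r} is empty")
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            sl = np.asarray(sl, dtype=float)
            if sl.ndim != 2 or sl.shape[1] != 3 or sl.shape[0] < 2:
                raise ValueError(
                    f"bundle {self.name!r}: streamline {i} must be an (n>=2, 3) array"
                )
            if not np.all(np.isfinite(sl)):
                raise ValueError(f"bundle {self.name!r}: streamline {i} has non-finite points")
            cleaned.append(sl)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class LesionMask:
    """Binary lesion map on a voxel grid."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = _check_affine(self.affine)
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask grid must be binary (0/1)")
        self.grid = grid.astype(np.uint8)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.grid.shape, affine=self.affine)


@dataclass
class BurdenResult:
    """Per-tract injured/canonical volumes and the burden ratio."""

    tract_name: str
    injured_volume_left: float
    injured_volume_right: float
    canonical_volume_left: float
    canonical_volume_right: float
    n_injured_left: int
    n_injured_right: int
    burden: float
    total_lesion_volume: float


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, exact halves away from zero."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x).astype(np.int64)


def world_to_voxel(points: np.ndarray, grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Map world-mm points to integer voxel indices.

    Returns ``(indices, in_grid)`` where ``in_grid`` flags points whose
    rounded index lies inside ``[0, shape)`` on every axis. Out-of-grid
    points are flagged, never clamped.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite coordinates")
    inv = np.linalg.inv(grid.affine)
    cont = points @ inv[:3, :3].T + inv[:3, 3]
    idx = _round_half_away(cont)
    shape = np.asarray(grid.shape)
    in_grid = np.all((idx >= 0) & (idx < shape), axis=1)
    return idx, in_grid


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Subdivide each segment so consecutive samples are <= ``step`` apart.

    Original vertices are always retained (no corner cutting).
    """
    points = np.asarray(points, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        k = max(int(np.ceil(length / step)), 1)
        t = np.arange(1, k + 1, dtype=float)[:, None] / k
        out.append(a + t * seg)
    return np.concatenate(out, axis=0)


def _voxel_set(streamlines, grid: VoxelGrid, step: float | None = None) -> set[int]:
    """Unique in-grid raveled voxel indices hit by any resampled sample."""
    if step is None:
        step = grid.voxel_size_mm / 2.0
    hit: set[int] = set()
    shape = grid.shape
    for sl in streamlines:
        pts = resample_polyline(np.asarray(sl, dtype=float), step)
        idx, ok = world_to_voxel(pts, grid)
        if not np.any(ok):
            continue
        flat = np.ravel_multi_index(tuple(idx[ok].T), shape)
        hit.update(np.unique(flat).tolist())
    return hit


def voxelize(
    streamlines,
    grid: VoxelGrid,
    step: float | None = None,
    name: str = "bundle",
) -> tuple[set[int], float]:
    """Voxelize streamlines: (set of raveled in-grid voxel indices, volume mm^3).

    Raises if no sample of any streamline lands inside the grid.
    """
    streamlines = list(streamlines)
    if not streamlines:
        raise ValueError("voxelize: no streamlines")
    hit = _voxel_set(streamlines, grid, step)
    if not hit:
        raise ValueError(f"voxelize: all points of {name!r} fall outside the grid")
    return hit, len(hit) * grid.voxel_volume_mm3


def filter_injured(
    bundle: TractBundle, mask: LesionMask, step: float | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Split a bundle into (injured, spared) streamlines.

    A streamline is injured iff at least one resampled point maps to a lesion
    voxel. Order within each part follows the bundle; the two parts form a
    disjoint partition of the bundle.
    """
    grid = mask.voxel_grid()
    if step is None:
        step = grid.voxel_size_mm / 2.0
    injured: list[np.ndarray] = []
    spared: list[np.ndarray] = []
    for sl in bundle.streamlines:
        pts = resample_polyline(sl, step)
        idx, ok = world_to_voxel(pts, grid)
        if np.any(ok) and np.any(mask.grid[tuple(idx[ok].T)] == 1):
            injured.append(sl)
        else:
            spared.append(sl)
    return injured, spared


def _frame_check(mask: LesionMask, grid: VoxelGrid | None) -> VoxelGrid:
    g = mask.voxel_grid()
    if grid is not None:
        if tuple(grid.shape) != tuple(g.shape) or not np.allclose(grid.affine, g.affine):
            raise FrameMismatchError(
                "mask and grid disagree: "
                f"shape {g.shape} vs {grid.shape}, affines "
                f"{'equal' if np.allclose(grid.affine, g.affine) else 'differ'}"
            )
    return g


def tract_burden(
    left: TractBundle | None,
    right: TractBundle | None,
    mask: LesionMask,
    grid: VoxelGrid | None = None,
    tract_name: str | None = None,
) -> BurdenResult:
    """Compute the lesion burden of a bilateral tract.

    burden = mean(injured volume L, R) / mean(canonical volume L, R); volumes
    are union-of-voxel volumes of the injured and full streamline sets. A
    missing side (``None``) contributes zero volume but still counts in the
    two-side mean, so the ratio is unchanged by where mass sits.
    """
    g = _frame_check(mask, grid)
    some = left or right
    if some is None:
        raise UndefinedBurdenError("tract has no streamlines on either side")
    name = tract_name or some.name.rsplit("_", 1)[0]
    step = g.voxel_size_mm / 2.0

    vols = {}
    n_inj = {}
    for side, bundle in (("left", left), ("right", right)):
        if bundle is None:
            vols[side] = (0.0, 0.0)
            n_inj[side] = 0
            continue
        can_set, can_vol = voxelize(bundle.streamlines, g, step, name=bundle.name)
        inj, _ = filter_injured(bundle, mask, step)
        n_inj[side] = len(inj)
        if inj:
            inj_set = _voxel_set(inj, g, step)
            inj_vol = len(inj_set) * g.voxel_volume_mm3
        else:
            inj_vol = 0.0
        vols[side] = (inj_vol, can_vol)

    can_total = vols["left"][1] + vols["right"][1]
    if can_total == 0:
        raise UndefinedBurdenError(f"tract {name!r}: canonical volume is zero on both sides")
    burden = (vols["left"][0] + vols["right"][0]) / can_total

    return BurdenResult(
        tract_name=name,
        injured_volume_left=vols["left"][0],
        injured_volume_right=vols["right"][0],
        canonical_volume_left=vols["left"][1],
        canonical_volume_right=vols["right"][1],
        n_injured_left=n_inj["left"],
        n_injured_right=n_inj["right"],
        burden=float(burden),
        total_lesion_volume=total_lesion_volume(mask),
    )


def total_lesion_volume(mask: LesionMask) -> float:
    """Total lesion volume in mm^3: lesion voxel count x voxel volume."""
    return float(int(mask.grid.sum()) * mask.voxel_volume_mm3)
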