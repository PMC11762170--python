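"""Feature/noise separation and point-cloud sampling utilities.

A spatial element is *positive* when some local stereo-orientation is
present in the 3x3x3 local space centered on it — i.e. at least one of
the 13 simple cells fires there — and *negative* otherwise. Because an
isolated voxel (or any voxel that completes no centered collinear
triple) activates no simple cell, scattered background noise is
negative and can be discarded while object structure is preserved.

Rule variants generalize the positive criterion to the number ``m`` of
active orientation types at an element: ``any`` (m >= 1, the default
separation), ``single`` (m == 1), ``multi`` (2 <= m <= 12) and ``all``
(m == 13). All counts are computed against the original grid before any
removal; elements are judged independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .core_cells import _EXP_CLAMP, DEFAULT_PARAMS, CellParams, VoxelGrid, enumerate_templates
from .recognizer import N_ORIENTATIONS, _neighbor_sum, extract_patch, local_profile

#: a simple cell counts as "active" above this activation; with the
#: default sharp sigmoid the activations are ~0 or ~1, so any cut in
#: (0.1, 0.9) is equivalent
ACTIVE_THRESHOLD = 0.5


@dataclass(frozen=True)
class SeparationRule:
    """Predicate on m = number of active orientation types at an element:
    keep the element iff lo <= m <= hi."""

    name: str
    lo: int
    hi: int

    def applies(self, m):
        m = np.asarray(m)
        out = (m >= self.lo) & (m <= self.hi)
        return bool(out) if out.ndim == 0 else out


RULES: dict[str, SeparationRule] = {
    "any": SeparationRule("any", 1, 13),
    "single": SeparationRule("single", 1, 1),
    "multi": SeparationRule("multi", 2, 12),
    "all": SeparationRule("all", 13, 13),
}


def get_rule(name: str) -> SeparationRule:
    try:
        return RULES[name]
    except KeyError:
        raise ValueError(f"unknown separation rule {name!r}; choose from {sorted(RULES)}") from None


@dataclass(eq=False)
class PointCloud:
    """Point list with optional per-point positive/negative labels."""

    points: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("point coordinates must be finite")
        self.points = pts
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (len(pts),):
                raise ValueError("labels must cover every point")
            if not set(np.unique(labels)) <= {"positive", "negative"}:
                raise ValueError("labels must be 'positive' or 'negative'")
            self.labels = labels

    def __len__(self) -> int:
        return len(self.points)


def orientation_count(
    grid: VoxelGrid, element: Sequence[int], params: CellParams = DEFAULT_PARAMS
) -> int:
    """Number of orientation types (0..13) active in the local space
    centered on ``element``."""
    profile = local_profile(extract_patch(grid, element), params)
    return int((profile > ACTIVE_THRESHOLD).sum())


def is_positive(
    grid: VoxelGrid,
    element: Sequence[int],
    params: CellParams = DEFAULT_PARAMS,
    rule: SeparationRule = RULES["any"],
) -> bool:
    """Whether ``element`` carries local orientation information under
    ``rule``. The default rule keeps an element iff any of its 13 simple
    cells is active."""
    return bool(rule.applies(orientation_count(grid, element, params)))


def active_count_map(grid: VoxelGrid, params: CellParams = DEFAULT_PARAMS) -> np.ndarray:
    """Per-voxel count of active orientation types, vectorized over the
    whole grid (same quantity as :func:`orientation_count` per element)."""
    occ = grid.occupancy.astype(np.float64)
    m = np.zeros(grid.dims, dtype=np.int16)
    for t in enumerate_templates():
        nb = _neighbor_sum(occ, t.direction)
        z = params.k * (occ + nb - params.theta)
        m += expit(np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)) > ACTIVE_THRESHOLD
    return m


def separate(
    grid: VoxelGrid,
    params: CellParams = DEFAULT_PARAMS,
    rule: SeparationRule = RULES["any"],
) -> tuple[VoxelGrid, VoxelGrid]:
    """Partition the occupied set into (positive, negative) grids.

    Positive elements pass the rule predicate on their active-orientation
    count; the two grids are disjoint and union to the input occupancy.
    """
    mask = grid.occupancy.astype(bool)
    keep = rule.applies(active_count_map(grid, params)) & mask
    positive = VoxelGrid(keep.astype(np.uint8))
    negative = VoxelGrid((mask & ~keep).astype(np.uint8))
    return positive, negative


def to_point_cloud(grid: VoxelGrid) -> PointCloud:
    """One point per occupied voxel, integer coordinates preserved."""
    return PointCloud(points=grid.coords().astype(np.float64))


def from_point_cloud(cloud: PointCloud, dims: Sequence[int] | None = None) -> VoxelGrid:
    """Rasterize integer-coordinate points back into a grid (the inverse
    of :func:`to_point_cloud` at the same dims)."""
    pts = np.rint(cloud.points).astype(np.int64)
    if len(pts) and (pts < 0).any():
        raise ValueError("point cloud has negative coordinates; cannot rasterize")
    if dims is None:
        dims = tuple(pts.max(axis=0) + 1) if len(pts) else (1, 1, 1)
    return VoxelGrid.from_coords(pts, dims)


def separate_cloud(
    grid: VoxelGrid,
    params: CellParams = DEFAULT_PARAMS,
    rule: SeparationRule = RULES["any"],
) -> PointCloud:
    """Labeled point cloud of all occupied voxels: positive where the
    element passes the separation rule."""
    positive, _ = separate(grid, params, rule)
    pts = grid.coords()
    labels = np.where(
        positive.occupancy[pts[:, 0], pts[:, 1], pts[:, 2]].astype(bool),
        "positive",
        "negative",
    )
    return PointCloud(points=pts.astype(np.float64), labels=labels)


def _check_sample_args(cloud: PointCloud, n: int) -> None:
    if not 0 <= n <= len(cloud):
        raise ValueError(f"sample size {n} outside 0..{len(cloud)}")


def sample_random(cloud: PointCloud, n: int, seed: int) -> PointCloud:
    """Uniform subset of ``n`` points without replacement, reproducible
    under ``seed``. Original point order is preserved."""
    _check_sample_args(cloud, n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(cloud), size=n, replace=False))
    return PointCloud(
        points=cloud.points[idx],
        labels=None if cloud.labels is None else cloud.labels[idx],
    )


def sample_fps(cloud: PointCloud, n: int, seed: int) -> PointCloud:
    """Greedy farthest point sampling under Euclidean distance.

    The first point is a seeded uniform draw; each subsequent point
    maximizes the distance to the already-selected set (ties to the
    lowest index). Deterministic given ``seed``.
    """
    _check_sample_args(cloud, n)
    if n == 0:
        return PointCloud(points=cloud.points[:0], labels=None)
    rng = np.random.default_rng(seed)
    pts = cloud.points
    selected = np.empty(n, dtype=np.int64)
    selected[0] = rng.integers(len(cloud))
    dist = np.linalg.norm(pts - pts[selected[0]], axis=1)
    for i in range(1, n):
        selected[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(pts - pts[selected[i]], axis=1))
    return PointCloud(
        points=pts[selected],
        labels=None if cloud.labels is None else cloud.labels[selected],
    )
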