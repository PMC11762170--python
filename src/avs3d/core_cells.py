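"""Cell models and the 13-orientation template geometry.

The artificial visual system is a three-stage Hubel-Wiesel cascade over
binary occupancy volumes:

* **depth-selective cells** report the occupancy (0/1) of a single voxel
  position inside a 3x3x3 local space;
* **simple stereo-orientation cells** combine three depth cells whose
  positions form a centered collinear triple, through a sharp sigmoid, so
  each cell fires only when a line fragment with its preferred 3D
  orientation is present;
* **complex stereo-orientation cells** (see :mod:`avs3d.recognizer`) sum
  all same-orientation simple cells across the volume, yielding
  position-invariant global selectivity.

Exactly 13 distinct line orientations pass through the center of a 3x3x3
neighborhood: the 26 non-center neighbors pair up antipodally into 13
directions (3 along the axes, 6 along face diagonals, 4 along body
diagonals). Each orientation template is the centered triple
``{-u, 0, +u}`` for a canonical direction ``u``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import IO, Iterable, Sequence

import numpy as np
from scipy.special import expit

Offset = tuple[int, int, int]

#: v-index of the neighborhood center under the fixed linearization
#: v = 1 + (dx+1) + 3*(dy+1) + 9*(dz+1)  (x fastest, then y, then z, 1-based)
V_CENTER = 14

# exp argument bound; float64 overflows near exp(709)
_EXP_CLAMP = 700.0


def v_index(offset: Offset) -> int:
    """Map a 3x3x3 offset ``(dx, dy, dz)`` with components in {-1, 0, 1}
    to its 1-based v-index (x fastest-varying, then y, then z)."""
    dx, dy, dz = offset
    for c in (dx, dy, dz):
        if c not in (-1, 0, 1):
            raise ValueError(f"offset component {c} outside {{-1,0,1}}")
    return 1 + (dx + 1) + 3 * (dy + 1) + 9 * (dz + 1)


@dataclass(frozen=True)
class CellParams:
    """Shared simple-cell sigmoid constants.

    Parameters
    ----------
    k:
        Response sensitivity (sigmoid steepness), dimensionless. The
        default ``1e4`` makes the activation an effectively binary gate
        on the three depth inputs.
    theta:
        Activation threshold on the summed depth inputs, dimensionless.
        The default ``2.5`` sits strictly between 2 and 3, so with binary
        inputs the cell fires only when its full triple is occupied.
    """

    k: float = 1e4
    theta: float = 2.5

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"sensitivity k must be positive, got {self.k}")


DEFAULT_PARAMS = CellParams()


@dataclass(eq=False)
class VoxelGrid:
    """Dense binary occupancy volume.

    ``occupancy`` is a 3-d uint8 array indexed ``[x, y, z]``; any
    linearized order used by this package (e.g. for noise placement) is
    Fortran order, so x varies fastest. Coordinates outside the grid are
    treated as empty (zero padding).
    """

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.occupancy)
        if arr.ndim != 3:
            raise ValueError(f"occupancy must be 3-d, got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError(f"grid dims must be >=1 on every axis, got {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("occupancy values must be exactly 0 or 1")
        self.occupancy = arr.astype(np.uint8)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.occupancy.shape)  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.size)

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def coords(self) -> np.ndarray:
        """Integer ``(N, 3)`` coordinates of occupied voxels, x fastest."""
        flat = np.flatnonzero(self.occupancy.ravel(order="F"))
        return np.stack(np.unravel_index(flat, self.dims, order="F"), axis=1)

    def contains(self, coord: Sequence[int]) -> bool:
        return all(0 <= int(c) < n for c, n in zip(coord, self.dims))

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.occupancy.copy())

    @classmethod
    def empty(cls, dims: Sequence[int]) -> "VoxelGrid":
        return cls(np.zeros(tuple(int(n) for n in dims), dtype=np.uint8))

    @classmethod
    def from_coords(cls, coords: Iterable[Sequence[int]], dims: Sequence[int]) -> "VoxelGrid":
        grid = cls.empty(dims)
        for c in coords:
            x, y, z = (int(v) for v in c)
            if not grid.contains((x, y, z)):
                raise ValueError(f"coordinate {(x, y, z)} outside dims {grid.dims}")
            grid.occupancy[x, y, z] = 1
        return grid


@dataclass(eq=False)
class LocalPatch:
    """The 3x3x3 neighborhood around one grid element.

    ``values[i-1]`` holds entry ``v_i`` under the fixed v-index
    convention; ``values[V_CENTER - 1]`` is the center. Entries whose
    absolute coordinate falls outside the parent grid are 0.
    """

    center: Offset
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (27,):
            raise ValueError(f"patch must have 27 entries, got shape {vals.shape}")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("patch entries must be exactly 0 or 1")
        self.values = vals.astype(np.uint8)

    def value_at(self, offset: Offset) -> int:
        return int(self.values[v_index(offset) - 1])


@dataclass(frozen=True)
class OrientationTemplate:
    """One of the 13 canonical line directions through the 3x3x3 center.

    ``direction`` is the canonical representative ``u`` (the
    lexicographically larger of ``{u, -u}``); ``member_offsets`` is the
    centered antipodal triple ``(-u, (0,0,0), +u)``.
    """

    id: int
    direction: Offset
    member_offsets: tuple[Offset, Offset, Offset]

    @property
    def orientation_class(self) -> str:
        """'axis', 'face' (face diagonal) or 'body' (body diagonal)."""
        nnz = sum(c != 0 for c in self.direction)
        return {1: "axis", 2: "face", 3: "body"}[nnz]


def canonical_direction(u: Sequence[int]) -> Offset:
    """The canonical representative of the antipodal pair {u, -u}:
    the lexicographically larger tuple."""
    pos = tuple(int(c) for c in u)
    neg = tuple(-c for c in pos)
    return pos if pos > neg else neg


@lru_cache(maxsize=1)
def _templates() -> tuple[OrientationTemplate, ...]:
    candidates = set()
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                u = (dx, dy, dz)
                if u != (0, 0, 0):
                    candidates.add(canonical_direction(u))
    by_class: dict[int, list[Offset]] = {1: [], 2: [], 3: []}
    for u in candidates:
        by_class[sum(c != 0 for c in u)].append(u)
    ordered: list[Offset] = []
    for nnz in (1, 2, 3):  # axes, then face diagonals, then body diagonals
        ordered.extend(sorted(by_class[nnz], reverse=True))
    out = []
    for i, u in enumerate(ordered, start=1):
        neg = tuple(-c for c in u)
        out.append(OrientationTemplate(id=i, direction=u, member_offsets=(neg, (0, 0, 0), u)))
    return tuple(out)


def enumerate_templates() -> list[OrientationTemplate]:
    """The 13 orientation templates in fixed id order.

    Ids 1-3 are the axis directions (+x, +y, +z), 4-9 the face
    diagonals, 10-13 the body diagonals; within each class directions
    are sorted lexicographically descending.
    """
    return list(_templates())


@lru_cache(maxsize=1)
def _direction_to_id() -> dict[Offset, int]:
    return {t.direction: t.id for t in _templates()}


def template_id_for_direction(u: Sequence[int]) -> int:
    """Template id whose orientation matches ``u`` (sign ignored)."""
    key = canonical_direction(u)
    try:
        return _direction_to_id()[key]
    except KeyError:
        raise ValueError(f"{tuple(u)} is not one of the 13 canonical directions") from None


def depth_response(patch: LocalPatch, index: int) -> int:
    """Depth-selective cell activation: the patch entry at v-index
    ``index`` — 1 iff the spatial element exists, else 0."""
    if not 1 <= int(index) <= 27:
        raise ValueError(f"v-index must be in 1..27, got {index}")
    return int(patch.values[int(index) - 1])


def simple_activation(d1: float, d2: float, d3: float, params: CellParams = DEFAULT_PARAMS) -> float:
    """Simple-cell sigmoid activation ``1 / (1 + exp(-k (d1+d2+d3 - theta)))``.

    Numerically stable for the default k = 1e4: the exponent argument is
    clamped to +-700 before exponentiation, and the result lies in [0, 1].
    """
    z = params.k * (float(d1) + float(d2) + float(d3) - params.theta)
    return float(expit(np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)))


def complex_aggregate(activations: Iterable[float]) -> float:
    """Complex-cell response: the plain sum of same-orientation simple-cell
    activations. An empty collection sums to 0."""
    vals = np.asarray(list(activations), dtype=np.float64)
    return float(vals.sum()) if vals.size else 0.0


def templates_to_json(fp: IO[str] | None = None) -> str:
    """Export the template table (id, direction, member offsets) as JSON."""
    table = [
        {
            "id": t.id,
            "class": t.orientation_class,
            "direction": list(t.direction),
            "member_offsets": [list(o) for o in t.member_offsets],
        }
        for t in enumerate_templates()
    ]
    text = json.dumps(table, indent=2)
    if fp is not None:
        fp.write(text)
    return text
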