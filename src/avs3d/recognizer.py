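"""Sliding local-space recognition pipeline.

Every occupied voxel of the input volume is taken as the center of a
3x3x3 local space; the 13 simple stereo-orientation cells are evaluated
on each local space, and one complex cell per orientation sums the
matching simple-cell activations over the whole volume. The complex cell
with the greatest activation indicates the global stereo-orientation.

Only occupied voxels are used as patch centers. This is equivalent to
scanning every position: an unoccupied center contributes a depth sum of
at most 2 < theta, so its simple activation is ~0 at the default
sensitivity (and exactly below 0.5 for any k > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .core_cells import (
    _EXP_CLAMP,
    DEFAULT_PARAMS,
    CellParams,
    LocalPatch,
    OrientationTemplate,
    VoxelGrid,
    enumerate_templates,
    simple_activation,
    v_index,
)

#: Sentinel returned when all 13 complex cells are silent (< 0.5):
#: featureless input carries no orientation to report.
NONE = None

N_ORIENTATIONS = 13


@dataclass(eq=False)
class RecognitionResult:
    """Classification outcome for one volume.

    ``predicted_orientation`` is a template id in 1..13, or ``None``
    (the NONE sentinel) when every complex-cell response is below 0.5.
    Ties are broken to the lowest id. ``responses`` is the unreduced
    13-vector, ``n_centers`` the number of patch centers evaluated.
    """

    responses: np.ndarray
    predicted_orientation: int | None
    n_centers: int

    def to_dict(self) -> dict:
        return {
            "responses": [float(c) for c in self.responses],
            "predicted": self.predicted_orientation,
            "n_centers": self.n_centers,
        }


def extract_patch(grid: VoxelGrid, center: Sequence[int]) -> LocalPatch:
    """Cut the 3x3x3 neighborhood around ``center`` out of ``grid``,
    zero-padding at the boundaries."""
    cx, cy, cz = (int(c) for c in center)
    if not grid.contains((cx, cy, cz)):
        raise ValueError(f"center {(cx, cy, cz)} outside grid dims {grid.dims}")
    vals = np.zeros(27, dtype=np.uint8)
    occ = grid.occupancy
    nx, ny, nz = grid.dims
    for dz in (-1, 0, 1):
        z = cz + dz
        if not 0 <= z < nz:
            continue
        for dy in (-1, 0, 1):
            y = cy + dy
            if not 0 <= y < ny:
                continue
            for dx in (-1, 0, 1):
                x = cx + dx
                if 0 <= x < nx:
                    vals[v_index((dx, dy, dz)) - 1] = occ[x, y, z]
    return LocalPatch(center=(cx, cy, cz), values=vals)


def local_profile(patch: LocalPatch, params: CellParams = DEFAULT_PARAMS) -> np.ndarray:
    """The 13 simple-cell activations for one local space, in template
    id order."""
    out = np.empty(N_ORIENTATIONS, dtype=np.float64)
    for i, t in enumerate(enumerate_templates()):
        d = [patch.value_at(o) for o in t.member_offsets]
        out[i] = simple_activation(d[0], d[1], d[2], params)
    return out


def _shifted(arr: np.ndarray, offset: Sequence[int]) -> np.ndarray:
    """Translate ``arr`` by ``offset`` with zero fill:
    result[p] = arr[p - offset]."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for o, n in zip(offset, arr.shape):
        o = int(o)
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _neighbor_sum(occ: np.ndarray, direction: Sequence[int]) -> np.ndarray:
    """Per-voxel count of occupied antipodal neighbors along ``direction``."""
    neg = tuple(-int(c) for c in direction)
    return _shifted(occ, direction) + _shifted(occ, neg)


def global_response(grid: VoxelGrid, params: CellParams = DEFAULT_PARAMS) -> np.ndarray:
    """Complex-cell response vector: for each of the 13 orientations, the
    sum of simple-cell activations over all occupied patch centers."""
    mask = grid.occupancy.astype(bool)
    out = np.zeros(N_ORIENTATIONS, dtype=np.float64)
    if not mask.any():
        return out
    occ = grid.occupancy.astype(np.float64)
    for i, t in enumerate(enumerate_templates()):
        nb = _neighbor_sum(occ, t.direction)
        z = params.k * (1.0 + nb[mask] - params.theta)  # center d = 1 at occupied voxels
        out[i] = expit(np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)).sum()
    return out


def classify(grid: VoxelGrid, params: CellParams = DEFAULT_PARAMS) -> RecognitionResult:
    """Classify a volume by argmax over the 13 complex-cell responses.

    All responses below 0.5 yield the NONE sentinel; ties go to the
    lowest template id (``np.argmax`` convention).
    """
    responses = global_response(grid, params)
    if responses.max(initial=0.0) < 0.5:
        predicted = NONE
    else:
        predicted = int(np.argmax(responses)) + 1
    return RecognitionResult(
        responses=responses,
        predicted_orientation=predicted,
        n_centers=grid.n_occupied,
    )


def classify_many(
    grids: Iterable[VoxelGrid], params: CellParams = DEFAULT_PARAMS
) -> list[RecognitionResult]:
    return [classify(g, params) for g in grids]


def normalize_responses(
    trace: Sequence[np.ndarray] | np.ndarray, zero_tol: float = 1e-9
) -> np.ndarray:
    """Normalize a response trace cell-by-cell by each cell's maximum
    over the trace.

    A cell whose trace maximum stays below ``zero_tol`` is treated as
    silent and left at zero: the sharp sigmoid leaves sub-1e-300 dust on
    inactive cells, and dividing such a series by its own dust maximum
    would fabricate full-scale activation. Any genuinely active cell has
    at least one simple-cell activation >= 0.5, orders of magnitude
    above the tolerance.
    """
    arr = np.asarray(trace, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValueError("trace must be nonempty")
    maxes = arr.max(axis=0)
    out = np.where(maxes > zero_tol, arr / np.where(maxes > 0, maxes, 1.0), 0.0)
    return out
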