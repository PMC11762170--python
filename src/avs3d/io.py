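"""File formats: dense volumes (.npy), sparse coordinate tables
(CSV/TSV with x,y,z columns), ASCII PLY and XYZ point clouds, and
JSON/CSV reports. All writers round-trip losslessly through the
matching reader; malformed input raises :class:`ParseError` naming the
offending line or field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_cells import VoxelGrid
from .feature_filter import PointCloud


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# dense volumes


def save_volume(path: str | Path, grid: VoxelGrid) -> None:
    np.save(Path(path), grid.occupancy)


def load_volume(path: str | Path) -> VoxelGrid:
    arr = np.load(Path(path))
    try:
        return VoxelGrid(arr)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# sparse coordinate tables


def save_coords(path: str | Path, grid: VoxelGrid) -> None:
    """Write occupied voxels as a CSV/TSV table with x,y,z columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(grid.coords(), columns=["x", "y", "z"]).to_csv(path, sep=sep, index=False)


def load_coords(path: str | Path, dims: Sequence[int] | None = None) -> VoxelGrid:
    """Read a 0-based x,y,z coordinate table; ``dims`` defaults to the
    tight bounding box (max coordinate + 1 per axis)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as e:
        raise ParseError(f"{path}: cannot parse coordinate table ({e})") from e
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: column {col!r} is not numeric")
    coords = df[["x", "y", "z"]].to_numpy()
    if len(coords):
        if not np.all(coords == np.floor(coords)):
            raise ParseError(f"{path}: coordinates must be integers")
        if (coords < 0).any():
            raise ParseError(f"{path}: coordinates must be non-negative (0-based)")
    coords = coords.astype(np.int64)
    if dims is None:
        dims = tuple(coords.max(axis=0) + 1) if len(coords) else (1, 1, 1)
    try:
        return VoxelGrid.from_coords(coords, dims)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# point clouds


def save_xyz(path: str | Path, cloud: PointCloud) -> None:
    np.savetxt(Path(path), cloud.points, fmt="%.6g")


def load_xyz(path: str | Path) -> PointCloud:
    points = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
        try:
            points.append([float(v) for v in parts[:3]])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from None
    return PointCloud(points=np.array(points, dtype=np.float64).reshape(-1, 3))


def save_ply(path: str | Path, cloud: PointCloud) -> None:
    """Write an ASCII PLY vertex cloud (x, y, z float properties)."""
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in cloud.points]
    Path(path).write_text("\n".join(lines) + "\n")


def load_ply(path: str | Path) -> PointCloud:
    """Read an ASCII PLY vertex cloud; x, y, z must be vertex properties."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}: missing 'ply' magic line")
    n_vertex = None
    prop_names: list[str] = []
    in_vertex_element = False
    body_start = None
    for i, raw in enumerate(lines[1:], start=2):
        tok = raw.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise ParseError(f"{path}:{i}: only ascii PLY is supported, got {tok[1]!r}")
        elif tok[0] == "element":
            in_vertex_element = tok[1] == "vertex"
            if in_vertex_element:
                try:
                    n_vertex = int(tok[2])
                except (IndexError, ValueError):
                    raise ParseError(f"{path}:{i}: bad vertex count in {raw!r}") from None
        elif tok[0] == "property" and in_vertex_element:
            prop_names.append(tok[-1])
        elif tok[0] == "end_header":
            body_start = i
            break
    if n_vertex is None or body_start is None:
        raise ParseError(f"{path}: header lacks a vertex element or end_header")
    try:
        cols = [prop_names.index(c) for c in ("x", "y", "z")]
    except ValueError as e:
        raise ParseError(f"{path}: vertex element lacks x/y/z properties") from e
    points = np.empty((n_vertex, 3), dtype=np.float64)
    body = lines[body_start:]
    if len(body) < n_vertex:
        raise ParseError(f"{path}: expected {n_vertex} vertex records, found {len(body)}")
    for r in range(n_vertex):
        parts = body[r].split()
        try:
            points[r] = [float(parts[c]) for c in cols]
        except (IndexError, ValueError):
            raise ParseError(
                f"{path}:{body_start + r + 1}: malformed vertex record {body[r]!r}"
            ) from None
    return PointCloud(points=points)


# ---------------------------------------------------------------------------
# dispatch and reports

VOLUME_EXTS = (".npy", ".csv", ".tsv")
CLOUD_EXTS = (".ply", ".xyz")


def load_any_volume(path: str | Path, dims: Sequence[int] | None = None) -> VoxelGrid:
    """Load a volume by extension: .npy dense, .csv/.tsv sparse coords."""
    suffix = Path(path).suffix.lower()
    if suffix == ".npy":
        return load_volume(path)
    if suffix in (".csv", ".tsv"):
        return load_coords(path, dims)
    raise ParseError(f"{path}: unknown volume extension {suffix!r} (use .npy/.csv/.tsv)")


def load_any_cloud(path: str | Path) -> PointCloud:
    suffix = Path(path).suffix.lower()
    if suffix == ".ply":
        return load_ply(path)
    if suffix == ".xyz":
        return load_xyz(path)
    raise ParseError(f"{path}: unknown point-cloud extension {suffix!r} (use .ply/.xyz)")


def save_cloud(path: str | Path, cloud: PointCloud) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".ply":
        save_ply(path, cloud)
    elif suffix == ".xyz":
        save_xyz(path, cloud)
    else:
        raise ParseError(f"{path}: unknown point-cloud extension {suffix!r} (use .ply/.xyz)")


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
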