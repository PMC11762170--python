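"""Synthetic stimulus and dataset generators.

Three seeded protocols probe the cascade the way physiologists probe
orientation-selective neurons:

* **drift gratings** — periodic bar patterns in a one-voxel-thick
  32x32x1 window at 0/45/90/135 degrees, drifting one voxel per frame
  along either orthogonal direction; each 100-frame motion block is
  followed by a 100-frame blank rest block (4 orientations x 2
  directions x 200 frames = 1600 frames, half grating, half blank);
* **random-dot volumes** — 300 uniformly scattered dots in a 32^3
  volume, with 0..5 "moving dots" each extended one step forward and
  backward along a common direction so that it forms a 3-voxel
  orientation fragment;
* **oriented line/bar objects** — straight runs of 3..9 steps along one
  of the 13 canonical directions at random positions in a 16^3 volume
  (axis-aligned lines may be extruded to 2x2 bars), organized into
  class-balanced train/val/test splits of 15,600 / 5,200 / 5,200
  samples, with optional background noise at 0..5% of the volume's
  voxel count.

All randomness flows through ``numpy.random.default_rng`` seeds recorded
per sample, so every dataset regenerates bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .core_cells import VoxelGrid, enumerate_templates, template_id_for_direction

#: annotation value used in integer columns of blank/rest frames
BLANK = -1

_SEED_MAX = 2**31


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# drift gratings


@dataclass(frozen=True)
class GratingProtocol:
    """Drift-grating stimulus protocol.

    The window is a ``width x height x 1`` voxel plane. Bars of
    ``bar_width`` voxels repeat every ``period`` voxels and drift one
    voxel per frame. ``bar_width=2`` guarantees that only the along-bar
    orientation template fires for all four in-plane orientations
    (wider bars would co-activate perpendicular templates).
    """

    width: int = 32
    height: int = 32
    bar_width: int = 2
    period: int = 8
    frames_per_phase: int = 100
    orientations: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if not 0 < self.bar_width < self.period:
            raise ValueError("bar_width must satisfy 0 < bar_width < period")
        for deg in self.orientations:
            if deg not in (0, 45, 90, 135):
                raise ValueError(f"unsupported grating orientation {deg}")

    @property
    def n_frames(self) -> int:
        # motion block + equal-length blank block, two drift signs each
        return len(self.orientations) * 2 * self.frames_per_phase * 2


#: template id matching each in-plane grating orientation: bars at 0deg
#: run along +x, 90deg along +y, 45deg along (1,1,0), 135deg along (1,-1,0)
GRATING_TEMPLATE_ID = {
    0: template_id_for_direction((1, 0, 0)),
    45: template_id_for_direction((1, 1, 0)),
    90: template_id_for_direction((0, 1, 0)),
    135: template_id_for_direction((1, -1, 0)),
}


def grating_frame(protocol: GratingProtocol, orientation_deg: int, phase: int) -> VoxelGrid:
    """One grating frame: stripes at the given orientation, translated
    by ``phase`` voxels along the drift direction."""
    x = np.arange(protocol.width)[:, None]
    y = np.arange(protocol.height)[None, :]
    if orientation_deg == 0:  # bars along x, drift along y
        q = np.broadcast_to(y, (protocol.width, protocol.height))
    elif orientation_deg == 90:  # bars along y, drift along x
        q = np.broadcast_to(x, (protocol.width, protocol.height))
    elif orientation_deg == 45:  # bars along (1,1)
        q = x - y
    elif orientation_deg == 135:  # bars along (1,-1)
        q = x + y
    else:
        raise ValueError(f"unsupported grating orientation {orientation_deg}")
    occ2d = ((q - phase) % protocol.period) < protocol.bar_width
    return VoxelGrid(occ2d[:, :, None].astype(np.uint8))


@dataclass(eq=False)
class StimulusSequence:
    """Ordered stimulus frames plus per-frame annotations.

    ``frames`` has shape (T, W, H, 1); ``annotations`` columns are
    frame, state ('moving'/'rest'), orientation_deg, template_id, block,
    phase — integer columns hold ``BLANK`` (-1) on rest frames.
    """

    frames: np.ndarray
    annotations: pd.DataFrame
    protocol: GratingProtocol

    def __len__(self) -> int:
        return len(self.frames)

    def grid(self, t: int) -> VoxelGrid:
        return VoxelGrid(self.frames[t])


def gen_grating_sequence(
    protocol: GratingProtocol = GratingProtocol(), seed: int | None = None
) -> StimulusSequence:
    """Generate the full drift-grating sequence.

    The protocol is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators and is unused.
    """
    frames: list[np.ndarray] = []
    rows: list[dict] = []
    blank = np.zeros((protocol.width, protocol.height, 1), dtype=np.uint8)
    block = 0
    for deg in protocol.orientations:
        for sign in (1, -1):
            for t in range(protocol.frames_per_phase):
                frames.append(grating_frame(protocol, deg, sign * t).occupancy)
                rows.append(
                    {
                        "frame": len(frames) - 1,
                        "state": "moving",
                        "orientation_deg": deg,
                        "template_id": GRATING_TEMPLATE_ID[deg],
                        "block": block,
                        "phase": t,
                    }
                )
            for t in range(protocol.frames_per_phase):
                frames.append(blank)
                rows.append(
                    {
                        "frame": len(frames) - 1,
                        "state": "rest",
                        "orientation_deg": BLANK,
                        "template_id": BLANK,
                        "block": block,
                        "phase": t,
                    }
                )
            block += 1
    return StimulusSequence(
        frames=np.stack(frames), annotations=pd.DataFrame(rows), protocol=protocol
    )


# ---------------------------------------------------------------------------
# random-dot volumes


@dataclass(frozen=True)
class RandomDotConfig:
    """Random-dot protocol: ``n_dots`` uniform dots per 3D sample, of
    which ``n_moving`` are extended into centered 3-voxel orientation
    fragments; ``n_samples`` samples per condition."""

    volume_dims: tuple[int, int, int] = (32, 32, 32)
    n_dots: int = 300
    n_moving: int = 0
    n_samples: int = 1300

    def __post_init__(self) -> None:
        if self.n_moving < 0 or self.n_moving > self.n_dots:
            raise ValueError("need 0 <= n_moving <= n_dots")
        if self.n_dots > int(np.prod(self.volume_dims)):
            raise ValueError("more dots than voxels")


def gen_random_dot_sample(
    config: RandomDotConfig, label: int, seed
) -> tuple[VoxelGrid, int]:
    """One random-dot volume: ``n_dots`` uniform dots; ``n_moving`` of
    them gain neighbors at p+u and p-u where u is the ``label``
    direction (dots are picked among those whose full triple fits inside
    the volume)."""
    if not 1 <= label <= 13:
        raise ValueError(f"label must be a template id 1..13, got {label}")
    rng = _as_rng(seed)
    dims = config.volume_dims
    total = int(np.prod(dims))
    flat = rng.choice(total, size=config.n_dots, replace=False)
    coords = np.stack(np.unravel_index(flat, dims, order="F"), axis=1)
    occ = np.zeros(dims, dtype=np.uint8)
    occ[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
    if config.n_moving > 0:
        u = np.array(enumerate_templates()[label - 1].direction)
        lo_ok = ((coords + u) >= 0).all(axis=1) & ((coords - u) >= 0).all(axis=1)
        hi_ok = ((coords + u) < dims).all(axis=1) & ((coords - u) < dims).all(axis=1)
        candidates = np.flatnonzero(lo_ok & hi_ok)
        if len(candidates) < config.n_moving:
            raise ValueError(
                f"volume {dims} too small to fit {config.n_moving} triples along {tuple(u)}"
            )
        chosen = rng.choice(candidates, size=config.n_moving, replace=False)
        for p in coords[chosen]:
            for q in (p + u, p - u):
                occ[q[0], q[1], q[2]] = 1
    return VoxelGrid(occ), label


# ---------------------------------------------------------------------------
# oriented line/bar object datasets


@dataclass(frozen=True)
class ObjectDatasetConfig:
    """Oriented-object dataset: 13 classes (the canonical directions),
    lengths 3..9, thickness 1 lines everywhere plus 2x2-section bars for
    the axis-aligned classes, in a 16^3 volume."""

    volume_dims: tuple[int, int, int] = (16, 16, 16)
    lengths: tuple[int, ...] = tuple(range(3, 10))
    thicknesses: tuple[int, ...] = (1, 2)
    train_size: int = 15_600
    val_size: int = 5_200
    test_size: int = 5_200
    noise_intensities: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)

    def __post_init__(self) -> None:
        for name, size in self.split_sizes.items():
            if size % 13 != 0:
                raise ValueError(f"{name} split size {size} not divisible by 13 classes")
        if max(self.lengths) > min(self.volume_dims):
            raise ValueError("longest object cannot fit inside the volume")
        if not set(self.thicknesses) <= {1, 2}:
            raise ValueError("thicknesses must be a subset of {1, 2}")

    @property
    def split_sizes(self) -> dict[str, int]:
        return {"train": self.train_size, "val": self.val_size, "test": self.test_size}


def gen_object(
    config: ObjectDatasetConfig,
    class_id: int,
    length: int,
    thickness: int = 1,
    seed=None,
) -> tuple[VoxelGrid, int]:
    """One straight line/bar object: ``length`` unit steps along the
    class direction from a uniformly drawn anchor, entirely inside the
    volume. ``thickness=2`` extrudes an axis-aligned line into a 2x2
    cross-section bar."""
    if not 1 <= class_id <= 13:
        raise ValueError(f"class_id must be 1..13, got {class_id}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    template = enumerate_templates()[class_id - 1]
    u = np.array(template.direction)
    if thickness == 2 and template.orientation_class != "axis":
        raise ValueError("thickness-2 bars are defined for axis-aligned classes only")
    if thickness not in (1, 2):
        raise ValueError(f"thickness must be 1 or 2, got {thickness}")
    rng = _as_rng(seed)
    dims = config.volume_dims
    perp = [a for a in range(3) if u[a] == 0] if thickness == 2 else []
    lo = np.zeros(3, dtype=np.int64)
    hi = np.array(dims, dtype=np.int64) - 1
    for a in range(3):
        if u[a] == 1:
            hi[a] -= length - 1
        elif u[a] == -1:
            lo[a] += length - 1
        if a in perp:
            hi[a] -= 1  # room for the +1 extrusion offset
    if (lo > hi).any():
        raise ValueError(
            f"object (class {class_id}, length {length}, thickness {thickness}) "
            f"does not fit inside volume {dims}"
        )
    anchor = np.array([int(rng.integers(lo[a], hi[a] + 1)) for a in range(3)])
    occ = np.zeros(dims, dtype=np.uint8)
    offsets = [np.zeros(3, dtype=np.int64)]
    if thickness == 2:
        a1, a2 = perp
        for o1 in (0, 1):
            for o2 in (0, 1):
                if o1 or o2:
                    off = np.zeros(3, dtype=np.int64)
                    off[a1], off[a2] = o1, o2
                    offsets.append(off)
    for i in range(length):
        base = anchor + i * u
        for off in offsets:
            p = base + off
            occ[p[0], p[1], p[2]] = 1
    return VoxelGrid(occ), class_id


@dataclass(eq=False)
class LabeledDataset:
    """Seeded object dataset: a manifest of per-sample metadata from
    which every volume regenerates deterministically.

    Manifest columns: split, class_id, length, thickness, sample_seed.
    """

    config: ObjectDatasetConfig
    manifest: pd.DataFrame

    def n_samples(self, split: str) -> int:
        return int((self.manifest["split"] == split).sum())

    def materialize(self, row: pd.Series) -> tuple[VoxelGrid, int]:
        return gen_object(
            self.config,
            class_id=int(row["class_id"]),
            length=int(row["length"]),
            thickness=int(row["thickness"]),
            seed=int(row["sample_seed"]),
        )

    def iter_split(self, split: str) -> Iterator[tuple[VoxelGrid, int]]:
        sub = self.manifest[self.manifest["split"] == split]
        if sub.empty:
            raise ValueError(f"unknown or empty split {split!r}")
        for _, row in sub.iterrows():
            yield self.materialize(row)

    def save(self, out_dir: str | Path, volumes: bool = False) -> None:
        """Write manifest.csv + config.json; with ``volumes=True`` also
        one dense .npz (stacked volumes + labels) per split."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        cfg = {k: getattr(self.config, k) for k in self.config.__dataclass_fields__}
        (out / "config.json").write_text(json.dumps(cfg, indent=2))
        if volumes:
            for split in self.config.split_sizes:
                grids, labels = [], []
                for grid, label in self.iter_split(split):
                    grids.append(grid.occupancy)
                    labels.append(label)
                np.savez_compressed(
                    out / f"{split}.npz",
                    volumes=np.stack(grids),
                    labels=np.array(labels, dtype=np.int64),
                )

    @classmethod
    def load(cls, in_dir: str | Path) -> "LabeledDataset":
        path = Path(in_dir)
        cfg = json.loads((path / "config.json").read_text())
        config = ObjectDatasetConfig(
            volume_dims=tuple(cfg["volume_dims"]),
            lengths=tuple(cfg["lengths"]),
            thicknesses=tuple(cfg["thicknesses"]),
            train_size=cfg["train_size"],
            val_size=cfg["val_size"],
            test_size=cfg["test_size"],
            noise_intensities=tuple(cfg["noise_intensities"]),
        )
        manifest = pd.read_csv(path / "manifest.csv")
        return cls(config=config, manifest=manifest)


def gen_dataset(config: ObjectDatasetConfig, seed: int) -> LabeledDataset:
    """Build the class-balanced manifest for all splits under one master
    seed. Lengths are uniform over ``config.lengths``; axis classes draw
    their thickness uniformly from ``config.thicknesses``, diagonal
    classes are always thickness-1 lines."""
    rng = np.random.default_rng(seed)
    axis_ids = {t.id for t in enumerate_templates() if t.orientation_class == "axis"}
    rows = []
    for split, size in config.split_sizes.items():
        per_class = size // 13
        class_ids = np.tile(np.arange(1, 14), per_class)
        lengths = rng.choice(config.lengths, size=size)
        thick_draw = rng.choice(config.thicknesses, size=size)
        for cid, length, thick in zip(class_ids, lengths, thick_draw):
            rows.append(
                {
                    "split": split,
                    "class_id": int(cid),
                    "length": int(length),
                    "thickness": int(thick) if cid in axis_ids else 1,
                    "sample_seed": int(rng.integers(_SEED_MAX)),
                }
            )
    return LabeledDataset(config=config, manifest=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# background noise


def inject_noise(grid: VoxelGrid, intensity_percent: float, seed) -> VoxelGrid:
    """Add background noise: ``round(intensity/100 * total voxels)``
    distinct currently-empty voxels are set to 1; object voxels are
    untouched. Intensity is a percentage of the TOTAL volume voxel
    count, placed uniformly among empty voxels."""
    if not 0 <= intensity_percent <= 100:
        raise ValueError(f"intensity must be in 0..100, got {intensity_percent}")
    n_noise = int(round(intensity_percent / 100.0 * grid.n_voxels))
    if n_noise == 0:
        return grid.copy()
    rng = _as_rng(seed)
    flat = grid.occupancy.ravel(order="F")
    empty = np.flatnonzero(flat == 0)
    if len(empty) < n_noise:
        raise ValueError(f"only {len(empty)} empty voxels; cannot add {n_noise} noise voxels")
    chosen = rng.choice(empty, size=n_noise, replace=False)
    out = flat.copy()
    out[chosen] = 1
    return VoxelGrid(out.reshape(grid.dims, order="F"))
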