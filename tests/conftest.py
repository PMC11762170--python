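"""Shared fixtures and the independent brute-force oracle.

The oracle enumerates centered collinear voxel triples by direct loops
over occupied coordinates and over the 13 canonical directions (derived
here from scratch by antipodal pairing of the 26 neighbor offsets), so
it shares no code path with the vectorized implementation it checks.
"""

import itertools

import numpy as np
import pytest

from avs3d import ObjectDatasetConfig, VoxelGrid, gen_dataset


def brute_canonical_directions() -> list[tuple[int, int, int]]:
    """All 13 line directions through a 3x3x3 center, one per antipodal
    pair, derived independently of the package's template table."""
    dirs = []
    for u in itertools.product((-1, 0, 1), repeat=3):
        if u == (0, 0, 0):
            continue
        if u >= tuple(-c for c in u):  # keep one representative per pair
            dirs.append(u)
    assert len(dirs) == 13
    return dirs


def brute_triple_counts(occ: np.ndarray) -> dict[tuple[int, int, int], int]:
    """Per-direction count of occupied voxels whose both antipodal
    neighbors along that direction are occupied and in bounds."""
    dims = occ.shape
    counts = {u: 0 for u in brute_canonical_directions()}
    for x, y, z in zip(*np.nonzero(occ)):
        for u in counts:
            fwd = (x + u[0], y + u[1], z + u[2])
            bwd = (x - u[0], y - u[1], z - u[2])
            if all(0 <= c < n for c, n in zip(fwd, dims)) and all(
                0 <= c < n for c, n in zip(bwd, dims)
            ):
                if occ[fwd] and occ[bwd]:
                    counts[u] += 1
    return counts


def brute_positive_set(occ: np.ndarray) -> set[tuple[int, int, int]]:
    """Occupied voxels that are the center of at least one triple."""
    dims = occ.shape
    positive = set()
    for x, y, z in zip(*np.nonzero(occ)):
        for u in brute_canonical_directions():
            fwd = (x + u[0], y + u[1], z + u[2])
            bwd = (x - u[0], y - u[1], z - u[2])
            if all(0 <= c < n for c, n in zip(fwd, dims)) and all(
                0 <= c < n for c, n in zip(bwd, dims)
            ):
                if occ[fwd] and occ[bwd]:
                    positive.add((x, y, z))
                    break
    return positive


def random_grid(rng: np.random.Generator, max_dim: int = 8) -> VoxelGrid:
    dims = tuple(int(rng.integers(1, max_dim + 1)) for _ in range(3))
    density = rng.uniform(0.05, 0.5)
    return VoxelGrid((rng.random(dims) < density).astype(np.uint8))


@pytest.fixture(scope="session")
def small_dataset():
    """Class-balanced 130-samples-per-split dataset for fast checks."""
    config = ObjectDatasetConfig(train_size=130, val_size=130, test_size=130)
    return gen_dataset(config, seed=7)
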