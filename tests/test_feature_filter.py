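"""Positive/negative information separation and point-cloud sampling."""

import numpy as np
import pytest

from avs3d import (
    RULES,
    PointCloud,
    VoxelGrid,
    get_rule,
    is_positive,
    orientation_count,
    sample_fps,
    sample_random,
    separate,
    to_point_cloud,
)
from avs3d.feature_filter import active_count_map, from_point_cloud, separate_cloud

from conftest import brute_positive_set, random_grid


def segment_plus_lattice_noise():
    """L=5 x-segment plus 10 isolated noise voxels spaced so that no
    accidental centered triple can form (pairwise gaps >= 2 on some axis
    from everything else)."""
    grid = VoxelGrid.empty((32, 16, 16))
    segment = [(i, 1, 1) for i in range(1, 6)]
    noise = [(3 * i + 1, 8, 3 * ((i * 7) % 4) + 6) for i in range(10)]
    for c in segment + noise:
        grid.occupancy[c] = 1
    assert grid.n_occupied == 15
    return grid, segment, noise


class TestOrientationCount:
    def test_isolated_voxel_has_no_orientation(self):
        grid = VoxelGrid.from_coords([(2, 2, 2)], dims=(5, 5, 5))
        assert orientation_count(grid, (2, 2, 2)) == 0

    def test_segment_interior_has_exactly_one(self):
        grid = VoxelGrid.from_coords([(i, 2, 2) for i in range(1, 6)], dims=(8, 8, 8))
        assert orientation_count(grid, (3, 2, 2)) == 1
        assert orientation_count(grid, (1, 2, 2)) == 0  # endpoint

    def test_full_block_center_has_all_thirteen(self):
        grid = VoxelGrid(np.ones((3, 3, 3), dtype=np.uint8))
        assert orientation_count(grid, (1, 1, 1)) == 13

    def test_rejects_element_outside_grid(self):
        with pytest.raises(ValueError):
            orientation_count(VoxelGrid.empty((3, 3, 3)), (3, 1, 1))


class TestRules:
    def test_rule_bounds(self):
        assert get_rule("any").applies(1) and get_rule("any").applies(13)
        assert not get_rule("any").applies(0)
        assert get_rule("single").applies(1) and not get_rule("single").applies(2)
        assert get_rule("multi").applies(2) and get_rule("multi").applies(12)
        assert not get_rule("multi").applies(13)
        assert get_rule("all").applies(13) and not get_rule("all").applies(12)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            get_rule("most")

    def test_is_positive_rule_variants(self):
        grid = VoxelGrid.from_coords([(i, 2, 2) for i in range(1, 6)], dims=(8, 8, 8))
        interior = (3, 2, 2)
        assert is_positive(grid, interior, rule=RULES["any"])
        assert is_positive(grid, interior, rule=RULES["single"])
        assert not is_positive(grid, interior, rule=RULES["all"])
        assert not is_positive(grid, (1, 2, 2), rule=RULES["any"])  # endpoint

    @pytest.mark.parametrize("seed", range(4))
    def test_exactly_one_rule_class_per_element(self, seed):
        grid = random_grid(np.random.default_rng(seed), max_dim=6)
        m = active_count_map(grid)[grid.occupancy.astype(bool)]
        zero = m == 0
        single = RULES["single"].applies(m)
        multi = RULES["multi"].applies(m)
        allr = RULES["all"].applies(m)
        assert np.all(zero.astype(int) + single + multi + allr == 1)
        assert np.array_equal(RULES["any"].applies(m), single | multi | allr)


class TestSeparate:
    def test_segment_interior_kept_noise_discarded(self):
        grid, segment, noise = segment_plus_lattice_noise()
        positive, negative = separate(grid)
        pos = {tuple(c) for c in positive.coords()}
        neg = {tuple(c) for c in negative.coords()}
        assert pos == set(segment[1:-1])  # 3 interior voxels
        assert neg == {segment[0], segment[-1]} | set(noise)

    def test_empty_grid_separates_to_empty(self):
        positive, negative = separate(VoxelGrid.empty((4, 4, 4)))
        assert positive.n_occupied == 0 and negative.n_occupied == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_brute_force(self, seed):
        grid = random_grid(np.random.default_rng(seed), max_dim=6)
        positive, negative = separate(grid)
        assert {tuple(c) for c in positive.coords()} == brute_positive_set(grid.occupancy)
        # disjoint union of the occupied set
        assert np.all(positive.occupancy + negative.occupancy == grid.occupancy)

    def test_full_block_all_interior_positive(self):
        grid = VoxelGrid(np.ones((5, 5, 5), dtype=np.uint8))
        positive, _ = separate(grid)
        assert {tuple(c) for c in positive.coords()} == brute_positive_set(grid.occupancy)

    @pytest.mark.parametrize("seed", range(4))
    def test_adding_voxels_never_flips_positive_to_negative(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_grid(rng, max_dim=6)
        positive_before, _ = separate(grid)
        extra = grid.occupancy.copy()
        empty = np.argwhere(extra == 0)
        if len(empty):
            add = empty[rng.choice(len(empty), size=min(5, len(empty)), replace=False)]
            extra[add[:, 0], add[:, 1], add[:, 2]] = 1
        positive_after, _ = separate(VoxelGrid(extra))
        assert np.all(positive_after.occupancy >= positive_before.occupancy)

    def test_vectorized_counts_agree_with_per_element_path(self):
        grid, _, _ = segment_plus_lattice_noise()
        m = active_count_map(grid)
        for c in map(tuple, grid.coords()):
            assert m[c] == orientation_count(grid, c)

    def test_labeled_cloud_covers_every_element(self):
        grid, segment, noise = segment_plus_lattice_noise()
        cloud = separate_cloud(grid)
        assert len(cloud) == grid.n_occupied
        lookup = {tuple(p.astype(int)): lab for p, lab in zip(cloud.points, cloud.labels)}
        assert all(lookup[c] == "positive" for c in segment[1:-1])
        assert all(lookup[c] == "negative" for c in noise)


class TestPointCloud:
    def test_round_trip_grid_cloud_grid(self):
        grid = VoxelGrid.from_coords([(0, 1, 2), (3, 3, 3), (5, 0, 1)], dims=(6, 6, 6))
        back = from_point_cloud(to_point_cloud(grid), dims=grid.dims)
        assert np.array_equal(back.occupancy, grid.occupancy)

    def test_rejects_bad_shapes_and_labels(self):
        with pytest.raises(ValueError):
            PointCloud(points=np.zeros((3, 2)))
        with pytest.raises(ValueError):
            PointCloud(points=np.array([[np.inf, 0, 0]]))
        with pytest.raises(ValueError):
            PointCloud(points=np.zeros((2, 3)), labels=np.array(["positive"]))


class TestSampling:
    @pytest.fixture
    def cloud(self):
        rng = np.random.default_rng(11)
        return PointCloud(points=rng.uniform(0, 20, size=(40, 3)))

    def test_random_sampling_is_seeded_and_bounded(self, cloud):
        a = sample_random(cloud, 10, seed=3)
        b = sample_random(cloud, 10, seed=3)
        assert np.array_equal(a.points, b.points)
        assert len(sample_random(cloud, 0, seed=0)) == 0
        assert len(sample_random(cloud, len(cloud), seed=0)) == len(cloud)
        with pytest.raises(ValueError):
            sample_random(cloud, len(cloud) + 1, seed=0)

    def test_fps_on_a_segment_hits_the_extremes(self):
        pts = np.array([[float(i), 0.0, 0.0] for i in range(10)])
        out = sample_fps(PointCloud(points=pts), 2, seed=5)
        xs = sorted(out.points[:, 0])
        # whatever the seeded start, the second pick is an extreme, and
        # the pair spans at least half the segment
        assert xs[1] in (0.0, 9.0) or xs[0] in (0.0, 9.0)
        assert xs[1] - xs[0] >= 4.5

    def test_fps_full_subset_and_determinism(self, cloud):
        full = sample_fps(cloud, len(cloud), seed=2)
        assert len(full) == len(cloud)
        assert {tuple(p) for p in full.points} == {tuple(p) for p in cloud.points}
        again = sample_fps(cloud, 7, seed=9)
        assert np.array_equal(again.points, sample_fps(cloud, 7, seed=9).points)

    def test_fps_spreads_wider_than_random(self):
        """FPS subsets have no smaller minimum pairwise distance than
        random subsets, on average (Monte-Carlo check)."""

        def min_pairwise(points):
            d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
            return d[np.triu_indices(len(points), k=1)].min()

        rng = np.random.default_rng(0)
        wins = 0
        trials = 20
        for s in range(trials):
            cloud = PointCloud(points=rng.uniform(0, 10, size=(60, 3)))
            fps = min_pairwise(sample_fps(cloud, 8, seed=s).points)
            rnd = min_pairwise(sample_random(cloud, 8, seed=s).points)
            wins += fps >= rnd
        assert wins >= trials * 0.9
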