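"""Seed-area detection, propagation, and geodesic depth."""

import networkx as nx
import numpy as np
import pytest

from rootgrowth.alignment import AlignedSeries, RigidMotion
from rootgrowth.seed_depth import (
    SeedArea,
    SeedMode,
    _neighborhood_sphericity,
    compute_depth,
    detect_seed,
    propagate_seed,
)
from rootgrowth.voxel_model import TimeSeries, VoxelShape, build_graph

from conftest import random_connected_shape


def ball_coords(center, r):
    c = np.asarray(center)
    rr = int(np.ceil(r))
    out = [
        c + np.array([x, y, z])
        for x in range(-rr, rr + 1)
        for y in range(-rr, rr + 1)
        for z in range(-rr, rr + 1)
        if x * x + y * y + z * z <= r * r
    ]
    return np.array(out)


def cylinder_coords(radius, z0, z1):
    rr = int(np.ceil(radius))
    return np.array(
        [
            (x, y, z)
            for z in range(z0, z1)
            for x in range(-rr, rr + 1)
            for y in range(-rr, rr + 1)
            if x * x + y * y <= radius * radius
        ]
    )


class TestDetectSeed:
    def test_ball_on_thin_cylinder_found_by_pca(self):
        # a large ball sitting on a thin stalk: the ball is the seed
        ball = ball_coords((0, 0, 0), 8)
        stalk = np.array([(0, 0, -z) for z in range(8, 60)])
        shape = VoxelShape(np.vstack([ball, stalk]), 1.0)
        # the ball is a large part of this toy shape, so allow it half the volume
        seed = detect_seed(shape, R=4.0, max_fraction=0.5)
        assert seed.mode == SeedMode.PCA
        zs = seed.coords()[:, 2]
        assert zs.min() >= -14  # confined to the ball plus its collar
        assert seed.n > 100

    def test_sphericity_matches_brute_force(self):
        shape = VoxelShape(ball_coords((0, 0, 0), 6), 1.0)
        R = 3.0
        ratios, fill = _neighborhood_sphericity(shape.coords, R)
        pts = shape.coords.astype(float)
        rng = np.random.default_rng(0)
        for i in rng.choice(shape.n, 10, replace=False):
            nb = pts[np.linalg.norm(pts - pts[i], axis=1) <= R]
            cov = np.cov(nb.T, bias=True)
            ev = np.linalg.eigvalsh(cov)
            assert ratios[i] == pytest.approx(ev[0] / ev[2], abs=1e-9)

    def test_thin_cylinder_falls_back_to_top_slice(self):
        shape = VoxelShape(np.array([(0, 0, -z) for z in range(40)]), 1.0)
        seed = detect_seed(shape, R=3.0)
        assert seed.mode == SeedMode.FALLBACK_TOP_SLICE
        assert seed.n == 1
        assert seed.coords()[0, 2] == 0  # topmost slice

    def test_solid_ball_alone_trips_fraction_guard(self):
        shape = VoxelShape(ball_coords((0, 0, 0), 7), 1.0)
        seed = detect_seed(shape, R=3.0, max_fraction=0.25)
        assert seed.mode == SeedMode.FALLBACK_TOP_SLICE


class TestPropagateSeed:
    def _aligned_identity(self, shapes):
        return AlignedSeries(
            series=TimeSeries(shapes),
            motions=[RigidMotion.identity() for _ in shapes],
        )

    def test_identity_nested(self):
        big = cylinder_coords(2, -30, 1)
        small = cylinder_coords(2, -15, 1)
        sT = VoxelShape(big, 1.0, 1)
        s0 = VoxelShape(small, 1.0, 0)
        seed_T = detect_seed(sT, R=3.0)
        aligned = self._aligned_identity([s0, sT])
        (seed_0,) = propagate_seed(seed_T, aligned)
        assert seed_0.mode == SeedMode.PROPAGATED
        assert set(map(tuple, seed_0.coords())) <= set(map(tuple, small))
        # seed voxels exist in both shapes; identity motions keep them put
        assert set(map(tuple, seed_0.coords())) == set(map(tuple, seed_T.coords()))

    def test_translated_series_tracks_seed(self):
        big = cylinder_coords(2, -30, 1)
        shift = np.array([7, -3, 2])
        sT = VoxelShape(big, 1.0, 1)
        s0 = VoxelShape(big + shift, 1.0, 0)
        # motion M_00 maps shape 0 into the common frame: undo the shift
        m0 = RigidMotion(np.eye(3), -shift.astype(float))
        aligned = AlignedSeries(
            series=TimeSeries([s0, sT]), motions=[m0, RigidMotion.identity()]
        )
        seed_T = detect_seed(sT, R=3.0)
        (seed_0,) = propagate_seed(seed_T, aligned)
        c_true = seed_T.points().mean(axis=0) + shift
        assert np.linalg.norm(seed_0.points().mean(axis=0) - c_true) < 1.0

    def test_missing_seed_region_still_nonempty(self):
        # earlier shape lacks the seed-area voxels entirely
        sT = VoxelShape(cylinder_coords(2, -30, 1), 1.0, 1)
        s0 = VoxelShape(cylinder_coords(2, -30, -10), 1.0, 0)
        seed_T = detect_seed(sT, R=3.0)  # near the top, absent from s0
        aligned = self._aligned_identity([s0, sT])
        (seed_0,) = propagate_seed(seed_T, aligned)
        assert seed_0.n >= 1


class TestComputeDepth:
    def test_chain_depths(self):
        shape = VoxelShape(np.array([(0, 0, -k) for k in range(11)]), 1.0)
        g = build_graph(shape)
        idx_top = int(np.nonzero(shape.coords[:, 2] == 0)[0][0])
        seed = SeedArea(shape=shape, indices=np.array([idx_top]), mode=SeedMode.PCA)
        depth = compute_depth(g, seed)
        zs = -shape.coords[:, 2]
        assert np.allclose(depth.values, zs.astype(float))

    def test_diagonal_step_contributes_sqrt2(self):
        coords = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 2]])  # last step is edge-diagonal
        shape = VoxelShape(coords, 1.0)
        g = build_graph(shape)
        i0 = int(np.nonzero((shape.coords == [0, 0, 0]).all(axis=1))[0][0])
        i2 = int(np.nonzero((shape.coords == [0, 1, 2]).all(axis=1))[0][0])
        seed = SeedArea(shape=shape, indices=np.array([i0]), mode=SeedMode.PCA)
        depth = compute_depth(g, seed)
        assert depth.values[i2] == pytest.approx(1.0 + np.sqrt(2))

    def test_all_seed_zero_and_lipschitz(self):
        shape = VoxelShape(random_connected_shape(np.random.default_rng(5), 200), 1.0)
        g = build_graph(shape)
        seed = SeedArea(shape=shape, indices=np.arange(shape.n), mode=SeedMode.PCA)
        depth = compute_depth(g, seed)
        assert np.all(depth.values == 0.0)

    def test_lipschitz_along_arcs(self):
        shape = VoxelShape(random_connected_shape(np.random.default_rng(6), 300), 1.0)
        g = build_graph(shape)
        seed = SeedArea(shape=shape, indices=np.array([0]), mode=SeedMode.PCA)
        depth = compute_depth(g, seed)
        i, j = g.arcs[:, 0], g.arcs[:, 1]
        assert np.all(np.abs(depth.values[i] - depth.values[j]) <= g.weights + 1e-9)

    def test_unreachable_voxel_raises(self):
        coords = np.array([[0, 0, 0], [0, 0, 1], [9, 9, 9]])
        shape = VoxelShape(coords, 1.0)
        g = build_graph(shape)
        seed = SeedArea(shape=shape, indices=np.array([0]), mode=SeedMode.PCA)
        with pytest.raises(ValueError, match="unreachable"):
            compute_depth(g, seed)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_independent_dijkstra(self, trial):
        """Multi-source geodesic depth equals an independent graph-library
        shortest path on random connected shapes (up to 1000 voxels)."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(50, 1000))
        shape = VoxelShape(random_connected_shape(rng, n), 0.5)
        g = build_graph(shape)
        k = int(rng.integers(1, 4))
        seed_idx = np.unique(rng.integers(0, shape.n, size=k))
        seed = SeedArea(shape=shape, indices=seed_idx, mode=SeedMode.PCA)
        depth = compute_depth(g, seed)

        G = nx.Graph()
        G.add_nodes_from(range(shape.n))
        for (i, j), w in zip(g.arcs, g.weights):
            G.add_edge(int(i), int(j), weight=float(w))
        G.add_node("virtual")
        for s in seed_idx:
            G.add_edge("virtual", int(s), weight=0.0)
        dist = nx.single_source_dijkstra_path_length(G, "virtual")
        expected = np.array([dist[i] for i in range(shape.n)])
        assert np.allclose(depth.values, expected, atol=1e-9)


def test_vertical_cylinder_bottom_depth_exact():
    """For a straight vertical one-voxel column the bottom voxel's depth is
    the column height times the edge length, exactly."""
    h = 25
    shape = VoxelShape(np.array([(0, 0, -k) for k in range(h + 1)]), 0.5)
    g = build_graph(shape)
    top = int(np.nonzero(shape.coords[:, 2] == 0)[0][0])
    bottom = int(np.nonzero(shape.coords[:, 2] == -h)[0][0])
    seed = SeedArea(shape=shape, indices=np.array([top]), mode=SeedMode.PCA)
    depth = compute_depth(g, seed)
    assert depth.values[bottom] == pytest.approx(h * 0.5)
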