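"""Shared fixtures: synthetic series, analyzed pipelines, random-shape helpers."""

from __future__ import annotations

import numpy as np
import pytest

from rootgrowth.pipeline import PipelineConfig, analyze
from rootgrowth.synthetic import (
    BranchSpec,
    validation_root_specs,
    generate_series,
    straight_branch_spec,
    straight_curve,
    tilt_profile_curve,
)

EDGE = 0.5


def random_connected_shape(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected voxel cloud grown by attaching 26-neighbours."""
    offsets = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)]
    )
    cells = {(0, 0, 0)}
    voxlist = [(0, 0, 0)]
    while len(cells) < n:
        base = voxlist[rng.integers(len(voxlist))]
        off = offsets[rng.integers(len(offsets))]
        cand = (base[0] + off[0], base[1] + off[1], base[2] + off[2])
        if cand not in cells:
            cells.add(cand)
            voxlist.append(cand)
    return np.array(sorted(cells), dtype=np.int64)


def random_lattice_tree(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random voxel set whose 26-connectivity graph is a tree: each new voxel
    must touch exactly one existing voxel."""
    offsets = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)]
    )
    cells = {(0, 0, 0)}
    voxlist = [(0, 0, 0)]
    tries = 0
    while len(cells) < n and tries < 200 * n:
        tries += 1
        base = voxlist[rng.integers(len(voxlist))]
        off = offsets[rng.integers(len(offsets))]
        cand = (base[0] + off[0], base[1] + off[1], base[2] + off[2])
        if cand in cells:
            continue
        touches = sum(
            (cand[0] + o[0], cand[1] + o[1], cand[2] + o[2]) in cells for o in offsets
        )
        if touches == 1:
            cells.add(cand)
            voxlist.append(cand)
    return np.array(sorted(cells), dtype=np.int64)


def outgrowth_specs() -> list[BranchSpec]:
    """Trunk + old side branch A + late branch B that out-grows A (but not
    the trunk): the depth hierarchy at A's fork picks the wrong through-
    branch, requiring exactly one switch repair."""
    trunk = BranchSpec(
        "trunk", straight_curve((0, 0, 0), 80.0), 1.2, {0: 70.0, 1: 74.0, 2: 78.0}
    )
    A = BranchSpec(
        "A",
        tilt_profile_curve(trunk.curve.point_at(20.0), 0.0, 50.0, 10.0, 45.0, decay=30.0),
        1.1,
        {0: 28.0, 1: 31.0, 2: 33.0},
        parent="trunk",
        attach_s=20.0,
    )
    B = BranchSpec(
        "B",
        tilt_profile_curve(A.curve.point_at(10.0), 140.0, 45.0, 5.0, 42.0, decay=25.0),
        1.0,
        {1: 5.0, 2: 40.0},
        parent="A",
        attach_s=10.0,
    )
    return [trunk, A, B]


@pytest.fixture(scope="session")
def straight_series():
    return generate_series(straight_branch_spec(), edge_length=EDGE)


@pytest.fixture(scope="session")
def straight_result(straight_series):
    series, truth, _ = straight_series
    return analyze(series, PipelineConfig(edge_length=EDGE, rng_seed=1)), truth


@pytest.fixture(scope="session")
def validation_small_series():
    return generate_series(validation_root_specs(scale=0.5), edge_length=EDGE)


@pytest.fixture(scope="session")
def validation_small_result(validation_small_series):
    series, truth, _ = validation_small_series
    return analyze(series, PipelineConfig(edge_length=EDGE, rng_seed=2)), truth


@pytest.fixture(scope="session")
def outgrowth_result():
    series, truth, _ = generate_series(outgrowth_specs(), edge_length=0.7)
    return analyze(series, PipelineConfig(edge_length=0.7, rng_seed=3))
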