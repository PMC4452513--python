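"""Structural and dynamic per-branch traits of a growth record.

For every branch and every acquisition time the sublevel set of the time
function (the part of the branch that existed at that time) yields: volume,
tip depth and location, length, tortuosity, average radius, the angles to
gravity and to the parent branch, the number of children, and whether the
branch out-grew its parent.  Branch axes are the major principal component
of the member voxel cloud; axes are orientation-less so angles are folded
into [0, 90] degrees.  Per-branch records aggregate to whole-root-system
totals and to growth increments between acquisitions, and the hierarchy
plus the seed area give a provisional biological classification of each
branch (primary / seminal / crown / lateral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branches import Branch
from .seed_depth import SeedArea
from .timefn import GrowthRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TraitRecord",
    "SeedTraits",
    "branch_traits",
    "trait_table",
    "aggregate_traits",
    "growth_increments",
    "seed_traits",
    "classify_branches",
]

_UP = np.array([0.0, 0.0, 1.0])


@dataclass
class TraitRecord:
    branch_id: int
    t: int
    volume: int  # voxel count
    volume_mm3: float
    depth_of_tip: float  # mm
    tip_xyz: tuple[float, float, float]  # mm, common frame
    length: float  # mm
    switch_event: bool
    tortuosity: float  # >= 1 up to discretization
    average_radius: float  # mm, nan when length degenerate
    angle_to_gravity: float  # degrees in [0, 90]
    angle_to_parent: float  # degrees in [0, 90]; 0 for the topmost branch
    n_children: int


@dataclass
class SeedTraits:
    seed_volume: int
    seed_orientation: float  # degrees in [0, 90]
    volume_fraction: float
    degenerate: bool


def _major_axis(points: np.ndarray) -> np.ndarray | None:
    if points.shape[0] < 2:
        return None
    c = points - points.mean(axis=0)
    cov = (c.T @ c) / points.shape[0]
    w, v = np.linalg.eigh(cov)
    if w[2] <= 1e-12:
        return None
    return v[:, 2]


def _folded_angle(axis: np.ndarray | None, reference: np.ndarray) -> float:
    """Angle between orientation-less axes, folded into [0, 90] degrees."""
    if axis is None:
        return 0.0
    cosang = abs(float(axis @ reference)) / (
        np.linalg.norm(axis) * np.linalg.norm(reference)
    )
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _branch_geometry(record: GrowthRecord, b: Branch, t: int):
    """(members_at_t, tip_at_t, length, chord) or None when empty at t."""
    mem = record.sublevel(b, t)
    if mem.size == 0:
        return None
    phi = record.depth.values
    # a branch has emerged at t only when it carries material beyond its
    # fork; junction-surface voxels alone (time-stamped through a
    # neighbouring branch's match) do not constitute a branch yet
    if b.fork is not None and phi[mem].max() <= phi[b.fork]:
        return None
    # tip at t: deepest member, lexicographic tie-break via stable argmax
    tip = int(mem[np.argmax(phi[mem])])
    pts = record.world_points()
    if b.fork is not None:
        length = float(phi[tip] - phi[b.fork])
        chord = float(np.linalg.norm(pts[tip] - pts[b.fork]))
    else:
        # topmost branch: measured from its seed-side end
        length = float(phi[tip])
        base = int(mem[np.argmin(phi[mem])])
        chord = float(np.linalg.norm(pts[tip] - pts[base]))
    return mem, tip, length, chord


def branch_traits(record: GrowthRecord, branch_id: int, t: int) -> TraitRecord | None:
    """Traits of one branch at one time; None when the branch does not yet
    exist at t."""
    b = record.hierarchy.branch(branch_id)
    geom = _branch_geometry(record, b, t)
    if geom is None:
        return None
    mem, tip, length, chord = geom
    phi = record.depth.values
    edge = record.shape.edge_length
    pts = record.world_points()
    volume = int(mem.size)
    volume_mm3 = volume * edge**3

    tortuosity = length / chord if chord > 1e-9 else float("nan")
    average_radius = (
        float(np.sqrt(volume_mm3 / (np.pi * length))) if length > 1e-9 else float("nan")
    )
    axis = _major_axis(pts[mem])
    angle_gravity = _folded_angle(axis, _UP)

    if b.parent is None:
        angle_parent = 0.0
        switch_event = False
    else:
        parent = record.hierarchy.branch(b.parent)
        pgeom = _branch_geometry(record, parent, t)
        if pgeom is None:
            # parent not yet present at t (can happen after switches)
            angle_parent = 0.0
            switch_event = True
        else:
            pmem, _, plength, _ = pgeom
            paxis = _major_axis(pts[pmem])
            angle_parent = _folded_angle(axis, paxis) if paxis is not None else 0.0
            switch_event = length > plength

    n_children = sum(
        1
        for cid in record.hierarchy.children.get(branch_id, [])
        if record.sublevel(record.hierarchy.branch(cid), t).size > 0
    )
    return TraitRecord(
        branch_id=branch_id,
        t=t,
        volume=volume,
        volume_mm3=volume_mm3,
        depth_of_tip=float(phi[tip]),
        tip_xyz=tuple(float(c) for c in pts[tip]),
        length=length,
        switch_event=bool(switch_event),
        tortuosity=float(tortuosity),
        average_radius=average_radius,
        angle_to_gravity=angle_gravity,
        angle_to_parent=angle_parent,
        n_children=n_children,
    )


def trait_table(record: GrowthRecord) -> pd.DataFrame:
    """All per-branch, per-time trait records as a tidy DataFrame."""
    rows = []
    for b in record.hierarchy.branches:
        for t in range(record.T + 1):
            rec = branch_traits(record, b.id, t)
            if rec is None:
                continue
            row = rec.__dict__.copy()
            tip = row.pop("tip_xyz")
            row["tip_x"], row["tip_y"], row["tip_z"] = tip
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_traits(record: GrowthRecord, t: int) -> dict[str, float]:
    """Whole-root-system totals at time t."""
    total_volume = 0
    total_volume_mm3 = 0.0
    total_length = 0.0
    n_branches = 0
    for b in record.hierarchy.branches:
        rec = branch_traits(record, b.id, t)
        if rec is None:
            continue
        n_branches += 1
        total_volume += rec.volume
        total_volume_mm3 += rec.volume_mm3
        total_length += rec.length
    total_avg_radius = (
        float(np.sqrt(total_volume_mm3 / (np.pi * total_length)))
        if total_length > 1e-9
        else float("nan")
    )
    return {
        "t": t,
        "n_branches": n_branches,
        "total_volume": total_volume,
        "total_volume_mm3": total_volume_mm3,
        "total_length": total_length,
        "total_average_radius": total_avg_radius,
    }


def growth_increments(record: GrowthRecord) -> pd.DataFrame:
    """Differences of the aggregate traits between consecutive times."""
    aggs = [aggregate_traits(record, t) for t in range(record.T + 1)]
    df = pd.DataFrame(aggs)
    inc = df.drop(columns=["t"]).diff().iloc[1:]
    inc.insert(0, "t_from", df["t"].iloc[:-1].to_numpy())
    inc.insert(1, "t_to", df["t"].iloc[1:].to_numpy())
    return inc.reset_index(drop=True)


def seed_traits(seed: SeedArea, shape=None) -> SeedTraits:
    """Volume, orientation and volume fraction of the seed area."""
    shape = shape if shape is not None else seed.shape
    pts = seed.points()
    degenerate = False
    orientation = 0.0
    if pts.shape[0] >= 2:
        c = pts - pts.mean(axis=0)
        cov = (c.T @ c) / pts.shape[0]
        w, v = np.linalg.eigh(cov)
        if w[2] <= 1e-12 or (w[2] - w[0]) / w[2] < 0.05:
            degenerate = True
        else:
            orientation = _folded_angle(v[:, 2], _UP)
    else:
        degenerate = True
    return SeedTraits(
        seed_volume=seed.n,
        seed_orientation=orientation,
        volume_fraction=seed.n / shape.n,
        degenerate=degenerate,
    )


def classify_branches(record: GrowthRecord, seed: SeedArea | None = None) -> dict[int, str]:
    """Provisional geometric classification of each branch.

    The topmost branch is the primary root; branches forking inside the
    seed area are seminal; branches forking above the seed area's bounding
    box are crown; everything else is lateral.  The rule is geometric and
    provisional — crown roots frequently emerge above the reconstructed
    volume, where geometry alone cannot identify them.
    """
    seed = seed if seed is not None else record.seed
    seed_set = set(map(int, seed.indices))
    seed_top_z = record.shape.coords[seed.indices][:, 2].max()
    out: dict[int, str] = {}
    for b in record.hierarchy.branches:
        if b.parent is None:
            out[b.id] = "primary"
        elif int(b.fork) in seed_set:
            out[b.id] = "seminal"
        elif record.shape.coords[b.fork, 2] > seed_top_z:
            out[b.id] = "crown"
        else:
            out[b.id] = "lateral"
    return out
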