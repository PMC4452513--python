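"""Ground-truthed synthetic root systems: balls swept along parametric curves.

A synthetic branch is a tube: the set of voxels whose centers lie within a
radius of a 3D curve, truncated at a per-timepoint tip arc length.  Branch
curves are built from tilt profiles (a tilt angle to the vertical that
changes along the arc — roots emerge at an angle and bend towards gravity)
or as helices (root waving/coiling), so the models resemble the root
systems the pipeline is meant for while every geometric trait — arc length,
chord, tortuosity, swept volume — is known analytically from the curve.

Series built from a set of branch specifications are nested by
construction (a root system only adds material), loop-free in
specification space, and may be perturbed by known random rigid motions to
exercise the alignment stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .alignment import RigidMotion
from .voxel_model import TimeSeries, VoxelShape

logger = logging.getLogger(__name__)

__all__ = [
    "Curve",
    "BranchSpec",
    "sweep_branch",
    "generate_series",
    "ground_truth",
    "evaluate_against_truth",
    "straight_branch_spec",
    "validation_root_specs",
    "curved_validation_specs",
]

_DOWN = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class Curve:
    """Arc-length parametrized polyline (mm); dense enough that polyline
    arc length equals curve arc length to well below voxel resolution."""

    points: np.ndarray
    cumlen: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("curve needs an (M, 3) point array")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cumlen", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def length(self) -> float:
        return float(self.cumlen[-1])

    def point_at(self, s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.cumlen, s, side="right")) - 1
        i = min(i, self.points.shape[0] - 2) if self.points.shape[0] > 1 else 0
        if self.points.shape[0] == 1:
            return self.points[0]
        seg = self.cumlen[i + 1] - self.cumlen[i]
        f = 0.0 if seg <= 0 else (s - self.cumlen[i]) / seg
        return (1 - f) * self.points[i] + f * self.points[i + 1]

    def tangent_at(self, s: float) -> np.ndarray:
        if self.points.shape[0] < 2:
            return _DOWN
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.cumlen, s, side="right")) - 1
        i = min(max(i, 0), self.points.shape[0] - 2)
        d = self.points[i + 1] - self.points[i]
        n = np.linalg.norm(d)
        return d / n if n > 0 else _DOWN

    def truncated(self, s: float) -> np.ndarray:
        """Polyline points up to arc length s (tip point included)."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.cumlen, s, side="right"))
        return np.concatenate([self.points[:i], self.point_at(s)[None, :]], axis=0)


def _integrate_directions(start, dirs: np.ndarray, step: float) -> Curve:
    pts = np.concatenate(
        [np.asarray(start, dtype=float)[None, :], np.cumsum(dirs * step, axis=0) + start]
    )
    return Curve(pts)


def tilt_profile_curve(
    start,
    azimuth_deg: float,
    tilt_from_deg: float,
    tilt_to_deg: float,
    length: float,
    decay: float | None = None,
    step: float = 0.05,
) -> Curve:
    """Planar curve whose tilt to the vertical varies along the arc.

    With ``decay`` the tilt relaxes exponentially from ``tilt_from_deg``
    towards ``tilt_to_deg`` with the given decay arc length (gravitropic
    bending); without it the tilt varies linearly (a circular arc).
    """
    n = max(1, int(np.ceil(length / step)))
    s = (np.arange(n) + 0.5) * (length / n)
    if decay is None:
        tilt = np.radians(tilt_from_deg + (tilt_to_deg - tilt_from_deg) * s / length)
    else:
        tilt = np.radians(
            tilt_to_deg + (tilt_from_deg - tilt_to_deg) * np.exp(-s / decay)
        )
    az = np.radians(azimuth_deg)
    dirs = np.stack(
        [np.sin(tilt) * np.cos(az) * np.ones_like(s),
         np.sin(tilt) * np.sin(az) * np.ones_like(s),
         -np.cos(tilt)],
        axis=1,
    )
    return _integrate_directions(start, dirs, length / n)


def helix_curve(
    start,
    pitch_angle_deg: float,
    turns: float,
    length: float,
    phase_deg: float = 0.0,
    step: float = 0.05,
) -> Curve:
    """Downward helix with a constant angle to the vertical."""
    n = max(1, int(np.ceil(length / step)))
    s = (np.arange(n) + 0.5) * (length / n)
    alpha = np.radians(pitch_angle_deg)
    omega = 2 * np.pi * turns / length
    phase = np.radians(phase_deg)
    dirs = np.stack(
        [np.sin(alpha) * np.cos(omega * s + phase),
         np.sin(alpha) * np.sin(omega * s + phase),
         -np.cos(alpha) * np.ones_like(s)],
        axis=1,
    )
    return _integrate_directions(start, dirs, length / n)


def straight_curve(start, length: float, direction=(0.0, 0.0, -1.0), step: float = 0.5) -> Curve:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    n = max(1, int(np.ceil(length / step)))
    s = np.linspace(0.0, length, n + 1)
    return Curve(np.asarray(start, dtype=float)[None, :] + s[:, None] * d[None, :])


@dataclass
class BranchSpec:
    """One synthetic branch: a curve, a radius profile and a growth schedule.

    ``schedule`` maps acquisition index t to the tip arc length at t; the
    branch exists from the smallest scheduled t on and the schedule must be
    non-decreasing.  ``radius`` is a constant or an ``(r_start, r_end)``
    pair tapering linearly along the full curve.
    """

    name: str
    curve: Curve
    radius: float | tuple[float, float]
    schedule: dict[int, float]
    parent: str | None = None
    attach_s: float = 0.0

    def __post_init__(self) -> None:
        r0, r1 = self.radius_pair()
        if r0 <= 0 or r1 <= 0:
            raise ValueError(f"branch {self.name}: radius must be positive")
        ts = sorted(self.schedule)
        lens = [self.schedule[t] for t in ts]
        if any(b < a - 1e-12 for a, b in zip(lens, lens[1:])):
            raise ValueError(f"branch {self.name}: growth schedule must be non-decreasing")
        if lens and lens[-1] > self.curve.length + 1e-9:
            raise ValueError(f"branch {self.name}: schedule exceeds curve length")

    def radius_pair(self) -> tuple[float, float]:
        if isinstance(self.radius, tuple):
            return float(self.radius[0]), float(self.radius[1])
        return float(self.radius), float(self.radius)

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        r0, r1 = self.radius_pair()
        L = max(self.curve.length, 1e-12)
        return r0 + (r1 - r0) * np.clip(np.asarray(s, dtype=float) / L, 0.0, 1.0)

    @property
    def appearance_t(self) -> int:
        return min(self.schedule)

    def tip_arclen(self, t: int) -> float | None:
        """Tip arc length at time t (None before appearance; frozen at the
        last scheduled value afterwards)."""
        ts = sorted(self.schedule)
        if t < ts[0]:
            return None
        past = [u for u in ts if u <= t]
        return float(self.schedule[past[-1]])


def _validate_specs(specs: list[BranchSpec]) -> dict[str, BranchSpec]:
    by_name = {}
    for s in specs:
        if s.name in by_name:
            raise ValueError(f"duplicate branch name {s.name!r}")
        by_name[s.name] = s
    for s in specs:
        if s.parent is None:
            continue
        if s.parent not in by_name:
            raise ValueError(f"branch {s.name}: unknown parent {s.parent!r}")
        # parent links must be acyclic (specs violate A2 otherwise)
        seen, cur = {s.name}, s.parent
        while cur is not None:
            if cur in seen:
                raise ValueError("specs violate A2: parent links form a loop")
            seen.add(cur)
            cur = by_name[cur].parent
        parent = by_name[s.parent]
        t0 = s.appearance_t
        plen = parent.tip_arclen(t0)
        if plen is None:
            raise ValueError(f"branch {s.name}: appears before its parent {s.parent}")
        if s.attach_s > plen + 1e-9:
            raise ValueError(
                f"branch {s.name}: attaches at arc length {s.attach_s} beyond "
                f"parent tip ({plen}) at its appearance"
            )
        if s.schedule[t0] >= plen - 1e-9:
            raise ValueError(
                f"specs violate A3: branch {s.name} is not shorter than its "
                f"parent when it first appears"
            )
        anchor = parent.curve.point_at(s.attach_s)
        if np.linalg.norm(s.curve.points[0] - anchor) > 1e-6:
            raise ValueError(
                f"branch {s.name}: curve must start on the parent axis at attach_s"
            )
    return by_name


def sweep_branch(spec: BranchSpec, t: int, edge_length: float) -> np.ndarray:
    """Voxels (integer grid coords) of one branch truncated at time t.

    A voxel is included when its center lies within the (possibly tapering)
    radius of the truncated curve; both ends are therefore capped with
    hemispheres.  Deterministic.
    """
    s_tip = spec.tip_arclen(t)
    if s_tip is None:
        return np.empty((0, 3), dtype=np.int64)
    r0, r1 = spec.radius_pair()
    rmax = max(r0, r1)
    if rmax < edge_length / 2:
        logger.warning(
            "branch %s: radius %.3f mm below half a voxel edge; tube may disconnect",
            spec.name, rmax,
        )
    poly = spec.curve.truncated(s_tip)
    # resample densely so nearest-sample distance approximates curve distance
    dense_step = edge_length / 8
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total > 0:
        s_dense = np.arange(0.0, total + dense_step / 2, dense_step)
        dense = np.stack([np.interp(s_dense, cum, poly[:, k]) for k in range(3)], axis=1)
    else:
        s_dense = np.zeros(1)
        dense = poly[:1]
    radii = spec.radius_at(s_dense)  # dense samples sit at these arc positions
    lo = np.floor((dense.min(axis=0) - rmax) / edge_length).astype(np.int64) - 1
    hi = np.ceil((dense.max(axis=0) + rmax) / edge_length).astype(np.int64) + 1
    gx, gy, gz = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    grid = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = grid.astype(float) * edge_length
    tree = cKDTree(dense)
    d, idx = tree.query(centers, k=1)
    inside = d <= radii[idx]
    return grid[inside]


def _swept_volume(spec: BranchSpec, t: int, by_name: dict[str, BranchSpec]) -> tuple[float, float]:
    """(cylinder volume, cap/junction-corrected swept volume) in mm^3.

    The cylinder volume is pi * integral r(s)^2 ds along the grown part of
    the curve; the swept solid additionally has hemispherical caps at both
    ends, minus the part of the tube buried inside the parent branch at the
    junction (computed by walking the curve until it leaves the parent
    tube).
    """
    s_tip = spec.tip_arclen(t)
    if s_tip is None:
        return 0.0, 0.0
    n = max(2, int(np.ceil(s_tip / 0.05)))
    s = np.linspace(0.0, s_tip, n)
    r = spec.radius_at(s)
    v_cyl = float(np.pi * np.trapezoid(r**2, s))
    r_start, r_tip = float(r[0]), float(r[-1])
    v = v_cyl + (2.0 / 3.0) * np.pi * (r_start**3 + r_tip**3)
    if spec.parent is not None:
        parent = by_name[spec.parent]
        ptree = cKDTree(parent.curve.points)
        pts = np.stack([spec.curve.point_at(si) for si in np.arange(0.0, min(s_tip, 20.0), 0.1)])
        d, idx = ptree.query(pts, k=1)
        p_r = parent.radius_at(parent.curve.cumlen[np.minimum(idx, parent.curve.cumlen.size - 1)])
        outside = np.nonzero(d > p_r)[0]
        buried_len = 0.1 * (outside[0] if outside.size else pts.shape[0])
        buried_len = min(buried_len, s_tip)
        v -= np.pi * r_start**2 * buried_len + (2.0 / 3.0) * np.pi * r_start**3
    return v_cyl, max(v, 0.0)


def ground_truth(specs: list[BranchSpec], T: int) -> pd.DataFrame:
    """Analytic per-branch, per-time geometry of a specification set."""
    by_name = _validate_specs(specs)
    rows = []
    for spec in specs:
        for t in range(T + 1):
            s_tip = spec.tip_arclen(t)
            if s_tip is None:
                continue
            tip = spec.curve.point_at(s_tip)
            base = spec.curve.points[0]
            chord = float(np.linalg.norm(tip - base))
            v_cyl, v_swept = _swept_volume(spec, t, by_name)
            tangent = spec.curve.tangent_at(0.0)
            emergence = float(np.degrees(np.arccos(np.clip(-tangent[2], -1.0, 1.0))))
            r0, r1 = spec.radius_pair()
            rows.append(
                {
                    "branch": spec.name,
                    "t": t,
                    "arc_length": s_tip,
                    "chord": chord,
                    "tortuosity": s_tip / chord if chord > 1e-9 else float("nan"),
                    "volume_cylinder": v_cyl,
                    "volume_swept": v_swept,
                    "radius": 0.5 * (r0 + r1),
                    "emergence_angle_deg": emergence,
                    "parent": spec.parent if spec.parent is not None else "",
                    "appearance_t": spec.appearance_t,
                    "tip_x": float(tip[0]),
                    "tip_y": float(tip[1]),
                    "tip_z": float(tip[2]),
                }
            )
    return pd.DataFrame(rows)


def _random_motion(rng: np.random.Generator, max_angle_deg: float, max_translation: float) -> RigidMotion:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.2 * max_angle_deg, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    trans = rng.uniform(-max_translation, max_translation, size=3)
    return RigidMotion(R, trans)


def generate_series(
    specs: list[BranchSpec],
    edge_length: float,
    T: int | None = None,
    seed_ball: tuple[tuple[float, float, float], float] | None = None,
    perturb: bool = False,
    max_angle_deg: float = 30.0,
    max_translation_mm: float = 8.0,
    dropout: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[TimeSeries, pd.DataFrame, list[RigidMotion]]:
    """Voxelize a specification set into a nested time-series.

    Returns the series, the analytic ground-truth table, and the list of
    true motions M_0t mapping each (possibly perturbed) shape back into the
    frame of the first shape.  With ``perturb`` every shape after the first
    is moved by a random rigid motion before re-voxelization, to exercise
    the alignment stage.  Identical seeds yield identical series.
    """
    by_name = _validate_specs(specs)
    if T is None:
        T = max(max(s.schedule) for s in specs)
    rng = np.random.default_rng(seed)
    truth = ground_truth(specs, T)

    shapes: list[VoxelShape] = []
    true_motions: list[RigidMotion] = []
    for t in range(T + 1):
        parts = [sweep_branch(s, t, edge_length) for s in specs]
        parts = [p for p in parts if p.shape[0] > 0]
        if seed_ball is not None:
            (cx, cy, cz), r = seed_ball
            ball_spec = BranchSpec(
                name="__seed__",
                curve=Curve(np.array([[cx, cy, cz]])),
                radius=r,
                schedule={0: 0.0},
            )
            parts.append(sweep_branch(ball_spec, t, edge_length))
        if not parts:
            raise ValueError(f"no branch exists at t={t}")
        coords = np.unique(np.concatenate(parts, axis=0), axis=0)
        if dropout > 0:
            keep = rng.random(coords.shape[0]) >= dropout
            coords = coords[keep]
        motion = RigidMotion.identity()
        if perturb and t > 0:
            applied = _random_motion(rng, max_angle_deg, max_translation_mm)
            pts = applied.apply(coords.astype(float) * edge_length)
            coords = np.unique(np.round(pts / edge_length).astype(np.int64), axis=0)
            motion = applied.inverse()  # maps observed shape back to true frame
        shapes.append(VoxelShape(coords, edge_length, time_index=t))
        true_motions.append(motion)
    return TimeSeries(shapes), truth, true_motions


# ---------------------------------------------------------------------------
# stock specification sets


def straight_branch_spec(
    length: float = 63.8, radius: float = 1.5
) -> list[BranchSpec]:
    """A single ball swept along a straight vertical segment."""
    return [
        BranchSpec(
            name="r0",
            curve=straight_curve((0.0, 0.0, 0.0), length + 1e-9),
            radius=radius,
            schedule={0: length},
        )
    ]


def validation_root_specs(scale: float = 1.0) -> list[BranchSpec]:
    """Three-timepoint caricature of a growing root system.

    Seven branches: a straight vertical primary, three first-order
    gravitropic laterals present from the start, and three later laterals
    appearing at t = 1 and t = 2 while still shorter than their parents.
    Branch lengths per timepoint and radii follow the hand-measured
    validation geometry (primary growing 63.8 -> 95.2 mm, radii 1.5 / 1.0 /
    0.885 / 0.685 mm).  ``scale`` shrinks all lengths for fast tests.
    """
    f = scale

    def sched(d: dict[int, float]) -> dict[int, float]:
        return {t: v * f for t, v in d.items()}

    r0 = BranchSpec(
        name="r0",
        curve=straight_curve((0.0, 0.0, 0.0), 96.0 * f),
        radius=1.5,
        schedule=sched({0: 63.8, 1: 71.1, 2: 95.22}),
    )
    specs = [r0]

    def lateral(name, parent_spec, attach, azim, tilt0, decay, schedule, radius):
        start = parent_spec.curve.point_at(attach * f)
        curve = tilt_profile_curve(
            start, azimuth_deg=azim, tilt_from_deg=tilt0, tilt_to_deg=8.0,
            length=max(schedule.values()) * f + 2.0, decay=decay * f,
        )
        return BranchSpec(
            name=name, curve=curve, radius=radius, schedule=sched(schedule),
            parent=parent_spec.name, attach_s=attach * f,
        )

    r1 = lateral("r1", r0, 2.0, 10.0, 45.0, 40.0, {0: 35.77, 1: 76.11, 2: 102.68}, 1.0)
    r2 = lateral("r2", r0, 4.0, 137.0, 55.0, 35.0, {0: 42.98, 1: 66.77, 2: 99.06}, 1.0)
    r6 = lateral("r6", r0, 10.0, 230.0, 50.0, 45.0, {0: 27.49, 1: 35.01, 2: 53.73}, 1.0)
    r3 = lateral("r3", r2, 30.0, 80.0, 55.0, 40.0, {1: 7.0, 2: 37.55}, 0.885)
    r5 = lateral("r5", r6, 22.0, 300.0, 60.0, 35.0, {1: 4.3, 2: 27.83}, 0.685)
    r4 = lateral("r4", r1, 55.0, 190.0, 50.0, 40.0, {2: 9.27}, 0.685)
    specs.extend([r1, r2, r6, r3, r5, r4])
    return specs


def curved_validation_specs() -> list[list[BranchSpec]]:
    """Single curved branches with analytic tortuosity: three gravitropic /
    circular arcs of increasing emergence tilt and two gentle helices."""
    out: list[list[BranchSpec]] = []
    arcs = [
        (35.0, 5.0, 70.0, 20.0),
        (50.0, 10.0, 60.0, 0.0),
        (45.0, 0.0, 65.0, 300.0),
    ]
    for tilt0, tilt1, length, azim in arcs:
        curve = tilt_profile_curve(
            (0.0, 0.0, 0.0), azimuth_deg=azim, tilt_from_deg=tilt0,
            tilt_to_deg=tilt1, length=length + 1.0,
        )
        out.append(
            [BranchSpec(name="arc", curve=curve, radius=1.5, schedule={0: length})]
        )
    helices = [(15.0, 1.0, 70.0), (20.0, 1.5, 60.0)]
    for pitch, turns, length in helices:
        curve = helix_curve((0.0, 0.0, 0.0), pitch_angle_deg=pitch, turns=turns,
                            length=length + 1.0)
        out.append(
            [BranchSpec(name="helix", curve=curve, radius=1.5, schedule={0: length})]
        )
    return out


# ---------------------------------------------------------------------------
# validation against ground truth


_COMPARED = {
    "length": "arc_length",
    "tortuosity": "tortuosity",
    "volume_mm3": "volume_swept",
    "average_radius": "radius",
}


def evaluate_against_truth(
    trait_df: pd.DataFrame, truth: pd.DataFrame, match_gate_mm: float = 6.0
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Relative errors of computed traits against the generator's truth.

    Branches are matched to truth branches by final-time tip proximity
    (optimal one-to-one assignment, gated).  Returns the long error table,
    the mean relative error per trait, and the list of unmatched truth
    branches (misses).
    """
    t_final = int(truth["t"].max())
    truth_final = truth[truth["t"] == t_final]
    traits_final = trait_df[trait_df["t"] == trait_df["t"].max()]
    P = traits_final[["tip_x", "tip_y", "tip_z"]].to_numpy(dtype=float)
    Q = truth_final[["tip_x", "tip_y", "tip_z"]].to_numpy(dtype=float)
    cost = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(ri, ci) if cost[r, c] <= match_gate_mm]
    matched = {
        truth_final.iloc[c]["branch"]: int(traits_final.iloc[r]["branch_id"])
        for r, c in pairs
    }
    misses = [b for b in truth_final["branch"] if b not in matched]

    rows = []
    for bname, bid in matched.items():
        tr = truth[truth["branch"] == bname].set_index("t")
        comp = trait_df[trait_df["branch_id"] == bid].set_index("t")
        for t in sorted(set(tr.index) & set(comp.index)):
            for trait, truth_col in _COMPARED.items():
                true_val = float(tr.loc[t, truth_col])
                comp_val = float(comp.loc[t, trait])
                if not np.isfinite(true_val) or abs(true_val) < 1e-12:
                    continue
                rows.append(
                    {
                        "branch": bname,
                        "branch_id": bid,
                        "t": t,
                        "trait": trait,
                        "true": true_val,
                        "computed": comp_val,
                        "rel_error": abs(comp_val - true_val) / abs(true_val),
                    }
                )
    errors = pd.DataFrame(rows)
    if errors.empty:
        summary = {k: float("nan") for k in _COMPARED}
    else:
        summary = errors.groupby("trait")["rel_error"].mean().to_dict()
    return errors, summary, misses
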