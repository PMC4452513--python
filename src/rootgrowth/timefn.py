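"""The time function: when was each voxel of the final shape created.

The final shape carries the whole growth history: every earlier shape is
(after alignment) approximately a subset of it.  The time function tau maps
each final voxel to the acquisition index at which it first existed.  It is
built branch-wise: every voxel starts at tau = T, then walking the series
back to front, each tip of an earlier shape is matched to its nearest final
voxel v, and all members of v's branch that are no deeper than v are stamped
with the earlier time (the earliest stamp wins).

Depth and time must agree at forks: the path from the seed to a fork cannot
be younger than material growing beyond the fork.  Where the depth-based
hierarchy contradicts the observed times — a side branch that out-grew its
parent between acquisitions gets classified as the through-going branch — a
*switch* repairs the hierarchy: the parent's segment between the two forks
is reassigned to the older child, which becomes the through-going branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .alignment import AlignedSeries, RigidMotion
from .branches import Branch, BranchHierarchy
from .seed_depth import DepthField, SeedArea
from .voxel_model import VoxelGraph, VoxelShape

logger = logging.getLogger(__name__)

__all__ = ["TimeField", "GrowthRecord", "PerTimepoint", "compute_time", "repair_switches"]


@dataclass
class TimeField:
    """Per-voxel creation time (acquisition index) on the final shape."""

    tau: np.ndarray
    T: int
    skipped_tips: int = 0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.int64)
        if self.tau.size and (self.tau.min() < 0 or self.tau.max() > self.T):
            raise ValueError("tau values must lie in [0, T]")


@dataclass
class PerTimepoint:
    """One timepoint's own graph, seed, depth and decomposition."""

    shape: VoxelShape
    graph: VoxelGraph
    seed: SeedArea
    depth: DepthField
    hierarchy: BranchHierarchy


@dataclass
class GrowthRecord:
    """The unified growth data structure on the final shape.

    Holds the final shape, its geodesic depth field, the branch hierarchy,
    the per-voxel creation times, and the motion placing the final shape
    into the common (first-shape) frame.  All per-branch traits are
    computed from this record.
    """

    shape: VoxelShape
    graph: VoxelGraph
    depth: DepthField
    hierarchy: BranchHierarchy
    time: TimeField
    seed: SeedArea
    to_world: RigidMotion = field(default_factory=RigidMotion.identity)
    switch_count: int = 0

    @property
    def T(self) -> int:
        return self.time.T

    def world_points(self) -> np.ndarray:
        return self.to_world.apply(self.shape.points())

    def sublevel(self, branch: Branch, t: int) -> np.ndarray:
        """Members of a branch already present at time t."""
        mem = branch.members
        return mem[self.time.tau[mem] <= t]


def compute_time(
    aligned: AlignedSeries,
    per_t: list[PerTimepoint],
    final_hierarchy: BranchHierarchy,
    final_depth: DepthField,
    tip_match_gate: float = 5.0,
) -> TimeField:
    """Build tau on the final shape from the per-timepoint decompositions.

    ``per_t`` must cover t = 0..T-1 (the earlier shapes).  ``tip_match_gate``
    is the maximum tip-to-final-voxel distance, in voxel edges, for a match
    to be accepted; farther matches are skipped and logged, which guards
    against wrong-branch stamping under imperfect alignment.
    """
    series = aligned.series
    T = series.T
    shape_T = series[T]
    tau = np.full(shape_T.n, T, dtype=np.int64)
    phi = final_depth.values
    final_world = aligned.world_points(T)
    tree = cKDTree(final_world)
    gate_mm = tip_match_gate * series.edge_length
    skipped = 0
    for t in range(T - 1, -1, -1):
        pt = per_t[t]
        tips = np.array([b.tip for b in pt.hierarchy.branches], dtype=np.int64)
        tip_world = aligned.motions[t].apply(pt.shape.points()[tips])
        dist, idx = tree.query(tip_world, k=1)
        for b_t, (dd, v) in enumerate(zip(dist, idx)):
            if dd > gate_mm:
                skipped += 1
                logger.info(
                    "t=%d: tip of branch %d matched at %.2f mm > gate, skipped",
                    t, b_t, dd,
                )
                continue
            j = final_hierarchy.labels[v]
            mem = final_hierarchy.branches[j].members
            sel = mem[phi[mem] <= phi[v] + 1e-12]
            tau[sel] = np.minimum(tau[sel], t)
    return TimeField(tau=tau, T=T, skipped_tips=skipped)


def _fork_conflict(record: GrowthRecord, b: Branch, indptr, indices) -> bool:
    """A fork is in conflict when the child branch carries material older
    than the fork voxel itself: by the density assumption a side branch is
    shorter than its parent when it first appears, so it can never predate
    its own fork."""
    v = b.fork
    tau = record.time.tau
    nbrs = indices[indptr[v]:indptr[v + 1]]
    child_nbrs = nbrs[record.hierarchy.labels[nbrs] == b.id]
    if child_nbrs.size == 0:
        mem = b.members
        child_nbrs = mem[np.argsort(record.depth.values[mem])[:1]]
    return int(tau[child_nbrs].min()) < int(tau[v])


def repair_switches(record: GrowthRecord, max_rounds: int | None = None) -> tuple["GrowthRecord", int]:
    """Repair depth/time inconsistencies at forks by switch operations.

    Forks are scanned in increasing depth; at a conflicting fork v of child
    p with parent q, the segment of q between v and q's own fork w is
    reassigned to p, the reassigned times are clamped to tau(v), and p
    becomes the through-going branch at v.  Scanning repeats until no
    conflict remains or the iteration cap (ten times the fork count) is hit.
    """
    hier = record.hierarchy
    phi = record.depth.values
    tau = record.time.tau
    indptr, indices = record.graph.neighbors()
    n_forks = max(1, sum(1 for b in hier.branches if b.fork is not None))
    cap = max_rounds if max_rounds is not None else 10 * n_forks
    switches = 0
    for _ in range(cap):
        conflict: Branch | None = None
        forked = [b for b in hier.branches if b.fork is not None]
        forked.sort(key=lambda b: phi[b.fork])
        for b in forked:
            if _fork_conflict(record, b, indptr, indices):
                conflict = b
                break
        if conflict is None:
            break
        p = conflict
        q = hier.branches[p.parent]
        v = p.fork
        w = q.fork  # may be None when q is the topmost branch
        qm = q.members
        # everything of q up to the depth of v: the stretch between v and w
        # plus any junction-surface voxels hugging the fork region
        seg_mask = phi[qm] <= phi[v] + 1e-12
        segment = qm[seg_mask]
        if segment.size == 0 or segment.size == qm.size:
            logger.warning("switch at fork of branch %d degenerate, skipped", p.id)
            # avoid re-detecting the same fork forever
            tau[v] = min(tau[v], int(tau[p.members].min()))
            continue
        tau_v = int(tau[v])
        # reassign the segment of q between v and w to p
        p.members = np.sort(np.concatenate([p.members, segment]))
        q.members = qm[~seg_mask]
        hier.labels[segment] = p.id
        tau[segment] = np.minimum(tau[segment], tau_v)
        # p becomes the through-going branch at v
        p.fork = w
        p.parent = q.parent
        q.fork = v
        q.parent = p.id
        if w is None:
            hier.root_id = p.id
        # children of q whose fork moved into p now hang off p
        for other in hier.branches:
            if other.id in (p.id, q.id) or other.parent is None:
                continue
            if other.parent == q.id and hier.labels[other.fork] == p.id:
                other.parent = p.id
        hier.rebuild_children()
        switches += 1
        logger.info("switch %d: branch %d took over its parent %d at the fork",
                    switches, p.id, q.id)
    else:
        logger.warning("switch repair hit the iteration cap; repair may be partial")
    # final pass: junction-surface voxels that sit shallower than a fork yet
    # carry a younger time are painting artifacts, not hierarchy errors —
    # clamp them down to the fork's time (repairs only ever lower tau)
    for _ in range(cap):
        changed = False
        for b in hier.branches:
            if b.fork is None:
                continue
            v = b.fork
            nbrs = indices[indptr[v]:indptr[v + 1]]
            bad = nbrs[(phi[nbrs] < phi[v]) & (tau[nbrs] > tau[v])]
            if bad.size:
                tau[bad] = tau[v]
                changed = True
        if not changed:
            break
    record.switch_count = switches
    return record, switches
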