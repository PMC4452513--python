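"""Decomposition of a root shape into a hierarchy of branches.

The decomposition is a path decomposition driven by the depth function.
Voxels are traversed in order of decreasing depth; each visited voxel opens
a singleton component, and each arc — activated right after its second
endpoint — either closes a redundant connection inside a component or merges
two components.  Each component carries the deepest voxel it contains, its
*tip*.  When an arc (u, v) merges the component of u (tip p, the shallower)
with the component of v (tip q, the deeper), two things can happen:

* the stub of p above u is shorter than the merge threshold — the whole
  component is absorbed into the branch of q (surface bumps do not deserve
  to be branches);
* otherwise the branch of p is consolidated: its members are frozen, v
  becomes its fork and the branch of q its parent.

The surviving component at the end forms the topmost (root) branch.  Member
sets partition the voxels; parent links form a tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seed_depth import DepthField
from .voxel_model import VoxelGraph

logger = logging.getLogger(__name__)

__all__ = ["Branch", "BranchHierarchy", "decompose"]


@dataclass
class Branch:
    """One branch: tip voxel, fork voxel on the parent, member voxels.

    ``tip``, ``fork`` and ``members`` are indices into the shape's voxel
    array.  The topmost branch has no fork and no parent.
    """

    id: int
    tip: int
    fork: int | None
    parent: int | None
    members: np.ndarray


@dataclass
class BranchHierarchy:
    branches: list[Branch]
    labels: np.ndarray  # voxel index -> branch id
    root_id: int
    loop_arcs: int = 0
    absorbed_tips: int = 0
    children: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {b.id: [] for b in self.branches}
            for b in self.branches:
                if b.parent is not None:
                    self.children[b.parent].append(b.id)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branch(self, bid: int) -> Branch:
        return self.branches[bid]

    def rebuild_children(self) -> None:
        self.children = {b.id: [] for b in self.branches}
        for b in self.branches:
            if b.parent is not None:
                self.children[b.parent].append(b.id)

    def validate(self, depth: np.ndarray) -> None:
        """Check the structural invariants (used by tests and after repair)."""
        seen = np.zeros(self.labels.size, dtype=bool)
        for b in self.branches:
            assert b.members.size > 0
            assert not seen[b.members].any(), "member sets must be disjoint"
            seen[b.members] = True
            assert np.all(self.labels[b.members] == b.id)
            assert b.tip in b.members
            assert depth[b.tip] >= depth[b.members].max() - 1e-9
            if b.id == self.root_id:
                assert b.fork is None and b.parent is None
            else:
                assert b.fork is not None and b.parent is not None
                assert self.labels[b.fork] == b.parent
                assert depth[b.fork] < depth[b.tip] + 1e-9
        assert seen.all(), "members must partition the voxel set"
        # parent links form a tree rooted at root_id
        for b in self.branches:
            hops, cur = 0, b.id
            while self.branches[cur].parent is not None:
                cur = self.branches[cur].parent
                hops += 1
                assert hops <= len(self.branches), "parent links contain a cycle"
            assert cur == self.root_id


def decompose(
    graph: VoxelGraph, depth: DepthField, merge_threshold: float
) -> BranchHierarchy:
    """Decompose a shape into branches by the depth-ordered pointer merge.

    ``merge_threshold`` (mm) is the minimum protrusion of a component's tip
    beyond a junction for the component to survive as a branch; shorter
    stubs are absorbed.  Ties in depth are broken lexicographically by voxel
    coordinate so the result is reproducible.
    """
    d = depth.values
    n = graph.n_nodes
    arcs = graph.arcs

    # traversal order: decreasing depth, lexicographic voxel order on ties
    coords = graph.shape.coords
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -d))
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)

    # an arc activates when its later (shallower) endpoint is visited
    pos_i = pos[arcs[:, 0]]
    pos_j = pos[arcs[:, 1]]
    act = np.maximum(pos_i, pos_j)
    arc_order = np.argsort(act, kind="stable")
    act_sorted = act[arc_order]

    # loop heuristic: an intra-component arc whose endpoints share no common
    # neighbour anywhere in the shape closes a non-local cycle (touching
    # branches); redundant arcs inside a solid tube always sit in triangles
    from scipy import sparse

    adj = sparse.coo_matrix(
        (
            np.ones(2 * arcs.shape[0], dtype=np.int32),
            (
                np.concatenate([arcs[:, 0], arcs[:, 1]]),
                np.concatenate([arcs[:, 1], arcs[:, 0]]),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    common_counts = np.asarray((adj @ adj)[arcs[:, 0], arcs[:, 1]]).ravel()
    triangle_free = common_counts == 0

    parent = np.arange(n, dtype=np.int64)  # union-find
    rank = np.zeros(n, dtype=np.int8)
    tip_of: dict[int, int] = {}
    pending: dict[int, list[int]] = {}
    claimed = np.full(n, -1, dtype=np.int64)

    finalized: list[tuple[int, int, int]] = []  # (tip, fork, parent_tip_hint)
    absorbed_into: dict[int, int] = {}
    loop_arcs = 0
    n_absorbed = 0

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    ai = 0
    n_arcs = act_sorted.size
    for k in range(n):
        v_new = int(order[k])
        tip_of[v_new] = v_new
        pending[v_new] = [v_new]
        # collect the arcs activated by this voxel and order them so the
        # component with the deepest tip attaches first (ties broken by the
        # traversal order of the arc's earlier endpoint) — this reproduces
        # deepest-path-first semantics at junction voxels
        batch: list[int] = []
        while ai < n_arcs and act_sorted[ai] == k:
            batch.append(int(arc_order[ai]))
            ai += 1
        if len(batch) > 1:
            def batch_key(arc_idx: int) -> tuple[int, int]:
                a0, a1 = arcs[arc_idx]
                other = int(a0) if pos[a0] < k else int(a1)
                return (pos[tip_of[find(other)]], pos[other])

            batch.sort(key=batch_key)
        for arc_idx in batch:
            a = arcs[arc_idx]
            u, v = int(a[0]), int(a[1])
            ru, rv = find(u), find(v)
            if ru == rv:
                if triangle_free[arc_idx]:
                    loop_arcs += 1  # non-local closure within one component
                continue
            p, q = tip_of[ru], tip_of[rv]
            # deeper tip (smaller traversal position) becomes q
            if pos[p] < pos[q]:
                p, q = q, p
                u, v = v, u
                ru, rv = rv, ru
            # now p is the shallower tip, u the endpoint in p's component
            if d[p] - d[u] < merge_threshold:
                absorbed_into[p] = q
                n_absorbed += 1
                mem_p = pending.pop(ru)
            else:
                bid = len(finalized)
                finalized.append((p, v, q))
                for m in pending[ru]:
                    claimed[m] = bid
                pending.pop(ru)
                mem_p = None
            mem_q = pending.pop(rv)
            # union by rank
            if rank[ru] < rank[rv]:
                parent[ru] = rv
                root = rv
            elif rank[ru] > rank[rv]:
                parent[rv] = ru
                root = ru
            else:
                parent[rv] = ru
                rank[ru] += 1
                root = ru
            tip_of[root] = q
            if mem_p is not None:
                if len(mem_p) > len(mem_q):
                    mem_p.extend(mem_q)
                    pending[root] = mem_p
                else:
                    mem_q.extend(mem_p)
                    pending[root] = mem_q
            else:
                pending[root] = mem_q

    # remaining pending sets are the topmost branch of each component
    # (graphs are connected in the pipeline, so exactly one remains)
    root_entries = sorted(pending.items(), key=lambda kv: pos[tip_of[kv[0]]])
    if len(root_entries) > 1:
        logger.warning("decompose: %d disconnected components", len(root_entries))
    records: list[tuple[int, int | None, int | None, np.ndarray]] = []
    tip2bid: dict[int, int] = {}
    for tip, fork, phint in finalized:
        tip2bid[tip] = len(records)
        records.append((tip, fork, phint, None))
    for root, members in root_entries:
        tip = tip_of[root]
        bid = len(records)
        tip2bid[tip] = bid
        records.append((tip, None, None, np.asarray(members, dtype=np.int64)))
        for m in members:
            claimed[m] = bid

    def resolve(tip_hint: int) -> int:
        while tip_hint in absorbed_into:
            tip_hint = absorbed_into[tip_hint]
        return tip2bid[tip_hint]

    # collect member arrays for finalized branches
    members_by_bid: dict[int, list[int]] = {i: [] for i in range(len(records))}
    for vox in range(n):
        members_by_bid[int(claimed[vox])].append(vox)

    branches: list[Branch] = []
    for bid, (tip, fork, phint, mem) in enumerate(records):
        members = np.asarray(members_by_bid[bid], dtype=np.int64)
        parent_bid = None if phint is None else resolve(phint)
        branches.append(Branch(id=bid, tip=tip, fork=fork, parent=parent_bid, members=members))

    # renumber: sort by decreasing tip depth, lexicographic tie-break
    key = sorted(
        range(len(branches)),
        key=lambda b: (pos[branches[b].tip]),
    )
    new_id = {old: new for new, old in enumerate(key)}
    labels = np.empty(n, dtype=np.int64)
    out: list[Branch] = []
    for old in key:
        b = branches[old]
        nb = Branch(
            id=new_id[old],
            tip=b.tip,
            fork=b.fork,
            parent=None if b.parent is None else new_id[b.parent],
            members=b.members,
        )
        labels[nb.members] = nb.id
        out.append(nb)
    root_id = new_id[tip2bid[tip_of[root_entries[0][0]]]]
    if loop_arcs:
        logger.warning("decompose: %d loop-closing arc(s) ignored", loop_arcs)
    return BranchHierarchy(
        branches=out,
        labels=labels,
        root_id=root_id,
        loop_arcs=loop_arcs,
        absorbed_tips=n_absorbed,
    )
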