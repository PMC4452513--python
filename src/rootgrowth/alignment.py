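"""Rigid registration of a voxel time-series into a common frame.

All shapes are registered into the coordinate frame of the first shape.
Because a root system only ever gains material, every earlier shape is
(approximately) a subset of every later one, so registration always uses the
earliest shape as the reference side.  A coarse motion is found with a
randomized congruent-4-point search (wide, approximately coplanar point
quadruples are matched through the two affine-invariant intersection ratios
of their diagonals), and refined with point-to-point iterative closest
point.  Composite motions between arbitrary timepoints follow from the
stored motions by composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .voxel_model import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RigidMotion",
    "AlignedSeries",
    "ICPResult",
    "kabsch",
    "coarse_align_4pcs",
    "refine_icp",
    "align_series",
    "alignment_quality",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidMotion:
    """Proper rigid motion ``x -> R x + t`` with translation in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=100 * _ORTHO_TOL):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=100 * _ORTHO_TOL):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidMotion":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidMotion") -> "RigidMotion":
        """Motion equivalent to applying ``other`` first, then ``self``."""
        return RigidMotion(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidMotion":
        return RigidMotion(self.rotation.T, -self.rotation.T @ self.translation)

    def is_identity(self, atol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def kabsch(target_pts: np.ndarray, moved_to: np.ndarray) -> RigidMotion:
    """Least-squares rigid motion mapping ``target_pts`` onto ``moved_to``."""
    P = np.asarray(moved_to, dtype=float)
    Q = np.asarray(target_pts, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidMotion(R, pc - R @ qc)


def _subsample(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    if points.shape[0] <= k:
        return points
    idx = rng.choice(points.shape[0], size=k, replace=False)
    return points[np.sort(idx)]


def _pick_base(points: np.ndarray, delta: float, rng: np.random.Generator):
    """Pick a wide, approximately coplanar 4-point base with intersecting
    diagonals; returns (indices, r1, r2) or None."""
    n = points.shape[0]
    ext = points.max(axis=0) - points.min(axis=0)
    diameter = float(np.linalg.norm(ext))
    min_span = max(10 * delta, 0.25 * diameter)
    for _ in range(60):
        a, b, c = rng.choice(n, size=3, replace=False)
        pa, pb, pc = points[a], points[b], points[c]
        ab = pb - pa
        normal = np.cross(ab, pc - pa)
        area = np.linalg.norm(normal)
        span = np.linalg.norm(ab)
        if span < min_span or area < 10 * delta * span:
            continue
        normal /= area
        # candidates close to the plane of (a, b, c)
        d_plane = np.abs((points - pa) @ normal)
        cand = np.nonzero(d_plane <= delta)[0]
        cand = cand[(cand != a) & (cand != b) & (cand != c)]
        if cand.size == 0:
            continue
        rng.shuffle(cand)
        for d in cand[:20]:
            pd = points[d]
            # intersection of segments (a,b) and (c,d) in their common plane
            u, v, w = pb - pa, pd - pc, pc - pa
            a11, a12 = u @ u, -(u @ v)
            a22 = v @ v
            det = a11 * a22 - a12 * a12
            if det < 1e-12:
                continue
            b1, b2 = u @ w, -(v @ w)
            s = (b1 * a22 - a12 * b2) / det
            t = (a11 * b2 - a12 * b1) / det
            if not (0.05 <= s <= 0.95 and 0.05 <= t <= 0.95):
                continue
            e1 = pa + s * u
            e2 = pc + t * v
            if np.linalg.norm(e1 - e2) > 2 * delta:
                continue
            return np.array([a, b, c, d]), float(s), float(t)
    return None


def _pairs_with_length(points: np.ndarray, length: float, tol: float, cap: int = 12000) -> np.ndarray:
    p32 = points.astype(np.float32)
    d2 = (
        np.sum(p32 * p32, axis=1)[:, None]
        + np.sum(p32 * p32, axis=1)[None, :]
        - 2.0 * (p32 @ p32.T)
    )
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    i, j = np.nonzero(np.abs(d - length) <= tol)
    keep = i < j
    pairs = np.stack([i[keep], j[keep]], axis=1)
    if pairs.shape[0] > cap:
        step = pairs.shape[0] // cap + 1
        pairs = pairs[::step]
    return pairs


def coarse_align_4pcs(
    source: np.ndarray,
    target: np.ndarray,
    overlap_fraction: float = 0.5,
    delta: float | None = None,
    seed: int | np.random.Generator = 0,
    n_bases: int = 24,
    max_base_points: int = 2500,
    max_score_points: int = 1500,
    good_enough: float = 0.95,
) -> RigidMotion:
    """Coarse rigid motion mapping ``target`` points onto ``source`` points.

    ``source`` is the earlier (contained) shape: candidate motions are scored
    by the fraction of a source sample lying within ``delta`` of the moved
    target, which is close to 1 for the true motion of a nested pair
    regardless of how much the target has grown.  The identity motion is
    always evaluated as a candidate, so pre-registered series cannot be made
    worse by an unlucky random search.  ``delta`` defaults to one voxel edge
    if the caller passes None (callers should pass the edge length).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape[0] < 4 or target.shape[0] < 4:
        raise ValueError("both point sets need at least 4 points")
    for name, pts in (("source", source), ("target", target)):
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise ValueError(f"{name} points are collinear")
    if delta is None:
        delta = 1.0
    rng = np.random.default_rng(seed)

    src_base = _subsample(source, max_base_points, rng)
    tgt_base = _subsample(target, max_base_points, rng)
    src_score = _subsample(source, min(800, max_score_points), rng)
    tgt_score = _subsample(target, max_score_points, rng)
    src_tree_pts = src_score

    def score(motion: RigidMotion) -> float:
        moved = motion.apply(tgt_score)
        tree = cKDTree(moved)
        d, _ = tree.query(src_tree_pts, k=1)
        return float(np.mean(d <= delta))

    best_motion = RigidMotion.identity()
    best_score = score(best_motion)
    found_base = False

    for _ in range(n_bases):
        if best_score >= good_enough:
            break  # a near-complete overlap cannot be improved meaningfully
        picked = _pick_base(src_base, delta, rng)
        if picked is None:
            continue
        found_base = True
        idx, r1, r2 = picked
        pa, pb, pc, pd = src_base[idx]
        d1 = np.linalg.norm(pb - pa)
        d2 = np.linalg.norm(pd - pc)
        pairs1 = _pairs_with_length(tgt_base, d1, 2 * delta)
        pairs2 = _pairs_with_length(tgt_base, d2, 2 * delta)
        if pairs1.shape[0] == 0 or pairs2.shape[0] == 0:
            continue
        # candidate intersection points from both pair orientations
        p1 = tgt_base[pairs1[:, 0]]
        p2 = tgt_base[pairs1[:, 1]]
        e1 = np.concatenate([p1 + r1 * (p2 - p1), p2 + r1 * (p1 - p2)])
        e1_pairs = np.concatenate([pairs1, pairs1[:, ::-1]])
        q1 = tgt_base[pairs2[:, 0]]
        q2 = tgt_base[pairs2[:, 1]]
        e2 = np.concatenate([q1 + r2 * (q2 - q1), q2 + r2 * (q1 - q2)])
        e2_pairs = np.concatenate([pairs2, pairs2[:, ::-1]])

        tree1 = cKDTree(e1)
        dists, m1s = tree1.query(e2, k=1, distance_upper_bound=1.5 * delta)
        hit2 = np.nonzero(np.isfinite(dists))[0]
        if hit2.size == 0:
            continue
        if hit2.size > 150:
            hit2 = hit2[np.sort(rng.choice(hit2.size, size=150, replace=False))]
        cands = [(int(m1s[m2]), int(m2)) for m2 in hit2]
        src_quad = np.stack([pa, pb, pc, pd])
        for m1, m2 in cands:
            i1, j1 = e1_pairs[m1]
            i2, j2 = e2_pairs[m2]
            tgt_quad = tgt_base[[i1, j1, i2, j2]]
            motion = kabsch(tgt_quad, src_quad)
            resid = np.linalg.norm(motion.apply(tgt_quad) - src_quad, axis=1).max()
            if resid > 3 * delta:
                continue
            sc = score(motion)
            if sc > best_score:
                best_score, best_motion = sc, motion
            if best_score >= good_enough:
                break

    if best_score <= 0.0 or (not found_base and best_score < 0.05):
        raise RuntimeError("4PCS failed: no acceptable base/congruent set found")
    logger.debug("4PCS best score %.3f", best_score)
    return best_motion


@dataclass
class ICPResult:
    """Refined motion plus the per-iteration RMS trace."""

    motion: RigidMotion
    rms_history: list[float]

    @property
    def n_iter(self) -> int:
        return len(self.rms_history)


def refine_icp(
    source: np.ndarray,
    target: np.ndarray,
    initial: RigidMotion,
    max_iter: int = 60,
    tol: float = 1e-5,
    max_points: int = 8000,
    seed: int | np.random.Generator = 0,
) -> ICPResult:
    """Point-to-point ICP refinement of a coarse motion.

    Correspondences are sampled from the source (the earlier, contained
    shape), so voxels that only exist in the grown target cannot bias the
    fit.  Returns the refined composite motion mapping target onto source;
    iteration stops when the RMS correspondence distance improves by less
    than ``tol`` mm.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape[0] == 0 or target.shape[0] == 0:
        raise ValueError("empty point set")
    rng = np.random.default_rng(seed)
    src = _subsample(source, max_points, rng)
    tgt = _subsample(target, max_points, rng)

    motion = initial
    history: list[float] = []
    for _ in range(max_iter):
        moved = motion.apply(tgt)
        tree = cKDTree(moved)
        d, idx = tree.query(src, k=1)
        rms = float(np.sqrt(np.mean(d**2)))
        if history and history[-1] - rms < tol:
            history.append(rms)
            break
        history.append(rms)
        motion = kabsch(tgt[idx], src)
    return ICPResult(motion=motion, rms_history=history)


@dataclass
class AlignedSeries:
    """A time-series plus the motions M_0t registering each shape to t=0.

    ``quality`` holds the mean sampled nearest-neighbour distance from the
    first shape to each aligned shape, in voxel-edge units; ``excluded``
    flags shapes whose average distance exceeded the exclusion threshold.
    """

    series: TimeSeries
    motions: list[RigidMotion]
    quality: list[float] = field(default_factory=list)
    excluded: list[bool] = field(default_factory=list)
    errors: dict[int, str] = field(default_factory=dict)

    def motion_between(self, s: int, t: int) -> RigidMotion:
        """Composite M_st mapping shape t into the frame of shape s."""
        return self.motions[s].inverse().compose(self.motions[t])

    def world_points(self, t: int) -> np.ndarray:
        """Voxel centers of shape t mapped into the frame of shape 0 (mm)."""
        return self.motions[t].apply(self.series[t].points())


def align_series(
    series: TimeSeries,
    *,
    delta: float | None = None,
    overlap_fraction: float = 0.5,
    icp_max_iter: int = 60,
    icp_tol: float = 1e-5,
    max_points: int = 20000,
    exclusion_threshold: float = 10.0,
    sample_fraction: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> AlignedSeries:
    """Register every shape of a series into the frame of the first shape."""
    rng = np.random.default_rng(seed)
    edge = series.edge_length
    if delta is None:
        delta = edge
    motions: list[RigidMotion] = [RigidMotion.identity()]
    errors: dict[int, str] = {}
    src = series[0].points()
    for t in range(1, len(series)):
        tgt = series[t].points()
        try:
            coarse = coarse_align_4pcs(
                src, tgt, overlap_fraction=overlap_fraction, delta=delta, seed=rng,
                max_score_points=min(max_points, 3000),
            )
            result = refine_icp(
                src, tgt, coarse, max_iter=icp_max_iter, tol=icp_tol,
                max_points=min(max_points, 8000), seed=rng,
            )
            motions.append(result.motion)
        except (RuntimeError, ValueError) as exc:
            logger.error("alignment failed for t=%d: %s", series[t].time_index, exc)
            errors[t] = str(exc)
            motions.append(RigidMotion.identity())
    aligned = AlignedSeries(series=series, motions=motions, errors=errors)
    if len(series) >= 2:
        quality = alignment_quality(
            aligned, sample_fraction=sample_fraction, seed=rng,
            exclusion_threshold=exclusion_threshold,
        )
        aligned.quality = quality
    aligned.excluded = [False] + [
        (t in errors) or (q > exclusion_threshold)
        for t, q in enumerate(aligned.quality, start=1)
    ]
    return aligned


def alignment_quality(
    aligned: AlignedSeries,
    sample_fraction: float = 0.10,
    seed: int | np.random.Generator = 0,
    exclusion_threshold: float = 10.0,
) -> list[float]:
    """Average sampled NN distance from shape 0 to each aligned shape.

    A fixed fraction of the first shape's voxels is sampled; for each later
    timepoint the mean Euclidean distance from the sample to the nearest
    voxel of the aligned shape is reported in voxel-edge units.  Values
    beyond the exclusion threshold mark shapes that failed to align.
    """
    series = aligned.series
    if len(series) < 2:
        raise ValueError("quality requires at least two shapes")
    rng = np.random.default_rng(seed)
    pts0 = series[0].points()
    k = max(1, int(round(sample_fraction * pts0.shape[0])))
    sample = _subsample(pts0, k, rng)
    edge = series.edge_length
    out: list[float] = []
    for t in range(1, len(series)):
        moved = aligned.world_points(t)
        tree = cKDTree(moved)
        d, _ = tree.query(sample, k=1)
        avg = float(np.mean(d)) / edge
        if avg > exclusion_threshold:
            logger.warning(
                "t=%d: average alignment distance %.2f edges exceeds %.2f, flagged",
                series[t].time_index, avg, exclusion_threshold,
            )
        out.append(avg)
    return out
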