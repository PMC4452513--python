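"""End-to-end pipeline: align, seed, depth, decompose, time, repair, traits.

``analyze`` turns a time-series of voxel shapes into a growth record and
trait tables; ``write_outputs`` serializes everything a downstream analysis
needs (trait tables, hierarchy, depth/time fields, colored point clouds,
alignment QC and run statistics).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import traits as traits_mod
from .alignment import AlignedSeries, align_series
from .branches import decompose
from .seed_depth import SeedArea, compute_depth, detect_seed, propagate_seed
from .timefn import GrowthRecord, PerTimepoint, compute_time, repair_switches
from .voxel_model import (
    TimeSeries,
    VoxelShape,
    build_graph,
    estimate_average_radius,
    largest_component,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisResult", "analyze", "write_outputs"]


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run.

    Defaults marked "auto" are derived from the estimated average branch
    radius of the final shape: the seed PCA radius is twice that radius (in
    voxels, at least 3) and the branch merge threshold twice that radius in
    mm, so stubs shorter than a branch is thick are treated as surface
    noise rather than branches.
    """

    edge_length: float = 1.0
    seed_pca_radius: float | None = None  # voxels; auto
    sphericity: float = 0.6
    max_seed_fraction: float = 0.25
    merge_threshold: float | None = None  # mm; auto
    icp_max_iter: int = 60
    icp_tol: float = 1e-5  # mm
    fourpcs_delta: float | None = None  # mm; defaults to one voxel edge
    fourpcs_overlap: float = 0.5
    tip_match_gate: float = 5.0  # voxel edges
    exclusion_threshold: float = 10.0  # voxel edges
    sample_fraction: float = 0.10
    max_points: int = 20000
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisResult:
    record: GrowthRecord
    aligned: AlignedSeries
    per_t: list[PerTimepoint]
    traits: pd.DataFrame
    aggregates: pd.DataFrame
    increments: pd.DataFrame
    seed_traits: traits_mod.SeedTraits
    classes: dict[int, str]
    config: PipelineConfig
    runtime_s: float = 0.0
    excluded_times: list[int] = field(default_factory=list)

    @property
    def switch_count(self) -> int:
        return self.record.switch_count


def analyze(series: TimeSeries, config: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full pipeline on a time-series of voxel shapes."""
    t_start = time.perf_counter()
    config = config or PipelineConfig(edge_length=series.edge_length)
    rng = np.random.default_rng(config.rng_seed)

    # connectivity is assumed; reduce to the largest component with a warning
    reduced: list[VoxelShape] = []
    for s in series.shapes:
        g = largest_component(build_graph(s))
        reduced.append(g.shape)
    series = TimeSeries(reduced)

    aligned = align_series(
        series,
        delta=config.fourpcs_delta,
        overlap_fraction=config.fourpcs_overlap,
        icp_max_iter=config.icp_max_iter,
        icp_tol=config.icp_tol,
        max_points=config.max_points,
        exclusion_threshold=config.exclusion_threshold,
        sample_fraction=config.sample_fraction,
        seed=rng,
    )
    excluded_times = [series[t].time_index for t, x in enumerate(aligned.excluded) if x]
    if excluded_times:
        logger.warning("excluding poorly aligned timepoints: %s", excluded_times)
        keep = [t for t, x in enumerate(aligned.excluded) if not x]
        kept_shapes = [series[t] for t in keep]
        kept_motions = [aligned.motions[t] for t in keep]
        kept_quality = [aligned.quality[t - 1] for t in keep if t > 0]
        series = TimeSeries(
            [dataclasses.replace(s, time_index=i) for i, s in enumerate(kept_shapes)]
        )
        aligned = AlignedSeries(
            series=series, motions=kept_motions, quality=kept_quality,
            excluded=[False] * len(keep), errors={},
        )

    T = series.T
    final_shape = series[T]
    r_hat = estimate_average_radius(final_shape)
    merge_threshold = (
        config.merge_threshold if config.merge_threshold is not None else 2.0 * r_hat
    )
    R = config.seed_pca_radius
    if R is None:
        R = max(3.0, float(np.ceil(2.0 * r_hat / series.edge_length)))

    graphs = [build_graph(series[t]) for t in range(T + 1)]
    seed_T = detect_seed(
        final_shape, graph=graphs[T], R=R,
        sphericity=config.sphericity, max_fraction=config.max_seed_fraction,
    )
    seeds: list[SeedArea] = (
        propagate_seed(seed_T, aligned) if T > 0 else []
    ) + [seed_T]

    per_t: list[PerTimepoint] = []
    for t in range(T + 1):
        depth_t = compute_depth(graphs[t], seeds[t])
        hier_t = decompose(graphs[t], depth_t, merge_threshold)
        per_t.append(
            PerTimepoint(
                shape=series[t], graph=graphs[t], seed=seeds[t],
                depth=depth_t, hierarchy=hier_t,
            )
        )

    final = per_t[T]
    tau = compute_time(
        aligned, per_t[:T], final.hierarchy, final.depth,
        tip_match_gate=config.tip_match_gate,
    )
    record = GrowthRecord(
        shape=final.shape,
        graph=final.graph,
        depth=final.depth,
        hierarchy=final.hierarchy,
        time=tau,
        seed=seed_T,
        to_world=aligned.motions[T],
    )
    record, n_switches = repair_switches(record)

    trait_df = traits_mod.trait_table(record)
    aggregates = pd.DataFrame(
        [traits_mod.aggregate_traits(record, t) for t in range(T + 1)]
    )
    increments = (
        traits_mod.growth_increments(record) if T > 0 else pd.DataFrame()
    )
    stats = traits_mod.seed_traits(seed_T)
    classes = traits_mod.classify_branches(record)
    return AnalysisResult(
        record=record,
        aligned=aligned,
        per_t=per_t,
        traits=trait_df,
        aggregates=aggregates,
        increments=increments,
        seed_traits=stats,
        classes=classes,
        config=config,
        runtime_s=time.perf_counter() - t_start,
        excluded_times=excluded_times,
    )


def write_outputs(result: AnalysisResult, outdir: str | Path) -> None:
    """Write the full output bundle of a run to a directory."""
    from ._ply import write_ply

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = result.record
    shape = record.shape
    coords = shape.coords
    sep = "\t"

    result.traits.to_csv(outdir / "traits.tsv", sep=sep, index=False)
    for t in range(record.T + 1):
        sub = result.traits[result.traits["t"] == t]
        sub.to_csv(outdir / f"traits_t{t}.tsv", sep=sep, index=False)
    result.aggregates.to_csv(outdir / "aggregates.tsv", sep=sep, index=False)
    if not result.increments.empty:
        result.increments.to_csv(outdir / "growth_increments.tsv", sep=sep, index=False)

    hier_rows = []
    for b in record.hierarchy.branches:
        fork = coords[b.fork] if b.fork is not None else (None, None, None)
        hier_rows.append(
            {
                "branch_id": b.id,
                "parent_id": b.parent if b.parent is not None else -1,
                "tip_x": coords[b.tip][0], "tip_y": coords[b.tip][1], "tip_z": coords[b.tip][2],
                "fork_x": fork[0], "fork_y": fork[1], "fork_z": fork[2],
                "n_voxels": b.members.size,
                "class": result.classes[b.id],
            }
        )
    pd.DataFrame(hier_rows).to_csv(outdir / "hierarchy.tsv", sep=sep, index=False)

    depth_df = pd.DataFrame(
        {
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
            "depth_mm": record.depth.values, "tau": record.time.tau,
            "branch_id": record.hierarchy.labels,
        }
    )
    depth_df.to_csv(outdir / "depth_time.tsv", sep=sep, index=False)

    pts = record.world_points()
    write_ply(outdir / "branches.ply", pts, _categorical_colors(record.hierarchy.labels))
    write_ply(outdir / "time.ply", pts, _scalar_colors(record.time.tau, record.T))

    for t, motion in enumerate(result.aligned.motions):
        nums = np.concatenate([motion.rotation.ravel(), motion.translation])
        np.savetxt(outdir / f"motion_t{t}.txt", nums[None, :], fmt="%.9f")

    qc = pd.DataFrame(
        {
            "time_index": [result.aligned.series[t].time_index for t in range(1, len(result.aligned.series))],
            "avg_distance_edges": result.aligned.quality,
            "excluded_flag": result.aligned.excluded[1:],
        }
    )
    qc.to_csv(outdir / "alignment_qc.tsv", sep=sep, index=False)

    stats = {
        "runtime_s": result.runtime_s,
        "avg_alignment_distance_edges": result.aligned.quality,
        "switch_events": result.switch_count,
        "skipped_tip_matches": record.time.skipped_tips,
        "loop_arcs": record.hierarchy.loop_arcs,
        "excluded_times": result.excluded_times,
        "seed_mode": record.seed.mode.value,
        "seed_traits": dataclasses.asdict(result.seed_traits),
        "config": result.config.to_dict(),
    }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, default=float)


def _categorical_colors(labels: np.ndarray) -> np.ndarray:
    palette = np.array(
        [
            (228, 26, 28), (55, 126, 184), (77, 175, 74), (152, 78, 163),
            (255, 127, 0), (255, 255, 51), (166, 86, 40), (247, 129, 191),
            (153, 153, 153), (26, 188, 156), (142, 68, 173), (241, 196, 15),
        ],
        dtype=np.uint8,
    )
    return palette[np.asarray(labels) % len(palette)]


def _scalar_colors(values: np.ndarray, vmax: float) -> np.ndarray:
    v = np.asarray(values, dtype=float) / max(vmax, 1)
    r = (255 * v).astype(np.uint8)
    b = (255 * (1 - v)).astype(np.uint8)
    g = np.full_like(r, 40)
    return np.stack([r, g, b], axis=1)
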