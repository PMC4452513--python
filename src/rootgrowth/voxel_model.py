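"""Voxel-set representation of reconstructed root shapes.

A root system imaged at one timepoint is a set of unit voxels on an integer
grid, together with the physical edge length of one voxel in millimetres.
For geodesic computations the shape is viewed as a weighted graph: nodes are
voxels, arcs join 26-neighbouring voxels, and an arc weighs 1, sqrt(2) or
sqrt(3) voxel edges depending on whether the two voxels share a face, an
edge or only a corner.

Two on-disk dialects are supported:

* dialect A — plain text, one ``x y z`` integer triple per line, ``#`` starts
  a comment;
* dialect B — a dense binary mask stored as a 3D TIFF volume (axis order
  ``z, y, x``); the grid origin of the mask is kept in the TIFF image
  description so that negative grid coordinates round-trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelShape",
    "VoxelGraph",
    "TimeSeries",
    "read_voxel_shape",
    "write_voxel_shape",
    "build_graph",
    "largest_component",
    "estimate_average_radius",
]


def _canonical_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.int64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("voxel coordinates must be an (N, 3) array")
    return np.unique(coords, axis=0)  # sorts lexicographically, drops duplicates


@dataclass(frozen=True)
class VoxelShape:
    """One timepoint's voxel set with its physical scale.

    ``coords`` is kept sorted lexicographically with duplicates removed, so
    that identical voxel sets always compare (and serialize) identically.
    """

    coords: np.ndarray
    edge_length: float
    time_index: int = 0

    def __post_init__(self) -> None:
        coords = _canonical_coords(self.coords)
        if coords.shape[0] == 0:
            raise ValueError("empty shape")
        if not self.edge_length > 0:
            raise ValueError("edge_length must be positive")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return int(self.coords.shape[0])

    def points(self) -> np.ndarray:
        """Voxel centers in millimetres (grid coordinate times edge length)."""
        return self.coords.astype(float) * self.edge_length

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.coords.min(axis=0), self.coords.max(axis=0)

    def to_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense boolean volume (z, y, x order) plus the grid origin."""
        lo, hi = self.bounds()
        dims = (hi - lo) + 1
        mask = np.zeros((dims[2], dims[1], dims[0]), dtype=bool)
        c = self.coords - lo
        mask[c[:, 2], c[:, 1], c[:, 0]] = True
        return mask, lo


@dataclass(frozen=True)
class TimeSeries:
    """Shapes of one root system ordered by acquisition index 0..T."""

    shapes: list[VoxelShape]

    def __post_init__(self) -> None:
        if len(self.shapes) == 0:
            raise ValueError("time series must contain at least one shape")
        idx = [s.time_index for s in self.shapes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("time_index must be strictly increasing")
        edges = {s.edge_length for s in self.shapes}
        if len(edges) != 1:
            raise ValueError("all shapes must share one voxel edge length")

    @property
    def T(self) -> int:
        return len(self.shapes) - 1

    @property
    def edge_length(self) -> float:
        return self.shapes[0].edge_length

    def __len__(self) -> int:
        return len(self.shapes)

    def __getitem__(self, i: int) -> VoxelShape:
        return self.shapes[i]


# 13 offsets covering one representative of each 26-neighbour pair
_OFFSETS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)
_OFFSET_CLASS = np.count_nonzero(_OFFSETS, axis=1)  # 1 face, 2 edge, 3 corner


@dataclass
class VoxelGraph:
    """Weighted 26-connectivity graph over the voxels of one shape.

    ``arcs`` holds each undirected arc once as ``(i, j)`` with ``i < j``
    indexing into ``shape.coords``; ``weights`` are in millimetres.
    """

    shape: VoxelShape
    arcs: np.ndarray
    weights: np.ndarray
    _csr: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.shape.n

    @property
    def n_arcs(self) -> int:
        return int(self.arcs.shape[0])

    def csr(self) -> sparse.csr_matrix:
        """Symmetric sparse adjacency with arc weights."""
        if self._csr is None:
            i, j = self.arcs[:, 0], self.arcs[:, 1]
            n = self.n_nodes
            m = sparse.coo_matrix(
                (
                    np.concatenate([self.weights, self.weights]),
                    (np.concatenate([i, j]), np.concatenate([j, i])),
                ),
                shape=(n, n),
            )
            self._csr = m.tocsr()
        return self._csr

    def neighbors(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR ``(indptr, indices)`` for fast neighbour lookups."""
        c = self.csr()
        return c.indptr, c.indices


def _ravel_keys(coords: np.ndarray, lo: np.ndarray, dims: np.ndarray) -> np.ndarray:
    c = coords - lo
    return (c[:, 0] * dims[1] + c[:, 1]) * dims[2] + c[:, 2]


def build_graph(shape: VoxelShape, *, integer_weights: bool = False) -> VoxelGraph:
    """Build the weighted 26-connectivity graph of a shape.

    Arc weights default to {1, sqrt(2), sqrt(3)} voxel edges for face/edge/
    corner adjacency, scaled by the physical edge length.  With
    ``integer_weights=True`` the weights {1, 2, 3} are used instead, for
    comparison with pipelines that use integral arc lengths.
    """
    coords = shape.coords
    lo, hi = shape.bounds()
    dims = (hi - lo) + 3  # pad so neighbour keys never collide
    lo = lo - 1
    keys = _ravel_keys(coords, lo, dims)  # sorted-unique order not guaranteed; sort
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]

    arc_i: list[np.ndarray] = []
    arc_j: list[np.ndarray] = []
    arc_cls: list[np.ndarray] = []
    for off, cls in zip(_OFFSETS, _OFFSET_CLASS):
        nb_keys = _ravel_keys(coords + off, lo, dims)
        pos = np.searchsorted(keys_sorted, nb_keys)
        pos_clip = np.minimum(pos, keys_sorted.size - 1)
        hit = keys_sorted[pos_clip] == nb_keys
        src = np.nonzero(hit)[0]
        dst = order[pos_clip[hit]]
        arc_i.append(src)
        arc_j.append(dst)
        arc_cls.append(np.full(src.size, cls, dtype=np.int8))

    i = np.concatenate(arc_i)
    j = np.concatenate(arc_j)
    cls = np.concatenate(arc_cls)
    lohi = np.sort(np.stack([i, j], axis=1), axis=1)
    if integer_weights:
        w = cls.astype(float) * shape.edge_length
    else:
        w = np.sqrt(cls.astype(float)) * shape.edge_length
    return VoxelGraph(shape=shape, arcs=lohi, weights=w)


def largest_component(graph: VoxelGraph) -> VoxelGraph:
    """Restrict a graph to its largest connected voxel component.

    Root shapes are assumed connected; reconstruction artefacts occasionally
    leave debris components, which are discarded with a warning.  Ties in
    component size are broken deterministically in favour of the component
    containing the lexicographically smallest voxel.
    """
    n_comp, labels = csgraph.connected_components(graph.csr(), directed=False)
    if n_comp <= 1:
        return graph
    sizes = np.bincount(labels, minlength=n_comp)
    best = np.nonzero(sizes == sizes.max())[0]
    # coords are lex-sorted, so the first voxel with a candidate label decides
    if best.size > 1:
        first_occurrence = np.array([np.argmax(labels == b) for b in best])
        keep = best[np.argmin(first_occurrence)]
    else:
        keep = best[0]
    mask = labels == keep
    dropped = n_comp - 1
    logger.warning(
        "shape t=%d: discarding %d smaller component(s) totalling %d voxels",
        graph.shape.time_index, dropped, int((~mask).sum()),
    )
    sub_shape = VoxelShape(
        coords=graph.shape.coords[mask],
        edge_length=graph.shape.edge_length,
        time_index=graph.shape.time_index,
    )
    new_index = np.cumsum(mask) - 1
    arc_keep = mask[graph.arcs[:, 0]] & mask[graph.arcs[:, 1]]
    arcs = new_index[graph.arcs[arc_keep]]
    return VoxelGraph(shape=sub_shape, arcs=arcs, weights=graph.weights[arc_keep])


def estimate_average_radius(shape: VoxelShape) -> float:
    """Estimate the mean branch radius in millimetres.

    For a solid tube the mean distance from interior points to the wall is a
    third of the radius, so three times the mean Euclidean distance transform
    (measured from voxel centers, hence the half-voxel offset) recovers the
    tube radius.  Used to derive defaults for the seed-detection radius and
    the branch merge threshold.
    """
    mask, _ = shape.to_mask()
    edt = ndimage.distance_transform_edt(np.pad(mask, 1))
    mean_interior = float(np.mean(np.maximum(edt[1:-1, 1:-1, 1:-1][mask] - 0.5, 0.0)))
    r_vox = max(3.0 * mean_interior, 0.5)
    return r_vox * shape.edge_length


def read_voxel_shape(path: str | Path, edge_length: float, time_index: int = 0) -> VoxelShape:
    """Read a shape from dialect A (text triples) or dialect B (3D TIFF)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_mask(path, edge_length, time_index)
    return _read_text(path, edge_length, time_index)


def _read_text(path: Path, edge_length: float, time_index: int) -> VoxelShape:
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'x y z', got {line.rstrip()!r}")
            try:
                rows.append(tuple(int(p) for p in parts))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate in {line.rstrip()!r}") from exc
    if not rows:
        raise ValueError(f"{path}: empty shape")
    return VoxelShape(np.array(rows, dtype=np.int64), edge_length, time_index)


def _read_mask(path: Path, edge_length: float, time_index: int) -> VoxelShape:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        vol = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        origin = np.zeros(3, dtype=np.int64)
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                origin = np.asarray(meta.get("origin", [0, 0, 0]), dtype=np.int64)
            except (json.JSONDecodeError, TypeError):
                pass
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {vol.shape}")
    z, y, x = np.nonzero(vol)
    if x.size == 0:
        raise ValueError(f"{path}: empty shape")
    coords = np.stack([x, y, z], axis=1).astype(np.int64) + origin
    return VoxelShape(coords, edge_length, time_index)


def write_voxel_shape(shape: VoxelShape, path: str | Path) -> None:
    """Write a shape in the dialect implied by the file suffix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        mask, lo = shape.to_mask()
        tifffile.imwrite(
            str(path),
            mask.astype(np.uint8),
            description=json.dumps({"origin": [int(v) for v in lo]}),
        )
        return
    with open(path, "w") as fh:
        fh.write(f"# voxel shape, t={shape.time_index}, edge_length_mm={shape.edge_length}\n")
        for x, y, z in shape.coords:
            fh.write(f"{x} {y} {z}\n")
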