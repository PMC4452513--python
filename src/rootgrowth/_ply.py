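"""Minimal ASCII PLY point-cloud writer (per-vertex RGB)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_ply(path: str | Path, points: np.ndarray, colors: np.ndarray) -> None:
    points = np.asarray(points, dtype=float)
    colors = np.asarray(colors, dtype=np.uint8)
    if points.shape[0] != colors.shape[0]:
        raise ValueError("points and colors must have equal length")
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {points.shape[0]}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n"
        )
        for (x, y, z), (r, g, b) in zip(points, colors):
            fh.write(f"{x:.4f} {y:.4f} {z:.4f} {r} {g} {b}\n")
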