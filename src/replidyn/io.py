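"""Readers and writers for the pipeline's on-disk formats.

Images are multi-channel TIFF with a JSON sidecar carrying channel roles and
pixel size; genomic tracks are bedGraph/BED (0-based, half-open); tables are
plain CSV/TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fiber_imaging import FiberImage, FiberTrace

__all__ = [
    "write_fiber_image",
    "read_fiber_image",
    "write_traces",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
]


def write_fiber_image(path: str | Path, image: FiberImage) -> None:
    """Multi-channel TIFF (C, H, W) plus a ``.json`` metadata sidecar."""
    path = Path(path)
    roles = sorted(image.channels)
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = {"channel_roles": roles, "pixel_size_um": image.pixel_size_um}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_fiber_image(path: str | Path) -> FiberImage:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    channels = {role: stack[i] for i, role in enumerate(meta["channel_roles"])}
    return FiberImage(channels=channels, pixel_size_um=meta["pixel_size_um"])


def write_traces(path: str | Path, traces: list[FiberTrace]) -> None:
    """CSV of centerline samples plus a JSON index of per-fiber metadata."""
    path = Path(path)
    rows = []
    index = []
    for trace in traces:
        for k, ((r, c), arc) in enumerate(zip(trace.points, trace.arclength_um)):
            rows.append(
                {
                    "fiber_id": trace.component_id,
                    "point_index": k,
                    "x_px": c,
                    "y_px": r,
                    "arclength_um": arc,
                }
            )
        index.append(
            {
                "fiber_id": trace.component_id,
                "length_um": trace.length_um,
                "ambiguous": trace.ambiguous,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(index, indent=1))


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open); the 4th column becomes ``name``/``class``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols
    return df


def write_bed(path: str | Path, df: pd.DataFrame, name_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"]
    if name_col and name_col in df.columns:
        cols.append(name_col)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, value_name: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", value_name]
    return df


def write_bedgraph(path: str | Path, df: pd.DataFrame, value_col: str) -> None:
    sub = df[["chrom", "start", "end", value_col]].dropna(subset=[value_col])
    sub.to_csv(path, sep="\t", header=False, index=False)
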