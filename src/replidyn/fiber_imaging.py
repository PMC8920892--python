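"""Localization of stretched DNA fibers in confocal images.

The stage turns a multi-channel fluorescence image of combed/stretched DNA
fibers into subpixel centerlines ("median lines"):

1. multiscale Hessian line filtering produces a ridgeness map in [0, 1];
2. a spatially variant morphological closing with an oriented linear
   structuring element reconnects fibers fragmented by noise or label gaps;
3. the map is thresholded (typically 0.5), connected components are thinned
   to one-pixel skeletons, spurs are pruned, and each simple path is fitted
   with a smoothing B-spline and resampled at a fixed arclength step.

Coordinate convention: pixel centers at integer coordinates, (row, col)
ordering; arclength in micrometers via ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from skimage.draw import line as draw_line
from skimage.feature import structure_tensor
from skimage.filters import sato
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

__all__ = [
    "FiberImage",
    "RidgeMap",
    "FiberTrace",
    "compute_ridge_map",
    "ridge_orientation",
    "reconnect",
    "extract_traces",
]


@dataclass
class FiberImage:
    """Pixel grid with channel roles and calibrated pixel size.

    ``channels`` maps a role name to a 2-D float array; roles are
    ``"first"`` (first-pulse analog), ``"second"`` (second-pulse analog) and
    optionally ``"dna"`` (total ssDNA counterstain).  All channels share one
    shape; ``pixel_size_um`` is the effective pixel size (0.142 um default
    mirrors a typical confocal acquisition of stretched fibers).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.142

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def structural_channel(self) -> np.ndarray:
        """Channel used for fiber localization: DNA if present, else the
        per-pixel maximum of the two label channels."""
        if "dna" in self.channels:
            return self.channels["dna"]
        return np.maximum(self.channels["first"], self.channels["second"])


@dataclass
class RidgeMap:
    """Per-pixel ridgeness in [0, 1] plus the scale of maximum response."""

    values: np.ndarray
    best_scale: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("ridgeness must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class FiberTrace:
    """Ordered subpixel centerline of one fiber.

    ``points`` is an (n, 2) array of (row, col) samples at a fixed arclength
    step; ``arclength_um`` is strictly increasing and starts at 0.
    """

    points: np.ndarray
    arclength_um: np.ndarray
    component_id: int
    pixel_size_um: float
    ambiguous: bool = False
    spline: tuple | None = field(default=None, repr=False)

    @property
    def length_um(self) -> float:
        return float(self.arclength_um[-1]) if len(self.arclength_um) else 0.0

    def tangents(self) -> np.ndarray:
        """Unit tangent per sample (central differences on the resampled path)."""
        d = np.gradient(self.points, axis=0)
        n = np.linalg.norm(d, axis=1)
        n[n == 0] = 1.0
        return d / n[:, None]


def compute_ridge_map(
    image: FiberImage,
    scales: tuple[float, ...] = (1.0, 1.6, 2.4),
    roi_mask: np.ndarray | None = None,
) -> RidgeMap:
    """Multiscale Hessian line-filter ("tubeness") response, normalized to [0, 1].

    The response is the maximum over ``scales`` of a Sato vesselness filter
    for bright curvilinear structures; pixels outside ``roi_mask`` are zero.
    """
    if len(scales) == 0:
        raise ValueError("at least one scale is required")
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if not roi_mask.any():
            raise ValueError("empty ROI")
    img = image.structural_channel()
    responses = np.stack(
        [sato(img, sigmas=[s], black_ridges=False, mode="reflect") for s in scales]
    )
    best = np.argmax(responses, axis=0)
    values = responses.max(axis=0)
    peak = values.max()
    if peak > 0:
        values = values / peak
    if roi_mask is not None:
        values = np.where(roi_mask, values, 0.0)
    return RidgeMap(
        values=values,
        best_scale=np.asarray(scales, dtype=float)[best],
        pixel_size_um=image.pixel_size_um,
    )


def _line_footprint(length: int, theta: float) -> np.ndarray:
    """Binary linear structuring element of given length and orientation.

    ``theta`` is the ridge direction in radians measured in (row, col)
    space, i.e. direction vector (sin, cos) ... we use (dr, dc) =
    (sin(theta), cos(theta)).
    """
    half = max(1, length // 2)
    dr = int(round(half * np.sin(theta)))
    dc = int(round(half * np.cos(theta)))
    size = 2 * max(abs(dr), abs(dc)) + 1
    fp = np.zeros((size, size), dtype=bool)
    c = size // 2
    rr, cc = draw_line(c - dr, c - dc, c + dr, c + dc)
    fp[rr, cc] = True
    return fp


def ridge_orientation(values: np.ndarray, sigma: float) -> np.ndarray:
    """Local ridge direction (radians in [0, pi)) from the structure tensor.

    The dominant eigenvector of the structure tensor is perpendicular to a
    line; the ridge direction is the minor eigenvector.
    """
    Arr, Arc, Acc = structure_tensor(values, sigma=sigma, order="rc")
    # orientation of the *major* eigenvector in (row, col) coordinates
    theta_major = 0.5 * np.arctan2(2 * Arc, Acc - Arr)
    theta = theta_major + np.pi / 2.0
    return np.mod(theta, np.pi)


def reconnect(
    rmap: RidgeMap,
    segment_length_px: int = 20,
    n_orientations: int = 8,
    orientation: np.ndarray | None = None,
) -> RidgeMap:
    """Spatially variant morphological closing along the local ridge direction.

    For each of ``n_orientations`` direction bins a grayscale closing with a
    linear structuring element of ``segment_length_px`` is computed; each
    pixel takes the closing of its own orientation bin.  The result is
    pointwise >= the input (closings are extensive) and, for a fixed
    ``orientation`` field, idempotent.
    """
    if segment_length_px < 3:
        raise ValueError("segment_length_px must be >= 3")
    A = rmap.values
    if A.size == 0 or not np.any(A):
        return RidgeMap(A.copy(), rmap.best_scale.copy(), rmap.pixel_size_um)
    if orientation is None:
        orientation = ridge_orientation(A, sigma=max(1.0, segment_length_px / 4.0))
    # bins centered on k*pi/n so axis-aligned fibers get an axis-aligned element
    bins = np.round(orientation / (np.pi / n_orientations)).astype(int) % n_orientations
    out = A.copy()
    for b in range(n_orientations):
        sel = bins == b
        if not sel.any():
            continue
        theta = b * np.pi / n_orientations
        fp = _line_footprint(segment_length_px, theta)
        closed = ndimage.grey_closing(A, footprint=fp, mode="constant", cval=0.0)
        out[sel] = closed[sel]
    out = np.maximum(out, A)
    return RidgeMap(np.clip(out, 0.0, 1.0), rmap.best_scale.copy(), rmap.pixel_size_um)


# ---------------------------------------------------------------------------
# skeleton graph helpers


_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant", cval=0)


def _walk_branch(skel, start, max_len):
    """Walk from an endpoint until a junction / endpoint / length limit.

    Returns (branch_pixels, terminal_kind) with terminal_kind in
    {"junction", "endpoint", "long"}.
    """
    counts = _neighbor_counts(skel)
    branch = [start]
    prev = None
    cur = start
    while True:
        if len(branch) > max_len:
            return branch, "long"
        nbrs = [
            (cur[0] + dr, cur[1] + dc)
            for dr, dc in _NBR
            if 0 <= cur[0] + dr < skel.shape[0]
            and 0 <= cur[1] + dc < skel.shape[1]
            and skel[cur[0] + dr, cur[1] + dc]
            and (cur[0] + dr, cur[1] + dc) != prev
        ]
        if prev is not None:
            nbrs = [p for p in nbrs if p not in branch]
        if not nbrs:
            return branch, "endpoint"
        if counts[cur] >= 3 and len(branch) > 1:
            return branch[:-1], "junction"
        nxt = nbrs[0]
        if counts[nxt] >= 3:
            return branch, "junction"
        prev, cur = cur, nxt
        branch.append(cur)


def _prune_spurs(skel: np.ndarray, spur_px: int) -> np.ndarray:
    """Iteratively remove endpoint branches shorter than ``spur_px`` that
    terminate at a junction (whole-path components are preserved)."""
    skel = skel.copy()
    while True:
        counts = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        removed = False
        for ep in map(tuple, endpoints):
            if not skel[ep]:
                continue
            branch, kind = _walk_branch(skel, ep, spur_px)
            if kind == "junction" and len(branch) <= spur_px:
                for p in branch:
                    skel[p] = False
                removed = True
        if not removed:
            return skel


def _order_path(skel: np.ndarray) -> np.ndarray | None:
    """Order the pixels of a simple-path skeleton end to end.

    Returns None if the skeleton is not a simple path (branching remains).
    """
    counts = _neighbor_counts(skel)
    pts = np.argwhere(skel)
    if len(pts) == 0:
        return None
    if np.any(counts[skel] > 2):
        return None
    ends = np.argwhere(skel & (counts <= 1))
    if len(ends) == 0:  # cycle
        return None
    start = tuple(ends[0])
    ordered = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        for dr, dc in _NBR:
            p = (cur[0] + dr, cur[1] + dc)
            if (
                0 <= p[0] < skel.shape[0]
                and 0 <= p[1] < skel.shape[1]
                and skel[p]
                and p not in visited
            ):
                nxt = p
                break
        if nxt is None:
            break
        ordered.append(nxt)
        visited.add(nxt)
        cur = nxt
    if len(ordered) != int(skel.sum()):
        return None
    return np.asarray(ordered, dtype=float)


def _fit_trace(
    ordered_px: np.ndarray,
    component_id: int,
    pixel_size_um: float,
    smoothing: float,
    arc_step_px: float,
    ambiguous: bool = False,
) -> FiberTrace | None:
    """Smoothing B-spline fit + uniform arclength resampling of an ordered
    pixel chain."""
    n = len(ordered_px)
    if n < 4:
        return None
    k = 3 if n > 3 else max(1, n - 1)
    try:
        tck, _ = interpolate.splprep(
            [ordered_px[:, 0], ordered_px[:, 1]], s=smoothing * n, k=k
        )
    except (TypeError, ValueError):
        return None
    u = np.linspace(0.0, 1.0, max(10 * n, 100))
    rr, cc = interpolate.splev(u, tck)
    pts = np.column_stack([rr, cc])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        return None
    n_samples = max(2, int(np.floor(total / arc_step_px)) + 1)
    arc_target = np.linspace(0.0, total, n_samples)
    u_target = np.interp(arc_target, arc, u)
    rr, cc = interpolate.splev(u_target, tck)
    return FiberTrace(
        points=np.column_stack([rr, cc]),
        arclength_um=arc_target * pixel_size_um,
        component_id=component_id,
        pixel_size_um=pixel_size_um,
        ambiguous=ambiguous,
        spline=tck,
    )


def extract_traces(
    rmap: RidgeMap,
    threshold: float = 0.5,
    min_length_um: float = 3.0,
    spur_px: int = 5,
    smoothing: float = 0.2,
    arc_step_px: float = 1.0,
    include_ambiguous: bool = False,
) -> list[FiberTrace]:
    """Threshold the ridge map, identify fibers as connected components and
    extract one subpixel centerline per simple-path skeleton.

    Components whose pruned skeleton still branches (crossing fibers) are
    flagged ``ambiguous`` and excluded unless ``include_ambiguous``.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    binary = rmap.values >= threshold
    labels = cc_label(binary, connectivity=2)
    traces: list[FiberTrace] = []
    for comp in range(1, labels.max() + 1):
        mask = labels == comp
        if mask.sum() < 4:
            continue
        skel = skeletonize(mask)
        skel = _prune_spurs(skel, spur_px)
        if skel.sum() < 4:
            continue
        ordered = _order_path(skel)
        if ordered is None:
            if include_ambiguous:
                pts = np.argwhere(skel).astype(float)
                trace = _fit_trace(
                    pts, comp, rmap.pixel_size_um, smoothing, arc_step_px, ambiguous=True
                )
                if trace is not None:
                    traces.append(trace)
            continue
        trace = _fit_trace(ordered, comp, rmap.pixel_size_um, smoothing, arc_step_px)
        if trace is None:
            continue
        if trace.length_um >= min_length_um:
            traces.append(trace)
    return traces
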