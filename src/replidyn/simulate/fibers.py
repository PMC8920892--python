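"""Synthetic DNA-fiber image generator with exact ground truth.

Each fiber is a gently curved quadratic/cubic B-spline path in the slide
plane.  Fork events (origin position, left/right speeds, firing time,
optional stall) paint first-pulse and second-pulse analog tracks along the
path using the stretched-fiber conversion 1 um = 2 kb: a fork moving at
``v`` kb/min covers ``v/2`` um/min, so a 30-min pulse at 1 kb/min leaves a
15-um track per fork.  Rendering applies a Gaussian PSF and mixed
Poisson-Gaussian noise; the returned ground truth (segment boundaries,
pattern class, fork speeds, origin positions, inter-origin distances) is
computed analytically before any rendering, so it is metameric-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from ..fiber_imaging import FiberImage
from ..fiber_patterns import (
    FIRST,
    SECOND,
    UNLABELED,
    BranchSegmentation,
    Segment,
    classify_pattern,
)
from ..protocol import KB_PER_UM, PulseProtocol

__all__ = [
    "ForkEvent",
    "FiberSpec",
    "NoiseParams",
    "FiberGroundTruth",
    "FiberCollisionError",
    "render_fiber_image",
    "true_segments",
    "make_path",
]


@dataclass(frozen=True)
class ForkEvent:
    """One origin with a left and a right fork.

    ``firing_time_min`` is relative to the start of the first pulse (may be
    negative for origins fired before labeling); ``stall_time_min`` stops
    both forks at that absolute time.  Speeds are in kb/min (>= 0).
    """

    origin_um: float
    left_speed_kb_min: float = 0.0
    right_speed_kb_min: float = 0.0
    firing_time_min: float = 0.0
    stall_time_min: float | None = None

    def __post_init__(self) -> None:
        if self.left_speed_kb_min < 0 or self.right_speed_kb_min < 0:
            raise ValueError("fork speeds must be non-negative")


@dataclass
class FiberSpec:
    """Planar fiber path (control points, um) plus its replication events."""

    control_points_um: np.ndarray
    fork_events: list[ForkEvent] = field(default_factory=list)
    label_gaps_um: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.control_points_um = np.asarray(self.control_points_um, dtype=float)
        if self.control_points_um.ndim != 2 or self.control_points_um.shape[1] != 2:
            raise ValueError("control points must be (n, 2)")


@dataclass(frozen=True)
class NoiseParams:
    """Confocal-regime acquisition noise: Gaussian PSF, Poisson shot noise
    and Gaussian read noise (as a fraction of the dynamic range)."""

    psf_sigma_px: float = 1.5
    photons_per_px: float = 400.0
    background_photons: float = 10.0
    read_noise_frac: float = 0.02
    enable: bool = True

    def noiseless(self) -> "NoiseParams":
        return NoiseParams(self.psf_sigma_px, self.photons_per_px,
                           self.background_photons, self.read_noise_frac, enable=False)


@dataclass
class FiberGroundTruth:
    """Planted truth for one rendered image (one entry per fiber)."""

    patterns: list[str]
    segments_um: list[list[Segment]]
    fork_speeds_kb_min: list[list[float]]
    second_track_lengths_um: list[list[float]]
    origin_positions_um: list[np.ndarray]
    iods_um: list[np.ndarray]
    paths_px: list[np.ndarray]
    pixel_size_um: float


class FiberCollisionError(ValueError):
    def __init__(self, pairs):
        self.pairs = pairs
        super().__init__(f"fibers too close to resolve: {pairs}")


# ---------------------------------------------------------------------------
# geometry


def make_path(
    length_um: float,
    start_um: tuple[float, float] = (0.0, 0.0),
    waviness_um: float = 0.5,
    n_control: int = 6,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Control points of a gently curved, non-self-intersecting fiber path:
    monotone in x with bounded transverse wobble (stretched-fiber
    morphology, so curvature stays small)."""
    rng = rng or np.random.default_rng(0)
    xs = np.linspace(0.0, length_um, n_control)
    ys = rng.normal(0.0, waviness_um, n_control)
    ys -= ys.mean()
    return np.column_stack([xs + start_um[0], ys + start_um[1]])


def _path_spline(spec: FiberSpec):
    """Arclength-parameterized path: returns (total_length_um, sampler)
    where sampler(s_um) -> (n, 2) positions in um."""
    cp = spec.control_points_um
    k = min(2, len(cp) - 1)
    tck, _ = interpolate.splprep([cp[:, 0], cp[:, 1]], s=0.0, k=k)
    u = np.linspace(0, 1, 2000)
    xy = np.column_stack(interpolate.splev(u, tck))
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arc[-1])

    def sampler(s_um: np.ndarray) -> np.ndarray:
        uu = np.interp(np.clip(s_um, 0, total), arc, u)
        return np.column_stack(interpolate.splev(uu, tck))

    return total, sampler


# ---------------------------------------------------------------------------
# analytic painted intervals


def _painted_intervals(
    spec: FiberSpec, protocol: PulseProtocol, path_length_um: float
) -> dict[str, list[tuple[float, float]]]:
    """Exact arclength intervals covered by each analog, before any optics:
    each fork paints speed x (time in pulse) x (1 um / 2 kb) from where it
    stood at the window start, bidirectionally from the origin."""
    p1, p2 = protocol.first_pulse_min, protocol.second_pulse_min
    windows = {FIRST: (0.0, p1), SECOND: (p1, p1 + p2)}
    out: dict[str, list[tuple[float, float]]] = {FIRST: [], SECOND: []}
    for ev in spec.fork_events:
        if ev.firing_time_min > p1 + p2:
            raise ValueError("firing time beyond the end of the second pulse")
        stop = ev.stall_time_min if ev.stall_time_min is not None else np.inf
        for sign, v_kb in ((-1.0, ev.left_speed_kb_min), (1.0, ev.right_speed_kb_min)):
            v_um = v_kb / KB_PER_UM
            if v_um <= 0:
                continue
            for label, (w0, w1) in windows.items():
                t0 = max(ev.firing_time_min, w0)
                t1 = min(w1, stop)
                if t1 <= t0:
                    continue
                d0 = v_um * (t0 - ev.firing_time_min)
                d1 = v_um * (t1 - ev.firing_time_min)
                a = ev.origin_um + sign * d0
                b = ev.origin_um + sign * d1
                lo, hi = min(a, b), max(a, b)
                lo, hi = max(0.0, lo), min(path_length_um, hi)
                if hi > lo:
                    out[label].append((lo, hi))
    # carve out unlabeled gaps
    for label in out:
        out[label] = _subtract_gaps(_merge(out[label]), spec.label_gaps_um)
    return out


def _merge(ivs):
    ivs = sorted(ivs)
    out = []
    for lo, hi in ivs:
        if out and lo <= out[-1][1] + 1e-9:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _subtract_gaps(ivs, gaps):
    for g0, g1 in sorted(gaps):
        nxt = []
        for lo, hi in ivs:
            if g1 <= lo or g0 >= hi:
                nxt.append((lo, hi))
                continue
            if lo < g0:
                nxt.append((lo, g0))
            if g1 < hi:
                nxt.append((g1, hi))
        ivs = nxt
    return ivs


def true_segments(
    spec: FiberSpec, protocol: PulseProtocol, path_length_um: float
) -> list[Segment]:
    """Ground-truth label segmentation of one fiber (contiguous first /
    second / unlabeled segments covering the whole path)."""
    painted = _painted_intervals(spec, protocol, path_length_um)
    edges = {0.0, path_length_um}
    for ivs in painted.values():
        for lo, hi in ivs:
            edges.update((lo, hi))
    edges = sorted(edges)
    segs: list[Segment] = []
    for lo, hi in zip(edges, edges[1:]):
        if hi - lo <= 1e-9:
            continue
        mid = 0.5 * (lo + hi)
        in_first = any(a <= mid < b for a, b in painted[FIRST])
        in_second = any(a <= mid < b for a, b in painted[SECOND])
        if in_first and not in_second:
            label = FIRST
        elif in_second and not in_first:
            label = SECOND
        elif in_first and in_second:
            label = FIRST  # overlap painted by both; dominated by earlier analog
        else:
            label = UNLABELED
        if segs and segs[-1].label == label:
            segs[-1] = Segment(segs[-1].start_um, hi, label)
        else:
            segs.append(Segment(lo, hi, label))
    return segs


# ---------------------------------------------------------------------------
# rendering


def render_fiber_image(
    specs: list[FiberSpec],
    protocol: PulseProtocol | None = None,
    pixel_size_um: float = 0.142,
    noise: NoiseParams | None = None,
    seed: int = 0,
    exclusion_um: float = 1.0,
    margin_px: int = 12,
    include_dna_channel: bool = True,
) -> tuple[FiberImage, FiberGroundTruth]:
    """Render fibers into a dual/triple-channel image and return the truth.

    Fibers closer than ``exclusion_um`` anywhere along their paths are
    rejected with a :class:`FiberCollisionError` listing the colliding
    indices.  Ground truth is returned both in um along each path and as
    pixel-coordinate path samples.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    protocol = protocol or PulseProtocol()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    lengths, samplers = [], []
    for spec in specs:
        L, sampler = _path_spline(spec)
        lengths.append(L)
        samplers.append(sampler)

    step_um = pixel_size_um / 3.0  # dense path sampling for painting
    dense_pts_um = []
    for L, sampler in zip(lengths, samplers):
        s = np.arange(0.0, L + step_um, step_um)
        dense_pts_um.append(sampler(np.clip(s, 0, L)))

    if len(specs) > 1:
        pairs = []
        trees = [cKDTree(p) for p in dense_pts_um]
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                d = trees[i].query(dense_pts_um[j], k=1)[0].min()
                if d < exclusion_um:
                    pairs.append((i, j))
        if pairs:
            raise FiberCollisionError(pairs)

    all_pts = np.vstack(dense_pts_um)
    origin = all_pts.min(axis=0) - margin_px * pixel_size_um
    extent = all_pts.max(axis=0) - origin + margin_px * pixel_size_um
    shape = (
        int(np.ceil(extent[1] / pixel_size_um)) + 1,  # rows from y
        int(np.ceil(extent[0] / pixel_size_um)) + 1,  # cols from x
    )

    def to_px(xy_um: np.ndarray) -> np.ndarray:
        rel = xy_um - origin
        return np.column_stack([rel[:, 1] / pixel_size_um, rel[:, 0] / pixel_size_um])

    channels = {FIRST: np.zeros(shape), SECOND: np.zeros(shape)}
    if include_dna_channel:
        channels["dna"] = np.zeros(shape)
    # photon density per unit path length, normalized so a line's blurred
    # cross-section peaks near photons_per_px
    density = noise.photons_per_px * np.sqrt(2 * np.pi) * noise.psf_sigma_px
    deposit = density * (step_um / pixel_size_um)

    gt = FiberGroundTruth([], [], [], [], [], [], [], pixel_size_um)
    for spec, L, sampler, dense in zip(specs, lengths, samplers, dense_pts_um):
        painted = _painted_intervals(spec, protocol, L)
        for label, ivs in painted.items():
            for lo, hi in ivs:
                s = np.arange(lo, hi, step_um)
                if len(s) == 0:
                    continue
                _paint(channels[label], to_px(sampler(s)), deposit)
        if include_dna_channel:
            _paint(channels["dna"], to_px(dense), 0.5 * deposit)
        segs = true_segments(spec, protocol, L)
        pattern = classify_pattern(BranchSegmentation(list(segs)))
        fired = sorted(
            ev.origin_um
            for ev in spec.fork_events
            if ev.firing_time_min <= protocol.total_min
        )
        origins = np.asarray(fired)
        gt.patterns.append(pattern.pattern)
        gt.segments_um.append(segs)
        gt.fork_speeds_kb_min.append(
            [s for ev in spec.fork_events for s in (ev.left_speed_kb_min, ev.right_speed_kb_min) if s > 0]
        )
        gt.second_track_lengths_um.append(list(pattern.second_track_lengths_um))
        gt.origin_positions_um.append(origins)
        gt.iods_um.append(np.diff(origins))
        gt.paths_px.append(to_px(dense))

    for role, img in channels.items():
        blurred = ndimage.gaussian_filter(img, noise.psf_sigma_px)
        signal = blurred + noise.background_photons
        if noise.enable:
            sampled = rng.poisson(np.clip(signal, 0, None)).astype(float)
            read_sd = noise.read_noise_frac * max(signal.max(), 1.0)
            sampled += rng.normal(0.0, read_sd, size=signal.shape)
            channels[role] = sampled
        else:
            channels[role] = signal
    return FiberImage(channels=channels, pixel_size_um=pixel_size_um), gt


def _paint(img: np.ndarray, pts_px: np.ndarray, amount: float) -> None:
    rr = np.round(pts_px[:, 0]).astype(int)
    cc = np.round(pts_px[:, 1]).astype(int)
    keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
    np.add.at(img, (rr[keep], cc[keep]), amount)
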