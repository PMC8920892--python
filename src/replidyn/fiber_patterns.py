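"""Branch detection along DNA fibers and replication-pattern classification.

Dual-channel intensity profiles are sampled along each fiber's median line.
Because the two analog channels are not directly comparable in absolute
intensity, segmentation operates on the logarithm of their point-wise ratio.
A CART-style regression tree (greedy recursive binary splitting of the
log-ratio sequence, accepted only above a complexity threshold; the chosen
boundaries are then re-placed exactly by dynamic programming, so they match
an exhaustive changepoint search) partitions each fiber into
piecewise-constant label branches, which a fixed grammar maps to a
replication pattern class:

    [first, second] / [second, first]      ongoing fork
    [first]                                stalled after first label
    [second]                               second-pulse origin
    [second, first, second]                first-pulse origin
    [first, second, first]                 termination
    >= 4 alternations                      multiple origins

Anything else is ambiguous by contract and excluded from statistics unless
accepted in review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fiber_imaging import FiberImage, FiberTrace
from .protocol import PulseProtocol

__all__ = [
    "LabelProfile",
    "Segment",
    "BranchSegmentation",
    "FiberPattern",
    "sample_profiles",
    "cart_segment",
    "classify_pattern",
    "review_queue",
]

FIRST = "first"
SECOND = "second"
UNLABELED = "unlabeled"

PATTERN_CLASSES = (
    "ongoing_fork",
    "stalled_after_first_label",
    "first_pulse_origin",
    "second_pulse_origin",
    "termination",
    "multi_origin",
    "ambiguous",
)


@dataclass
class LabelProfile:
    """Per-arclength channel intensities along one fiber.

    ``log_ratio`` is log(first/second) after background subtraction and is
    meaningful only where ``labeled_mask`` is True (total label intensity
    above background).
    """

    arclength_um: np.ndarray
    first: np.ndarray
    second: np.ndarray
    log_ratio: np.ndarray
    labeled_mask: np.ndarray
    fiber_id: int = -1

    def __post_init__(self) -> None:
        n = len(self.arclength_um)
        for name in ("first", "second", "log_ratio", "labeled_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError("profile fields must share one grid")

    @property
    def step_um(self) -> float:
        if len(self.arclength_um) < 2:
            return 0.0
        return float(np.median(np.diff(self.arclength_um)))


@dataclass(frozen=True)
class Segment:
    start_um: float
    end_um: float
    label: str
    mean_log_ratio: float = np.nan

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass
class BranchSegmentation:
    """Contiguous, non-overlapping label segments covering one fiber."""

    segments: list[Segment]
    fiber_id: int = -1

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.end_um, b.start_um):
                raise ValueError("segments must be contiguous")
            if a.label == b.label:
                raise ValueError("adjacent segments must have distinct labels")

    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.segments)


@dataclass
class FiberPattern:
    """Replication-pattern call for one fiber plus per-class measurements."""

    pattern: str
    fiber_id: int = -1
    n_origins: int = 0
    n_forks: int = 0
    second_track_lengths_um: list[float] = field(default_factory=list)
    first_track_lengths_um: list[float] = field(default_factory=list)
    origin_boundaries_um: list[tuple[float, float]] = field(default_factory=list)
    trace_length_um: float = np.nan
    snr: float = np.nan


# ---------------------------------------------------------------------------
# profile sampling


def _background(channel: np.ndarray) -> tuple[float, float]:
    """Robust background level and spread (fibers are sparse, so the median
    and MAD of the whole channel estimate the off-fiber distribution)."""
    med = float(np.median(channel))
    mad = float(np.median(np.abs(channel - med)))
    return med, 1.4826 * mad


def sample_profiles(
    image: FiberImage,
    trace: FiberTrace,
    width_px: int = 5,
    k_sigma: float = 3.0,
    rel_floor: float = 0.2,
) -> LabelProfile:
    """Sample both label channels along the median line.

    The intensity at each arclength point is the mean over a perpendicular
    cross-section of ``width_px`` (odd).  A point is labeled when the summed
    background-subtracted signal exceeds ``k_sigma`` background s.d. and a
    relative floor of ``rel_floor`` times the profile peak (the latter sets
    the half-response track edge under pure PSF blur).
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be odd and >= 1")
    pts = trace.points
    tang = trace.tangents()
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(width_px) - width_px // 2
    rows = pts[:, 0][:, None] + offsets[None, :] * normal[:, 0][:, None]
    cols = pts[:, 1][:, None] + offsets[None, :] * normal[:, 1][:, None]
    shape = image.shape
    inside = (rows >= 0) & (rows <= shape[0] - 1) & (cols >= 0) & (cols <= shape[1] - 1)
    if not inside.all():
        import warnings

        warnings.warn("trace leaves image bounds; cross-sections truncated")
    out: dict[str, np.ndarray] = {}
    for role in (FIRST, SECOND):
        ch = image.channels[role]
        vals = ndimage.map_coordinates(
            ch, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(rows.shape)
        out[role] = vals.mean(axis=1)
    bg1, s1 = _background(image.channels[FIRST])
    bg2, s2 = _background(image.channels[SECOND])
    f = out[FIRST] - bg1
    s = out[SECOND] - bg2
    total = f + s
    sigma_bg = float(np.hypot(s1, s2)) / np.sqrt(width_px)
    peak = float(total.max()) if len(total) else 0.0
    thresh = max(k_sigma * sigma_bg, rel_floor * peak)
    labeled = total > thresh
    eps = max(1e-12, 1e-3 * peak)
    log_ratio = np.log(np.clip(f, eps, None) / np.clip(s, eps, None))
    log_ratio = np.where(labeled, log_ratio, np.nan)
    return LabelProfile(
        arclength_um=trace.arclength_um.copy(),
        first=out[FIRST],
        second=out[SECOND],
        log_ratio=log_ratio,
        labeled_mask=labeled,
        fiber_id=trace.component_id,
    )


# ---------------------------------------------------------------------------
# CART changepoint segmentation


def _sse(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-segment squared error of values[i:j] from prefix sums."""
    n = j - i
    if n <= 0:
        return 0.0
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return float(s2 - s * s / n)


def _best_split(prefix, prefix2, i, j, min_pts):
    """Best single changepoint of values[i:j]; returns (split, gain) or None."""
    n = j - i
    if n < 2 * min_pts:
        return None
    ks = np.arange(i + min_pts, j - min_pts + 1)
    sl = prefix[ks] - prefix[i]
    s2l = prefix2[ks] - prefix2[i]
    nl = ks - i
    sr = prefix[j] - prefix[ks]
    s2r = prefix2[j] - prefix2[ks]
    nr = j - ks
    sse_tot = (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
    best = int(np.argmin(sse_tot))
    gain = _sse(prefix, prefix2, i, j) - float(sse_tot[best])
    return int(ks[best]), gain


def _grow_tree(prefix, prefix2, i, j, min_pts, min_gain, cuts):
    res = _best_split(prefix, prefix2, i, j, min_pts)
    if res is None:
        return
    k, gain = res
    if gain < min_gain:
        return
    cuts.append(k)
    _grow_tree(prefix, prefix2, i, k, min_pts, min_gain, cuts)
    _grow_tree(prefix, prefix2, k, j, min_pts, min_gain, cuts)


def _refine_cuts(prefix, prefix2, i, j, cuts, min_pts):
    """Exact placement of the boundaries found by the tree: dynamic
    programming over all partitions of values[i:j] into len(cuts)+1
    segments of at least ``min_pts`` points, minimizing total SSE.  The
    tree chooses the number of segments; this recovers the global optimum
    for that number (equal to exhaustive changepoint search)."""
    k = len(cuts)
    if k == 0:
        return []
    n = j - i

    def seg_sse(a, b):
        # SSE of values[i+a : i+b] for vector a, scalar b
        s = prefix[i + b] - prefix[i + a]
        m = b - a
        return (prefix2[i + b] - prefix2[i + a]) - s * s / m

    n_segs = k + 1
    INF = np.inf
    cost = np.full((n + 1, n_segs + 1), INF)
    back = np.zeros((n + 1, n_segs + 1), dtype=int)
    ends = np.arange(min_pts, n + 1)
    cost[ends, 1] = seg_sse(np.zeros(len(ends), dtype=int), ends)
    for m in range(2, n_segs + 1):
        for b in range(m * min_pts, n - (n_segs - m) * min_pts + 1):
            a = np.arange((m - 1) * min_pts, b - min_pts + 1)
            cand = cost[a, m - 1] + seg_sse(a, b)
            best = int(np.argmin(cand))
            cost[b, m] = cand[best]
            back[b, m] = int(a[best])
    out = []
    b = n
    for m in range(n_segs, 1, -1):
        b = int(back[b, m])
        out.append(b)
    return sorted(out)


def _runs(mask: np.ndarray):
    """Contiguous runs of a boolean array as (start, end, value)."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        out.append((i, j, bool(mask[i])))
        i = j
    return out


def cart_segment(
    profile: LabelProfile,
    min_segment_um: float = 1.0,
    complexity: float = 0.01,
    dead_zone: float = 0.2,
) -> BranchSegmentation:
    """Partition a fiber's log-ratio profile into label branches.

    Within each labeled stretch, a regression tree recursively splits the
    log-ratio sequence at the changepoint minimizing within-segment squared
    error; a split is accepted only if its error reduction is at least
    ``complexity`` times the total profile SSE and both children span
    ``min_segment_um``.  Leaves map to first/second by the sign of their mean
    log ratio; leaves inside the ``dead_zone`` (|mean| < dead_zone) merge
    with the neighboring leaf of closest mean.  Unlabeled stretches become
    unlabeled segments.  The result is invariant to a common positive
    rescaling of both channels.
    """
    h = profile.step_um
    n = len(profile.arclength_um)
    if n == 0:
        raise ValueError("empty profile")
    min_pts = max(1, int(round(min_segment_um / h))) if h > 0 else 1
    labeled_runs = _runs(profile.labeled_mask)
    # total SSE over all labeled points sets the split-acceptance scale
    lab_vals = profile.log_ratio[profile.labeled_mask]
    if lab_vals.size == 0:
        seg = Segment(profile.arclength_um[0], float(profile.arclength_um[-1] + h), UNLABELED)
        return BranchSegmentation([seg], fiber_id=profile.fiber_id)
    total_sse = float(np.sum((lab_vals - lab_vals.mean()) ** 2))
    min_gain = complexity * total_sse

    def edge_um(idx: int) -> float:
        # boundary between grid points idx-1 and idx
        if idx <= 0:
            return float(profile.arclength_um[0] - h / 2)
        if idx >= n:
            return float(profile.arclength_um[-1] + h / 2)
        return float(0.5 * (profile.arclength_um[idx - 1] + profile.arclength_um[idx]))

    pieces: list[Segment] = []
    for i, j, is_labeled in labeled_runs:
        if not is_labeled:
            pieces.append(Segment(edge_um(i), edge_um(j), UNLABELED))
            continue
        vals = profile.log_ratio[i:j]
        prefix = np.concatenate([[0.0], np.cumsum(vals)])
        prefix2 = np.concatenate([[0.0], np.cumsum(vals**2)])
        # index prefix arrays relative to run start
        cuts: list[int] = []
        _grow_tree(prefix, prefix2, 0, j - i, min_pts, min_gain, cuts)
        cuts = _refine_cuts(prefix, prefix2, 0, j - i, cuts, min_pts)
        bounds = [0] + cuts + [j - i]
        leaves = [
            (a, b, float((prefix[b] - prefix[a]) / (b - a)))
            for a, b in zip(bounds, bounds[1:])
        ]
        leaves = _merge_dead_zone(leaves, dead_zone)
        for a, b, mean in leaves:
            label = FIRST if mean > 0 else SECOND
            pieces.append(Segment(edge_um(i + a), edge_um(i + b), label, mean))
    pieces = _merge_adjacent(pieces)
    return BranchSegmentation(pieces, fiber_id=profile.fiber_id)


def _merge_dead_zone(leaves, dead_zone):
    """Merge leaves with |mean| < dead_zone into the neighbor of closest mean."""
    leaves = list(leaves)
    while len(leaves) > 1:
        idx = None
        for k, (a, b, m) in enumerate(leaves):
            if abs(m) < dead_zone:
                idx = k
                break
        if idx is None:
            break
        a, b, m = leaves[idx]
        cand = []
        if idx > 0:
            cand.append((abs(leaves[idx - 1][2] - m), idx - 1))
        if idx + 1 < len(leaves):
            cand.append((abs(leaves[idx + 1][2] - m), idx + 1))
        _, nb = min(cand)
        na, nb_end, nm = leaves[nb]
        lo, hi = min(a, na), max(b, nb_end)
        w1, w2 = b - a, nb_end - na
        merged = (lo, hi, (m * w1 + nm * w2) / (w1 + w2))
        lo_idx = min(idx, nb)
        leaves[lo_idx : lo_idx + 2] = [merged]
    return leaves


def _merge_adjacent(pieces: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in pieces:
        if out and out[-1].label == seg.label:
            prev = out[-1]
            w1, w2 = prev.length_um, seg.length_um
            if w1 + w2 > 0 and prev.label != UNLABELED:
                mean = (prev.mean_log_ratio * w1 + seg.mean_log_ratio * w2) / (w1 + w2)
            else:
                mean = prev.mean_log_ratio
            out[-1] = Segment(prev.start_um, seg.end_um, prev.label, mean)
        else:
            out.append(seg)
    return out


# ---------------------------------------------------------------------------
# grammar classification


def _classify_sequence(seq: tuple[str, ...]) -> tuple[str, int, int]:
    """Map a label sequence to (pattern, n_origins, n_forks)."""
    F, S = FIRST, SECOND
    if seq in ((F, S), (S, F)):
        return "ongoing_fork", 0, 1
    if seq == (F,):
        return "stalled_after_first_label", 0, 0
    if seq == (S,):
        return "second_pulse_origin", 1, 0
    if seq == (S, F, S):
        return "first_pulse_origin", 1, 0
    if seq == (F, S, F):
        return "termination", 0, 0
    if len(seq) >= 4:
        n_origins = sum(
            1
            for k in range(1, len(seq) - 1)
            if seq[k] == F and seq[k - 1] == S and seq[k + 1] == S
        )
        # leading [first, second] or trailing [second, first] edges are
        # elongating forks attached to the origin cluster
        n_forks = int(seq[0] == F) + int(seq[-1] == F)
        return "multi_origin", n_origins, n_forks
    return "ambiguous", 0, 0


def classify_pattern(
    seg: BranchSegmentation,
    protocol: PulseProtocol | None = None,
    gap_tolerance_um: float = 2.0,
) -> FiberPattern:
    """Classify the replication pattern of a segmented fiber.

    Unlabeled segments shorter than ``gap_tolerance_um`` are elided (their
    flanking labels merge when equal); larger internal gaps split the fiber
    into independent events.  A fiber hosting a single event takes that
    event's class; multi-event fibers are reported ambiguous (their events
    still contribute origin/fork counts).
    """
    labeled = [s for s in seg.segments if s.label != UNLABELED]
    if not labeled:
        return FiberPattern("ambiguous", fiber_id=seg.fiber_id)
    # drop leading/trailing unlabeled, elide short internal gaps
    inner = [
        s
        for s in seg.segments
        if s.label != UNLABELED or s.length_um >= gap_tolerance_um
    ]
    while inner and inner[0].label == UNLABELED:
        inner.pop(0)
    while inner and inner[-1].label == UNLABELED:
        inner.pop()
    events: list[list[Segment]] = [[]]
    for s in inner:
        if s.label == UNLABELED:
            events.append([])
        else:
            if events[-1] and events[-1][-1].label == s.label:
                prev = events[-1][-1]
                events[-1][-1] = Segment(
                    prev.start_um, s.end_um, s.label, prev.mean_log_ratio
                )
            else:
                events[-1].append(s)
    events = [e for e in events if e]
    results = [(_classify_sequence(tuple(x.label for x in e)), e) for e in events]
    n_origins = sum(r[0][1] for r in results)
    n_forks = sum(r[0][2] for r in results)
    pattern = results[0][0][0] if len(results) == 1 else "ambiguous"
    pat = FiberPattern(
        pattern,
        fiber_id=seg.fiber_id,
        n_origins=n_origins,
        n_forks=n_forks,
    )
    for (_, _, _), e in results:
        for k, s in enumerate(e):
            if s.label == SECOND:
                # only second-label tracks adjacent to a first-label track
                # measure ongoing synthesis (continuation forks)
                adj_first = (k > 0 and e[k - 1].label == FIRST) or (
                    k + 1 < len(e) and e[k + 1].label == FIRST
                )
                if adj_first:
                    pat.second_track_lengths_um.append(s.length_um)
            else:
                pat.first_track_lengths_um.append(s.length_um)
                flanked = (
                    0 < k < len(e) - 1
                    and e[k - 1].label == SECOND
                    and e[k + 1].label == SECOND
                )
                if flanked or tuple(x.label for x in e) == (SECOND, FIRST, SECOND):
                    pat.origin_boundaries_um.append((s.start_um, s.end_um))
    last = seg.segments[-1].end_um
    pat.trace_length_um = last - seg.segments[0].start_um
    return pat


# ---------------------------------------------------------------------------
# review queue


def review_queue(
    patterns: list[FiberPattern],
    min_length_um: float = 3.0,
    min_snr: float = 0.0,
    reject_ids: list[int] | None = None,
) -> tuple[pd.DataFrame, list[FiberPattern]]:
    """Semi-automated curation stage.

    Emits a reviewable table of flagged fibers (ambiguous, short, low SNR)
    and applies an accept/reject id list on re-import.  Deterministic given
    the list; unknown ids in the reject list are an error.
    """
    known = {p.fiber_id for p in patterns}
    reject = set(reject_ids or [])
    unknown = reject - known
    if unknown:
        raise ValueError(f"reject list references unknown fiber ids: {sorted(unknown)}")
    rows = []
    for p in patterns:
        flags = []
        if p.pattern == "ambiguous":
            flags.append("ambiguous")
        if np.isfinite(p.trace_length_um) and p.trace_length_um < min_length_um:
            flags.append("short")
        if np.isfinite(p.snr) and p.snr < min_snr:
            flags.append("low_snr")
        if flags:
            rows.append({"fiber_id": p.fiber_id, "pattern": p.pattern, "flags": ";".join(flags)})
    queue = pd.DataFrame(rows, columns=["fiber_id", "pattern", "flags"])
    curated = [p for p in patterns if p.fiber_id not in reject]
    return queue, curated
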