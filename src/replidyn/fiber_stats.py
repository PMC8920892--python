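"""Fiber-level statistics: fork speed, origins and inter-origin distances,
pattern proportions and group comparisons.

Fork speed uses the established stretching conversion 1 um = 2 kb, so
``speed = track_length_um * 2 / pulse_min`` in kb/min.  Speeds of ongoing
forks are measured on the second-pulse track (standard fiber-assay
convention); first-pulse-only fibers are excluded from speed but counted in
pattern proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fiber_imaging import FiberImage, FiberTrace
from .fiber_patterns import FiberPattern
from .protocol import KB_PER_UM

__all__ = [
    "ForkMeasurement",
    "IODMeasurement",
    "fork_speed",
    "straighten",
    "origins_and_iods",
    "pattern_proportion_test",
    "origin_to_fork_ratio",
    "group_compare",
]


@dataclass
class ForkMeasurement:
    fiber_id: int
    pattern: str
    track_length_um: float
    speed_kb_min: float
    group: str = ""


@dataclass
class IODMeasurement:
    fiber_id: int
    boundaries_um: np.ndarray
    origins_um: np.ndarray
    iods_um: np.ndarray = field(init=False)
    iods_kb: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.iods_um = np.diff(self.origins_um)
        self.iods_kb = self.iods_um * KB_PER_UM


def fork_speed(track_length_um: float, pulse_min: float) -> float:
    """Fork speed in kb/min from a labeled track length in micrometers."""
    if pulse_min <= 0:
        raise ValueError("pulse_min must be positive")
    if track_length_um < 0:
        raise ValueError("track length must be non-negative")
    return track_length_um * KB_PER_UM / pulse_min


def straighten(image: FiberImage, trace: FiberTrace, width_px: int = 19) -> dict[str, np.ndarray]:
    """Resample the image along a fiber into a straightened strip.

    Each column of the output is the perpendicular cross-section at one
    arclength sample (intensities linearly interpolated), so the strip's x
    axis is arclength in pixels.  Returns one (width_px, n_arc) strip per
    channel role.
    """
    if width_px % 2 == 0 or width_px < 1:
        raise ValueError("width_px must be odd")
    pts = trace.points
    tang = trace.tangents()
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(width_px) - width_px // 2
    rows = pts[:, 0][None, :] + offsets[:, None] * normal[:, 0][None, :]
    cols = pts[:, 1][None, :] + offsets[:, None] * normal[:, 1][None, :]
    strips = {}
    for role, ch in image.channels.items():
        strips[role] = ndimage.map_coordinates(
            ch, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(rows.shape)
    return strips


def origins_and_iods(boundary_xs_um: Sequence[float], fiber_id: int = -1) -> IODMeasurement:
    """Origin positions and inter-origin distances from label boundaries.

    Each origin is flanked by two first/second-label boundaries; its position
    is the mean of the adjacent boundary pair, and IODs are consecutive
    differences between origin positions (in um, and in kb via 1 um = 2 kb).
    """
    b = np.asarray(boundary_xs_um, dtype=float)
    if b.size < 2 or b.size % 2 != 0:
        raise ValueError("unpaired boundary: need an even number of boundaries >= 2")
    if np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    origins = 0.5 * (b[0::2] + b[1::2])
    return IODMeasurement(fiber_id=fiber_id, boundaries_um=b, origins_um=origins)


def pattern_proportion_test(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int], cls: str
) -> dict[str, float]:
    """Two-sample test for equality of proportions with continuity correction.

    Tests whether the proportion of pattern ``cls`` (vs. the rest) differs
    between two fiber populations, using the Yates-corrected chi-square on
    the 2x2 table (the classic two-proportion "binomial" test).
    """
    x1, n1 = counts_a.get(cls, 0), sum(counts_a.values())
    x2, n2 = counts_b.get(cls, 0), sum(counts_b.values())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need a positive total count")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        # a class absent from both groups: no evidence of difference
        return {"proportion_a": x1 / n1, "proportion_b": x2 / n2, "statistic": 0.0, "pvalue": 1.0}
    yates = min(0.5, float(np.abs(table - expected).min()))
    statistic = float(np.sum((np.abs(table - expected) - yates) ** 2 / expected))
    pvalue = float(stats.chi2.sf(statistic, df=1))
    return {
        "proportion_a": x1 / n1,
        "proportion_b": x2 / n2,
        "statistic": statistic,
        "pvalue": pvalue,
    }


def origin_to_fork_ratio(patterns: Sequence[FiberPattern]) -> float | None:
    """Ratio of first-pulse origin events (including those decomposed from
    multi-origin fibers) to ongoing-fork events; None when no forks."""
    n_origins = sum(
        p.n_origins for p in patterns if p.pattern in ("first_pulse_origin", "multi_origin")
    )
    n_forks = sum(
        p.n_forks for p in patterns if p.pattern in ("ongoing_fork", "multi_origin")
    )
    if n_forks == 0:
        return None
    return n_origins / n_forks


def _box_summary(values: np.ndarray) -> dict[str, float]:
    """Median / IQR / whisker-range summary in the standard boxplot
    convention (whiskers = range without outliers beyond 1.5 x IQR)."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(lo), "whisker_high": float(hi), "n": int(values.size)}


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "ranksum",
) -> dict[str, object]:
    """Two-sided group comparison: Wilcoxon rank-sum or Welch's t-test.

    The rank-sum test is exact for small untied samples and uses the
    tie-corrected normal approximation otherwise.  Identical constant
    samples yield p = 1 by contract.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    summary = {"a": _box_summary(a), "b": _box_summary(b)}
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"statistic": 0.0, "pvalue": 1.0, "method": method, "summary": summary}
    if method == "ranksum":
        has_ties = len(np.unique(pooled)) < pooled.size
        mode = "asymptotic" if has_ties or max(a.size, b.size) > 25 else "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mode)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("method must be 'ranksum' or 'welch'")
    return {"statistic": stat, "pvalue": min(1.0, p), "method": method, "summary": summary}


def measurements_frame(
    patterns: Sequence[FiberPattern], pulse_min: float, group: str = ""
) -> pd.DataFrame:
    """Tidy table: one row per measured fork track (speed) per fiber."""
    rows = []
    for p in patterns:
        if not p.second_track_lengths_um:
            rows.append(
                {
                    "fiber_id": p.fiber_id,
                    "group": group,
                    "pattern": p.pattern,
                    "track_length_um": np.nan,
                    "speed_kb_min": np.nan,
                }
            )
        for L in p.second_track_lengths_um:
            rows.append(
                {
                    "fiber_id": p.fiber_id,
                    "group": group,
                    "pattern": p.pattern,
                    "track_length_um": L,
                    "speed_kb_min": fork_speed(L, pulse_min),
                }
            )
    return pd.DataFrame(rows)
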