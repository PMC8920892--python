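"""End-to-end fiber analysis: image -> traces -> patterns -> measurements.

This wires the localization, branch-detection and statistics stages into the
three-step pipeline used on real acquisitions, and provides population-level
helpers for simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiber_imaging import FiberImage, compute_ridge_map, extract_traces, reconnect
from .fiber_patterns import FiberPattern, cart_segment, classify_pattern, sample_profiles
from .fiber_stats import fork_speed, measurements_frame
from .protocol import PulseProtocol

__all__ = ["FiberPipelineConfig", "analyze_image", "analyze_population"]


@dataclass(frozen=True)
class FiberPipelineConfig:
    scales_px: tuple[float, ...] = (1.0, 1.6, 2.4)
    selem_px: int = 20
    threshold: float = 0.5
    min_length_um: float = 3.0
    profile_width_px: int = 5
    min_segment_um: float = 1.0
    complexity: float = 0.01
    dead_zone: float = 0.2
    gap_tolerance_um: float = 2.0


def analyze_image(
    image: FiberImage,
    protocol: PulseProtocol | None = None,
    config: FiberPipelineConfig | None = None,
) -> list[FiberPattern]:
    """Run localization, segmentation and pattern classification on one image."""
    protocol = protocol or PulseProtocol()
    config = config or FiberPipelineConfig()
    rmap = compute_ridge_map(image, scales=config.scales_px)
    rmap = reconnect(rmap, segment_length_px=config.selem_px)
    traces = extract_traces(
        rmap, threshold=config.threshold, min_length_um=config.min_length_um
    )
    patterns = []
    for trace in traces:
        profile = sample_profiles(image, trace, width_px=config.profile_width_px)
        seg = cart_segment(
            profile,
            min_segment_um=config.min_segment_um,
            complexity=config.complexity,
            dead_zone=config.dead_zone,
        )
        patterns.append(
            classify_pattern(seg, protocol, gap_tolerance_um=config.gap_tolerance_um)
        )
    return patterns


def analyze_population(
    images: list[FiberImage],
    protocol: PulseProtocol | None = None,
    config: FiberPipelineConfig | None = None,
    group: str = "",
) -> pd.DataFrame:
    """Analyze a cohort of images; returns the tidy per-track measurement
    table (fiber ids are made unique across images)."""
    protocol = protocol or PulseProtocol()
    frames = []
    offset = 0
    for img in images:
        patterns = analyze_image(img, protocol, config)
        for p in patterns:
            p.fiber_id += offset
        offset += 10_000
        frames.append(
            measurements_frame(patterns, protocol.second_pulse_min, group=group)
        )
    if not frames:
        return pd.DataFrame(
            columns=["fiber_id", "group", "pattern", "track_length_um", "speed_kb_min"]
        )
    return pd.concat(frames, ignore_index=True)


def population_median_speed(measurements: pd.DataFrame) -> float:
    """Median fork speed over measured second-pulse tracks."""
    speeds = measurements["speed_kb_min"].dropna()
    if speeds.empty:
        return float("nan")
    return float(speeds.median())
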