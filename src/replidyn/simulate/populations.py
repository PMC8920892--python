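"""Fiber-population generators for the pattern classes of the dual-pulse assay.

These build :class:`FiberSpec` populations that emulate the event types seen
on stretched fibers — ongoing forks, stalled forks, first- and second-pulse
origins, terminations, multi-origin clusters — with per-fork speeds drawn
from a lognormal distribution around a configurable median (the
distribution of per-fork speeds within a cell type is a modeling choice;
lognormal is the default).
"""

from __future__ import annotations

import numpy as np

from ..protocol import KB_PER_UM, PulseProtocol
from .fibers import FiberSpec, ForkEvent, make_path

__all__ = [
    "lognormal_speeds",
    "ongoing_fork_spec",
    "stalled_spec",
    "first_pulse_origin_spec",
    "second_pulse_origin_spec",
    "termination_spec",
    "multi_origin_spec",
    "unlabeled_spec",
    "evenly_spaced_origins_spec",
    "population_specs",
]

DEFAULT_MIX = {
    "ongoing_fork": 0.40,
    "stalled_after_first_label": 0.15,
    "first_pulse_origin": 0.15,
    "second_pulse_origin": 0.10,
    "termination": 0.10,
    "multi_origin": 0.10,
}


def lognormal_speeds(
    n: int, median_kb_min: float, sigma_log: float = 0.25, rng=None
) -> np.ndarray:
    """Per-fork speeds (kb/min), lognormal with the given median."""
    rng = rng or np.random.default_rng(0)
    return median_kb_min * np.exp(rng.normal(0.0, sigma_log, n))


def _path_for(track_um: float, rng, margin_um: float = 4.0, waviness: float = 0.4):
    length = track_um + 2 * margin_um
    return make_path(length, waviness_um=waviness, rng=rng), margin_um


def ongoing_fork_spec(speed_kb_min, protocol: PulseProtocol, rng) -> FiberSpec:
    """Single rightward fork firing at the start of the first pulse:
    [first, second]."""
    v_um = speed_kb_min / KB_PER_UM
    track = v_um * protocol.total_min
    cp, margin = _path_for(track, rng)
    return FiberSpec(cp, [ForkEvent(margin, 0.0, speed_kb_min, 0.0)])


def stalled_spec(speed_kb_min, protocol: PulseProtocol, rng) -> FiberSpec:
    """Fork that stalls before the second pulse: [first]."""
    stall = rng.uniform(0.5, 1.0) * protocol.first_pulse_min
    v_um = speed_kb_min / KB_PER_UM
    cp, margin = _path_for(v_um * stall, rng)
    return FiberSpec(cp, [ForkEvent(margin, 0.0, speed_kb_min, 0.0, stall_time_min=stall)])


def first_pulse_origin_spec(speed_kb_min, protocol: PulseProtocol, rng) -> FiberSpec:
    """Origin fired during the first pulse, both forks active:
    [second, first, second]."""
    t0 = rng.uniform(0.0, 0.4) * protocol.first_pulse_min
    v_um = speed_kb_min / KB_PER_UM
    track = 2 * v_um * (protocol.total_min - t0)
    cp, margin = _path_for(track, rng)
    return FiberSpec(cp, [ForkEvent(margin + track / 2, speed_kb_min, speed_kb_min, t0)])


def second_pulse_origin_spec(speed_kb_min, protocol: PulseProtocol, rng) -> FiberSpec:
    """Origin fired during the second pulse: [second]."""
    t0 = protocol.first_pulse_min + rng.uniform(0.1, 0.5) * protocol.second_pulse_min
    v_um = speed_kb_min / KB_PER_UM
    track = 2 * v_um * (protocol.total_min - t0)
    cp, margin = _path_for(max(track, 3.0), rng)
    return FiberSpec(cp, [ForkEvent(margin + track / 2, speed_kb_min, speed_kb_min, t0)])


def termination_spec(speed_kb_min, protocol: PulseProtocol, rng) -> FiberSpec:
    """Two converging forks that meet during the second pulse:
    [first, second, first]."""
    v_um = speed_kb_min / KB_PER_UM
    meet = protocol.first_pulse_min + rng.uniform(0.3, 0.8) * protocol.second_pulse_min
    gap = 2 * v_um * meet  # separation so the forks meet exactly at `meet`
    cp, margin = _path_for(gap, rng)
    left = ForkEvent(margin, 0.0, speed_kb_min, 0.0, stall_time_min=meet)
    right = ForkEvent(margin + gap, speed_kb_min, 0.0, 0.0, stall_time_min=meet)
    return FiberSpec(cp, [left, right])


def multi_origin_spec(speed_kb_min, protocol: PulseProtocol, rng, n_origins: int = 2) -> FiberSpec:
    """Several first-pulse origins on one fiber whose inward forks do not
    merge: [second, first, second, first, second, ...]."""
    t0 = rng.uniform(0.0, 0.3) * protocol.first_pulse_min
    v_um = speed_kb_min / KB_PER_UM
    travel = v_um * (protocol.total_min - t0)
    spacing = 2 * travel + rng.uniform(1.2, 1.8)
    track = spacing * (n_origins - 1) + 2 * travel
    cp, margin = _path_for(track, rng)
    events = [
        ForkEvent(margin + travel + k * spacing, speed_kb_min, speed_kb_min, t0)
        for k in range(n_origins)
    ]
    return FiberSpec(cp, events)


def unlabeled_spec(rng, length_um: float = 15.0) -> FiberSpec:
    """Unreplicated fiber (DNA counterstain only): ambiguous by contract."""
    cp, _ = _path_for(length_um - 8.0, rng)
    return FiberSpec(cp, [])


def evenly_spaced_origins_spec(
    speed_kb_min: float,
    protocol: PulseProtocol,
    rng,
    n_origins: int = 5,
    spacing_um: float = 25.0,
) -> FiberSpec:
    """Origins fired in the first pulse at a fixed spacing; used for
    inter-origin-distance recovery (forks must not merge, so the spacing
    has to exceed twice the per-fork travel)."""
    t0 = 2.0
    v_um = speed_kb_min / KB_PER_UM
    travel = v_um * (protocol.total_min - t0)
    if spacing_um <= 2 * travel + 1.0:
        raise ValueError("spacing too small: converging forks would merge")
    track = spacing_um * (n_origins - 1) + 2 * travel
    cp, margin = _path_for(track, rng, waviness=0.3)
    events = [
        ForkEvent(margin + travel + k * spacing_um, speed_kb_min, speed_kb_min, t0)
        for k in range(n_origins)
    ]
    return FiberSpec(cp, events)


def population_specs(
    n: int,
    protocol: PulseProtocol | None = None,
    median_speed_kb_min: float = 1.34,
    sigma_log: float = 0.25,
    mix: dict[str, float] | None = None,
    seed: int = 0,
):
    """Draw ``n`` independent fiber specs from a pattern-class mixture.

    Returns ``(specs, classes)`` where ``classes`` are the intended pattern
    classes ("ambiguous" entries are unlabeled fibers).
    """
    protocol = protocol or PulseProtocol()
    rng = np.random.default_rng(seed)
    mix = dict(mix or DEFAULT_MIX)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    makers = {
        "ongoing_fork": ongoing_fork_spec,
        "stalled_after_first_label": stalled_spec,
        "first_pulse_origin": first_pulse_origin_spec,
        "second_pulse_origin": second_pulse_origin_spec,
        "termination": termination_spec,
        "multi_origin": multi_origin_spec,
        "ambiguous": lambda s, p, r: unlabeled_spec(r),
    }
    speeds = lognormal_speeds(n, median_speed_kb_min, sigma_log, rng)
    chosen = rng.choice(len(classes), size=n, p=probs)
    specs = [makers[classes[c]](speeds[i], protocol, rng) for i, c in enumerate(chosen)]
    return specs, [classes[c] for c in chosen]
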