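"""Dual-pulse labeling protocol for DNA fiber assays.

Nascent DNA is labeled with two thymidine analogs given sequentially
(classically IdU then CldU, 30 min each).  Labeled track lengths convert to
synthesized DNA with the established stretching factor of 1 um = 2 kb.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Established conversion for stretched DNA fibers: 1 um of track = 2 kb.
KB_PER_UM: float = 2.0


@dataclass(frozen=True)
class PulseProtocol:
    """Sequential dual-label pulse protocol.

    Parameters
    ----------
    first_pulse_min, second_pulse_min:
        Pulse durations in minutes; both must be positive.
    first_label, second_label:
        Analog names (distinct), e.g. ``"IdU"`` and ``"CldU"``.
    """

    first_pulse_min: float = 30.0
    second_pulse_min: float = 30.0
    first_label: str = "IdU"
    second_label: str = "CldU"

    def __post_init__(self) -> None:
        if self.first_pulse_min <= 0 or self.second_pulse_min <= 0:
            raise ValueError("pulse durations must be positive")
        if self.first_label == self.second_label:
            raise ValueError("pulse labels must be distinct")

    @property
    def total_min(self) -> float:
        return self.first_pulse_min + self.second_pulse_min
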