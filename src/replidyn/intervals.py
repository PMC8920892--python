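"""Small genomic-interval engine: merging and overlap arithmetic.

All coordinates are 0-based, half-open (BED convention).  Intervals are
plain ``(start, end)`` integer arrays grouped per chromosome; this is all
the Repli-seq enrichment stage needs.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts, ends):
    """Merge overlapping/adjacent half-open intervals.

    Returns sorted, disjoint ``(starts, ends)`` arrays.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def total_bp(starts, ends) -> int:
    s, e = merge_intervals(starts, ends)
    return int(np.sum(e - s))


def overlap_bp(a_starts, a_ends, b_starts, b_ends) -> int:
    """Total base pairs of overlap between two interval sets (same chromosome)."""
    a_s, a_e = merge_intervals(a_starts, a_ends)
    b_s, b_e = merge_intervals(b_starts, b_ends)
    i = j = 0
    total = 0
    while i < len(a_s) and j < len(b_s):
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if hi > lo:
            total += hi - lo
        if a_e[i] < b_e[j]:
            i += 1
        else:
            j += 1
    return int(total)
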