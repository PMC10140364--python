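"""Small vectorized interval utilities shared across modules.

All intervals are 0-based half-open ``(start, end)`` tuples on one chromosome.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(intervals):
    """Merge overlapping/adjacent intervals into a sorted disjoint list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def membership(positions, merged):
    """Boolean mask: does each position fall inside any merged interval?

    ``merged`` must come from :func:`merge_intervals` (sorted, disjoint).
    """
    positions = np.asarray(positions)
    if not merged:
        return np.zeros(positions.shape, dtype=bool)
    bounds = np.fromiter((b for iv in merged for b in iv), dtype=np.int64)
    # odd insertion index == inside an interval
    return np.searchsorted(bounds, positions, side="right") % 2 == 1


def overlap_length(start, end, merged):
    """Total overlap of ``[start, end)`` with a merged interval list."""
    total = 0
    for s, e in merged:
        if s >= end:
            break
        total += max(0, min(end, e) - max(start, s))
    return total


def complement(merged, chrom_length):
    """Complement of a merged interval list within ``[0, chrom_length)``."""
    out = []
    prev = 0
    for s, e in merged:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < chrom_length:
        out.append((prev, chrom_length))
    return out
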