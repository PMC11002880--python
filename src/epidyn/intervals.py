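"""Interval engine: merging, overlap queries and gap/closest computations.

Everything here operates on plain (chrom, start, end) triples in 0-based
half-open coordinates; the overlap predicate is ">= 1 shared bp" so
adjacency (end == start) never counts. These primitives back the master
peak construction, fragment counting and cCRE annotation and are checked
against brute-force oracles in the test suite.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Iterable, Sequence

import numpy as np


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def merge_single_linkage(triples: Sequence[tuple]) -> list:
    """Single-linkage union of intervals.

    Parameters
    ----------
    triples : sequence of (chrom, start, end)

    Returns
    -------
    list of (chrom, start, end, member_indices) sorted by (chrom, start),
    where member_indices are indices into ``triples`` of the intervals merged
    into that cluster. Transitive: A-B overlap and B-C overlap merges A, C
    even if A and C are disjoint.
    """
    if not triples:
        return []
    order = sorted(range(len(triples)), key=lambda i: (triples[i][0], triples[i][1], triples[i][2]))
    out = []
    cur_chrom, cur_start, cur_end = None, None, None
    members: list = []
    for i in order:
        chrom, start, end = triples[i][:3]
        if chrom == cur_chrom and start < cur_end:
            cur_end = max(cur_end, end)
            members.append(i)
        else:
            if members:
                out.append((cur_chrom, cur_start, cur_end, members))
            cur_chrom, cur_start, cur_end = chrom, start, end
            members = [i]
    out.append((cur_chrom, cur_start, cur_end, members))
    return out


class IntervalIndex:
    """Overlap queries against a fixed set of (possibly overlapping) intervals."""

    def __init__(self, triples: Iterable[tuple]):
        by_chrom: dict = {}
        for idx, (chrom, start, end) in enumerate(triples):
            by_chrom.setdefault(chrom, []).append((start, end, idx))
        self._by_chrom = {}
        for chrom, items in by_chrom.items():
            items.sort()
            starts = np.array([it[0] for it in items], dtype=np.int64)
            ends = np.array([it[1] for it in items], dtype=np.int64)
            idxs = np.array([it[2] for it in items], dtype=np.int64)
            # prefix-max of ends bounds how far left an overlap can begin
            self._by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends), idxs)

    def query(self, chrom: str, start: int, end: int) -> list:
        """Indices (input order) of stored intervals overlapping [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, cummax_ends, idxs = entry
        hi = int(np.searchsorted(starts, end, side="left"))  # starts[i] < end
        lo = int(np.searchsorted(cummax_ends[:hi], start, side="right"))
        if lo >= hi:
            return []
        sel = ends[lo:hi] > start
        return sorted(int(i) for i in idxs[lo:hi][sel])


def count_cover(
    targets: Sequence[tuple], queries_by_chrom: dict
) -> np.ndarray:
    """Count, per non-overlapping sorted target, how many query intervals overlap it.

    ``targets`` must be pairwise non-overlapping (chrom, start, end), any order.
    ``queries_by_chrom`` maps chrom -> (starts array, ends array). Each query
    increments every target it overlaps by exactly one.
    """
    counts = np.zeros(len(targets), dtype=np.int64)
    by_chrom: dict = {}
    for idx, (chrom, start, end) in enumerate(targets):
        by_chrom.setdefault(chrom, []).append((start, end, idx))
    for chrom, items in by_chrom.items():
        q = queries_by_chrom.get(chrom)
        if q is None:
            continue
        items.sort()
        t_starts = np.array([it[0] for it in items], dtype=np.int64)
        t_ends = np.array([it[1] for it in items], dtype=np.int64)
        t_idx = np.array([it[2] for it in items], dtype=np.int64)
        q_starts, q_ends = q
        # target overlaps query iff t_start < q_end and t_end > q_start;
        # with non-overlapping sorted targets both arrays are sorted, so the
        # overlapping targets form the contiguous index range [lo, hi)
        lo = np.searchsorted(t_ends, q_starts, side="right")
        hi = np.searchsorted(t_starts, q_ends, side="left")
        delta = np.zeros(len(items) + 1, dtype=np.int64)
        valid = hi > lo
        np.add.at(delta, lo[valid], 1)
        np.add.at(delta, hi[valid], -1)
        counts[t_idx] += np.cumsum(delta[:-1])
    return counts


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Bases strictly between two non-overlapping intervals (0 if adjacent).

    Returns -1 when the intervals overlap.
    """
    if a_start < b_end and b_start < a_end:
        return -1
    if b_start >= a_end:
        return b_start - a_end
    return a_start - b_end


def point_interval_distance(point: int, start: int, end: int) -> int:
    """Distance from a base position to an interval; 0 when covered."""
    if start <= point < end:
        return 0
    if start > point:
        return start - point
    return point - (end - 1)
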