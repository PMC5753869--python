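"""Interval arithmetic on 0-based half-open genomic intervals.

All intervals in this package are ``(start, end)`` tuples with
``0 <= start < end``, half-open on the right, matching BED conventions.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or touching intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"empty or inverted interval ({a}, {b})")
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def normalize_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Return a sorted, non-overlapping version of *intervals*.

    Emits a warning when the input was unsorted or overlapping, per the
    masking contract.
    """
    ivs = list(intervals)
    merged = merge_intervals(ivs)
    if [tuple(map(int, iv)) for iv in ivs] != merged:
        warnings.warn("mask intervals were unsorted or overlapping; normalized", stacklevel=2)
    return merged


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(b - a for a, b in merge_intervals(intervals)) if intervals else 0


def point_in_intervals(points, intervals: Sequence[tuple[int, int]]):
    """Boolean membership of 0-based *points* in merged *intervals* (vectorized)."""
    import numpy as np

    points = np.asarray(points)
    mask = np.zeros(points.shape, dtype=bool)
    for a, b in intervals:
        mask |= (points >= a) & (points < b)
    return mask


def overlap_length(iv: tuple[int, int], intervals: Iterable[tuple[int, int]]) -> int:
    """Number of bp of *iv* covered by the (merged) interval set."""
    a, b = iv
    out = 0
    for s, e in merge_intervals(intervals):
        out += max(0, min(b, e) - max(a, s))
    return out


def read_bed(path) -> list[tuple[int, int]]:
    """Read start/end from a BED-like file (first three columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((int(fields[1]), int(fields[2])))
    return out


def write_bed(path, intervals: Iterable[tuple[int, int]], chrom: str,
              extra_columns: Sequence[Sequence] | None = None) -> None:
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(intervals):
            row = [chrom, str(a), str(b)]
            if extra_columns is not None:
                row.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(row) + "\n")
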