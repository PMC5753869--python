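"""Coverage-ratio CNV detection and union masking.

Two modes are provided.  Single-sample mode normalizes a windowed depth
track by its median and converts it to copy number (2 x normalized depth),
calling sustained runs at <= 1.5 or >= 2.5 copies.  Contrast mode compares
median-normalized pooled carrier depth against pooled controls and calls
windows whose ratio leaves [0.75, 1.25] - the band a single-copy change on
one of two haplotypes must exceed; contrast calls are labelled
driver-specific.  The union of all calls over samples and modes gives the
mask used to exclude CNV regions from downstream SNP analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import merge_intervals

LOSS = "loss"
GAIN = "gain"


@dataclass
class CoverageTrack:
    """Windowed depths of one sample (or a pool) on one chromosome."""

    sample: str
    chrom: str
    window_size: int
    starts: np.ndarray   # window start positions, bp
    depths: np.ndarray   # reads per window

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.starts) != len(self.depths):
            raise ValueError("starts and depths differ in length")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass
class CnvCall:
    start: int
    end: int
    estimated_copy_number: float
    direction: str       # loss | gain
    mode: str            # single | contrast
    sample: str = ""

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def read_coverage_tsv(path) -> dict[str, CoverageTrack]:
    """Read the long-format coverage TSV (sample, chrom, window_start, depth)."""
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for sample, sub in df.groupby("sample", sort=True):
        sub = sub.sort_values("window_start")
        starts = sub["window_start"].to_numpy()
        wsize = int(np.diff(starts).min()) if len(starts) > 1 else 1000
        tracks[str(sample)] = CoverageTrack(
            str(sample), str(sub["chrom"].iloc[0]), wsize, starts, sub["depth"].to_numpy()
        )
    return tracks


def pool_tracks(tracks: Sequence[CoverageTrack], name: str = "pool") -> CoverageTrack:
    """Sum depths across samples on an identical window grid."""
    first = tracks[0]
    for t in tracks[1:]:
        if not np.array_equal(t.starts, first.starts):
            raise ValueError("cannot pool tracks on different window grids")
    return CoverageTrack(
        name, first.chrom, first.window_size, first.starts,
        np.sum([t.depths for t in tracks], axis=0),
    )


def _runs_to_calls(
    starts: np.ndarray,
    window_size: int,
    called: np.ndarray,
    copy: np.ndarray,
    direction_of,
    min_windows: int,
    gap_windows: int,
    mode: str,
    sample: str,
) -> list[CnvCall]:
    """Merge flagged windows of equal direction into calls (gap-tolerant),
    discarding runs shorter than *min_windows* called windows."""
    calls: list[CnvCall] = []
    idx = np.nonzero(called)[0]
    if len(idx) == 0:
        return calls
    run: list[int] = [idx[0]]
    for i in idx[1:]:
        if i - run[-1] <= gap_windows + 1 and direction_of(i) == direction_of(run[-1]):
            run.append(i)
        else:
            calls.extend(_finalize_run(run, starts, window_size, copy, direction_of, min_windows, mode, sample))
            run = [i]
    calls.extend(_finalize_run(run, starts, window_size, copy, direction_of, min_windows, mode, sample))
    return calls


def _finalize_run(run, starts, window_size, copy, direction_of, min_windows, mode, sample):
    if len(run) < min_windows:
        return []
    a = int(starts[run[0]])
    b = int(starts[run[-1]]) + window_size
    mean_copy = float(np.mean([copy[i] for i in run]))
    return [CnvCall(a, b, mean_copy, direction_of(run[0]), mode, sample)]


def coverage_to_copy_number_calls(
    track: CoverageTrack,
    loss_copy: float = 1.5,
    gain_copy: float = 2.5,
    min_windows: int = 3,
    gap_windows: int = 1,
) -> list[CnvCall]:
    """Single-sample caller: copy number = 2 x depth / median depth.

    Windows at <= *loss_copy* or >= *gain_copy* copies are merged into runs
    (same direction, gaps of up to *gap_windows* windows tolerated); runs
    shorter than *min_windows* called windows are discarded.
    """
    if len(track.depths) < 20:
        raise ValueError("need at least 20 windows for median normalization")
    med = float(np.median(track.depths))
    if med <= 0:
        raise ValueError("all-zero (or zero-median) coverage track")
    copy = 2.0 * track.depths / med
    called = (copy <= loss_copy) | (copy >= gain_copy)

    def direction_of(i):
        return LOSS if copy[i] <= loss_copy else GAIN

    return _runs_to_calls(
        track.starts, track.window_size, called, copy, direction_of,
        min_windows, gap_windows, "single", track.sample,
    )


def contrast_cnv_calls(
    carrier_track: CoverageTrack,
    control_track: CoverageTrack,
    gain_ratio: float = 1.25,
    loss_ratio: float = 0.75,
    min_windows: int = 3,
    gap_windows: int = 1,
) -> tuple[list[CnvCall], int]:
    """Pooled carrier-vs-control caller; calls are driver-specific.

    Windows with zero control depth are excluded from the ratio; the count
    of excluded windows is returned alongside the calls.
    """
    if not np.array_equal(carrier_track.starts, control_track.starts):
        raise ValueError("carrier and control tracks are on different window grids")
    if len(carrier_track.depths) < 20:
        raise ValueError("need at least 20 windows for median normalization")
    med_ca = float(np.median(carrier_track.depths))
    med_co = float(np.median(control_track.depths))
    if med_ca <= 0 or med_co <= 0:
        raise ValueError("zero-median pooled track")
    norm_ca = carrier_track.depths / med_ca
    norm_co = control_track.depths / med_co
    valid = norm_co > 0
    n_excluded = int((~valid).sum())
    ratio = np.full(len(norm_ca), 1.0)
    ratio[valid] = norm_ca[valid] / norm_co[valid]
    called = valid & ((ratio >= gain_ratio) | (ratio <= loss_ratio))
    copy = 2.0 * ratio  # implied carrier copies given diploid controls

    def direction_of(i):
        return LOSS if ratio[i] <= loss_ratio else GAIN

    calls = _runs_to_calls(
        carrier_track.starts, carrier_track.window_size, called, copy, direction_of,
        min_windows, gap_windows, "contrast", carrier_track.sample,
    )
    return calls, n_excluded


def union_cnv_mask(calls: Iterable[CnvCall]) -> list[tuple[int, int]]:
    """Union of call intervals over all samples and modes, merged and sorted."""
    ivs = [c.interval() for c in calls]
    return merge_intervals(ivs) if ivs else []


def calls_to_frame(calls: Sequence[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "copy_number": [c.estimated_copy_number for c in calls],
            "direction": [c.direction for c in calls],
            "mode": [c.mode for c in calls],
            "sample": [c.sample for c in calls],
        }
    )
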