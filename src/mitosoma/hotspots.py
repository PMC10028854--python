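"""Sliding-window mutation-frequency scans and repeat-tract frequencies.

Windows are taken over the circular genome (they wrap the origin), so a scan
at step 1 produces exactly L windows and rotating the genome rotates the
track.  A window's frequency is the summed alternate-allele depth over the
window divided by the summed duplex depth, which makes the depth-weighted
track mean equal to the global mutation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import ConditionTable


@dataclass
class WindowTrack:
    """Per-window mean mutation frequency; ``starts`` are 1-based window starts."""

    starts: np.ndarray
    frequency: np.ndarray
    window: int
    step: int
    L: int
    counts: np.ndarray = field(repr=False, default=None)
    depths: np.ndarray = field(repr=False, default=None)


def _circular_window_sum(arr: np.ndarray, window: int) -> np.ndarray:
    ext = np.concatenate([arr, arr[: window - 1]])
    cs = np.concatenate([[0.0], np.cumsum(ext)])
    return cs[window:] - cs[:-window]


def sliding_window_scan(table: ConditionTable, window: int = 150, step: int = 1) -> WindowTrack:
    """Circular sliding-window mutation-frequency track.

    Window ``i`` covers positions ``i .. i+window-1`` (wrapping); its
    frequency is ``sum(alt counts) / sum(duplex depth)`` over the window.
    """
    if window > table.L:
        raise ValueError(f"window {window} exceeds genome length {table.L}")
    if step < 1:
        raise ValueError("step must be >= 1")
    counts = _circular_window_sum(table.position_alt_depth(), window)
    depths = _circular_window_sum(table.depth, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depths > 0, counts / depths, np.nan)
    starts = np.arange(1, table.L + 1)
    sl = slice(None, None, step)
    return WindowTrack(starts[sl], freq[sl], window, step, table.L, counts[sl], depths[sl])


def tract_frequency(table: ConditionTable, start: int, end: int) -> float:
    """Aggregate mutation frequency of a positional tract [start, end]."""
    if not 1 <= start <= end <= table.L:
        raise ValueError(f"need 1 <= start <= end <= {table.L}")
    counts = table.position_alt_depth()[start - 1 : end]
    depth = table.depth[start - 1 : end]
    if depth.sum() <= 0:
        raise ValueError(f"zero duplex depth over tract {start}-{end}")
    return float(counts.sum() / depth.sum())


def call_hotspots(track: WindowTrack, background: float, fold_threshold: float) -> list[dict]:
    """Merged intervals of windows elevated above ``fold_threshold * background``.

    Maximal runs of elevated windows (wrapping the origin) are merged into
    position intervals covering the union of their windows; each interval
    reports its peak window frequency.  Interval ``end`` may exceed L when a
    hotspot wraps the origin (positions are mod L).
    """
    if track.step != 1:
        raise ValueError("hotspot calling requires a step-1 track")
    elevated = np.nan_to_num(track.frequency) >= fold_threshold * background
    if not elevated.any():
        return []
    if elevated.all():
        return [
            {"start": 1, "end": track.L, "peak_frequency": float(np.nanmax(track.frequency))}
        ]
    # rotate so the scan starts on a non-elevated window; runs then never split
    offset = int(np.flatnonzero(~elevated)[0])
    rot = np.roll(elevated, -offset)
    edges = np.flatnonzero(np.diff(np.concatenate([[False], rot, [False]]).astype(int)))
    intervals = []
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        first = (run_start + offset) % track.L  # 0-based window index
        length = run_end - run_start  # number of windows in the run
        idx = (first + np.arange(length)) % track.L
        intervals.append(
            {
                "start": int(first + 1),
                "end": int(first + length - 1 + track.window),
                "peak_frequency": float(np.nanmax(track.frequency[idx])),
            }
        )
    intervals.sort(key=lambda d: d["start"])
    return intervals


def write_bedgraph(track: WindowTrack, path, chrom: str = "chrM") -> None:
    """Write the track as bedGraph (0-based half-open window starts)."""
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": track.starts - 1,
            "end": track.starts - 1 + track.window,
            "value": track.frequency,
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def write_hotspot_bed(intervals: list[dict], path, chrom: str = "chrM") -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{chrom}\t{iv['start'] - 1}\t{iv['end']}\thotspot_{i + 1}\t"
                f"{iv['peak_frequency']:.3g}\t.\n"
            )
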