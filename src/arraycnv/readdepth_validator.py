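"""Sliding-window read-depth CNV detection for cross-platform validation.

The genome is tiled with fixed-width windows (default 400 bp); reads are
counted by start position, counts are corrected for GC-content bias by
bin-mean rescaling, integer copy numbers come from the ratio to the
genome-wide median (diploid baseline), and runs of non-diploid windows
become depth CNVRs used to confirm array-derived CNVRs by overlap with
compatible polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .cnvr_builder import Cnvr
from .signal_io import GenomicInterval
from ._util import round_half_up

__all__ = [
    "WindowDepth",
    "window_counts",
    "gc_correct",
    "estimate_copy_number",
    "call_depth_cnvrs",
    "validate_cnvrs",
]

DEFAULT_WIDTH = 400
GC_BINS = 50
GC_MIN_WINDOWS = 20
MAX_CN = 10
MIN_RUN = 5


@dataclass
class WindowDepth:
    """Per-chromosome window-tiled depth track."""

    chrom: str
    width: int
    raw: np.ndarray  # integer read counts per window
    gc: np.ndarray | None = None  # GC fraction per window
    corrected: np.ndarray | None = None
    copy_number: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.raw)

    def window_start(self, w: int) -> int:
        return w * self.width


def window_counts(
    read_starts: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    width: int = DEFAULT_WIDTH,
) -> dict[str, WindowDepth]:
    """Count read starts into half-open fixed-width windows per chromosome.

    Every read lands in exactly one window (the one containing its start
    position), so window counts conserve the read total; a final partial
    window is kept.
    """
    tracks: dict[str, WindowDepth] = {}
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-int(length) // width))
        starts = np.sort(np.asarray(read_starts.get(chrom, []), dtype=np.int64))
        if starts.size and (starts[0] < 0 or starts[-1] >= length):
            raise ValueError(f"read start outside chromosome {chrom}")
        counts = np.bincount(starts // width, minlength=n_win).astype(np.int64)
        tracks[chrom] = WindowDepth(chrom, width, counts)
    return tracks


def gc_correct(
    tracks: Mapping[str, WindowDepth],
    gc_per_window: Mapping[str, np.ndarray] | None = None,
    n_bins: int = GC_BINS,
    min_windows: int = GC_MIN_WINDOWS,
) -> dict[str, WindowDepth]:
    """Rescale window counts by GC-bin means to remove coverage bias.

    corrected = raw * (global mean) / (mean of the window's GC bin); bins
    with fewer than ``min_windows`` windows are left uncorrected, and the
    output is rescaled so the cohort total mass is conserved.
    """
    chroms = list(tracks)
    raw = np.concatenate([tracks[c].raw.astype(float) for c in chroms])
    if gc_per_window is not None:
        gc = np.concatenate([np.asarray(gc_per_window[c], float) for c in chroms])
    else:
        gc = np.concatenate(
            [
                np.asarray(tracks[c].gc, float)
                if tracks[c].gc is not None
                else np.full(tracks[c].n_windows, np.nan)
                for c in chroms
            ]
        )
    corrected = raw.copy()
    global_mean = raw.mean() if raw.size else 0.0
    ok = ~np.isnan(gc)
    if ok.any() and global_mean > 0:
        bins = np.clip((gc[ok] * n_bins).astype(int), 0, n_bins - 1)
        factors = np.ones(ok.sum())
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < min_windows:
                continue
            bin_mean = raw[ok][sel].mean()
            if bin_mean > 0:
                factors[sel] = global_mean / bin_mean
        corrected[ok] = raw[ok] * factors
        total_raw = raw.sum()
        total_corr = corrected.sum()
        if total_corr > 0:
            corrected *= total_raw / total_corr
    out: dict[str, WindowDepth] = {}
    offset = 0
    for c in chroms:
        n = tracks[c].n_windows
        out[c] = replace(
            tracks[c],
            gc=gc[offset : offset + n].copy(),
            corrected=corrected[offset : offset + n].copy(),
        )
        offset += n
    return out


def estimate_copy_number(
    tracks: Mapping[str, WindowDepth], max_cn: int = MAX_CN
) -> dict[str, WindowDepth]:
    """Integer CN per window: round(2 * corrected / genome-median), capped.

    Rounding is half away from zero so a 1.5x-median window reads as CN3.
    The autosomal median corrected count is the diploid baseline; a zero
    median means degenerate coverage and is rejected.
    """
    corrected = np.concatenate(
        [
            t.corrected if t.corrected is not None else t.raw.astype(float)
            for t in tracks.values()
        ]
    )
    m = float(np.median(corrected))
    if m <= 0:
        raise ValueError("median corrected count is zero: degenerate coverage")
    out: dict[str, WindowDepth] = {}
    for c, t in tracks.items():
        corr = t.corrected if t.corrected is not None else t.raw.astype(float)
        cn = np.floor(2.0 * corr / m + 0.5).astype(np.int64)  # half away from zero
        out[c] = replace(t, corrected=corr, copy_number=np.clip(cn, 0, max_cn))
    return out


def call_depth_cnvrs(
    tracks: Mapping[str, WindowDepth],
    min_run: int = MIN_RUN,
    bridge: int = 1,
) -> list[GenomicInterval]:
    """Segment window CN tracks into discrete depth CNVRs.

    Maximal runs of CN != 2 spanning at least ``min_run`` windows become
    intervals; interruptions of at most ``bridge`` diploid windows inside
    a run of the same polarity are bridged over (Poisson noise produces
    isolated diploid windows inside real events).
    """
    out: list[GenomicInterval] = []
    for chrom, t in tracks.items():
        cn = t.copy_number
        if cn is None:
            raise ValueError("estimate_copy_number must run first")
        n = len(cn)
        i = 0
        while i < n:
            if cn[i] == 2:
                i += 1
                continue
            polarity = 1 if cn[i] > 2 else -1
            j = i
            gap = 0
            last_variant = i
            while j + 1 < n:
                nxt = cn[j + 1]
                if nxt != 2 and ((nxt > 2) == (polarity > 0)):
                    j += 1
                    last_variant = j
                    gap = 0
                elif nxt == 2 and gap < bridge:
                    j += 1
                    gap += 1
                else:
                    break
            j = last_variant
            n_windows = j - i + 1
            if n_windows >= min_run:
                seg_cn = int(np.round(np.median(cn[i : j + 1][cn[i : j + 1] != 2])))
                out.append(
                    GenomicInterval(
                        chrom,
                        t.window_start(i),
                        t.window_start(j) + t.width,
                        f"depthCNVR:{chrom}:{i}",
                        {"copy_number": str(seg_cn)},
                    )
                )
            i = j + 1
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def validate_cnvrs(
    array_cnvrs: Sequence[Cnvr],
    depth_cnvrs: Sequence[GenomicInterval],
    min_reciprocal: float = 0.0,
) -> tuple[dict[str, bool], float]:
    """Confirm array CNVRs against depth CNVRs by overlap with polarity.

    A CNVR is confirmed when at least one depth CNVR overlaps it by >= 1
    bp (optionally a reciprocal-overlap fraction) with compatible
    polarity: gain needs depth CN > 2, loss needs CN < 2, both accepts
    either.  Returns (per-CNVR flags, confirmation rate in percent).
    """
    flags: dict[str, bool] = {}
    for r in array_cnvrs:
        confirmed = False
        for d in depth_cnvrs:
            if d.chrom != r.chrom:
                continue
            ov = min(r.end, d.end) - max(r.start, d.start)
            if ov <= 0:
                continue
            if min_reciprocal > 0:
                if ov < min_reciprocal * (r.end - r.start) or ov < min_reciprocal * (
                    d.end - d.start
                ):
                    continue
            cn = int(d.attributes.get("copy_number", "2"))
            if cn == 2:
                continue
            if (
                r.event == "both"
                or (r.event == "gain" and cn > 2)
                or (r.event == "loss" and cn < 2)
            ):
                confirmed = True
                break
        flags[r.id] = confirmed
    n = len(array_cnvrs)
    rate = round_half_up(100.0 * sum(flags.values()) / n, 2) if n else 0.0
    return flags, rate
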