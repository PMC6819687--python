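"""Population-level CNV region (CNVR) construction.

Per-sample calls are merged into transitive-overlap clusters per
chromosome; clusters supported by a single individual are discarded;
surviving clusters get consensus boundaries at the 2.5% cumulative mass
of the per-base call-coverage profile, an event class (gain / loss /
both) and CNVR identifiers in genomic order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hmm_caller import CnvCall
from ._util import round_half_up

__all__ = [
    "Cnvr",
    "merge_calls",
    "trim_boundaries",
    "filter_singletons",
    "classify_event",
    "build_cnvrs",
    "summarize_cnvrs",
    "cnvrs_to_table",
]

TRIM_FRACTION = 0.025


@dataclass(frozen=True)
class Cnvr:
    """A population CNVR with trimmed consensus boundaries."""

    id: str
    chrom: str
    start: int
    end: int
    raw_start: int
    raw_end: int
    event: str  # gain | loss | both
    n_individuals: int
    supporting_calls: tuple[CnvCall, ...]

    def __post_init__(self) -> None:
        if not (self.raw_start <= self.start < self.end <= self.raw_end):
            raise ValueError("trimmed boundaries must lie within the raw extent")
        samples = {c.sample for c in self.supporting_calls}
        if self.n_individuals != len(samples):
            raise ValueError("n_individuals must count distinct samples")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_calls(calls: Sequence[CnvCall]) -> list[list[CnvCall]]:
    """Cluster calls into maximal transitive-overlap components per chromosome.

    Overlap requires >= 1 bp under half-open coordinates, so abutting
    calls stay separate.  A sorted sweep suffices: after sorting by
    start, a call belongs to the open cluster iff it starts before the
    cluster's running maximum end.
    """
    clusters: list[list[CnvCall]] = []
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        current: list[CnvCall] = []
        current_end = -1
        for c in chrom_calls:
            if current and c.start < current_end:
                current.append(c)
                current_end = max(current_end, c.end)
            else:
                if current:
                    clusters.append(current)
                current = [c]
                current_end = c.end
        if current:
            clusters.append(current)
    return clusters


def trim_boundaries(cluster: Sequence[CnvCall], fraction: float = TRIM_FRACTION) -> tuple[int, int]:
    """Consensus (start, end) at the 2.5% cumulative coverage mass.

    Builds the per-base profile c(x) = number of supporting calls
    covering base x over the cluster extent (via a breakpoint sweep, not
    per-base arrays).  With total mass M, the start is the smallest base
    x whose preceding cumulative mass reaches fraction*M, and the end the
    largest half-open bound whose suffix mass reaches fraction*M.
    """
    if not cluster:
        raise ValueError("empty cluster")
    points = sorted({c.start for c in cluster} | {c.end for c in cluster})
    seg_cov = []
    for a, b in zip(points[:-1], points[1:]):
        cov = sum(1 for c in cluster if c.start <= a and c.end >= b)
        seg_cov.append((a, b, cov))
    total = sum((b - a) * cov for a, b, cov in seg_cov)
    target = fraction * total

    # smallest x with mass of [raw_start, x) >= target
    acc = 0.0
    start = points[0]
    for a, b, cov in seg_cov:
        seg_mass = (b - a) * cov
        if cov > 0 and acc + seg_mass >= target:
            need = target - acc
            start = a + math.ceil(need / cov)
            break
        acc += seg_mass
    # largest x with mass of [x, raw_end) >= target
    acc = 0.0
    end = points[-1]
    for a, b, cov in reversed(seg_cov):
        seg_mass = (b - a) * cov
        if cov > 0 and acc + seg_mass >= target:
            need = target - acc
            end = b - math.ceil(need / cov)
            break
        acc += seg_mass
    if start >= end:  # degenerate tiny cluster: keep the untrimmed extent
        return points[0], points[-1]
    return start, end


def filter_singletons(clusters: Sequence[Sequence[CnvCall]]) -> list[list[CnvCall]]:
    """Drop clusters supported by fewer than two distinct individuals."""
    return [list(cl) for cl in clusters if len({c.sample for c in cl}) >= 2]


def classify_event(cluster: Sequence[CnvCall]) -> str:
    """gain if every supporting copy number > 2, loss if all < 2, else both."""
    cns = {c.copy_number for c in cluster}
    if all(cn > 2 for cn in cns):
        return "gain"
    if all(cn < 2 for cn in cns):
        return "loss"
    return "both"


def build_cnvrs(calls: Sequence[CnvCall], min_individuals: int = 2) -> list[Cnvr]:
    """merge -> singleton filter -> trim -> classify -> label in genome order."""
    clusters = merge_calls(calls)
    if min_individuals > 1:
        clusters = [
            list(cl)
            for cl in clusters
            if len({c.sample for c in cl}) >= min_individuals
        ]
    records = []
    for cl in clusters:
        start, end = trim_boundaries(cl)
        records.append(
            (
                cl[0].chrom,
                start,
                end,
                min(c.start for c in cl),
                max(c.end for c in cl),
                classify_event(cl),
                len({c.sample for c in cl}),
                tuple(cl),
            )
        )
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    return [
        Cnvr(f"CNVR{i + 1}", chrom, s, e, rs, re_, ev, ni, calls_)
        for i, (chrom, s, e, rs, re_, ev, ni, calls_) in enumerate(records)
    ]


def summarize_cnvrs(
    cnvrs: Sequence[Cnvr],
    chrom_lengths: Mapping[str, int],
    n_individuals: int | None = None,
    n_calls: int | None = None,
) -> dict:
    """Genome summary: counts, length stats, event classes, per-chromosome
    distribution, genome fraction and per-individual means.

    Percentages are rounded half-up to two decimals.  ``chrom_lengths``
    must cover every CNVR chromosome; its total defines the genome size
    used for the coverage fraction.
    """
    for r in cnvrs:
        if r.chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length supplied for {r.chrom!r}")
    n = len(cnvrs)
    genome = float(sum(chrom_lengths.values()))
    summary: dict = {"n_cnvrs": n}
    per_chrom: dict[str, dict] = {}
    for chrom in chrom_lengths:
        cnt = sum(1 for r in cnvrs if r.chrom == chrom)
        per_chrom[chrom] = {
            "count": cnt,
            "pct": round_half_up(100.0 * cnt / n, 2) if n else 0.0,
        }
    summary["per_chromosome"] = per_chrom
    if n:
        lengths = np.array([r.length for r in cnvrs], dtype=float)
        total_len = float(lengths.sum())
        summary.update(
            min_length=float(lengths.min()),
            mean_length=float(lengths.mean()),
            max_length=float(lengths.max()),
            total_length=total_len,
            genome_fraction_pct=round_half_up(100.0 * total_len / genome, 2),
        )
    else:
        summary.update(
            min_length=None, mean_length=None, max_length=None,
            total_length=0.0, genome_fraction_pct=0.0,
        )
    events = {"gain": 0, "loss": 0, "both": 0}
    for r in cnvrs:
        events[r.event] += 1
    summary["events"] = {
        ev: {"count": c, "pct": round_half_up(100.0 * c / n, 2) if n else 0.0}
        for ev, c in events.items()
    }
    if n_individuals:
        summary["mean_cnvrs_per_individual"] = round_half_up(n / n_individuals, 2)
        if n_calls is not None:
            summary["mean_cnvs_per_individual"] = round_half_up(
                n_calls / n_individuals, 2
            )
    return summary


def cnvrs_to_table(cnvrs: Sequence[Cnvr]):
    """Tab-friendly DataFrame (1-based inclusive coordinates for reports)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.id for r in cnvrs],
            "chrom": [r.chrom for r in cnvrs],
            "start": [r.start + 1 for r in cnvrs],
            "end": [r.end for r in cnvrs],
            "length": [r.length for r in cnvrs],
            "event": [r.event for r in cnvrs],
            "n_individuals": [r.n_individuals for r in cnvrs],
        }
    )
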