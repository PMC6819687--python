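"""Synthetic SNP-array cohorts with known copy-number truth.

Emulates the data the calling pipeline consumes in the field: a dense
autosomal marker map (~3.08 kb mean spacing), per-sample LRR/BAF signal
with implanted CNV events across a configurable carrier-frequency
spectrum, genotype matrices in Hardy-Weinberg proportions, samples with
injected QC failure modes (long-range LRR waves, off-cluster BAF
contamination, high genotype missingness), and pooled read-depth tracks
with smooth GC bias — all pure functions of (config, seed).

What it does not emulate: linkage disequilibrium between markers, array
batch effects beyond the injected waves, and sequence-level reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cnvr_builder import Cnvr
from .quality_control import GenotypeMatrix
from .readdepth_validator import WindowDepth
from .signal_io import (
    GenomicInterval,
    MarkerMap,
    SignalMatrix,
    write_marker_map,
    write_signal_file,
)

__all__ = [
    "SimConfig",
    "TruthEvent",
    "TruthSet",
    "simulate_cohort",
    "simulate_pool_depth",
    "compare_to_truth",
    "write_cohort_files",
]

#: LRR shift per copy number (matches the HMM's default state means)
CN_LRR_MEAN = {0: -3.5, 1: -0.67, 2: 0.0, 3: 0.40, 4: 0.68}


@dataclass(frozen=True)
class TruthEvent:
    """One implanted CNV event shared by its carrier samples."""

    chrom: str
    start: int  # 0-based half-open over marker span
    end: int
    copy_number: int
    carriers: tuple[str, ...]
    first_marker: int  # global marker indices of the span
    last_marker: int

    @property
    def n_markers(self) -> int:
        return self.last_marker - self.first_marker + 1


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of a simulated cohort."""

    events: tuple[TruthEvent, ...]
    qc_fail_samples: tuple[str, ...]

    @property
    def expected_cnvrs(self) -> list[GenomicInterval]:
        """Events carried by >= 2 individuals, as population-level intervals."""
        out = [
            GenomicInterval(
                e.chrom,
                e.start,
                e.end,
                f"truth:{e.chrom}:{e.start}",
                {"copy_number": str(e.copy_number), "n_carriers": str(len(e.carriers))},
            )
            for e in self.events
            if len(e.carriers) >= 2
        ]
        out.sort(key=lambda iv: (iv.chrom, iv.start))
        return out


@dataclass(frozen=True)
class SimConfig:
    """Cohort-scale simulation parameters.

    Defaults mirror the study design the pipeline targets: a 90-animal
    cohort genotyped on a dense array with ~3.08 kb mean marker spacing,
    events of 5-30 markers at copy numbers 0-4, a carrier spectrum that
    includes single-carrier events (to exercise singleton filtering),
    and two 12-sample sequencing pools at 30x coverage with 150 bp
    reads.  The genome is represented by two 10 Mb autosomes so a full
    run stays desk-sized; all rates are per-marker or per-window.
    """

    n_samples: int = 90
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    marker_spacing: float = 3_080.0
    lrr_noise_sd: float = 0.2
    baf_cluster_sd: float = 0.02
    n_events: int = 12
    n_singleton_events: int = 3
    event_markers_min: int = 5
    event_markers_max: int = 30
    carriers_min: int = 2
    carriers_max: int = 8
    event_copy_numbers: tuple[int, ...] = (0, 1, 1, 3, 3, 4)
    genotype_missing_rate: float = 0.01
    n_wavy_samples: int = 0
    wave_amplitude: float = 0.3
    wave_period: float = 10_000_000.0
    n_baf_drift_samples: int = 0
    # uniform contamination puts ~10% of its mass in the drift zones, so a
    # 0.3 fraction yields drift ~0.03, clearly past the 0.02 gate
    baf_contamination: float = 0.3
    n_high_missing_samples: int = 0
    high_missing_rate: float = 0.15
    pool_size: int = 12
    coverage: float = 30.0
    read_length: int = 150
    window_width: int = 400
    gc_mean: float = 0.45
    gc_amplitude: float = 0.06
    gc_period: float = 2_000_000.0
    gc_bias_strength: float = 0.0
    seed: int = 0

    def sample_names(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


def _place_markers(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Exponentially spaced markers: realistic gaps exercise the
    distance-dependent transitions of the HMM."""
    names: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    for chrom in config.chrom_names():
        pos = 1
        i = 0
        while True:
            gap = max(1, int(rng.exponential(config.marker_spacing)))
            pos += gap
            if pos > config.chrom_length:
                break
            i += 1
            names.append(f"{chrom}_snp{i}")
            chroms.append(chrom)
            positions.append(pos)
    return MarkerMap(names, chroms, positions)


def _plan_events(
    config: SimConfig,
    marker_map: MarkerMap,
    samples: Sequence[str],
    eligible: Sequence[str],
    rng: np.random.Generator,
) -> list[TruthEvent]:
    """Place non-overlapping events on random marker spans.

    Carriers are drawn only from ``eligible`` samples (clean-signal ones)
    so every implanted multi-carrier event is in principle recoverable.
    """
    n_total = config.n_events + config.n_singleton_events
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in marker_map.chrom_names()}
    events: list[TruthEvent] = []
    cn0_carriers: set[str] = set()  # at most one homozygous deletion per genome
    guard = 0
    while len(events) < n_total and guard < 10_000:
        guard += 1
        chrom = config.chrom_names()[rng.integers(config.n_chromosomes)]
        sl = marker_map.chrom_slice(chrom)
        n_chrom = sl.stop - sl.start
        cn = int(config.event_copy_numbers[rng.integers(len(config.event_copy_numbers))])
        # homozygous deletions are kept short (they are in real genomes, and
        # their extreme LRR shift would otherwise dominate a desk-scale
        # genome's LRR standard deviation)
        span_max = min(config.event_markers_max, 10) if cn == 0 else config.event_markers_max
        span = int(rng.integers(config.event_markers_min, span_max + 1))
        if n_chrom < span + 10:
            continue
        first = int(rng.integers(5, n_chrom - span - 5))
        last = first + span - 1
        # keep a 5-marker buffer between events so truth regions stay distinct
        if any(first - 5 <= b and a <= last + 5 for a, b in taken[chrom]):
            continue
        if len(events) < config.n_events:
            n_car = int(rng.integers(config.carriers_min, config.carriers_max + 1))
        else:
            n_car = 1
        pool = [s for s in eligible if s not in cn0_carriers] if cn == 0 else eligible
        if len(pool) < n_car:
            continue
        taken[chrom].append((first, last))
        carriers = tuple(
            sorted(rng.choice(np.asarray(pool, dtype=object), n_car, replace=False))
        )
        if cn == 0:
            cn0_carriers.update(carriers)
        gfirst, glast = sl.start + first, sl.start + last
        events.append(
            TruthEvent(
                chrom=chrom,
                start=int(marker_map.positions[gfirst]) - 1,
                end=int(marker_map.positions[glast]),
                copy_number=cn,
                carriers=carriers,
                first_marker=gfirst,
                last_marker=glast,
            )
        )
    if len(events) < n_total:
        raise ValueError("could not place the configured events; genome too small")
    events.sort(key=lambda e: (e.chrom, e.start))
    return events


def simulate_cohort(
    config: SimConfig,
) -> tuple[MarkerMap, SignalMatrix, GenotypeMatrix, TruthSet]:
    """Generate a full cohort: markers, signals, genotypes and truth.

    Per marker, an allele frequency p ~ U(0.05, 0.95) defines both the
    Hardy-Weinberg genotypes and the expected BAF clusters.  Each
    sample's BAF at a marker reflects its local copy number k: the
    number of B copies is binomial(k, p) (the diploid state reuses the
    genotype), the cluster center is b/k, and Gaussian cluster noise is
    added and clipped to [0, 1]; zero-copy markers emit uniform BAF.
    LRR is the copy-state mean plus Gaussian noise, plus an injected
    sinusoid for designated wavy samples.
    """
    rng = np.random.default_rng(config.seed)
    samples = config.sample_names()
    marker_map = _place_markers(config, rng)
    n_s, n_m = len(samples), len(marker_map)

    # QC-failure designations: last samples in the roster, non-overlapping
    fail: list[str] = []
    cursor = n_s
    for count in (
        config.n_wavy_samples,
        config.n_baf_drift_samples,
        config.n_high_missing_samples,
    ):
        cursor -= count
    wavy = samples[cursor : cursor + config.n_wavy_samples]
    baf_bad = samples[
        cursor + config.n_wavy_samples : cursor
        + config.n_wavy_samples
        + config.n_baf_drift_samples
    ]
    high_missing = samples[cursor + config.n_wavy_samples + config.n_baf_drift_samples :]
    fail = list(wavy) + list(baf_bad) + list(high_missing)
    eligible = [s for s in samples if s not in fail]

    events = _plan_events(config, marker_map, samples, eligible, rng)
    truth = TruthSet(tuple(events), tuple(fail))

    p = rng.uniform(0.05, 0.95, n_m)  # per-marker B allele frequency
    genotypes = rng.binomial(2, p[None, :], size=(n_s, n_m)).astype(np.int8)

    # local copy number per (sample, marker)
    cn = np.full((n_s, n_m), 2, dtype=np.int8)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for e in events:
        for s in e.carriers:
            cn[sample_idx[s], e.first_marker : e.last_marker + 1] = e.copy_number

    b_copies = rng.binomial(cn, p[None, :])
    b_copies = np.where(cn == 2, genotypes, b_copies)
    with np.errstate(divide="ignore", invalid="ignore"):
        centers = np.where(cn > 0, b_copies / np.maximum(cn, 1), 0.5)
    baf = np.clip(centers + rng.normal(0.0, config.baf_cluster_sd, (n_s, n_m)), 0, 1)
    baf[cn == 0] = rng.uniform(0.0, 1.0, int((cn == 0).sum()))

    lrr_mean = np.vectorize(CN_LRR_MEAN.get)(cn.astype(int)).astype(float)
    lrr = lrr_mean + rng.normal(0.0, config.lrr_noise_sd, (n_s, n_m))

    for s in wavy:
        i = sample_idx[s]
        phase = rng.uniform(0, 2 * np.pi)
        lrr[i] += config.wave_amplitude * np.sin(
            2 * np.pi * marker_map.positions / config.wave_period + phase
        )
    for s in baf_bad:
        i = sample_idx[s]
        mask = rng.random(n_m) < config.baf_contamination
        baf[i, mask] = rng.uniform(0.0, 1.0, int(mask.sum()))

    gt_missing = rng.random((n_s, n_m)) < config.genotype_missing_rate
    for s in high_missing:
        i = sample_idx[s]
        gt_missing[i] = rng.random(n_m) < config.high_missing_rate
    calls = np.where(gt_missing, np.int8(-1), genotypes)

    signal = SignalMatrix(marker_map, samples, lrr, baf)
    gmat = GenotypeMatrix(marker_map, samples, calls)
    return marker_map, signal, gmat, truth


def _gc_profile(config: SimConfig, chrom_index: int, window_starts: np.ndarray) -> np.ndarray:
    return config.gc_mean + config.gc_amplitude * np.sin(
        2 * np.pi * (window_starts + chrom_index * 777_777) / config.gc_period
    )


def _gc_bias(config: SimConfig, gc: np.ndarray) -> np.ndarray:
    """Unimodal coverage bias peaking at the genome-typical GC."""
    if config.gc_bias_strength <= 0:
        return np.ones_like(gc)
    return np.exp(
        -config.gc_bias_strength * ((gc - config.gc_mean) / 0.1) ** 2
    )


def simulate_pool_depth(
    config: SimConfig, truth: TruthSet, seed: int | None = None
) -> dict[str, dict[str, WindowDepth]]:
    """Window read-count tracks for two sequencing pools.

    The expected count per window is (coverage * width / read_length)
    scaled by the pool-mean copy number over 2 and by the GC bias curve;
    realized counts are Poisson.  Pool 1 holds the first ``pool_size``
    cohort samples, pool 2 the next.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    samples = config.sample_names()
    pools = {
        "pool1": samples[: config.pool_size],
        "pool2": samples[config.pool_size : 2 * config.pool_size],
    }
    base = config.coverage * config.window_width / config.read_length
    out: dict[str, dict[str, WindowDepth]] = {}
    for pool_name, members in pools.items():
        tracks: dict[str, WindowDepth] = {}
        for ci, chrom in enumerate(config.chrom_names()):
            n_win = -(-config.chrom_length // config.window_width)
            starts = np.arange(n_win) * config.window_width
            gc = _gc_profile(config, ci, starts)
            mean_cn = np.full(n_win, 2.0)
            for e in truth.events:
                if e.chrom != chrom:
                    continue
                n_car = sum(1 for s in e.carriers if s in members)
                if n_car == 0:
                    continue
                w0 = e.start // config.window_width
                w1 = -(-e.end // config.window_width)
                pool_cn = (
                    n_car * e.copy_number + (len(members) - n_car) * 2
                ) / len(members)
                mean_cn[w0:w1] = pool_cn
            expected = base * (mean_cn / 2.0) * _gc_bias(config, gc)
            raw = rng.poisson(expected).astype(np.int64)
            tracks[chrom] = WindowDepth(chrom, config.window_width, raw, gc=gc)
        out[pool_name] = tracks
    return out


def compare_to_truth(
    called: Sequence[Cnvr | GenomicInterval],
    truth: TruthSet,
    min_overlap_fraction: float = 0.5,
) -> tuple[float | None, float, list[tuple[int, int]]]:
    """(precision, recall, per-recovered-event boundary errors in bp).

    An expected CNVR counts as recovered when a called region of
    matching polarity (gain vs loss; 'both' matches either) covers at
    least ``min_overlap_fraction`` of it; a called region is a true
    positive when it participates in such a match.  Precision is None
    when nothing was called.
    """

    def _polarity(obj) -> str:
        if isinstance(obj, Cnvr):
            return obj.event
        return "gain" if int(obj.attributes["copy_number"]) > 2 else "loss"

    expected = truth.expected_cnvrs
    matched_called: set[int] = set()
    n_recovered = 0
    boundary_errors: list[tuple[int, int]] = []
    for exp in expected:
        exp_pol = "gain" if int(exp.attributes["copy_number"]) > 2 else "loss"
        best = None
        best_ov = 0
        for ci, c in enumerate(called):
            if c.chrom != exp.chrom:
                continue
            pol = _polarity(c)
            if pol != "both" and pol != exp_pol:
                continue
            ov = min(c.end, exp.end) - max(c.start, exp.start)
            if ov > best_ov:
                best_ov = ov
                best = ci
        if best is not None and best_ov >= min_overlap_fraction * len(exp):
            n_recovered += 1
            matched_called.add(best)
            c = called[best]
            boundary_errors.append((abs(c.start - exp.start), abs(c.end - exp.end)))
    recall = n_recovered / len(expected) if expected else 1.0
    precision = len(matched_called) / len(called) if called else None
    return precision, recall, boundary_errors


def write_cohort_files(
    outdir,
    marker_map: MarkerMap,
    signal: SignalMatrix,
    genotypes: GenotypeMatrix,
    truth: TruthSet,
    pfb: np.ndarray | None = None,
) -> dict[str, Path]:
    """Emit the cohort in the same file dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if pfb is not None:
        marker_map = MarkerMap(
            marker_map.names, list(marker_map.chroms), list(marker_map.positions), pfb
        )
    paths["marker_map"] = outdir / "markers.pfb"
    write_marker_map(marker_map, paths["marker_map"])
    for sample in signal.samples:
        lrr, baf = signal.sample_signals(sample)
        p = outdir / f"{sample}.signal.txt"
        write_signal_file(p, sample, marker_map, lrr, baf)
        paths[f"signal:{sample}"] = p
    paths["genotypes"] = outdir / "genotypes.tsv"
    genotypes.write(paths["genotypes"])
    paths["truth"] = outdir / "truth.bed"
    with open(paths["truth"], "w") as fh:
        for e in truth.events:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\tCN{e.copy_number}"
                f"\t{len(e.carriers)}\t{','.join(e.carriers)}\n"
            )
    return paths
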