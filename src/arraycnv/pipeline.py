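"""End-to-end orchestration: QC -> calling -> CNVRs -> validation -> annotation.

The pipeline runs the stages in cohort order — genotype missingness,
SNP filters, intensity QC, HMM calling on passing samples over retained
markers, CNVR construction, then the optional read-depth validation and
annotation stages — and renders a run report whose every percentage is
recomputable from the printed numerator and denominator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import cnvr_builder, hmm_caller, overlap_annotation, quality_control
from . import readdepth_validator, signal_io, synthetic_data
from ._util import round_half_up

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "paper_summary_check"]

log = logging.getLogger("arraycnv")


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, at their standard defaults.

    Defaults: genotype call rate >= 0.90, MAF >= 0.05, sample
    missingness <= 0.1, LRR SD <= 0.3, BAF drift <= 0.02, |waviness| <=
    0.05, >= 3 SNPs per call, 400 bp depth windows, 2.5% CNVR boundary
    trimming.
    """

    sim: synthetic_data.SimConfig | None = None
    input_dir: str | None = None
    output_dir: str | None = None
    seed: int = 0
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    max_missing: float = 0.1
    lrr_sd_max: float = 0.3
    baf_drift_max: float = 0.02
    waviness_max: float = 0.05
    min_snps: int = 3
    min_individuals: int = 2
    window_width: int = 400
    trim_fraction: float = 0.025
    depth_min_run: int = 5
    validate_depth: bool = True
    qtl_path: str | None = None
    gene_path: str | None = None
    reference_cnvr_paths: dict = field(default_factory=dict)
    hmm: hmm_caller.HmmModel = field(default_factory=hmm_caller.HmmModel)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        hmm = raw.pop("hmm", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = synthetic_data.SimConfig(**sim)
        if hmm is not None:
            cfg.hmm = hmm_caller.HmmModel(**{k: tuple(v) if isinstance(v, list) else v
                                             for k, v in hmm.items()})
        return cfg


@dataclass
class RunReport:
    """Machine-checkable record of one pipeline run."""

    stages: dict = field(default_factory=dict)
    cnvr_summary: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)
    truth_metrics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def paper_summary_check(
    counts: Mapping[str, tuple[float, float, str]]
) -> dict[str, float]:
    """Percentages/means at two decimals from named (num, den, kind) triples.

    ``kind`` is 'pct' (100*num/den) or 'mean' (num/den); rounding is
    half-up, the convention of published summary tables.
    """
    out: dict[str, float] = {}
    for name, (num, den, kind) in counts.items():
        if den == 0:
            raise ZeroDivisionError(f"{name}: zero denominator")
        value = num / den
        if kind == "pct":
            value *= 100.0
        elif kind != "mean":
            raise ValueError(f"{name}: unknown kind {kind!r}")
        out[name] = round_half_up(value, 2)
    return out


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(dataclasses.asdict(config)).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig):
    """Execute the full workflow and return (report, cnvrs, extras).

    With ``config.sim`` set the cohort is simulated (and truth metrics
    are computed); otherwise inputs are read from ``config.input_dir``.
    Optional stages (depth validation, QTL/gene annotation, concordance)
    are skipped with an explicit report placeholder when their inputs
    are absent.
    """
    report = RunReport()
    report.provenance = {"seed": config.seed, "config_hash": _config_hash(config)}
    truth = None
    pools = None

    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        marker_map, signal, genotypes, truth = synthetic_data.simulate_cohort(sim)
        if config.validate_depth:
            pools = synthetic_data.simulate_pool_depth(sim, truth)
        chrom_lengths = sim.chrom_lengths()
    elif config.input_dir is not None:
        indir = Path(config.input_dir)
        marker_map = signal_io.read_marker_map(indir / "markers.pfb")
        genotypes = quality_control.GenotypeMatrix.read(
            indir / "genotypes.tsv", marker_map
        )
        samples = genotypes.samples
        lrr = np.full((len(samples), len(marker_map)), np.nan)
        baf = np.full((len(samples), len(marker_map)), np.nan)
        for i, s in enumerate(samples):
            lrr[i], baf[i], _ = signal_io.read_signal_file(
                indir / f"{s}.signal.txt", s, marker_map
            )
        signal = signal_io.SignalMatrix(marker_map, samples, lrr, baf)
        chrom_lengths = {
            c: int(marker_map.positions[marker_map.chrom_slice(c)][-1]) + 1
            for c in marker_map.chrom_names()
        }
    else:
        raise ValueError("config needs either sim parameters or input_dir")

    # --- stage 1: sample genotype missingness ---------------------------
    kept_samples = quality_control.sample_missingness_filter(
        genotypes, config.max_missing
    )
    report.stages["sample_missingness"] = {
        "input": len(genotypes.samples),
        "removed": len(genotypes.samples) - len(kept_samples),
    }
    log.info("missingness filter removed %d samples", len(genotypes.samples) - len(kept_samples))

    # --- stage 2: SNP filters -------------------------------------------
    retained_markers, snp_counts = quality_control.snp_qc(
        genotypes,
        samples=kept_samples,
        call_rate_min=config.call_rate_min,
        maf_min=config.maf_min,
        hwe_p_min=config.hwe_p_min,
    )
    report.stages["snp_qc"] = snp_counts

    # --- stage 3: per-sample intensity QC -------------------------------
    stats = quality_control.sample_signal_qc(
        signal,
        marker_map,
        lrr_sd_max=config.lrr_sd_max,
        baf_drift_max=config.baf_drift_max,
        waviness_max=config.waviness_max,
    )
    stats = [s for s in stats if s.sample in set(kept_samples)]
    passing = [s.sample for s in stats if s.passed]
    report.stages["signal_qc"] = {
        "input": len(stats),
        "removed": len(stats) - len(passing),
        "failed_samples": sorted(set(s.sample for s in stats) - set(passing)),
    }

    # --- PFB from passing samples ---------------------------------------
    pfb = signal_io.compute_pfb(signal, passing)

    # --- stage 4: HMM calling on retained markers -----------------------
    marker_idx = np.asarray(
        [marker_map.index_of(m) for m in retained_markers], dtype=np.int64
    )
    sub_map = signal_io.MarkerMap(
        [marker_map.names[i] for i in marker_idx],
        list(marker_map.chroms[marker_idx]),
        list(marker_map.positions[marker_idx]),
        pfb[marker_idx],
    )
    model = dataclasses.replace(config.hmm, min_snps=config.min_snps)
    all_calls: list[hmm_caller.CnvCall] = []
    for sample in passing:
        lrr_s, baf_s = signal.sample_signals(sample)
        calls = hmm_caller.call_cnvs(
            model, sample, lrr_s[marker_idx], baf_s[marker_idx], sub_map
        )
        all_calls.extend(calls)
    report.stages["calling"] = {
        "samples": len(passing),
        "markers": len(sub_map),
        "n_calls": len(all_calls),
    }

    # --- stage 5: CNVR construction -------------------------------------
    cnvrs = cnvr_builder.build_cnvrs(all_calls, min_individuals=config.min_individuals)
    report.cnvr_summary = cnvr_builder.summarize_cnvrs(
        cnvrs, chrom_lengths, n_individuals=len(passing), n_calls=len(all_calls)
    )

    # --- stage 6: read-depth validation ---------------------------------
    if pools is not None and cnvrs:
        depth_regions: list[signal_io.GenomicInterval] = []
        for pool_tracks in pools.values():
            tracks = readdepth_validator.gc_correct(pool_tracks)
            tracks = readdepth_validator.estimate_copy_number(tracks)
            depth_regions.extend(
                readdepth_validator.call_depth_cnvrs(tracks, min_run=config.depth_min_run)
            )
        flags, rate = readdepth_validator.validate_cnvrs(cnvrs, depth_regions)
        report.validation = {
            "n_depth_cnvrs": len(depth_regions),
            "n_confirmed": int(sum(flags.values())),
            "rate_pct": rate,
        }
    else:
        report.validation = {"skipped": True}

    # --- stage 7: annotation (optional inputs) --------------------------
    report.annotation = {}
    if config.qtl_path and cnvrs:
        qtls = signal_io.read_bed_intervals(config.qtl_path)
        n_ov, n_qtl, n_traits, _ = overlap_annotation.qtl_overlap(cnvrs, qtls)
        report.annotation["qtl"] = {
            "n_cnvrs_overlapping": n_ov,
            "n_distinct_qtls": n_qtl,
            "n_distinct_traits": n_traits,
        }
    else:
        report.annotation["qtl"] = {"skipped": True}
    if config.gene_path and cnvrs:
        genes, _ = signal_io.read_gff3_genes(config.gene_path)
        _, hist = overlap_annotation.annotate_genes(cnvrs, genes)
        report.annotation["genes"] = {"histogram": hist}
    else:
        report.annotation["genes"] = {"skipped": True}
    concord = {}
    for label, path in (config.reference_cnvr_paths or {}).items():
        ref = signal_io.read_bed_intervals(path)
        rec = overlap_annotation.concordance(cnvrs, ref, label)
        concord[label] = dataclasses.asdict(rec)
    report.annotation["concordance"] = concord or {"skipped": True}

    # --- truth metrics for simulated cohorts ----------------------------
    if truth is not None:
        precision, recall, berr = synthetic_data.compare_to_truth(cnvrs, truth)
        report.truth_metrics = {
            "precision": precision,
            "recall": recall,
            "n_expected": len(truth.expected_cnvrs),
            "boundary_errors_bp": [list(b) for b in berr],
        }

    _self_check(report)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        cnvr_builder.cnvrs_to_table(cnvrs).to_csv(
            outdir / "cnvrs.tsv", sep="\t", index=False
        )
        with open(outdir / "calls.txt", "w") as fh:
            fh.write("\n".join(hmm_caller.calls_to_penncnv_lines(all_calls)) + "\n")
        report.to_json(outdir / "report.json")

    return report, cnvrs, {"calls": all_calls, "truth": truth, "pfb": pfb}


def _self_check(report: RunReport) -> None:
    """Every reported percentage must recompute from its own counts."""
    summ = report.cnvr_summary
    n = summ.get("n_cnvrs", 0)
    if not n:
        return
    for ev, rec in summ["events"].items():
        expected = paper_summary_check({ev: (rec["count"], n, "pct")})[ev]
        if rec["pct"] != expected:
            raise AssertionError(f"inconsistent percentage for event {ev}")
    if not report.validation.get("skipped"):
        v = report.validation
        expected = paper_summary_check({"v": (v["n_confirmed"], n, "pct")})["v"]
        if v["rate_pct"] != expected:
            raise AssertionError("inconsistent validation rate")
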