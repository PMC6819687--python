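"""Readers and writers for SNP-array CNV calling inputs.

Covers the marker map / population-B-allele-frequency (PFB) table, the
per-sample split signal files carrying Log R Ratio (LRR) and B allele
frequency (BAF), BED-like interval files and GFF3 gene records.

Coordinate convention: everything held in memory is 0-based half-open;
1-based dialects (PennCNV-style reports, GFF3) are converted at the I/O
edge so that interval length is always ``end - start``.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "SignalMatrix",
    "GenomicInterval",
    "read_marker_map",
    "write_marker_map",
    "read_signal_file",
    "write_signal_file",
    "compute_pfb",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_gff3_genes",
]

#: sentinel for a missing LRR/BAF entry
MISSING = float("nan")

PFB_MIN = 0.01
PFB_MAX = 0.99


def _opener(path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text transparently."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled half-open genomic interval with free-form attributes."""

    chrom: str
    start: int
    end: int
    label: str = ""
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class MarkerMap:
    """Ordered autosomal marker backbone: names, positions and PFB values.

    Markers are stored sorted by (chrom, position); position is 1-based as
    on the array manifest.  PFB values are clamped to [0.01, 0.99] so that
    every genotype cluster keeps nonzero weight in the HMM emission model.
    """

    def __init__(
        self,
        names: Sequence[str],
        chroms: Sequence[str],
        positions: Sequence[int],
        pfb: Sequence[float] | None = None,
    ) -> None:
        n = len(names)
        if not (len(chroms) == len(positions) == n):
            raise ValueError("names, chroms, positions must have equal length")
        if pfb is None:
            pfb = np.full(n, 0.5)
        pfb = np.asarray(pfb, dtype=float)
        order = sorted(range(n), key=lambda i: (str(chroms[i]), int(positions[i])))
        self.names = [str(names[i]) for i in order]
        self.chroms = np.asarray([str(chroms[i]) for i in order], dtype=object)
        self.positions = np.asarray([int(positions[i]) for i in order], dtype=np.int64)
        self.pfb = np.clip(pfb[order], PFB_MIN, PFB_MAX)
        seen: dict[str, int] = {}
        for name in self.names:
            seen[name] = seen.get(name, 0) + 1
            if seen[name] > 1:
                raise ValueError(f"duplicate marker name: {name!r}")
        for chrom in self.chrom_names():
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"non-increasing positions on {chrom}")
        self._index = {name: i for i, name in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self._index[name]

    def chrom_names(self) -> list[str]:
        out: list[str] = []
        for c in self.chroms:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of markers on ``chrom``."""
        idx = np.flatnonzero(self.chroms == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Name": self.names,
                "Chr": self.chroms,
                "Position": self.positions,
                "PFB": self.pfb,
            }
        )


class SignalMatrix:
    """Per-sample, per-marker LRR and BAF tables aligned to a MarkerMap.

    Missing entries are NaN; the HMM skips them rather than imputing.
    """

    def __init__(
        self,
        marker_map: MarkerMap,
        samples: Sequence[str],
        lrr: np.ndarray | None = None,
        baf: np.ndarray | None = None,
    ) -> None:
        self.marker_map = marker_map
        self.samples = list(samples)
        shape = (len(self.samples), len(marker_map))
        self.lrr = np.full(shape, MISSING) if lrr is None else np.asarray(lrr, float)
        self.baf = np.full(shape, MISSING) if baf is None else np.asarray(baf, float)
        if self.lrr.shape != shape or self.baf.shape != shape:
            raise ValueError("signal tables must be (n_samples, n_markers)")
        with np.errstate(invalid="ignore"):
            bad = (self.baf < 0) | (self.baf > 1)
        if np.any(bad):
            raise ValueError("BAF entries outside [0, 1]")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def sample_signals(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.sample_index(sample)
        return self.lrr[i], self.baf[i]


def read_marker_map(path) -> MarkerMap:
    """Read a tab-delimited marker map (Name, Chr, Position[, PFB]).

    Rows may arrive in any order; the map is sorted by (chrom, position).
    A missing PFB column defaults to 0.5 (uninformative allele frequency).
    """
    df = pd.read_csv(path, sep="\t", dtype={"Name": str, "Chr": str})
    required = {"Name", "Chr", "Position"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker map must have columns {sorted(required)}")
    pos = pd.to_numeric(df["Position"], errors="coerce")
    if pos.isna().any():
        line = int(pos.index[pos.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"non-numeric position at line {line}")
    pfb = df["PFB"].to_numpy(float) if "PFB" in df.columns else None
    return MarkerMap(df["Name"].tolist(), df["Chr"].tolist(), pos.astype(int).tolist(), pfb)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_signal_file(
    path, sample_id: str, marker_map: MarkerMap
) -> tuple[np.ndarray, np.ndarray, int]:
    """Read one split signal file into map-aligned (lrr, baf) vectors.

    The file carries columns ``Name``, ``<sample>.Log R Ratio`` and
    ``<sample>.B Allele Freq``; markers absent from the file stay NaN.
    Out-of-range BAF values are clamped into [0, 1]; the number of clamped
    entries is returned so callers can log it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Name": str})
    lrr_col = f"{sample_id}.Log R Ratio"
    baf_col = f"{sample_id}.B Allele Freq"
    if lrr_col not in df.columns or baf_col not in df.columns:
        raise ValueError(f"signal file lacks columns for sample {sample_id!r}")
    lrr = np.full(len(marker_map), MISSING)
    baf = np.full(len(marker_map), MISSING)
    raw_lrr = pd.to_numeric(df[lrr_col], errors="coerce").to_numpy()
    raw_baf = pd.to_numeric(df[baf_col], errors="coerce").to_numpy()
    clamped = int(np.sum((raw_baf < 0) | (raw_baf > 1)))
    raw_baf = np.clip(raw_baf, 0.0, 1.0)
    for name, lv, bv in zip(df["Name"], raw_lrr, raw_baf):
        try:
            i = marker_map.index_of(name)
        except KeyError:
            continue
        lrr[i] = lv
        baf[i] = bv
    return lrr, baf, clamped


def write_signal_file(path, sample_id: str, marker_map: MarkerMap, lrr, baf) -> None:
    df = pd.DataFrame(
        {
            "Name": marker_map.names,
            f"{sample_id}.Log R Ratio": np.asarray(lrr, float),
            f"{sample_id}.B Allele Freq": np.asarray(baf, float),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def compute_pfb(signal: SignalMatrix, qc_pass_samples: Iterable[str]) -> np.ndarray:
    """Per-marker population B-allele frequency from cohort BAF.

    pfb[m] is the mean non-missing BAF over the given samples, clamped to
    [0.01, 0.99]; markers with no data fall back to the uninformative 0.5.
    """
    samples = list(qc_pass_samples)
    if not samples:
        raise ValueError("compute_pfb requires at least one sample")
    rows = [signal.sample_index(s) for s in samples]
    baf = signal.baf[rows]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        pfb = np.nanmean(baf, axis=0)
    pfb = np.where(np.isnan(pfb), 0.5, pfb)
    return np.clip(pfb, PFB_MIN, PFB_MAX)


def read_bed_intervals(path, one_based: bool = False) -> list[GenomicInterval]:
    """Read a 3+ column BED-like file into sorted intervals.

    ``one_based=True`` reads a 1-based fully-closed dialect and converts it
    to the internal 0-based half-open convention.  Columns beyond the
    fourth are kept as numbered attributes.
    """
    out: list[GenomicInterval] = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end")
            label = fields[3] if len(fields) > 3 else ""
            attrs = {f"col{i + 1}": v for i, v in enumerate(fields[4:], start=4)}
            attrs["dialect"] = "1-based" if one_based else "bed"
            out.append(GenomicInterval(chrom, start, end, label, attrs))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed_intervals(intervals: Sequence[GenomicInterval], path) -> None:
    with _opener(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_gff3_genes(path) -> tuple[list[GenomicInterval], int]:
    """Extract gene features from a GFF3 file as internal intervals.

    Returns (genes, n_skipped).  Only features of type ``gene`` (and the
    non-coding *_gene variants Ensembl uses) are kept; mRNA/exon/CDS rows
    are structural children and are excluded.  GFF3's 1-based inclusive
    coordinates become 0-based half-open.  The gene id and biotype are
    preserved as attributes; features whose attribute column cannot be
    parsed are skipped and counted.
    """
    import pyranges

    gr = pyranges.read_gff3(str(path))
    df = gr.df
    genes: list[GenomicInterval] = []
    skipped = 0
    gene_like = df["Feature"].astype(str).str.endswith("gene")
    for _, row in df[gene_like].iterrows():
        gid = row.get("ID") or row.get("gene_id")
        if gid is None or (isinstance(gid, float) and math.isnan(gid)):
            skipped += 1
            continue
        gid = str(gid)
        if gid.startswith("gene:"):
            gid = gid[5:]
        biotype = row.get("biotype")
        if biotype is None or (isinstance(biotype, float) and math.isnan(biotype)):
            biotype = str(row["Feature"])
        genes.append(
            GenomicInterval(
                str(row["Chromosome"]),
                int(row["Start"]),
                int(row["End"]),
                gid,
                {"biotype": str(biotype)},
            )
        )
    genes.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return genes, skipped
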