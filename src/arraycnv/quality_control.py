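"""Marker- and sample-level quality control for SNP-array CNV calling.

Two layers, applied in cohort order: genotype-based filters first (sample
missingness, then SNP call rate / minor allele frequency / Hardy-Weinberg
exact test), then intensity-based per-sample filters (LRR standard
deviation, BAF drift, waviness factor) that gate entry into the HMM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .signal_io import MarkerMap, SignalMatrix

__all__ = [
    "GenotypeMatrix",
    "SampleQcStats",
    "hwe_exact_test",
    "snp_qc",
    "sample_missingness_filter",
    "sample_signal_qc",
]

# genotype codes: 0 = AA, 1 = AB, 2 = BB, -1 = missing
MISSING_GT = -1

LRR_SD_MAX = 0.3
BAF_DRIFT_MAX = 0.02
WAVINESS_MAX = 0.05
#: off-cluster BAF zones whose occupancy defines BAF drift
DRIFT_ZONES = ((0.2, 0.25), (0.75, 0.8))
WAVINESS_BIN_BP = 1_000_000
MIN_INFORMATIVE_MARKERS = 100


class GenotypeMatrix:
    """Sample x marker genotype calls coded {0: AA, 1: AB, 2: BB, -1: NA}."""

    def __init__(self, marker_map: MarkerMap, samples: Sequence[str], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(marker_map)):
            raise ValueError("calls must be (n_samples, n_markers)")
        if not np.isin(calls, [-1, 0, 1, 2]).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.marker_map = marker_map
        self.samples = list(samples)
        self.calls = calls

    @classmethod
    def read(cls, path, marker_map: MarkerMap) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df[marker_map.names]
        calls = df.fillna(MISSING_GT).to_numpy(dtype=np.int8)
        return cls(marker_map, [str(s) for s in df.index], calls)

    def write(self, path) -> None:
        pd.DataFrame(
            self.calls, index=self.samples, columns=self.marker_map.names
        ).replace(MISSING_GT, pd.NA).to_csv(path, sep="\t", na_rep="NA")


@dataclass(frozen=True)
class SampleQcStats:
    """Intensity-QC summary for one sample.

    ``passed`` requires lrr_sd <= 0.3, baf_drift <= 0.02 and
    |waviness_factor| <= 0.05; samples with too few informative markers
    are flagged unreliable and fail outright.
    """

    sample: str
    lrr_sd: float
    baf_drift: float
    waviness_factor: float
    missing_rate: float
    reliable: bool
    passed: bool


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as observed) whose conditional
    probability does not exceed that of the observed table.  Returns a
    p-value in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype call required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    # attainable heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # log P(n_ab = h | n, n_a) for the conditional (hypergeometric-form) law
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_idx = int(np.searchsorted(hets, n_ab))
    p_obs = probs[obs_idx]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def sample_missingness_filter(
    genotypes: GenotypeMatrix, max_missing: float = 0.1
) -> list[str]:
    """Samples whose missing-call fraction is <= ``max_missing`` (strict > removed)."""
    miss = (genotypes.calls == MISSING_GT).mean(axis=1)
    return [s for s, m in zip(genotypes.samples, miss) if m <= max_missing]


def snp_qc(
    genotypes: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> tuple[list[str], dict[str, int]]:
    """Marker filters: call rate, minor allele frequency, HWE exact test.

    A marker is removed if it fails any filter; the returned counts
    attribute each marker to every filter it fails, so they may overlap
    (``removed_exclusive`` gives the non-overlapping total).
    """
    if samples is None:
        samples = genotypes.samples
    rows = [genotypes.samples.index(s) for s in samples]
    calls = genotypes.calls[rows]
    n_samples = len(rows)
    if n_samples == 0 or calls.size == 0:
        raise ValueError("empty genotype matrix")

    observed = calls != MISSING_GT
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / n_samples
    n_ab = (calls == 1).sum(axis=0)
    n_bb = (calls == 2).sum(axis=0)
    n_aa = n_obs - n_ab - n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = (2 * n_bb + n_ab) / (2 * n_obs)
    maf = np.minimum(freq_b, 1 - freq_b)

    fail_cr = call_rate < call_rate_min
    fail_maf = np.where(n_obs > 0, maf < maf_min, True)
    fail_hwe = np.zeros(len(genotypes.marker_map), dtype=bool)
    for m in range(len(genotypes.marker_map)):
        if n_obs[m] == 0:
            fail_hwe[m] = True
            continue
        p = hwe_exact_test(int(n_aa[m]), int(n_ab[m]), int(n_bb[m]))
        fail_hwe[m] = p < hwe_p_min

    fail_any = fail_cr | fail_maf | fail_hwe
    retained = [
        name for name, bad in zip(genotypes.marker_map.names, fail_any) if not bad
    ]
    counts = {
        "call_rate": int(fail_cr.sum()),
        "maf": int(fail_maf.sum()),
        "hwe": int(fail_hwe.sum()),
        "removed_exclusive": int(fail_any.sum()),
        "retained": len(retained),
    }
    return retained, counts


def _waviness_factor(
    lrr: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    gc_track: Mapping[tuple[str, int], float] | None,
) -> float:
    """SD of per-1-Mb-bin median LRR; signed by correlation with bin GC.

    Long-range intensity waves inflate the dispersion of bin medians even
    when the marker-level SD looks acceptable.  When a GC value per
    (chrom, bin) is supplied the sign records whether the waves track GC.
    """
    medians: list[float] = []
    gcs: list[float] = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        pos = positions[mask]
        vals = lrr[mask]
        bins = pos // WAVINESS_BIN_BP
        for b in np.unique(bins):
            v = vals[bins == b]
            v = v[~np.isnan(v)]
            if v.size == 0:
                continue
            medians.append(float(np.median(v)))
            if gc_track is not None:
                gcs.append(float(gc_track.get((str(chrom), int(b)), np.nan)))
    if len(medians) < 2:
        return 0.0
    wf = float(np.std(medians, ddof=0))
    if gc_track is not None and len(gcs) == len(medians):
        med = np.asarray(medians)
        gc = np.asarray(gcs)
        ok = ~np.isnan(gc)
        if ok.sum() >= 2 and np.std(gc[ok]) > 0 and np.std(med[ok]) > 0:
            r = float(np.corrcoef(med[ok], gc[ok])[0, 1])
            if r < 0:
                wf = -wf
    return wf


def sample_signal_qc(
    signal: SignalMatrix,
    marker_map: MarkerMap | None = None,
    gc_track: Mapping[tuple[str, int], float] | None = None,
    lrr_sd_max: float = LRR_SD_MAX,
    baf_drift_max: float = BAF_DRIFT_MAX,
    waviness_max: float = WAVINESS_MAX,
) -> list[SampleQcStats]:
    """Per-sample intensity QC over autosomal markers.

    * ``lrr_sd`` - standard deviation of non-missing LRR;
    * ``baf_drift`` - fraction of non-missing markers with BAF in the
      off-cluster zones [0.2, 0.25] or [0.75, 0.8];
    * ``waviness_factor`` - see :func:`_waviness_factor`.
    """
    if marker_map is None:
        marker_map = signal.marker_map
    out: list[SampleQcStats] = []
    for sample in signal.samples:
        lrr, baf = signal.sample_signals(sample)
        ok_l = ~np.isnan(lrr)
        ok_b = ~np.isnan(baf)
        n_inf = int((ok_l | ok_b).sum())
        missing_rate = 1.0 - n_inf / max(len(marker_map), 1)
        reliable = n_inf >= MIN_INFORMATIVE_MARKERS
        lrr_sd = float(np.std(lrr[ok_l], ddof=0)) if ok_l.any() else float("nan")
        if ok_b.any():
            b = baf[ok_b]
            in_zone = np.zeros(b.shape, dtype=bool)
            for lo, hi in DRIFT_ZONES:
                in_zone |= (b >= lo) & (b <= hi)
            baf_drift = float(in_zone.mean())
        else:
            baf_drift = float("nan")
        wf = _waviness_factor(lrr, marker_map.chroms, marker_map.positions, gc_track)
        passed = (
            reliable
            and lrr_sd <= lrr_sd_max
            and baf_drift <= baf_drift_max
            and abs(wf) <= waviness_max
        )
        out.append(
            SampleQcStats(sample, lrr_sd, baf_drift, wf, missing_rate, reliable, passed)
        )
    return out
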