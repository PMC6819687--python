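"""Six-state hidden-Markov segmentation of LRR/BAF into copy-number calls.

The chain runs over the ordered markers of one chromosome.  States are
copy numbers 0-4 plus a copy-neutral loss-of-heterozygosity state (CN2
signal intensity, homozygous BAF pattern).  Emissions combine a Gaussian
LRR term with a genotype-cluster mixture for BAF whose cluster weights
come from the marker's population B-allele frequency; transitions decay
with inter-marker distance so that widely spaced markers are nearly
independent while dense markers are sticky.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .signal_io import GenomicInterval, MarkerMap, SignalMatrix

__all__ = [
    "STATES",
    "STATE_COPY_NUMBER",
    "HmmModel",
    "CnvCall",
    "transition_matrix",
    "emission_loglik",
    "emission_matrix",
    "viterbi_decode",
    "call_cnvs",
    "calls_to_penncnv_lines",
]

STATES = ("CN0", "CN1", "CN2", "CN2-LOH", "CN3", "CN4")
STATE_COPY_NUMBER = {"CN0": 0, "CN1": 1, "CN2": 2, "CN2-LOH": 2, "CN3": 3, "CN4": 4}
_CN2_IDX = STATES.index("CN2")

#: genotype-cluster BAF centers per state; None means uniform (no DNA)
_BAF_CENTERS: dict[str, np.ndarray | None] = {
    "CN0": None,
    "CN1": np.array([0.0, 1.0]),
    "CN2": np.array([0.0, 0.5, 1.0]),
    "CN2-LOH": np.array([0.0, 1.0]),
    "CN3": np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    "CN4": np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
}
#: number of allele copies drawn binomially to weight the clusters
_BAF_COPIES = {"CN1": 1, "CN2": 2, "CN2-LOH": 1, "CN3": 3, "CN4": 4}


@dataclass(frozen=True)
class HmmModel:
    """Parameters of the copy-number HMM.

    ``lrr_mean`` follows the characteristic intensity shifts of each copy
    state (deep negative for homozygous deletion, ~-0.67 for one copy,
    0 for diploid, +0.4/+0.68 for three/four copies).  ``stay_prob`` is
    the per-marker self-transition probability in the dense-marker limit;
    ``decay_length`` is the distance scale over which state memory fades.
    """

    lrr_mean: tuple[float, ...] = (-3.5, -0.67, 0.0, 0.0, 0.40, 0.68)
    lrr_sd: tuple[float, ...] = (1.3, 0.25, 0.2, 0.2, 0.25, 0.3)
    baf_cluster_sd: float = 0.03
    baf_outlier_weight: float = 0.01
    stay_prob: tuple[float, ...] = (0.95, 0.95, 0.999, 0.95, 0.95, 0.95)
    #: relative weight of each state as a transition/initial target; favors CN2
    base_weight: tuple[float, ...] = (0.02, 0.10, 0.70, 0.03, 0.10, 0.05)
    decay_length: float = 100_000.0
    min_snps: int = 3

    def __post_init__(self) -> None:
        cn_states = [STATES.index(s) for s in ("CN0", "CN1", "CN2", "CN3", "CN4")]
        means = [self.lrr_mean[i] for i in cn_states]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("lrr_mean must be nondecreasing in copy number")
        if not all(0 < p < 1 for p in self.stay_prob):
            raise ValueError("stay_prob entries must lie in (0, 1)")


def transition_matrix(model: HmmModel, d: float) -> np.ndarray:
    """Distance-dependent transition matrix for an inter-marker gap of ``d`` bp.

    The self-transition probability interpolates between 1 at d = 0 and
    ``stay_prob`` as d >> decay_length; the complementary mass is split
    among the other states proportionally to their base weights, so the
    chain relaxes toward the CN2-dominated prior over long gaps.
    """
    if d < 0:
        raise ValueError("distance must be nonnegative")
    k = len(STATES)
    mix = 1.0 - np.exp(-d / model.decay_length)
    stay = np.asarray(model.stay_prob)
    diag = 1.0 - (1.0 - stay) * mix
    w = np.asarray(model.base_weight, dtype=float)
    T = np.empty((k, k))
    for i in range(k):
        others = np.delete(np.arange(k), i)
        wi = w[others]
        T[i, others] = (1.0 - diag[i]) * wi / wi.sum()
        T[i, i] = diag[i]
    return T


def _truncnorm_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Gaussian density truncated to [0, 1] (BAF support)."""
    z = norm.cdf((1.0 - mu) / sd) - norm.cdf((0.0 - mu) / sd)
    return norm.pdf(x, loc=mu, scale=sd) / z


def _baf_loglik(model: HmmModel, state: str, baf: np.ndarray, pfb: np.ndarray) -> np.ndarray:
    """Log-density of BAF under a state's genotype-cluster mixture.

    Clusters sit at b/k for b successes of a Binomial(k, pfb) draw, k the
    state's copy number; each cluster is a boundary-truncated Gaussian,
    and a small uniform outlier component absorbs stray values.  The
    zero-copy state has no allelic signal, so its BAF is uniform.
    """
    centers = _BAF_CENTERS[state]
    w_out = model.baf_outlier_weight
    if centers is None:
        return np.zeros_like(baf)  # log of uniform density 1 on [0,1]
    k = _BAF_COPIES[state]
    n = baf.shape[0]
    dens = np.zeros(n)
    if state == "CN2-LOH":
        # heterozygosity lost: clusters at 0 and 1 with weights (1-p, p)
        weights = np.stack([1.0 - pfb, pfb], axis=1)
    else:
        from scipy.stats import binom

        b = np.arange(k + 1)
        weights = binom.pmf(b[None, :], k, pfb[:, None])
    for j, mu in enumerate(centers):
        dens += weights[:, j] * _truncnorm_pdf(baf, float(mu), model.baf_cluster_sd)
    dens = w_out * 1.0 + (1.0 - w_out) * dens
    return np.log(dens)


def emission_matrix(
    model: HmmModel, lrr: np.ndarray, baf: np.ndarray, pfb: np.ndarray
) -> np.ndarray:
    """(n_markers, n_states) emission log-likelihoods.

    Missing LRR or BAF contributes zero log-likelihood (the marker is
    uninformative for that channel rather than imputed).
    """
    lrr = np.asarray(lrr, float)
    baf = np.asarray(baf, float)
    pfb = np.asarray(pfb, float)
    n = lrr.shape[0]
    out = np.zeros((n, len(STATES)))
    ok_l = ~np.isnan(lrr)
    ok_b = ~np.isnan(baf)
    for s, state in enumerate(STATES):
        if ok_l.any():
            out[ok_l, s] += norm.logpdf(
                lrr[ok_l], loc=model.lrr_mean[s], scale=model.lrr_sd[s]
            )
        if ok_b.any():
            out[ok_b, s] += _baf_loglik(model, state, baf[ok_b], pfb[ok_b])
    return out


def emission_loglik(
    model: HmmModel, state: str, lrr: float, baf: float, pfb: float
) -> float:
    """Scalar emission log-likelihood for one marker in one state."""
    s = STATES.index(state)
    return float(
        emission_matrix(model, np.array([lrr]), np.array([baf]), np.array([pfb]))[0, s]
    )


def initial_distribution(model: HmmModel) -> np.ndarray:
    """Stationary-style start distribution strongly favoring CN2."""
    pi = np.asarray(model.base_weight, float)
    pi = pi / pi.sum()
    # sharpen toward the diploid state: genomes start diploid
    pi = 0.01 * pi
    pi[_CN2_IDX] += 0.99
    return pi / pi.sum()


def viterbi_decode(
    model: HmmModel,
    lrr: np.ndarray,
    baf: np.ndarray,
    pfb: np.ndarray,
    positions: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Most probable state path over one chromosome (log-domain Viterbi).

    Ties break toward the lower state index.  Returns (path indices into
    STATES, joint log-probability of the path).
    """
    n = len(positions)
    if n == 0:
        return np.empty(0, dtype=np.int64), 0.0
    E = emission_matrix(model, lrr, baf, pfb)
    k = len(STATES)
    with np.errstate(divide="ignore"):
        delta = np.log(initial_distribution(model)) + E[0]
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        d = float(positions[t] - positions[t - 1])
        with np.errstate(divide="ignore"):
            logT = np.log(transition_matrix(model, d))
        scores = delta[:, None] + logT  # (from, to)
        back[t] = np.argmax(scores, axis=0)  # first max -> lowest index on ties
        delta = scores[back[t], np.arange(k)] + E[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    best = float(delta[path[-1]])
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, best


@dataclass(frozen=True)
class CnvCall:
    """One per-sample called segment with copy number != 2."""

    sample: str
    chrom: str
    start: int  # 0-based half-open, first marker position
    end: int  # 0-based half-open, one past last marker position
    copy_number: int
    state: str
    num_snps: int
    confidence: float  # summed log-likelihood ratio of state vs CN2

    def __post_init__(self) -> None:
        if self.copy_number == 2:
            raise ValueError("CNV calls must have copy number != 2")
        if self.num_snps < 1 or self.end <= self.start:
            raise ValueError("malformed CNV call")

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.start,
            self.end,
            f"{self.sample}:{self.state}",
            {"copy_number": str(self.copy_number), "sample": self.sample},
        )


def call_cnvs(
    model: HmmModel,
    sample: str,
    lrr: np.ndarray,
    baf: np.ndarray,
    marker_map: MarkerMap,
    pfb: np.ndarray | None = None,
) -> list[CnvCall]:
    """Viterbi-decode one sample genome-wide and extract CNV calls.

    Maximal runs of a non-diploid state become calls; runs shorter than
    ``model.min_snps`` markers are dropped, and copy-neutral LOH runs are
    never reported as CNVs.  Call confidence is the summed per-marker
    log-likelihood advantage of the called state over CN2, which is
    positive whenever the segment genuinely prefers the called state.
    """
    if pfb is None:
        pfb = marker_map.pfb
    calls: list[CnvCall] = []
    for chrom in marker_map.chrom_names():
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.positions[sl]
        if pos.size == 0:
            continue
        l, b, p = lrr[sl], baf[sl], pfb[sl]
        path, _ = viterbi_decode(model, l, b, p, pos)
        E = emission_matrix(model, l, b, p)
        i = 0
        n = len(path)
        while i < n:
            s = path[i]
            j = i
            while j + 1 < n and path[j + 1] == s:
                j += 1
            state = STATES[s]
            cn = STATE_COPY_NUMBER[state]
            run_len = j - i + 1
            if cn != 2 and run_len >= model.min_snps:
                conf = float((E[i : j + 1, s] - E[i : j + 1, _CN2_IDX]).sum())
                calls.append(
                    CnvCall(
                        sample=sample,
                        chrom=chrom,
                        start=int(pos[i]) - 1,  # marker positions are 1-based
                        end=int(pos[j]),
                        copy_number=cn,
                        state=state,
                        num_snps=run_len,
                        confidence=conf,
                    )
                )
            i = j + 1
    return calls


def calls_to_penncnv_lines(calls: Sequence[CnvCall]) -> list[str]:
    """Render calls in the classic one-line-per-CNV text layout (1-based)."""
    lines = []
    for c in calls:
        lines.append(
            f"{c.chrom}:{c.start + 1}-{c.end}\tnumsnp={c.num_snps}\t"
            f"length={c.length}\tstate={c.state},cn={c.copy_number}\t"
            f"{c.sample}\tconf={c.confidence:.3f}"
        )
    return lines
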