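"""Cross-study concordance, QTL overlap, gene content and term enrichment.

All overlap predicates default to >= 1 bp on half-open intervals, the
same convention the CNVR builder and depth validator use; reciprocal
fraction thresholds are optional parameters, never defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .cnvr_builder import Cnvr
from .signal_io import GenomicInterval
from ._util import round_half_up

__all__ = [
    "ConcordanceRecord",
    "EnrichmentResult",
    "concordance",
    "qtl_overlap",
    "annotate_genes",
    "term_enrichment",
]


@dataclass(frozen=True)
class ConcordanceRecord:
    """One row of a cross-study CNVR comparison table."""

    study_label: str
    n_overlapping: int
    concordant_length: int  # bp of query covered by the reference set
    pct_count: float
    pct_length: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric term-enrichment record with Bonferroni correction."""

    term: str
    k: int  # selected genes carrying the term
    K: int  # background genes carrying the term
    n: int  # selection size
    N: int  # background size
    p_raw: float
    p_bonferroni: float
    associated_gene_pct: float


def _reference_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _covered_length(tree: IntervalTree, start: int, end: int) -> int:
    """Length of [start, end) covered by the union of tree intervals."""
    hits = sorted(
        (max(start, h.begin), min(end, h.end)) for h in tree.overlap(start, end)
    )
    covered = 0
    cur_end = start
    for a, b in hits:
        if b <= cur_end:
            continue
        covered += b - max(a, cur_end)
        cur_end = b
    return covered


def concordance(
    query_cnvrs: Sequence[Cnvr],
    reference: Sequence[GenomicInterval],
    study_label: str,
) -> ConcordanceRecord:
    """Count- and length-level concordance of a CNVR set with a reference.

    ``n_overlapping`` counts query CNVRs with any (>= 1 bp) overlap;
    ``concordant_length`` sums, per query CNVR, the length of its merged
    intersection with the reference set.  Percentages are over the query
    count and query total length, rounded half-up to two decimals.
    """
    if not query_cnvrs:
        raise ValueError("empty query CNVR set")
    trees = _reference_trees(reference)
    n_overlap = 0
    concordant = 0
    total_len = 0
    for r in query_cnvrs:
        total_len += r.length
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        cov = _covered_length(tree, r.start, r.end)
        if cov > 0:
            n_overlap += 1
            concordant += cov
    return ConcordanceRecord(
        study_label,
        n_overlap,
        concordant,
        round_half_up(100.0 * n_overlap / len(query_cnvrs), 2),
        round_half_up(100.0 * concordant / total_len, 2),
    )


def qtl_overlap(
    cnvrs: Sequence[Cnvr], qtls: Sequence[GenomicInterval]
) -> tuple[int, int, int, dict[str, list[GenomicInterval]]]:
    """CNVR-QTL overlap counts: (overlapping CNVRs, distinct QTLs, distinct
    traits, per-CNVR QTL lists).

    A QTL's identity is its label; its trait is the ``trait`` attribute
    (falling back to the label when absent).
    """
    trees = _reference_trees(qtls)
    per_cnvr: dict[str, list[GenomicInterval]] = {}
    hit_qtls: set[str] = set()
    hit_traits: set[str] = set()
    n_overlapping = 0
    for r in cnvrs:
        tree = trees.get(r.chrom)
        hits = (
            sorted((h.data for h in tree.overlap(r.start, r.end)),
                   key=lambda iv: (iv.start, iv.end))
            if tree
            else []
        )
        per_cnvr[r.id] = hits
        if hits:
            n_overlapping += 1
            for q in hits:
                hit_qtls.add(q.label)
                hit_traits.add(q.attributes.get("trait", q.label))
    return n_overlapping, len(hit_qtls), len(hit_traits), per_cnvr


def annotate_genes(
    cnvrs: Sequence[Cnvr], genes: Sequence[GenomicInterval]
) -> tuple[dict[str, list[GenomicInterval]], dict[str, int]]:
    """Genes partially or entirely overlapping each CNVR, plus a histogram.

    The histogram buckets CNVRs by gene content: none, exactly one, two
    or more — the shape used to describe whether CNVs sit in gene-poor
    regions.
    """
    trees = _reference_trees(genes)
    per_cnvr: dict[str, list[GenomicInterval]] = {}
    hist = {"0": 0, "1": 0, "2+": 0}
    for r in cnvrs:
        tree = trees.get(r.chrom)
        hits = (
            sorted((h.data for h in tree.overlap(r.start, r.end)),
                   key=lambda iv: (iv.start, iv.end))
            if tree
            else []
        )
        per_cnvr[r.id] = hits
        hist["0" if not hits else "1" if len(hits) == 1 else "2+"] += 1
    return per_cnvr, hist


def term_enrichment(
    selected_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of terms in a gene selection.

    For each term with at least one selected gene, the upper-tail
    probability of drawing >= k annotated genes in a selection of n from
    a background of N containing K annotated genes; Bonferroni-corrected
    over the number of tested terms.  ``associated_gene_pct`` is
    100*k/K, the share of the term's background genes that were hit.
    Results are sorted by corrected p-value.
    """
    selected = set(selected_genes)
    background = set(background_genes)
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    term_background: dict[str, set[str]] = {}
    skipped_terms = 0
    for gene, terms in annotation.items():
        if gene not in background:
            continue
        for t in terms:
            term_background.setdefault(t, set()).add(gene)
    N, n = len(background), len(selected)
    tested = []
    for term, genes_with_term in term_background.items():
        k = len(genes_with_term & selected)
        if k < 1:
            continue
        K = len(genes_with_term)
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((term, k, K, p))
    m = len(tested)
    results = [
        EnrichmentResult(
            term,
            k,
            K,
            n,
            N,
            p,
            min(1.0, p * m),
            round_half_up(100.0 * k / K, 2),
        )
        for term, k, K, p in tested
    ]
    results.sort(key=lambda r: (r.p_bonferroni, r.p_raw, r.term))
    return results
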