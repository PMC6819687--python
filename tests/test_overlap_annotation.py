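from math import comb

import numpy as np
import pytest

from arraycnv.cnvr_builder import build_cnvrs
from arraycnv.overlap_annotation import (
    annotate_genes,
    concordance,
    qtl_overlap,
    term_enrichment,
)
from arraycnv.signal_io import GenomicInterval
from conftest import make_call


def _cnvr_set(spans, chrom="chr1"):
    """CNVRs with exact (untrimmed) boundaries, for overlap arithmetic."""
    from arraycnv.cnvr_builder import Cnvr

    out = []
    for i, (s, e) in enumerate(spans):
        calls = (make_call(s, e, "A", cn=3, chrom=chrom),
                 make_call(s, e, "B", cn=3, chrom=chrom))
        out.append(Cnvr(f"CNVR{i + 1}", chrom, s, e, s, e, "gain", 2, calls))
    return out


def hypergeom_oracle(k, N, K, n):
    """Upper-tail P(X >= k) by direct combinatorial summation."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


class TestConcordance:
    def test_single_intersection(self):
        cnvrs = _cnvr_set([(100, 200)])
        ref = [GenomicInterval("chr1", 150, 250)]
        rec = concordance(cnvrs, ref, "ref")
        assert rec.n_overlapping == 1 and rec.concordant_length == 50

    def test_full_coverage_is_100_pct_length(self):
        cnvrs = _cnvr_set([(100, 200), (1000, 1200)])
        ref = [GenomicInterval("chr1", 0, 10_000)]
        rec = concordance(cnvrs, ref, "ref")
        assert rec.pct_length == 100.0 and rec.pct_count == 100.0

    def test_overlapping_reference_intervals_not_double_counted(self):
        cnvrs = _cnvr_set([(100, 200)])
        ref = [
            GenomicInterval("chr1", 100, 180),
            GenomicInterval("chr1", 150, 220),
        ]
        rec = concordance(cnvrs, ref, "ref")
        assert rec.concordant_length == 100

    def test_monotone_in_reference(self):
        rng = np.random.default_rng(41)
        cnvrs = _cnvr_set([(i * 10_000, i * 10_000 + 5_000) for i in range(10)])
        refs = [
            GenomicInterval("chr1", int(s), int(s) + 2_000)
            for s in rng.integers(0, 100_000, 20)
        ]
        prev_n, prev_len = 0, 0
        for cut in range(0, 21, 5):
            rec = concordance(cnvrs, refs[:cut], "ref") if cut else None
            if rec is None:
                continue
            assert rec.n_overlapping >= prev_n
            assert rec.concordant_length >= prev_len
            prev_n, prev_len = rec.n_overlapping, rec.concordant_length

    def test_published_table_arithmetic(self):
        # 61 of 166 CNVRs overlapping, 1.48 Mb concordant of 15.55 Mb total
        # -> 36.75% count concordance and 9.52% length concordance
        spans = []
        for i in range(166):
            start = i * 1_000_000
            length = 122_500 if i == 0 else 93_500  # total 15.55 Mb
            spans.append((start, start + length))
        cnvrs = _cnvr_set(spans)
        ref = []
        for i in range(61):
            start = cnvrs[i].start
            cov = 40_000 if i == 0 else 24_000  # total 1.48 Mb
            ref.append(GenomicInterval("chr1", start, start + cov))
        rec = concordance(cnvrs, ref, "study")
        assert sum(r.length for r in cnvrs) == 15_550_000
        assert rec.n_overlapping == 61 and rec.concordant_length == 1_480_000
        assert rec.pct_count == 36.75
        assert rec.pct_length == 9.52

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            concordance([], [], "ref")

    def test_sweep_matches_base_set_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            spans = sorted(
                {(int(s), int(s) + int(l)) for s, l in zip(
                    rng.integers(0, 80_000, 5), rng.integers(1_000, 10_000, 5))}
            )
            spans = [
                (s, e) for i, (s, e) in enumerate(spans)
                if all(e2 <= s for _, e2 in spans[:i])
            ]
            if not spans:
                continue
            cnvrs = _cnvr_set(spans)
            refs = [
                GenomicInterval("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 90_000, 8), rng.integers(1, 8_000, 8))
            ]
            rec = concordance(cnvrs, refs, "x")
            ref_bases = set()
            for r in refs:
                ref_bases.update(range(r.start, r.end))
            want = sum(
                len(set(range(r.start, r.end)) & ref_bases) for r in cnvrs
            )
            assert rec.concordant_length == want


class TestQtlOverlap:
    def test_distinct_counting(self):
        cnvrs = _cnvr_set([(1000, 2000)])
        qtls = [
            GenomicInterval("chr1", 0, 5_000, "QTL1", {"trait": "growth"}),
            GenomicInterval("chr1", 500, 1_500, "QTL2", {"trait": "growth"}),
            GenomicInterval("chr1", 1_900, 3_000, "QTL3", {"trait": "litter size"}),
        ]
        n_cnvr, n_qtl, n_traits, per = qtl_overlap(cnvrs, qtls)
        assert (n_cnvr, n_qtl, n_traits) == (1, 3, 2)
        assert len(per[cnvrs[0].id]) == 3

    def test_no_qtls_zeros(self):
        cnvrs = _cnvr_set([(1000, 2000)])
        assert qtl_overlap(cnvrs, [])[:3] == (0, 0, 0)


class TestAnnotateGenes:
    def test_partial_overlap_assigns_and_histogram(self):
        cnvrs = _cnvr_set([(150, 300), (10_000, 11_000), (50_000, 51_000)])
        genes = [
            GenomicInterval("chr1", 100, 200, "G1"),
            GenomicInterval("chr1", 10_100, 10_200, "G2"),
            GenomicInterval("chr1", 10_400, 10_500, "G3"),
        ]
        per, hist = annotate_genes(cnvrs, genes)
        assert [g.label for g in per[cnvrs[0].id]] == ["G1"]
        assert hist == {"0": 1, "1": 1, "2+": 1}


class TestTermEnrichment:
    def test_matches_combinatorial_oracle(self):
        N, n, K, k = 100, 10, 10, 5
        background = [f"g{i}" for i in range(N)]
        selected = background[:n]
        annotation = {g: ["T1"] for g in background[: k]}  # 5 selected with term
        annotation.update({g: ["T1"] for g in background[n : n + K - k]})
        results = term_enrichment(selected, annotation, background)
        (r,) = results
        assert (r.k, r.K, r.n, r.N) == (k, K, n, N)
        assert r.p_raw == pytest.approx(hypergeom_oracle(k, N, K, n), rel=1e-9)

    def test_certain_event_p_one(self):
        background = ["g1", "g2"]
        results = term_enrichment(
            background, {"g1": ["T"], "g2": ["T"]}, background
        )
        assert results[0].p_raw == pytest.approx(1.0)

    def test_bonferroni_scales_with_tested_terms(self):
        background = [f"g{i}" for i in range(50)]
        selected = background[:5]
        ann1 = {g: ["T1"] for g in background[:10]}
        res1 = term_enrichment(selected, ann1, background)
        ann2 = dict(ann1)
        for g in background[:5]:
            ann2[g] = ann2[g] + ["T2"]
        res2 = term_enrichment(selected, ann2, background)
        t1_before = next(r for r in res1 if r.term == "T1")
        t1_after = next(r for r in res2 if r.term == "T1")
        assert t1_after.p_raw == pytest.approx(t1_before.p_raw)
        assert t1_after.p_bonferroni == pytest.approx(
            min(1.0, t1_before.p_raw * 2)
        )

    def test_selection_outside_background_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(["x"], {}, ["y"])

    def test_associated_gene_pct_uses_term_background(self):
        background = [f"g{i}" for i in range(20)]
        ann = {g: ["T"] for g in background[:10]}
        res = term_enrichment(background[:2], ann, background)
        assert res[0].associated_gene_pct == pytest.approx(100.0 * res[0].k / 10)
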