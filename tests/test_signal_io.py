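import io

import numpy as np
import pytest

from arraycnv import signal_io
from arraycnv.signal_io import GenomicInterval, MarkerMap, SignalMatrix


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestMarkerMap:
    def test_read_sorted_identity(self, tmp_path):
        p = _write(
            tmp_path,
            "m.txt",
            "Name\tChr\tPosition\nr1\tchr1\t100\nr2\tchr1\t200\nr3\tchr1\t300\n",
        )
        mm = signal_io.read_marker_map(p)
        assert mm.names == ["r1", "r2", "r3"]
        assert list(mm.positions) == [100, 200, 300]
        assert np.allclose(mm.pfb, 0.5)  # PFB column absent -> 0.5

    def test_rows_resorted_by_position(self, tmp_path):
        p = _write(
            tmp_path, "m.txt", "Name\tChr\tPosition\nr2\tchr1\t300\nr1\tchr1\t100\n"
        )
        mm = signal_io.read_marker_map(p)
        assert list(mm.positions) == [100, 300]
        assert mm.names == ["r1", "r2"]

    def test_duplicate_name_rejected_with_name(self, tmp_path):
        p = _write(
            tmp_path, "m.txt", "Name\tChr\tPosition\nr1\tchr1\t100\nr1\tchr1\t200\n"
        )
        with pytest.raises(ValueError, match="r1"):
            signal_io.read_marker_map(p)

    def test_non_numeric_position_rejected_with_line(self, tmp_path):
        p = _write(
            tmp_path, "m.txt", "Name\tChr\tPosition\nr1\tchr1\t100\nr2\tchr1\tabc\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            signal_io.read_marker_map(p)

    def test_roundtrip_to_6_decimals(self, tmp_path):
        rng = np.random.default_rng(0)
        mm = MarkerMap(
            [f"r{i}" for i in range(50)],
            ["chr1"] * 25 + ["chr2"] * 25,
            list(range(100, 2600, 100)) + list(range(100, 2600, 100)),
            rng.uniform(0.01, 0.99, 50),
        )
        p = tmp_path / "map.pfb"
        signal_io.write_marker_map(mm, p)
        back = signal_io.read_marker_map(p)
        assert back.names == mm.names
        assert np.allclose(back.pfb, mm.pfb, atol=5e-7)


class TestSignalFile:
    @pytest.fixture
    def mm(self):
        return MarkerMap(["r1", "r2", "r3"], ["chr1"] * 3, [100, 200, 300])

    def test_shuffled_rows_align_to_map_order(self, tmp_path, mm):
        p = _write(
            tmp_path,
            "s.txt",
            "Name\tS1.Log R Ratio\tS1.B Allele Freq\n"
            "r3\t0.3\t0.9\nr1\t0.1\t0.1\nr2\t0.2\t0.5\n",
        )
        lrr, baf, clamped = signal_io.read_signal_file(p, "S1", mm)
        assert np.allclose(lrr, [0.1, 0.2, 0.3])
        assert np.allclose(baf, [0.1, 0.5, 0.9])
        assert clamped == 0

    def test_out_of_range_baf_clamped_and_counted(self, tmp_path, mm):
        p = _write(
            tmp_path,
            "s.txt",
            "Name\tS1.Log R Ratio\tS1.B Allele Freq\nr1\t0.0\t1.2\nr2\t0.0\t0.5\n",
        )
        lrr, baf, clamped = signal_io.read_signal_file(p, "S1", mm)
        assert baf[0] == 1.0 and clamped == 1

    def test_absent_marker_is_missing(self, tmp_path, mm):
        p = _write(
            tmp_path,
            "s.txt",
            "Name\tS1.Log R Ratio\tS1.B Allele Freq\nr1\t0.0\t0.5\n",
        )
        lrr, baf, _ = signal_io.read_signal_file(p, "S1", mm)
        assert np.isnan(lrr[1]) and np.isnan(baf[2])

    def test_roundtrip_to_6_decimals(self, tmp_path, mm):
        rng = np.random.default_rng(1)
        lrr = rng.normal(0, 0.3, 3)
        baf = rng.uniform(0, 1, 3)
        p = tmp_path / "sig.txt"
        signal_io.write_signal_file(p, "S1", mm, lrr, baf)
        lrr2, baf2, _ = signal_io.read_signal_file(p, "S1", mm)
        assert np.allclose(lrr, lrr2, atol=5e-7)
        assert np.allclose(baf, baf2, atol=5e-7)


class TestComputePfb:
    def _matrix(self, baf_rows):
        n = len(baf_rows[0])
        mm = MarkerMap(
            [f"r{i}" for i in range(n)], ["chr1"] * n, list(range(100, 100 * (n + 1), 100))
        )
        baf = np.asarray(baf_rows, float)
        lrr = np.zeros_like(baf)
        return SignalMatrix(mm, [f"S{i}" for i in range(len(baf_rows))], lrr, baf)

    def test_mean_of_constant_half(self):
        sm = self._matrix([[0.5], [0.5], [0.5]])
        assert signal_io.compute_pfb(sm, sm.samples)[0] == 0.5

    def test_clamped_at_low_bound(self):
        sm = self._matrix([[0.0], [0.0]])
        assert signal_io.compute_pfb(sm, sm.samples)[0] == 0.01

    def test_symmetric_values_average_to_half(self):
        sm = self._matrix([[0.0], [0.5], [1.0]])
        assert signal_io.compute_pfb(sm, sm.samples)[0] == pytest.approx(0.5)

    def test_all_missing_marker_defaults_half(self):
        sm = self._matrix([[np.nan], [np.nan]])
        assert signal_io.compute_pfb(sm, sm.samples)[0] == 0.5

    def test_empty_sample_set_rejected(self):
        sm = self._matrix([[0.5]])
        with pytest.raises(ValueError):
            signal_io.compute_pfb(sm, [])

    def test_output_always_within_clamp_bounds(self):
        rng = np.random.default_rng(3)
        sm = self._matrix(rng.uniform(0, 1, (5, 20)).tolist())
        pfb = signal_io.compute_pfb(sm, sm.samples)
        assert np.all((pfb >= 0.01) & (pfb <= 0.99))


class TestBedIntervals:
    def test_bed_row_half_open(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr1\t99\t200\tq1\n")
        (iv,) = signal_io.read_bed_intervals(p)
        assert (iv.chrom, iv.start, iv.end, iv.label) == ("chr1", 99, 200, "q1")

    def test_one_based_dialect_converts(self, tmp_path):
        p = _write(tmp_path, "a.txt", "chr1\t100\t200\n")
        (iv,) = signal_io.read_bed_intervals(p, one_based=True)
        assert (iv.start, iv.end) == (99, 200)
        assert iv.attributes["dialect"] == "1-based"

    def test_inverted_row_rejected(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr1\t200\t100\n")
        with pytest.raises(ValueError, match="line 1"):
            signal_io.read_bed_intervals(p)

    def test_rows_returned_sorted(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr2\t5\t10\nchr1\t50\t60\nchr1\t5\t10\n")
        ivs = signal_io.read_bed_intervals(p)
        assert [(iv.chrom, iv.start) for iv in ivs] == [
            ("chr1", 5),
            ("chr1", 50),
            ("chr2", 5),
        ]


GFF = """##gff-version 3
chr1\tens\tgene\t101\t200\t.\t+\t.\tID=gene:G1;biotype=protein_coding
chr1\tens\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=gene:G1
chr1\tens\texon\t101\t150\t.\t+\t.\tParent=t1
chr2\tens\tgene\t501\t900\t.\t-\t.\tID=gene:G2;biotype=snRNA
"""


class TestGff3Genes:
    def test_gene_features_extracted_and_converted(self, tmp_path):
        p = _write(tmp_path, "g.gff3", GFF)
        genes, skipped = signal_io.read_gff3_genes(p)
        assert [g.label for g in genes] == ["G1", "G2"]
        g1 = genes[0]
        assert (g1.start, g1.end) == (100, 200)  # 1-based inclusive -> half-open
        assert genes[1].attributes["biotype"] == "snRNA"
        assert skipped == 0

    def test_non_gene_features_excluded(self, tmp_path):
        p = _write(tmp_path, "g.gff3", GFF)
        genes, _ = signal_io.read_gff3_genes(p)
        assert len(genes) == 2


def test_interval_invariant_start_before_end():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
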