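"""Promoter annotation: manifest/GTF ingestion, windows, joins, islands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdriver.annotation import (
    CpGIsland,
    ManifestFormatError,
    ProbeRecord,
    PromoterWindow,
    TranscriptRecord,
    find_cpg_islands,
    join_probes_to_promoters,
    promoter_windows,
    read_gtf_lnc,
    read_manifest,
    read_pairs_tsv,
    read_windows_bed,
    windows_to_bed,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestManifest:
    def test_well_formed_rows_ingested_in_order(self, tmp_path):
        p = _write(
            tmp_path, "m.tsv",
            "probe_id\tchrom\tpos\tstrand\n"
            "cg000001\tchr1\t100\t+\ncg000002\tchr1\t200\t-\ncg000003\tchr2\t50\t+\n",
        )
        recs = read_manifest(p)
        assert [r.probe_id for r in recs] == ["cg000001", "cg000002", "cg000003"]
        assert recs[1] == ProbeRecord("cg000002", "chr1", 200, "-")

    def test_duplicate_probe_id_raises_naming_the_probe(self, tmp_path):
        p = _write(
            tmp_path, "m.tsv",
            "probe_id\tchrom\tpos\tstrand\ncg000001\tchr1\t1\t+\ncg000001\tchr1\t2\t+\n",
        )
        with pytest.raises(ManifestFormatError, match="cg000001"):
            read_manifest(p)

    def test_header_only_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "m.tsv", "probe_id\tchrom\tpos\tstrand\n")
        assert read_manifest(p) == []

    def test_missing_column_and_bad_pos(self, tmp_path):
        p = _write(tmp_path, "m.tsv", "probe_id\tchrom\tstrand\ncg1\tchr1\t+\n")
        with pytest.raises(ManifestFormatError, match="pos"):
            read_manifest(p)
        p2 = _write(
            tmp_path, "m2.tsv",
            "probe_id\tchrom\tpos\tstrand\ncg1\tchr1\tabc\t+\n",
        )
        with pytest.raises(ManifestFormatError, match="row 2"):
            read_manifest(p2)


class TestGtf:
    GTF = (
        'chr1\tx\ttranscript\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
        'gene_type "lincRNA";\n'
        'chr1\tx\texon\t100\t150\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
        'gene_type "lincRNA";\n'
        'chr1\tx\ttranscript\t300\t400\t.\t-\t.\tgene_id "g1"; transcript_id "t2"; '
        'gene_type "lincRNA";\n'
    )

    def test_coordinates_converted_to_half_open(self, tmp_path):
        p = _write(tmp_path, "a.gtf", self.GTF)
        recs = read_gtf_lnc(p, {"lincRNA"})
        assert recs[0].start == 99 and recs[0].end == 200

    def test_biotype_filter(self, tmp_path):
        p = _write(tmp_path, "a.gtf", self.GTF)
        assert read_gtf_lnc(p, {"antisense"}) == []

    def test_two_transcripts_share_gene_id(self, tmp_path):
        p = _write(tmp_path, "a.gtf", self.GTF)
        recs = read_gtf_lnc(p, {"lincRNA"})
        assert len(recs) == 2
        assert {r.gene_id for r in recs} == {"g1"}

    def test_bad_strand_raises(self, tmp_path):
        p = _write(
            tmp_path, "b.gtf",
            'chr1\tx\ttranscript\t1\t10\t.\t*\t.\tgene_id "g"; transcript_id "t"; '
            'gene_type "lincRNA";\n',
        )
        with pytest.raises(ValueError, match="strand"):
            read_gtf_lnc(p, {"lincRNA"})


def _tx(start, end, strand, gene="g", chrom="chr1"):
    return TranscriptRecord(gene, f"{gene}.t", gene, "lincRNA", chrom, start, end, strand)


class TestPromoterWindows:
    def test_plus_strand_geometry(self):
        w = promoter_windows([_tx(5000, 9000, "+")])[0]
        assert (w.start, w.end, w.tss) == (2500, 6000, 5000)

    def test_clipping_at_origin(self):
        w = promoter_windows([_tx(100, 900, "+")])[0]
        assert (w.start, w.end) == (0, 1100)

    def test_minus_strand_geometry_by_offset_enumeration(self):
        # oracle: genomic positions whose strand-relative offset lies in
        # [-2500, +1000) for a minus-strand TSS at 8999
        tss = 8999
        positions = [p for p in range(6000, 13000) if -2500 <= tss - p < 1000]
        w = promoter_windows([_tx(5000, 9000, "-")])[0]
        assert (w.start, w.end) == (min(positions), max(positions) + 1)
        assert (w.start, w.end, w.tss) == (8000, 11500, tss)

    @given(
        start=st.integers(3000, 50_000),
        length=st.integers(1, 20_000),
        strand=st.sampled_from("+-"),
    )
    @settings(max_examples=100, deadline=None)
    def test_unclipped_length_and_tss_containment(self, start, length, strand):
        w = promoter_windows([_tx(start, start + length, strand)])[0]
        if w.start > 0:
            assert w.end - w.start == 3500
        assert w.start <= w.tss < w.end

    def test_strand_flip_symmetry(self):
        """Reverse-complementing the coordinate system maps windows exactly."""
        L = 100_000
        for start, end in [(5000, 9000), (40_000, 41_234)]:
            w_plus = promoter_windows([_tx(start, end, "+")])[0]
            w_flip = promoter_windows([_tx(L - end, L - start, "-")])[0]
            assert (w_flip.start, w_flip.end) == (L - w_plus.end, L - w_plus.start)


class TestJoin:
    def _window(self, gene, start, end, chrom="chr1"):
        return PromoterWindow(gene, chrom, start, end, "+", start)

    def test_half_open_boundaries(self):
        w = self._window("g1", 2500, 6000)
        inside = ProbeRecord("cgA", "chr1", 2500, "+")
        outside = ProbeRecord("cgB", "chr1", 6000, "+")
        assert join_probes_to_promoters([inside], [w]) == [("cgA", "g1")]
        assert join_probes_to_promoters([outside], [w]) == []

    def test_chromosome_mismatch_yields_nothing(self):
        w = self._window("g1", 0, 1000, chrom="chr2")
        p = ProbeRecord("cgA", "chr1", 10, "+")
        assert join_probes_to_promoters([p], [w]) == []

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(20):
            probes = [
                ProbeRecord(f"cg{i:03d}", f"chr{rng.integers(1, 3)}",
                            int(rng.integers(0, 5000)), "+")
                for i in range(50)
            ]
            windows = []
            for j in range(5):
                s = int(rng.integers(0, 4500))
                windows.append(
                    PromoterWindow(f"g{j}", f"chr{rng.integers(1, 3)}",
                                   s, s + int(rng.integers(1, 800)), "+", s)
                )
            expected = sorted(
                {
                    (p.probe_id, w.gene_id)
                    for p in probes
                    for w in windows
                    if p.chrom == w.chrom and w.start <= p.pos < w.end
                },
                key=lambda pg: (pg[1], pg[0]),
            )
            assert join_probes_to_promoters(probes, windows) == expected

    def test_bed_round_trip(self, tmp_path):
        windows = promoter_windows([_tx(5000, 9000, "+"), _tx(7000, 8000, "-", "g2")])
        path = tmp_path / "w.bed"
        windows_to_bed(windows, path)
        assert read_windows_bed(path) == windows


class TestCpGIslands:
    def test_at_only_sequence_has_no_island(self):
        assert find_cpg_islands("AT" * 200) == []

    def test_pure_cpg_island_statistics(self):
        isl = find_cpg_islands("CG" * 150)
        assert isl == [CpGIsland(0, 300, 1.0, 2.0)]

    def test_two_separated_islands(self):
        seq = "CG" * 150 + "AT" * 500 + "CG" * 150
        islands = find_cpg_islands(seq)
        assert len(islands) == 2
        assert islands[0].start == 0 and islands[1].end == len(seq)

    def test_short_sequence_empty(self):
        assert find_cpg_islands("CG" * 50) == []

    def test_islands_disjoint_sorted_and_above_thresholds(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, 3000, p=[0.15, 0.35, 0.35, 0.15]))
        islands = find_cpg_islands(seq)
        for a, b in zip(islands, islands[1:]):
            assert a.end < b.start  # disjoint and sorted
        for isl in islands:
            assert isl.end - isl.start >= 200
            assert isl.gc_fraction >= 0.5
            assert isl.obs_exp_cpg >= 0.6

    def test_matches_brute_force_window_scan(self):
        seq = "CG" * 150 + "AT" * 500 + "CG" * 150
        win = 200
        passing = []
        for s in range(len(seq) - win + 1):
            w = seq[s : s + win]
            c, g = w.count("C"), w.count("G")
            cg = sum(1 for i in range(win - 1) if w[i : i + 2] == "CG")
            if (c + g) / win >= 0.5 and c and g and cg * win / (c * g) >= 0.6:
                passing.append(s)
        merged = []
        for s in passing:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = s + win
            else:
                merged.append([s, s + win])
        got = [(i.start, i.end) for i in find_cpg_islands(seq)]
        assert got == [tuple(m) for m in merged]
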