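"""Gene territories, peak clustering, direct-target calls, BED round-trips."""

from itertools import combinations

import pytest

from cardiodiv.triage import (
    GeneModel,
    GenomicInterval,
    PeakRecord,
    classify_direct_target,
    clustered,
    gene_territory,
    read_peaks_bed,
    write_peaks_bed,
)


def iv(start, end, chrom="chr2L"):
    return GenomicInterval(chrom, start, end)


@pytest.fixture
def gene_two_exons():
    return GeneModel("g", span=iv(1000, 1300), exons=(iv(1000, 1100), iv(1200, 1300)))


@pytest.fixture
def neighbors():
    return GeneModel("up", span=iv(0, 500)), GeneModel("down", span=iv(2000, 2500))


class TestTerritory:
    def test_single_exon_gene_flanks_only(self, neighbors):
        up, down = neighbors
        gene = GeneModel("g", span=iv(1000, 1300), exons=(iv(1000, 1300),))
        territory = gene_territory(gene, up, down)
        assert territory == [iv(500, 1000), iv(1300, 2000)]

    def test_intron_included(self, gene_two_exons, neighbors):
        up, down = neighbors
        territory = gene_territory(gene_two_exons, up, down)
        assert iv(1100, 1200) in territory

    def test_abutting_neighbor_contributes_nothing(self, gene_two_exons):
        up = GeneModel("up", span=iv(0, 1000))  # ends exactly at the gene start
        territory = gene_territory(gene_two_exons, up, None)
        assert territory == [iv(1100, 1200)]

    def test_overlapping_neighbor_rejected(self, gene_two_exons):
        bad = GeneModel("up", span=iv(0, 1100))
        with pytest.raises(ValueError):
            gene_territory(gene_two_exons, upstream_neighbor=bad)

    def test_territory_avoids_exons_and_neighbors(self, gene_two_exons, neighbors):
        up, down = neighbors
        territory = gene_territory(gene_two_exons, up, down)
        for t in territory:
            for other in (*gene_two_exons.exons, up.span, down.span):
                assert not t.overlaps(other)

    def test_no_exon_structure_falls_back_to_gene_body(self):
        gene = GeneModel("g", span=iv(100, 200))
        with pytest.warns(UserWarning):
            territory = gene_territory(gene)
        assert territory == [iv(100, 200)]


class TestClustering:
    def test_overlap_clusters_at_any_gap(self):
        assert clustered(iv(10, 50), iv(40, 90), max_gap=0)

    def test_gap_threshold(self):
        a, b = iv(0, 100), iv(700, 800)  # 600 bp apart
        assert not clustered(a, b, max_gap=500)
        assert clustered(a, b, max_gap=600)

    def test_symmetry_and_brute_force_oracle(self, rng):
        peaks = [
            iv(int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 5000, 30), rng.integers(50, 400, 30))
        ]
        for a, b in combinations(peaks, 2):
            gap = max(0, max(a.start, b.start) - min(a.end, b.end))  # O(n^2) oracle
            for mg in (0, 100, 1000):
                assert clustered(a, b, mg) == clustered(b, a, mg) == (gap <= mg)


class TestDirectTargetCalls:
    TERRITORY = [iv(500, 1000), iv(1100, 1200), iv(1300, 2000)]

    def test_overlapping_jumu_and_tin_is_direct(self):
        peaks = [
            PeakRecord(iv(1120, 1180), "Jumu"),
            PeakRecord(iv(1150, 1195), "Tin"),
        ]
        call = classify_direct_target(self.TERRITORY, peaks, max_gap=0, gene="g")
        assert call.status == "direct"
        assert call.supporting_tfs == ("Tin",)

    def test_no_jumu_peak_means_indirect(self):
        peaks = [PeakRecord(iv(1120, 1180), "Tin"), PeakRecord(iv(600, 700), "Twi")]
        assert classify_direct_target(self.TERRITORY, peaks, gene="g").status == "no_jumu_peak"

    def test_jumu_only_when_partner_beyond_gap(self):
        peaks = [PeakRecord(iv(600, 650), "Jumu"), PeakRecord(iv(1800, 1900), "Mad")]
        call = classify_direct_target(self.TERRITORY, peaks, max_gap=100, gene="g")
        assert call.status == "jumu_only"
        assert call.best_gap == 1150

    def test_peaks_outside_territory_ignored(self):
        peaks = [PeakRecord(iv(100, 200), "Jumu"), PeakRecord(iv(150, 250), "Tin")]
        assert classify_direct_target(self.TERRITORY, peaks, gene="g").status == "no_jumu_peak"

    def test_partial_overlap_counts_as_inside(self):
        peaks = [PeakRecord(iv(450, 550), "Jumu"), PeakRecord(iv(520, 560), "Hand")]
        assert classify_direct_target(self.TERRITORY, peaks, gene="g").status == "direct"

    def test_input_order_invariance(self, rng):
        peaks = [
            PeakRecord(iv(int(s), int(s) + 60), tf)
            for s, tf in zip(
                rng.integers(400, 1900, 12),
                ["Jumu", "Tin", "Twi", "Mad"] * 3,
            )
        ]
        ref = classify_direct_target(self.TERRITORY, peaks, max_gap=50, gene="g")
        shuffled = [peaks[i] for i in rng.permutation(len(peaks))]
        got = classify_direct_target(self.TERRITORY, shuffled, max_gap=50, gene="g")
        assert got.status == ref.status and got.supporting_tfs == ref.supporting_tfs

    def test_shrinking_gap_never_promotes(self, rng):
        # monotonicity: direct calls can only be lost, never gained, as max_gap shrinks
        rank = {"no_jumu_peak": 0, "jumu_only": 1, "direct": 2}
        for trial in range(20):
            peaks = [
                PeakRecord(iv(int(s), int(s) + 80), tf)
                for s, tf in zip(
                    rng.integers(400, 1900, 8), ["Jumu", "Tin", "Pnt", "Jumu"] * 2
                )
            ]
            statuses = [
                classify_direct_target(self.TERRITORY, peaks, max_gap=g, gene="g").status
                for g in (500, 200, 50, 0)
            ]
            ranks = [rank[s] for s in statuses]
            assert ranks == sorted(ranks, reverse=True)

    def test_empty_territory_rejected(self):
        with pytest.raises(ValueError):
            classify_direct_target([], [], gene="g")


class TestBedIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        peaks = [
            PeakRecord(iv(int(s), int(s) + int(w)), tf)
            for s, w, tf in zip(
                rng.integers(0, 10000, 25),
                rng.integers(100, 500, 25),
                ["Jumu", "Tin", "Twi", "Su(H)", "Hand"] * 5,
            )
        ]
        path = tmp_path / "peaks.bed"
        write_peaks_bed(peaks, path)
        assert read_peaks_bed(path) == peaks
        # a second write of the re-read peaks is byte-identical
        path2 = tmp_path / "peaks2.bed"
        write_peaks_bed(read_peaks_bed(path), path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_per_tf_files_equal_pooled(self, tmp_path):
        pooled = [
            PeakRecord(iv(100, 200), "Jumu"),
            PeakRecord(iv(150, 260), "Tin"),
            PeakRecord(iv(5000, 5100), "Jumu"),
        ]
        territory = [iv(0, 10000)]
        by_tf = {}
        for p in pooled:
            by_tf.setdefault(p.tf, []).append(p)
        reread = []
        for tf, ps in by_tf.items():
            path = tmp_path / f"{tf}.bed"
            write_peaks_bed(ps, path)
            reread.extend(read_peaks_bed(path, tf=tf))
        a = classify_direct_target(territory, pooled, gene="g")
        b = classify_direct_target(territory, reread, gene="g")
        assert (a.status, a.supporting_tfs) == (b.status, b.supporting_tfs)


class TestGeneModelIO:
    def test_bed12_blocks_become_exons(self, tmp_path):
        from cardiodiv.triage import read_gene_models_bed12

        bed = tmp_path / "genes.bed"
        bed.write_text(
            "chr2L\t1000\t1300\tg1\t0\t+\t1000\t1300\t0\t2\t100,100\t0,200\n"
            "chr2L\t2000\t2400\tg2\t0\t-\t2000\t2400\t0\t1\t400\t0\n"
        )
        genes = read_gene_models_bed12(bed)
        assert [(e.start, e.end) for e in genes[0].exons] == [(1000, 1100), (1200, 1300)]
        assert [(i.start, i.end) for i in genes[0].introns()] == [(1100, 1200)]
        assert [(e.start, e.end) for e in genes[1].exons] == [(2000, 2400)]

    def test_gff3_coordinates_converted_to_zero_based(self, tmp_path):
        from cardiodiv.triage import read_gene_models_gff3

        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr2L\t.\tgene\t1001\t1300\t.\t+\t.\tID=g1;Name=g1\n"
            "chr2L\t.\tmRNA\t1001\t1300\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "chr2L\t.\texon\t1001\t1100\t.\t+\t.\tID=g1.e1;Parent=g1.t1\n"
            "chr2L\t.\texon\t1201\t1300\t.\t+\t.\tID=g1.e2;Parent=g1.t1\n"
        )
        (gene,) = read_gene_models_gff3(gff)
        assert gene.span == GenomicInterval("chr2L", 1000, 1300, "+")
        assert [(e.start, e.end) for e in gene.exons] == [(1000, 1100), (1200, 1300)]


class TestIntervalValidation:
    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", 100, 100)

    def test_cross_chromosome_gap_rejected(self):
        with pytest.raises(ValueError):
            iv(0, 10).gap_to(GenomicInterval("chr3R", 0, 10))
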