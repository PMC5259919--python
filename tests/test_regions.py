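"""Region derivation and bin labelling, cross-checked per basepair."""

from __future__ import annotations

import numpy as np
import pytest

from shoremeth.regions import (
    BinIndex,
    GenomicInterval,
    RegionSet,
    assign_bins,
    derive_introns,
    derive_promoters,
    derive_shores_shelves,
    intersect_intervals,
    merge_intervals,
    reflect,
    subtract_intervals,
)

from _oracles import bins_overlapping_mask, per_bp_membership

MB = 1_000_000


def island_set(ivs, size=MB, chrom="chr1"):
    return RegionSet(
        [GenomicInterval(chrom, s, e, label="CpGI") for s, e in ivs], {chrom: size}
    )


def spans(rs: RegionSet, label: str, chrom="chr1"):
    return sorted((iv.start, iv.end) for iv in rs.by_label(label) if iv.chrom == chrom)


class TestShoresShelves:
    def test_single_island_flanks(self):
        out = derive_shores_shelves(island_set([(10_000, 10_500)]), 2000, 2000)
        assert spans(out, "shore") == [(8_000, 10_000), (10_500, 12_500)]
        assert spans(out, "shelf") == [(6_000, 8_000), (12_500, 14_500)]

    def test_close_islands_share_subtracted_shore(self):
        out = derive_shores_shelves(island_set([(10_000, 10_500), (11_000, 11_400)]), 2000, 2000)
        shores = spans(out, "shore")
        assert (10_500, 11_000) in shores
        # islands themselves never appear inside shores
        for s, e in shores:
            assert e <= 10_000 or s >= 10_500
            assert e <= 11_000 or s >= 11_400

    def test_island_at_chromosome_start_clips_left_flank(self):
        out = derive_shores_shelves(island_set([(0, 300)]), 2000, 2000)
        assert spans(out, "shore") == [(300, 2_300)]

    def test_island_exceeding_chromosome_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            island_set([(999_900, 1_000_200)])

    def test_empty_input_gives_empty_output(self):
        out = derive_shores_shelves(island_set([]))
        assert out.intervals == []

    def test_non_island_labels_rejected(self):
        rs = RegionSet([GenomicInterval("chr1", 0, 10, label="shore")], {"chr1": MB})
        with pytest.raises(ValueError, match="CpGI"):
            derive_shores_shelves(rs)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_bp_oracle_and_disjoint(self, seed):
        """Shores/shelves equal brute-force flank-band set arithmetic, all disjoint."""
        rng = np.random.default_rng(seed)
        size = 100_000
        isl = []
        pos = 0
        while pos < size - 3000:
            pos += int(rng.integers(500, 8000))
            ln = int(rng.integers(200, 1500))
            if pos + ln > size:
                break
            isl.append((pos, pos + ln))
            pos += ln
        rs = island_set(isl, size=size)
        out = derive_shores_shelves(rs, 2000, 2000)

        island_bp = per_bp_membership(isl, size)
        shore_band = per_bp_membership(
            [(s - 2000, s) for s, _ in isl] + [(e, e + 2000) for _, e in isl], size
        )
        shelf_band = per_bp_membership(
            [(s - 4000, s - 2000) for s, _ in isl] + [(e + 2000, e + 4000) for _, e in isl],
            size,
        )
        shore_expect = shore_band & ~island_bp
        shelf_expect = shelf_band & ~island_bp & ~shore_expect
        shore_got = per_bp_membership(spans(out, "shore"), size)
        shelf_got = per_bp_membership(spans(out, "shelf"), size)
        assert np.array_equal(shore_got, shore_expect)
        assert np.array_equal(shelf_got, shelf_expect)
        assert not (shore_got & island_bp).any()
        assert not (shelf_got & shore_got).any()
        assert not (shelf_got & island_bp).any()


class TestPromoters:
    def g(self, start, end, strand, gid="G1", size=MB):
        return RegionSet(
            [GenomicInterval("chr1", start, end, strand, "gene", gid)], {"chr1": size}
        )

    def test_plus_strand_upstream_window(self):
        out = derive_promoters(self.g(50_000, 53_000, "+"), 2000)
        assert spans(out, "promoter") == [(48_000, 50_000)]

    def test_minus_strand_mirror(self):
        out = derive_promoters(self.g(47_000, 50_000, "-"), 2000)
        assert spans(out, "promoter") == [(50_000, 52_000)]

    def test_clipped_at_chromosome_start(self):
        out = derive_promoters(self.g(1_500, 4_000, "+"), 2000)
        assert spans(out, "promoter") == [(0, 1_500)]

    def test_missing_strand_names_gene(self):
        with pytest.raises(ValueError, match="G1"):
            derive_promoters(self.g(50_000, 53_000, "."))

    def test_gene_id_propagated(self):
        out = derive_promoters(self.g(50_000, 53_000, "+", gid="MYGENE"))
        assert out.intervals[0].gene_id == "MYGENE"

    def test_involution_under_reflection(self):
        """Reflecting genes, deriving, and reflecting back equals direct derivation."""
        rng = np.random.default_rng(3)
        genes = RegionSet(
            [
                GenomicInterval(
                    "chr1",
                    s := int(rng.integers(5000, MB - 10_000)),
                    s + int(rng.integers(1000, 5000)),
                    "+" if rng.random() < 0.5 else "-",
                    "gene",
                    f"G{i}",
                )
                for i in range(20)
            ],
            {"chr1": MB},
        )
        direct = derive_promoters(genes, 2000)
        mirrored = reflect(derive_promoters(reflect(genes), 2000))
        assert sorted(
            (iv.start, iv.end, iv.gene_id) for iv in direct.intervals
        ) == sorted((iv.start, iv.end, iv.gene_id) for iv in mirrored.intervals)


class TestAssignBins:
    def test_bin_straddling_island_shore_boundary(self):
        rs = island_set([(10_000, 10_500)], size=20_000)
        full = RegionSet(list(rs.intervals), {"chr1": 20_000})
        full.extend(derive_shores_shelves(rs, 2000, 2000))
        bins = BinIndex({"chr1": 20_000}, 100)
        labels = assign_bins(bins, full)
        row = list(bins.overlapping("chr1", 9_950, 10_050))
        assert len(row) == 2  # window spans two grid bins
        assert {"CpGI", "shore"} <= labels[row[0]] | labels[row[1]]
        # the bin [9900,10000) is shore-only, [10000,10100) island-only
        assert "shore" in labels[row[0]] and "CpGI" not in labels[row[0]]
        assert "CpGI" in labels[row[1]]

    def test_intronic_bin_carries_gene_and_intron(self):
        genes = RegionSet(
            [
                GenomicInterval("chr1", 1000, 7000, "+", "gene", "G1"),
                GenomicInterval("chr1", 1000, 2000, "+", "exon", "G1"),
                GenomicInterval("chr1", 6000, 7000, "+", "exon", "G1"),
            ],
            {"chr1": 10_000},
        )
        full = RegionSet(list(genes.intervals), {"chr1": 10_000})
        full.extend(derive_introns(genes))
        labels = assign_bins(BinIndex({"chr1": 10_000}, 100), full)
        assert labels[30] == {"gene", "intron"}  # bin [3000,3100) mid-intron

    def test_promoter_shore_intersection_label(self):
        rs = RegionSet(
            [
                GenomicInterval("chr1", 48_000, 50_000, "+", "promoter", "G1"),
                GenomicInterval("chr1", 49_000, 51_000, ".", "shore"),
            ],
            {"chr1": 60_000},
        )
        labels = assign_bins(BinIndex({"chr1": 60_000}, 100), rs)
        assert "promoter_shore" in labels[495]      # bin [49500,49600): in both
        assert "promoter_shore" not in labels[485]  # promoter only
        assert "promoter_shore" not in labels[505]  # shore only

    def test_unlabelled_bins_are_intergenic(self):
        labels = assign_bins(BinIndex({"chr1": 1000}, 100), RegionSet([], {"chr1": 1000}))
        assert all(lab == {"intergenic"} for lab in labels)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_bp_oracle_on_random_genomes(self, seed):
        """Bin labelling agrees with literal per-basepair membership."""
        rng = np.random.default_rng(100 + seed)
        size = 100_000
        labels_avail = ["CpGI", "shore", "promoter", "exon", "gene", "TFBS"]
        ivs = []
        for _ in range(60):
            s = int(rng.integers(0, size - 2000))
            e = s + int(rng.integers(1, 2000))
            ivs.append(
                GenomicInterval(
                    "chr1", s, e, ".", labels_avail[int(rng.integers(len(labels_avail)))]
                )
            )
        rs = RegionSet(ivs, {"chr1": size})
        bins = BinIndex({"chr1": size}, 100)
        got = assign_bins(bins, rs)
        for label in labels_avail:
            mask = per_bp_membership(
                [(iv.start, iv.end) for iv in ivs if iv.label == label], size
            )
            expect = bins_overlapping_mask(mask, 100)
            assert {i for i, lab in enumerate(got) if label in lab} == expect
        # derived intersections
        prom = per_bp_membership(
            [(iv.start, iv.end) for iv in ivs if iv.label == "promoter"], size
        )
        shore = per_bp_membership(
            [(iv.start, iv.end) for iv in ivs if iv.label == "shore"], size
        )
        expect_ps = bins_overlapping_mask(prom & shore, 100)
        assert {i for i, lab in enumerate(got) if "promoter_shore" in lab} == expect_ps


class TestIntervalArithmetic:
    def test_merge_subtract_intersect_agree_with_bp_oracle(self):
        rng = np.random.default_rng(11)
        size = 10_000
        a = [(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, size - 500, 30), rng.integers(1, 500, 30))]
        b = [(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, size - 500, 30), rng.integers(1, 500, 30))]
        ma, mb = per_bp_membership(a, size), per_bp_membership(b, size)
        assert np.array_equal(per_bp_membership(merge_intervals(a), size), ma)
        assert np.array_equal(per_bp_membership(subtract_intervals(a, b), size), ma & ~mb)
        assert np.array_equal(per_bp_membership(intersect_intervals(a, b), size), ma & mb)

    def test_bin_index_tiles_without_overlap(self):
        bi = BinIndex({"chr1": 950, "chr2": 400}, 100)
        assert bi.n_bins == 10 + 4
        assert bi.bin_bounds(9) == ("chr1", 900, 950)  # truncated final bin
        assert bi.bin_bounds(10) == ("chr2", 0, 100)
        assert list(bi.overlapping("chr1", 250, 251)) == [2]
        assert list(bi.overlapping("chr2", 0, 400)) == [10, 11, 12, 13]
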