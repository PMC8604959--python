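"""Genome coordinate model: digestion, promoter windows, feature hierarchy,
interval intersection and fragment binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crev2g.genome import (
    GeneModel,
    GenomicInterval,
    annotate_feature,
    bin_fragments,
    digest_genome,
    intersect,
    promoter_window,
)


def scan_cuts(seq: str, motif: str) -> list[tuple[int, int]]:
    """Independent linear string-scan digestion oracle."""
    cuts = [0]
    for i in range(len(seq) - len(motif) + 1):
        if seq[i : i + len(motif)] == motif and i > 0:
            cuts.append(i)
    cuts.append(len(seq))
    return list(zip(cuts, cuts[1:]))


class TestDigest:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAGATCAAAGATCAA", [(0, 3), (3, 10), (10, 16)]),
            ("GATCGATC", [(0, 4), (4, 8)]),
            ("AAAAAAAA", [(0, 8)]),  # no motif: one whole-chromosome fragment
        ],
    )
    def test_cut_positions(self, seq, expected):
        fm = digest_genome({"c": seq}, "GATC")
        got = [(f.start, f.end) for f in fm.fragments_by_chrom["c"]]
        assert got == expected
        assert got == scan_cuts(seq, "GATC")

    def test_random_sequences_match_scan_oracle_and_conserve_length(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            fm = digest_genome({"c": seq}, "GATC")
            frags = [(f.start, f.end) for f in fm.fragments_by_chrom["c"]]
            assert frags == scan_cuts(seq, "GATC")
            assert sum(b - a for a, b in frags) == len(seq)

    def test_empty_sequence_and_motif_errors(self):
        with pytest.raises(ValueError):
            digest_genome({"c": ""}, "GATC")
        with pytest.raises(ValueError):
            digest_genome({"c": "ACGT"}, "")

    def test_fragment_lookup(self):
        fm = digest_genome({"c": "AAAGATCAAAGATCAA"}, "GATC")
        assert fm.fragment_id_at("c", 0) == 0
        assert fm.fragment_id_at("c", 3) == 1
        assert fm.fragment_id_at("c", 15) == 2
        with pytest.raises(ValueError):
            fm.fragment_id_at("c", 16)


def _gene(strand="+", tss=10_000, chrom="chr1"):
    if strand == "+":
        exons = [GenomicInterval(chrom, tss, tss + 100),
                 GenomicInterval(chrom, tss + 300, tss + 400)]
    else:
        exons = [GenomicInterval(chrom, tss - 399, tss - 299),
                 GenomicInterval(chrom, tss - 99, tss + 1)]
    return GeneModel("g", chrom, strand, exons)


class TestPromoterWindow:
    def test_plus_strand_default(self):
        assert promoter_window(_gene("+")) == GenomicInterval("chr1", 8500, 10500)

    def test_minus_strand_mirrors(self):
        assert promoter_window(_gene("-")) == GenomicInterval("chr1", 9500, 11500)

    def test_clipped_at_chromosome_start(self):
        win = promoter_window(_gene("+", tss=100))
        assert (win.start, win.end) == (0, 600)

    def test_width_invariant(self):
        for tss in (100, 1500, 50_000):
            for strand in "+-":
                w = promoter_window(_gene(strand, tss=max(tss, 400)))
                assert len(w) <= 2000
                if w.start > 0:
                    assert len(w) == 2000


class TestAnnotateFeature:
    def make_genes(self):
        # gene A (+): tss 1000, first intron spans [1100, 9000)
        a = GeneModel(
            "A", "chr1", "+",
            exons=[GenomicInterval("chr1", 1000, 1100),
                   GenomicInterval("chr1", 9000, 9100),
                   GenomicInterval("chr1", 9500, 9600)],
            utr3=[GenomicInterval("chr1", 9550, 9600)],
        )
        # gene B (+): tss 3000, CDS in its second exon, far from any promoter
        b = GeneModel(
            "B", "chr1", "+",
            exons=[GenomicInterval("chr1", 3000, 3100),
                   GenomicInterval("chr1", 5000, 5100)],
            cds=[GenomicInterval("chr1", 5000, 5100)],
            utr5=[GenomicInterval("chr1", 3000, 3050)],
        )
        return [a, b]

    @staticmethod
    def oracle(iv, genes):
        """Enumerate every overlapped label, return the min-rank one."""
        hierarchy = ["Promoter", "5UTR", "CDS", "3UTR", "FirstIntron",
                     "OtherIntron", "Intergenic"]
        labels = set()
        for g in genes:
            if iv.overlaps(promoter_window(g)):
                labels.add("Promoter")
            for lab, ivs in [("5UTR", g.utr5), ("CDS", g.cds), ("3UTR", g.utr3)]:
                if any(iv.overlaps(x) for x in ivs):
                    labels.add(lab)
            fi = g.first_intron()
            if fi and iv.overlaps(fi):
                labels.add("FirstIntron")
            for intr in g.introns():
                if intr != fi and iv.overlaps(intr):
                    labels.add("OtherIntron")
        return min(labels, key=hierarchy.index) if labels else "Intergenic"

    def test_promoter_beats_first_intron(self):
        genes = self.make_genes()
        # [2000, 2100) is inside B's promoter window and A's first intron
        iv = GenomicInterval("chr1", 2000, 2100)
        assert self.oracle(iv, genes) == "Promoter"
        assert annotate_feature(iv, genes) == "Promoter"

    def test_cds_beats_first_intron_across_genes(self):
        genes = self.make_genes()
        # [5000, 5050) overlaps B's CDS and A's first intron, no promoter
        iv = GenomicInterval("chr1", 5000, 5050)
        assert self.oracle(iv, genes) == "CDS"
        assert annotate_feature(iv, genes) == "CDS"

    def test_intergenic_when_nothing_overlaps(self):
        assert annotate_feature(GenomicInterval("chr1", 50_000, 50_100),
                                self.make_genes()) == "Intergenic"

    def test_matches_enumeration_oracle_on_random_windows(self):
        genes = self.make_genes()
        rng = np.random.default_rng(3)
        for _ in range(200):
            s = int(rng.integers(0, 12_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 400)))
            assert annotate_feature(iv, genes) == self.oracle(iv, genes)

    def test_order_independence(self):
        genes = self.make_genes()
        iv = GenomicInterval("chr1", 4990, 5060)
        assert annotate_feature(iv, genes) == annotate_feature(iv, genes[::-1])

    def test_first_intron_strand_aware(self):
        g = GeneModel("m", "chr1", "-",
                      exons=[GenomicInterval("chr1", 100, 200),
                             GenomicInterval("chr1", 300, 400),
                             GenomicInterval("chr1", 500, 600)])
        # on the minus strand the first intron is the rightmost gap
        assert g.first_intron() == GenomicInterval("chr1", 400, 500)

    def test_single_exon_gene_has_no_intron(self):
        g = GeneModel("s", "chr1", "+", exons=[GenomicInterval("chr1", 100, 200)])
        assert g.first_intron() is None


class TestIntersect:
    def test_boundary_cases(self):
        a = [GenomicInterval("c", 0, 10)]
        assert intersect(a, [GenomicInterval("c", 9, 20)]) == [(0, 0, 1)]
        assert intersect(a, [GenomicInterval("c", 10, 20)]) == []

    def test_min_overlap_threshold(self):
        a = [GenomicInterval("c", 0, 10)]
        b = [GenomicInterval("c", 5, 20)]
        assert intersect(a, b, min_overlap=5) == [(0, 0, 5)]
        assert intersect(a, b, min_overlap=6) == []

    @staticmethod
    def brute_force(a, b, min_overlap=1):
        out = set()
        for i, x in enumerate(a):
            for j, y in enumerate(b):
                ov = x.overlap_bp(y)
                if ov >= min_overlap:
                    out.add((i, j, ov))
        return out

    def test_matches_all_pairs_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            def rand_set(n):
                return [
                    GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + int(l))
                    for s, l in zip(rng.integers(0, 5000, n), rng.integers(1, 300, n))
                ]
            a, b = rand_set(int(rng.integers(1, 120))), rand_set(int(rng.integers(1, 120)))
            assert set(intersect(a, b)) == self.brute_force(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = [GenomicInterval("c", int(s), int(s) + 50) for s in rng.integers(0, 2000, 40)]
        b = [GenomicInterval("c", int(s), int(s) + 80) for s in rng.integers(0, 2000, 30)]
        fwd = {(i, j, ov) for i, j, ov in intersect(a, b)}
        rev = {(j, i, ov) for i, j, ov in intersect(b, a)}
        assert fwd == rev


class TestBinFragments:
    def test_identity_at_k1(self):
        fm = digest_genome({"c": "AAAGATCAAAGATCAA"}, "GATC")
        assert bin_fragments(fm, 1) is fm

    def test_remainder_rule(self):
        seq = "AAA" + "GATCAA" * 8  # 9 fragments
        fm = digest_genome({"c": seq}, "GATC")
        assert len(fm.fragments_by_chrom["c"]) == 9
        fm4 = bin_fragments(fm, 4)
        sizes = [len(f) for f in fm4.fragments_by_chrom["c"]]
        assert len(sizes) == 3  # groups of 4, 4 and the trailing 1
        # conservation: binned spans tile the chromosome
        assert sum(sizes) == len(seq)
        assert fm4.fragments_by_chrom["c"][0].start == 0
        assert fm4.fragments_by_chrom["c"][-1].end == len(seq)

    def test_invalid_k(self):
        fm = digest_genome({"c": "GATCGATC"}, "GATC")
        with pytest.raises(ValueError):
            bin_fragments(fm, 0)


class TestProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_digestion_conserves_chromosome_length(self, seq):
        fm = digest_genome({"c": seq}, "GATC")
        frags = fm.fragments_by_chrom["c"]
        assert sum(len(f) for f in frags) == len(seq)
        assert frags[0].start == 0 and frags[-1].end == len(seq)
        for a, b in zip(frags, frags[1:]):
            assert a.end == b.start

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=10**6),
        st.sampled_from("+-"),
        st.integers(min_value=0, max_value=5000),
        st.integers(min_value=1, max_value=5000),
    )
    def test_promoter_window_width_bound(self, tss, strand, up, down):
        g = GeneModel("g", "chr1", strand,
                      exons=[GenomicInterval("chr1", tss, tss + 1),
                             GenomicInterval("chr1", tss + 10, tss + 20)])
        tss_eff = g.tss
        win = promoter_window(g, upstream=up, downstream=down)
        assert len(win) <= up + down
        if win.start > 0:
            assert len(win) == up + down
        assert win.start <= tss_eff < win.end or (up == 0 or down == 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 200)),
                 min_size=1, max_size=30),
        st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 200)),
                 min_size=1, max_size=30),
    )
    def test_intersect_pair_set_symmetric(self, xs, ys):
        a = [GenomicInterval("c", s, s + l) for s, l in xs]
        b = [GenomicInterval("c", s, s + l) for s, l in ys]
        fwd = {(i, j, ov) for i, j, ov in intersect(a, b)}
        rev = {(j, i, ov) for i, j, ov in intersect(b, a)}
        assert fwd == rev
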