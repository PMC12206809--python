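"""Feature assignment, codon consequences, motif overlap."""

import numpy as np
import pytest

from famdiv.io import GeneModel, SequenceRecord, VariantRecord, reverse_complement
from famdiv.effects import (ReferenceMismatchError, annotate_variants,
                            assign_feature, coding_consequence, overlaps_motif)

from oracles import full_translation_consequence


def _variant(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, pos + 1)


@pytest.fixture
def toy_gene():
    """Plus-strand gene: 10 bp utr5, CDS 30 bp split over two exons, 10 bp utr3."""
    # layout on chr1 starting at 100:
    # [100,110) utr5 | [110,125) CDS | [125,145) intron | [145,160) CDS | [160,170) utr3
    cds = "ATG" + "GGATACTACGCA" + "TACGGAGGAACT" + "TAA"  # 30 bp
    seq = (
        "C" * 100
        + "ACGTACGTAC"          # utr5
        + cds[:15]              # CDS part 1
        + "GT" + "A" * 16 + "AG"  # intron
        + cds[15:]              # CDS part 2
        + "TTTTTTTTTT"          # utr3
        + "C" * 100
    )
    gene = GeneModel(
        gene_id="g1", chrom="chr1", strand="+", start=100, end=170,
        exons=[(100, 125), (145, 170)],
        cds_segments=[(110, 125, 0), (145, 160, 0)],
        utr5=[(100, 110)], utr3=[(160, 170)],
    )
    genome = {"chr1": SequenceRecord("chr1", seq)}
    return gene, genome


class TestAssignFeature:
    def test_precedence_partition(self, toy_gene):
        gene, _ = toy_gene
        cases = {
            112: "CDS", 130: "intron", 105: "utr5", 165: "utr3",
            50: "upstream", 99: "upstream", 500: "intergenic",
        }
        for pos, want in cases.items():
            feat, gid = assign_feature(_variant("chr1", pos, "A", "G"), [gene])
            assert feat == want
            assert (gid == "g1") == (want != "intergenic")

    def test_minus_strand_upstream_window(self):
        gene = GeneModel(gene_id="g2", chrom="chr1", strand="-", start=5000, end=6000)
        feat, gid = assign_feature(_variant("chr1", 7500, "A", "G"), [gene])
        assert (feat, gid) == ("upstream", "g2")
        assert assign_feature(_variant("chr1", 8200, "A", "G"), [gene])[0] == "intergenic"

    def test_cds_beats_promoter_of_neighbour(self, toy_gene):
        gene, _ = toy_gene
        neighbour = GeneModel(gene_id="g3", chrom="chr1", strand="+",
                              start=300, end=400)
        feat, gid = assign_feature(_variant("chr1", 150, "A", "G"),
                                   [gene, neighbour])
        assert (feat, gid) == ("CDS", "g1")

    def test_every_variant_gets_exactly_one_feature(self, bundle):
        genome, models, sites = bundle[0], bundle[1], bundle[2]
        for chrom, pos, ref, alts, _ in sites:
            feat, _ = assign_feature(_variant(chrom, pos, ref, alts[0]), models)
            assert feat in ("CDS", "utr5", "utr3", "intron", "upstream", "intergenic")


class TestCodingConsequence:
    def test_synonymous_third_position(self, toy_gene):
        gene, genome = toy_gene
        # codon 2 is GGA at [113,116); third position 115: GGA->GGG
        v = _variant("chr1", 115, genome["chr1"].seq[115], "G")
        c = coding_consequence(v, gene, genome)
        assert c.consequence == "synonymous" and c.aa_change is None
        assert c.codon_change == "GGA>GGG"

    def test_nonsense_gain(self, toy_gene):
        gene, genome = toy_gene
        # codon 3 TAC at [116,119): TAC->TAA at its third base
        v = _variant("chr1", 118, "C", "A")
        c = coding_consequence(v, gene, genome)
        assert c.consequence == "nonsense" and c.aa_change == "Y3*"

    def test_reference_mismatch_named(self, toy_gene):
        gene, genome = toy_gene
        with pytest.raises(ReferenceMismatchError, match="chr1:116"):
            coding_consequence(_variant("chr1", 115, "T", "G"), gene, genome)

    def test_matches_full_translation_oracle_on_random_snps(self, bundle):
        genome, models = bundle[0], bundle[1]
        rng = np.random.default_rng(17)
        n_checked = 0
        while n_checked < 300:
            gene = models[int(rng.integers(len(models)))]
            s, e, _ = gene.cds_segments[int(rng.integers(len(gene.cds_segments)))]
            pos = int(rng.integers(s, e))
            ref = genome[gene.chrom].seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v = _variant(gene.chrom, pos, ref, alt)
            mine = coding_consequence(v, gene, genome)
            kind, aa = full_translation_consequence(gene, genome, pos, alt)
            # the oracle reports the first protein difference; for a clean
            # single-codon change they must agree exactly
            assert mine.consequence == kind
            if mine.consequence in ("missense", "nonsense"):
                assert mine.aa_change == aa
            n_checked += 1

    def test_strand_symmetry(self, toy_gene):
        """Mirroring a gene to the minus strand with complemented alleles
        preserves the consequence."""
        gene, genome = toy_gene
        L = len(genome["chr1"].seq)
        mirrored_seq = reverse_complement(genome["chr1"].seq)
        mirror = {"chr1": SequenceRecord("chr1", mirrored_seq)}

        def flip(iv):
            return (L - iv[1], L - iv[0])

        gene_m = GeneModel(
            gene_id="g1m", chrom="chr1", strand="-",
            start=L - gene.end, end=L - gene.start,
            exons=[flip(iv) for iv in gene.exons],
            cds_segments=[(*flip((s, e)), p) for s, e, p in gene.cds_segments],
            utr5=[flip(iv) for iv in gene.utr5],
            utr3=[flip(iv) for iv in gene.utr3],
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos in range(110, 125):
            ref = genome["chr1"].seq[pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                c_plus = coding_consequence(_variant("chr1", pos, ref, alt),
                                            gene, genome)
                c_minus = coding_consequence(
                    _variant("chr1", L - pos - 1, comp[ref], comp[alt]),
                    gene_m, mirror)
                assert c_plus.consequence == c_minus.consequence
                assert c_plus.aa_change == c_minus.aa_change


class TestMotifOverlap:
    INTERVALS = [("chr1", 100, 108)]

    def test_half_open_inclusion(self):
        assert overlaps_motif(_variant("chr1", 100, "A", "G"), self.INTERVALS)
        assert overlaps_motif(_variant("chr1", 107, "A", "G"), self.INTERVALS)

    def test_half_open_exclusion(self):
        assert not overlaps_motif(_variant("chr1", 108, "A", "G"), self.INTERVALS)
        assert not overlaps_motif(_variant("chr2", 100, "A", "G"), self.INTERVALS)

    def test_counts_match_interval_scan_on_synthetic_truth(self, bundle):
        from famdiv.motifs import scan_promoters
        genome, models, sites = bundle[0], bundle[1], bundle[2]
        _, intervals = scan_promoters(models, genome)
        flat = [iv for ivs in intervals.values() for iv in ivs]
        got = sum(overlaps_motif(_variant(c, p, r, a[0]), flat)
                  for c, p, r, a, _ in sites)
        brute = 0
        for c, p, *_ in sites:
            brute += any(ch == c and s <= p < e for ch, s, e in flat)
        assert got == brute


def test_annotate_variants_rows(bundle):
    from famdiv.motifs import scan_promoters
    genome, models, sites, truth = bundle[0], bundle[1], bundle[2], bundle[5]
    from famdiv.io import VariantRecord
    variants = [VariantRecord(c, p, r, a[0], p + 1) for c, p, r, a, _ in sites]
    _, intervals = scan_promoters(models, genome)
    rows = annotate_variants(variants, models, genome, intervals)
    assert len(rows) == len(sites)
    # planted features recovered
    for row, v in zip(rows, variants):
        feat, gid = truth.variant_features[(v.chrom, v.pos)]
        assert row["feature"] == feat and row["gene"] == gid
    # planted nonsynonymous changes reproduce recorded amino-acid notation
    by_key = {(r["chrom"], r["pos"] - 1, r["alt"]): r for r in rows}
    for (chrom, pos, alt), aa in truth.nonsyn_truth.items():
        row = by_key[(chrom, pos, alt)]
        assert row["consequence"] == "missense"
        assert row["aa_change"] == aa
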