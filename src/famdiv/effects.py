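"""Feature assignment and codon-level coding consequences for SNPs.

Each SNP is assigned exactly one feature class with the precedence
CDS > UTR > intron > upstream > intergenic (a site in a coding exon of one
gene and the promoter of a neighbour is counted as CDS). Coding
consequences are computed by locating the variant on the spliced 5'->3'
CDS, substituting within its codon (complementing the alternate allele on
minus-strand genes) and translating with the standard nuclear code.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .io import GeneModel, SequenceRecord, VariantRecord

__all__ = [
    "FEATURE_PRECEDENCE",
    "ReferenceMismatchError",
    "Consequence",
    "assign_feature",
    "assign_features_all",
    "coding_consequence",
    "overlaps_motif",
    "annotate_variants",
]

FEATURE_PRECEDENCE = ("CDS", "utr5", "utr3", "intron", "upstream", "intergenic")
_RANK = {f: i for i, f in enumerate(FEATURE_PRECEDENCE)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the genome FASTA at a site."""


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or '*') for a DNA codon, standard code."""
    return _CODON_TO_AA[codon.upper()]


def _feature_within_gene(pos: int, gene: GeneModel) -> str | None:
    """Feature class of a position relative to one gene, or None if outside
    both the span and the strand-aware upstream window (handled by caller)."""
    if not (gene.start <= pos < gene.end):
        return None
    for s, e, _ in gene.cds_segments:
        if s <= pos < e:
            return "CDS"
    for s, e in gene.utr5:
        if s <= pos < e:
            return "utr5"
    for s, e in gene.utr3:
        if s <= pos < e:
            return "utr3"
    for s, e in gene.exons:
        if s <= pos < e:
            # exon base not annotated as CDS/UTR: side relative to the CDS
            # decides which UTR it behaves as
            if gene.cds_segments:
                cds_start = gene.cds_segments[0][0]
                before = pos < cds_start
                return "utr5" if (before == (gene.strand == "+")) else "utr3"
            return "utr5"
    return "intron"


def _in_upstream(pos: int, gene: GeneModel, promoter_len: int) -> bool:
    if gene.strand == "+":
        return gene.start - promoter_len <= pos < gene.start
    return gene.end <= pos < gene.end + promoter_len


def assign_features_all(variant: VariantRecord, genes: list[GeneModel],
                        promoter_len: int = 2000) -> list[tuple[str, str]]:
    """(feature, gene_id) for every gene whose span or promoter covers the site."""
    out = []
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        feat = _feature_within_gene(variant.pos, gene)
        if feat is not None:
            out.append((feat, gene.gene_id))
        elif _in_upstream(variant.pos, gene, promoter_len):
            out.append(("upstream", gene.gene_id))
    return out


def assign_feature(variant: VariantRecord, genes: list[GeneModel],
                   promoter_len: int = 2000) -> tuple[str, str | None]:
    """Single (feature, gene_id) for a variant under CDS-first precedence.

    Ties between genes at equal precedence go to the first gene in input
    order (deterministic).
    """
    candidates = assign_features_all(variant, genes, promoter_len)
    if not candidates:
        return ("intergenic", None)
    best = min(candidates, key=lambda fg: _RANK[fg[0]])
    return best


@dataclass
class Consequence:
    """Codon-level effect of a coding SNP."""

    consequence: str  # synonymous | missense | nonsense | stoploss | none
    codon_change: str | None  # "NNN>NNN"
    aa_change: str | None  # "X<pos>Y", 1-based protein coordinates
    low_confidence: bool = False  # CDS length not divisible by 3


def coding_consequence(variant: VariantRecord, gene: GeneModel,
                       genome: dict[str, SequenceRecord]) -> Consequence:
    """Effect of substituting the alternate allele within its codon.

    Requires the variant to fall in a CDS segment of ``gene``. Raises
    :class:`ReferenceMismatchError` when the VCF REF disagrees with the
    genome FASTA.
    """
    ref_base = genome[gene.chrom].seq[variant.pos]
    if ref_base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.source_pos}: VCF REF {variant.ref!r} "
            f"but genome has {ref_base!r}"
        )
    off = gene.cds_offset(variant.pos)
    if off is None:
        raise ValueError(
            f"variant {variant.chrom}:{variant.source_pos} not in CDS of {gene.gene_id}"
        )
    low_conf = not gene.cds_frame_ok
    cds = gene.spliced_cds(genome)
    alt = variant.alt if gene.strand == "+" else _COMPLEMENT[variant.alt]
    codon_i = off // 3
    within = off % 3
    codon = cds[codon_i * 3: codon_i * 3 + 3]
    if len(codon) < 3:  # trailing partial codon of a frame-broken model
        return Consequence("none", None, None, low_confidence=True)
    alt_codon = codon[:within] + alt + codon[within + 1:]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref == aa_alt:
        return Consequence("synonymous", f"{codon}>{alt_codon}", None, low_conf)
    if aa_alt == "*":
        kind = "nonsense"
    elif aa_ref == "*":
        kind = "stoploss"
    else:
        kind = "missense"
    return Consequence(kind, f"{codon}>{alt_codon}",
                       f"{aa_ref}{codon_i + 1}{aa_alt}", low_conf)


def overlaps_motif(variant: VariantRecord,
                   motif_intervals: list[tuple[str, int, int]]) -> bool:
    """True iff the variant position lies within a [start, end) motif interval."""
    return any(chrom == variant.chrom and s <= variant.pos < e
               for chrom, s, e in motif_intervals)


def annotate_variants(variants: list[VariantRecord], genes: list[GeneModel],
                      genome: dict[str, SequenceRecord],
                      motif_intervals: dict[str, list[tuple[str, int, int]]] | None = None,
                      promoter_len: int = 2000,
                      sift_annotations: dict[tuple[str, int], str] | None = None) -> list[dict]:
    """Annotated rows (one per variant) for the TSV interface.

    ``motif_intervals`` maps gene id to genomic P1BS site intervals;
    ``sift_annotations`` is an optional pass-through of externally computed
    deleteriousness labels keyed by (chrom, 1-based pos).
    """
    genes_by_id = {g.gene_id: g for g in genes}
    all_intervals = [iv for ivs in (motif_intervals or {}).values() for iv in ivs]
    rows = []
    for v in variants:
        feature, gene_id = assign_feature(v, genes, promoter_len)
        consequence, codon_change, aa_change = "noncoding", None, None
        if feature == "CDS" and gene_id is not None:
            c = coding_consequence(v, genes_by_id[gene_id], genome)
            consequence, codon_change, aa_change = c.consequence, c.codon_change, c.aa_change
        elif feature == "intergenic":
            consequence = "none"
        row = {
            "chrom": v.chrom, "pos": v.source_pos, "ref": v.ref, "alt": v.alt,
            "gene": gene_id or ".", "feature": feature,
            "consequence": consequence,
            "codon_change": codon_change or ".",
            "aa_change": aa_change or ".",
            "in_p1bs": overlaps_motif(v, all_intervals),
        }
        if sift_annotations is not None:
            row["sift"] = sift_annotations.get((v.chrom, v.source_pos), ".")
        rows.append(row)
    return rows
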