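"""Promoter extraction and degenerate IUPAC motif scanning.

The main use is scanning 2-kb upstream regions of phosphate-transporter
genes for the PHR1-binding site P1BS (default consensus ``GNATATNC``), the
cis-element through which the phosphate-starvation response regulator PHR1
induces phosphate-starvation-inducible genes.

Matching is set-based per position: an IUPAC pattern code matches the set
of bases it denotes; an ``N`` in the *subject* matches nothing except a
pattern ``N`` (conservative policy for gappy assemblies). Both strands are
scanned by default, with all hit coordinates reported on the forward axis
of the scanned sequence. Note that P1BS is IUPAC-palindromic: every
forward-strand site is simultaneously a reverse-strand site at the same
offset, so site counts should use :func:`count_motif_sites` (unique
offsets) rather than raw hit counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneModel, SequenceRecord, reverse_complement

__all__ = [
    "P1BS_PATTERN",
    "MotifHit",
    "PromoterRegion",
    "extract_promoter",
    "scan_motif",
    "count_motif_sites",
    "scan_promoters",
]

#: canonical PHR1-binding-site consensus
P1BS_PATTERN = "GNATATNC"

# base -> bitmask; subject N gets a private bit so it only matches pattern N
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 16}
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _pattern_masks(pattern: str) -> np.ndarray:
    masks = []
    for code in pattern.upper():
        if code not in _IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        mask = sum(_BASE_BITS[b] for b in _IUPAC_SETS[code])
        if code == "N":
            mask |= _BASE_BITS["N"]  # pattern N also matches subject N
        masks.append(mask)
    return np.array(masks, dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    out = np.zeros(len(seq), dtype=np.uint8)
    for base, bit in _BASE_BITS.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = bit
    return out


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on the forward axis of the scanned sequence."""

    gene_id: str | None
    offset: int  # 0-based start within the scanned sequence
    strand_of_hit: str  # '+' or '-'
    matched_seq: str  # forward-axis substring (revcomp it for '-' hits)
    genomic_pos: int | None = None  # forward-genome start, when known


@dataclass
class PromoterRegion:
    """A strand-aware upstream region of a gene.

    ``seq`` reads 5'->3' relative to the gene; ``start``/``end`` are the
    forward-genome interval it was cut from.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    seq: str
    truncated: bool

    def __len__(self) -> int:
        return len(self.seq)

    def to_genomic(self, offset: int, length: int = 1) -> int:
        """Forward-genome start of an oriented-promoter interval."""
        if self.strand == "+":
            return self.start + offset
        return self.end - offset - length

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(f"{self.gene_id}:promoter", self.seq)


def extract_promoter(gene: GeneModel, genome: dict[str, SequenceRecord],
                     length: int = 2000) -> PromoterRegion:
    """Cut the ``length``-bp region immediately upstream of the gene span.

    For plus-strand genes this is the region 5' of the span start; for
    minus-strand genes the reverse complement of the region 3' of the span
    end. The region is truncated at the contig boundary (flagged).
    """
    if gene.chrom not in genome:
        raise ValueError(f"chromosome {gene.chrom!r} of {gene.gene_id} not in genome")
    chrom_seq = genome[gene.chrom].seq
    if gene.start < 0 or gene.end > len(chrom_seq):
        raise ValueError(f"gene {gene.gene_id} span outside contig {gene.chrom}")
    if gene.strand == "+":
        start = max(0, gene.start - length)
        end = gene.start
        seq = chrom_seq[start:end]
    else:
        start = gene.end
        end = min(len(chrom_seq), gene.end + length)
        seq = reverse_complement(chrom_seq[start:end])
    return PromoterRegion(gene.gene_id, gene.chrom, gene.strand, start, end,
                          seq, truncated=(end - start) < length)


def scan_motif(sequence: str, iupac_pattern: str, both_strands: bool = True,
               gene_id: str | None = None) -> list[MotifHit]:
    """All (possibly overlapping) matches of an IUPAC pattern in a sequence.

    Hits are ordered by ascending offset, '+' before '-' at equal offset.
    Offsets are always on the forward axis of ``sequence``.
    """
    sequence = sequence.upper()
    fwd_masks = _pattern_masks(iupac_pattern)
    m = len(fwd_masks)
    if len(sequence) < m:
        return []
    subject = _encode(sequence)
    n_win = len(sequence) - m + 1

    def _match(masks: np.ndarray) -> np.ndarray:
        ok = np.ones(n_win, dtype=bool)
        for k in range(m):
            ok &= (subject[k:k + n_win] & masks[k]) != 0
        return ok

    hits = []
    fwd = _match(fwd_masks)
    if both_strands:
        rev_masks = _pattern_masks(reverse_complement(iupac_pattern.upper()))
        rev = _match(rev_masks)
    else:
        rev = np.zeros(n_win, dtype=bool)
    for off in np.flatnonzero(fwd | rev):
        off = int(off)
        sub = sequence[off:off + m]
        if fwd[off]:
            hits.append(MotifHit(gene_id, off, "+", sub))
        if rev[off]:
            hits.append(MotifHit(gene_id, off, "-", sub))
    return hits


def count_motif_sites(hits: list[MotifHit]) -> int:
    """Number of distinct motif sites (unique offsets) among hits.

    For IUPAC-palindromic patterns such as P1BS each site produces both a
    '+' and a '-' hit; this collapses them.
    """
    return len({h.offset for h in hits})


def scan_promoters(genes: list[GeneModel], genome: dict[str, SequenceRecord],
                   pattern: str = P1BS_PATTERN, length: int = 2000,
                   both_strands: bool = True):
    """Scan every gene's promoter; returns (rows, genomic_intervals).

    ``rows`` is a list of dicts for the TSV interface; ``genomic_intervals``
    maps gene id to a list of forward-genome ``(chrom, start, end)`` motif
    site intervals (unique sites).
    """
    rows = []
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    m = len(pattern)
    for gene in genes:
        promoter = extract_promoter(gene, genome, length)
        hits = scan_motif(promoter.seq, pattern, both_strands, gene_id=gene.gene_id)
        seen_offsets = set()
        intervals[gene.gene_id] = []
        for h in hits:
            gpos = promoter.to_genomic(h.offset, m)
            rows.append({
                "gene_id": gene.gene_id, "motif": pattern, "offset": h.offset,
                "genomic_pos": gpos, "strand": h.strand_of_hit,
                "matched_seq": h.matched_seq,
                "promoter_truncated": promoter.truncated,
            })
            if h.offset not in seen_offsets:
                seen_offsets.add(h.offset)
                intervals[gene.gene_id].append((gene.chrom, gpos, gpos + m))
    return rows, intervals
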