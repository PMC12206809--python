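"""Readers and writers for FASTA, GFF3 and VCF, and the shared coordinate model.

Every coordinate inside the package is 0-based half-open on the forward
genomic strand. GFF3 and VCF use 1-based inclusive coordinates; the
conversion happens here, at the file boundary, and nowhere else.

Only single-nucleotide variants enter the genotype matrix: indels and MNPs
are skipped (and counted), multiallelic SNP records are split into one
biallelic record per alternate allele. Phased separators are treated as
unphased and half-missing genotype calls as fully missing.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from cyvcf2 import VCF
import gffutils

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype dosage
MISSING: int = -1

_DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()


def read_fasta(path) -> dict[str, SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into an ordered id -> record map.

    Residues are uppercased on ingest. Duplicate ids, RNA (``U``) and any
    character outside {A,C,G,T,N} raise ``ValueError`` naming the record
    and the offending position.
    """
    records: dict[str, SequenceRecord] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"non-IUPAC DNA character {seq[pos]!r} in record "
                    f"{rec.id!r} at residue {pos + 1} of {path}"
                )
            records[rec.id] = SequenceRecord(rec.id, seq)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene's coordinate frame: span, exons, CDS and UTR segments.

    Segment lists are kept in genomic (ascending) order regardless of
    strand; 5'->3' iteration for minus-strand genes is provided by
    :meth:`cds_in_transcription_order`. ``cds_segments`` entries are
    ``(start, end, phase)``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)

    @property
    def cds_frame_ok(self) -> bool:
        """True when the total CDS length is divisible by 3."""
        return self.cds_length % 3 == 0

    def cds_in_transcription_order(self) -> list[tuple[int, int, int]]:
        """CDS segments ordered 5'->3' along the transcript."""
        if self.strand == "+":
            return list(self.cds_segments)
        return list(reversed(self.cds_segments))

    def spliced_cds(self, genome: dict[str, SequenceRecord]) -> str:
        """The 5'->3' coding sequence spliced out of the genome."""
        chrom_seq = genome[self.chrom].seq
        parts = [chrom_seq[s:e] for s, e, _ in self.cds_segments]
        cds = "".join(parts)
        if self.strand == "-":
            cds = reverse_complement(cds)
        return cds

    def cds_offset(self, pos: int) -> int | None:
        """Offset of genomic ``pos`` along the spliced 5'->3' CDS, or None."""
        off = 0
        if self.strand == "+":
            for s, e, _ in self.cds_segments:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
        else:
            for s, e, _ in reversed(self.cds_segments):
                if s <= pos < e:
                    return off + (e - 1 - pos)
                off += e - s
        return None


def _validate_model(model: GeneModel) -> None:
    for i in range(1, len(model.exons)):
        if model.exons[i][0] < model.exons[i - 1][1]:
            raise ValueError(
                f"overlapping exons in gene {model.gene_id}: "
                f"{model.exons[i - 1]} and {model.exons[i]}"
            )
    if not model.cds_frame_ok:
        logger.warning(
            "gene %s: CDS length %d not divisible by 3 (flagged, not fatal)",
            model.gene_id, model.cds_length,
        )


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features from a GFF3 file.

    One transcript per gene is assumed (the first mRNA child). Coordinates
    are converted from GFF's 1-based inclusive to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="gene"))
        if not parents or parents[0].id not in gene_ids:
            raise ValueError(f"CDS feature {cds.id!r} has no parent gene")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons, cds, utr5, utr3 = [], [], [], []
        for f in db.children(parent, order_by="start"):
            iv = (f.start - 1, f.end)
            if f.featuretype == "exon":
                exons.append(iv)
            elif f.featuretype == "CDS":
                phase = int(f.frame) if f.frame not in (".", None) else 0
                cds.append((f.start - 1, f.end, phase))
            elif f.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif f.featuretype == "three_prime_UTR":
                utr3.append(iv)
        model = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start - 1, end=gene.end,
            exons=exons, cds_segments=cds, utr5=utr5, utr3=utr3,
        )
        _validate_model(model)
        models.append(model)
    return models


def write_gff3(models: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR rows)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in models:
            s, e = m.start + 1, m.end
            attrs = f"ID={m.gene_id}"
            out.write(f"{m.chrom}\tfamdiv\tgene\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            mrna_id = f"{m.gene_id}.t1"
            out.write(
                f"{m.chrom}\tfamdiv\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(m.exons, 1):
                out.write(
                    f"{m.chrom}\tfamdiv\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (cs, ce, phase) in enumerate(m.cds_segments, 1):
                out.write(
                    f"{m.chrom}\tfamdiv\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )
            for kind, ivs in (("five_prime_UTR", m.utr5), ("three_prime_UTR", m.utr3)):
                for i, (us, ue) in enumerate(ivs, 1):
                    out.write(
                        f"{m.chrom}\tfamdiv\t{kind}\t{us + 1}\t{ue}\t.\t{m.strand}\t.\t"
                        f"ID={mrna_id}.{kind}{i};Parent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP site (internal 0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    source_pos: int  # original VCF POS (1-based)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.source_pos}")


@dataclass
class GenotypeMatrix:
    """Samples x loci alternate-allele dosage matrix with missing sentinel."""

    samples: list[str]
    loci: list[VariantRecord]
    dosages: np.ndarray  # int8, shape (n_samples, n_loci), MISSING = -1
    n_skipped_non_snp: int = 0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing genotype calls."""
        return (self.dosages == MISSING).mean(axis=0)

    def alt_frequency(self) -> np.ndarray:
        """Per-locus alternate allele frequency over non-missing calls (nan if all missing)."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nansum(d, axis=0) / (2 * np.sum(~np.isnan(d), axis=0))

    def maf(self) -> np.ndarray:
        """Per-locus minor allele frequency (nan where all calls missing)."""
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci where ``keep`` is True (order preserved)."""
        keep = np.asarray(keep, dtype=bool)
        loci = [v for v, k in zip(self.loci, keep) if k]
        return GenotypeMatrix(list(self.samples), loci, self.dosages[:, keep],
                              self.n_skipped_non_snp)


def read_vcf(path) -> GenotypeMatrix:
    """Ingest a VCF into a biallelic-SNP genotype matrix.

    Multiallelic SNP records are split into one column per alternate allele
    with dosages recoded per alt; indels/MNPs are skipped and counted in
    ``n_skipped_non_snp``. ``./.`` and half-missing calls become MISSING.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for v in vcf:
        alts = v.ALT
        if len(v.REF) != 1 or any(len(a) != 1 or a not in "ACGT" for a in alts):
            skipped += 1
            continue
        gts = v.genotypes  # [[a1, a2, phased], ...]
        allele_pairs = np.array([[g[0], g[1]] for g in gts], dtype=np.int16)
        if allele_pairs.shape[0] != len(samples):
            raise ValueError(
                f"sample count mismatch at {v.CHROM}:{v.POS}: "
                f"{allele_pairs.shape[0]} genotypes for {len(samples)} samples"
            )
        missing = (allele_pairs < 0).any(axis=1)
        for ai, alt in enumerate(alts, start=1):
            dose = (allele_pairs == ai).sum(axis=1).astype(np.int8)
            dose[missing] = MISSING
            loci.append(VariantRecord(v.CHROM, v.POS - 1, v.REF, alt, v.POS))
            columns.append(dose)
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNP records", path, skipped)
    dosages = (np.stack(columns, axis=1) if columns
               else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, loci, dosages, n_skipped_non_snp=skipped)


def write_vcf(sites, samples: Sequence[str], path) -> None:
    """Write sites as uncompressed VCF 4.2.

    ``sites`` is an iterable of ``(chrom, pos0, ref, alts, pairs)`` where
    ``alts`` is a list of alternate alleles and ``pairs`` an (n_samples, 2)
    integer array of allele indices with -1 for missing.
    """
    sites = list(sites)
    contigs = dict.fromkeys(chrom for chrom, *_ in sites)
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for chrom in contigs:
            out.write(f"##contig=<ID={chrom}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples) + "\n")
        for chrom, pos0, ref, alts, pairs in sites:
            gt_strs = []
            for a1, a2 in pairs:
                if a1 < 0 or a2 < 0:
                    gt_strs.append("./.")
                else:
                    gt_strs.append(f"{a1}/{a2}")
            out.write(
                f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strs) + "\n"
            )
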