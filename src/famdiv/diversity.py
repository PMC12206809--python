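"""Sequence-diversity accounting over a filtered SNP panel.

Implements the bookkeeping used to characterise polymorphism within a gene
family from low-coverage resequencing of a diversity panel: MAF/missingness
filtering (keep MAF > 0.01 and missing fraction < 0.10 by default),
transition/transversion classing, SNP densities per gene and per feature
(reported as integer bp-per-SNP; a region with no SNPs is reported as "no
polymorphism", never divided by), private-variant detection (minor allele
carried by exactly one accession) and per-accession polymorphic-site
counts (carrier-of-alternate, dosage >= 1).

MAF uses allele counting over non-missing calls: the denominator is
2 x (non-missing samples) at the locus. The analyzed length of a gene is
its span plus the 2-kb putative regulatory region upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GeneModel, GenotypeMatrix, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "filter_variants",
    "substitution_class",
    "ts_fraction",
    "bp_per_snp",
    "snp_density",
    "private_variants",
    "per_accession_counts",
    "DiversitySummary",
    "summarize",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def filter_variants(matrix: GenotypeMatrix, maf_min: float = 0.01,
                    max_missing: float = 0.10) -> GenotypeMatrix:
    """Keep loci with MAF > ``maf_min`` and missing fraction < ``max_missing``.

    Both thresholds are strict, matching the filter "MAF > 0.01 and <10%
    missing data". All-missing loci are removed (and logged). Locus order
    is preserved; the operation is idempotent.
    """
    maf = matrix.maf()
    miss = matrix.missing_fraction()
    all_missing = np.isnan(maf)
    if all_missing.any():
        logger.info("filter_variants: removed %d all-missing loci", all_missing.sum())
    keep = ~all_missing & (maf > maf_min) & (miss < max_missing)
    return matrix.subset(keep)


def substitution_class(ref: str, alt: str) -> str:
    """'transition' (purine<->purine or pyrimidine<->pyrimidine) or 'transversion'."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"substitution_class: non-ACGT allele {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("substitution_class: ref == alt")
    same_class = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    return "transition" if same_class else "transversion"


def ts_fraction(loci: list[VariantRecord]) -> float:
    """Fraction of loci that are transitions."""
    if not loci:
        raise ValueError("ts_fraction: no loci")
    n_ts = sum(substitution_class(v.ref, v.alt) == "transition" for v in loci)
    return n_ts / len(loci)


def bp_per_snp(n_snps: int, length_bp: int) -> int | None:
    """Density as integer bp per SNP; None marks 'no polymorphism'."""
    if length_bp <= 0:
        raise ValueError(f"bp_per_snp: non-positive region length {length_bp}")
    if n_snps == 0:
        return None
    return round(length_bp / n_snps)


def _dedup_sites(loci: list[VariantRecord]) -> list[int]:
    """Indices of the first record per distinct (chrom, pos) site.

    Split multiallelic records share a site; global totals count each site
    once while per-alt rows remain available."""
    seen: set[tuple[str, int]] = set()
    keep = []
    for i, v in enumerate(loci):
        key = (v.chrom, v.pos)
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return keep


def snp_density(annotations: list[dict], genes: list[GeneModel],
                feature_lengths: dict[str, int] | None = None,
                promoter_len: int = 2000) -> tuple[list[dict], list[dict]]:
    """Per-gene and per-feature SNP densities.

    ``annotations`` are rows from :func:`famdiv.effects.annotate_variants`
    restricted to the filtered panel. A gene's analyzed length is its span
    plus ``promoter_len``. ``feature_lengths`` (feature -> total bp) enables
    the per-feature table; when omitted it is derived from the models.
    Sites are de-duplicated by (chrom, pos) before counting so split
    multiallelic records do not double-count.
    """
    seen: set[tuple[str, int]] = set()
    gene_counts: dict[str, int] = {g.gene_id: 0 for g in genes}
    feat_counts: dict[str, int] = {}
    for row in annotations:
        key = (row["chrom"], row["pos"])
        if key in seen:
            continue
        seen.add(key)
        if row["gene"] in gene_counts:
            gene_counts[row["gene"]] += 1
        feat_counts[row["feature"]] = feat_counts.get(row["feature"], 0) + 1

    per_gene = []
    for g in genes:
        analyzed = (g.end - g.start) + promoter_len
        n = gene_counts[g.gene_id]
        per_gene.append({
            "gene": g.gene_id, "n_snps": n, "analyzed_bp": analyzed,
            "bp_per_snp": bp_per_snp(n, analyzed),
        })

    if feature_lengths is None:
        feature_lengths = feature_lengths_from_models(genes, promoter_len)
    per_feature = []
    for feat, length in feature_lengths.items():
        n = feat_counts.get(feat, 0)
        per_feature.append({
            "feature": feat, "n_snps": n, "feature_bp": length,
            "bp_per_snp": bp_per_snp(n, length) if length > 0 else None,
        })
    return per_gene, per_feature


def feature_lengths_from_models(genes: list[GeneModel],
                                promoter_len: int = 2000) -> dict[str, int]:
    """Total bp per feature class across gene models (upstream = promoter_len each)."""
    out = {"CDS": 0, "utr5": 0, "utr3": 0, "intron": 0, "upstream": 0}
    for g in genes:
        cds = sum(e - s for s, e, _ in g.cds_segments)
        u5 = sum(e - s for s, e in g.utr5)
        u3 = sum(e - s for s, e in g.utr3)
        exon = sum(e - s for s, e in g.exons)
        out["CDS"] += cds
        out["utr5"] += u5
        out["utr3"] += u3
        out["intron"] += (g.end - g.start) - exon
        out["upstream"] += promoter_len
    return out


def private_variants(matrix: GenotypeMatrix,
                     sample_annotations: dict[str, str] | None = None) -> list[dict]:
    """Loci whose minor allele is carried by exactly one accession.

    The minor allele at a locus is the rarer of ref/alt over non-missing
    calls; a carrier holds >= 1 copy of it (het or hom). Missing calls are
    excluded from both frequency and carrier determination.
    """
    rows = []
    d = matrix.dosages
    for j, v in enumerate(matrix.loci):
        col = d[:, j]
        valid = col != MISSING
        if not valid.any():
            continue
        alt_copies = int(col[valid].sum())
        total = 2 * int(valid.sum())
        minor_is_alt = alt_copies <= total - alt_copies
        if minor_is_alt:
            carriers = np.flatnonzero(valid & (col >= 1))
        else:
            carriers = np.flatnonzero(valid & (col <= 1))
        if len(carriers) == 1 and alt_copies not in (0, total):
            sample = matrix.samples[int(carriers[0])]
            rows.append({
                "chrom": v.chrom, "pos": v.source_pos, "ref": v.ref, "alt": v.alt,
                "sample": sample,
                "status": (sample_annotations or {}).get(sample, "."),
            })
    return rows


def per_accession_counts(matrix: GenotypeMatrix) -> dict[str, int]:
    """Per-sample count of loci carrying any non-reference allele (dosage >= 1)."""
    carrier = matrix.dosages >= 1  # MISSING (-1) excluded automatically
    counts = carrier.sum(axis=1)
    return {s: int(c) for s, c in zip(matrix.samples, counts)}


@dataclass
class DiversitySummary:
    """Combined diversity accounting for a filtered panel."""

    n_sites_total: int
    per_gene: list[dict]
    per_feature: list[dict]
    ts_fraction: float
    per_accession: dict[str, int]
    private: list[dict]
    maf_spectrum: dict = field(default_factory=dict)
    overall_bp_per_snp: int | None = None
    analyzed_bp_total: int = 0

    def to_dict(self) -> dict:
        return {
            "n_sites_total": self.n_sites_total,
            "overall_bp_per_snp": self.overall_bp_per_snp,
            "analyzed_bp_total": self.analyzed_bp_total,
            "ts_fraction": self.ts_fraction,
            "per_gene": self.per_gene,
            "per_feature": self.per_feature,
            "per_accession": self.per_accession,
            "private": self.private,
            "maf_spectrum": self.maf_spectrum,
        }


def summarize(matrix: GenotypeMatrix, annotations: list[dict],
              genes: list[GeneModel], promoter_len: int = 2000,
              sample_annotations: dict[str, str] | None = None,
              maf_bins: int = 10) -> DiversitySummary:
    """Full diversity summary of a (filtered) genotype matrix.

    ``annotations`` must be row-aligned with ``matrix.loci``. Site totals
    de-duplicate split multiallelic records by (chrom, pos).
    """
    if len(annotations) != matrix.n_loci:
        raise ValueError("annotations not aligned with matrix loci")
    site_idx = _dedup_sites(matrix.loci)
    per_gene, per_feature = snp_density(annotations, genes, promoter_len=promoter_len)
    analyzed_total = sum(r["analyzed_bp"] for r in per_gene)
    n_sites = len(site_idx)
    maf = matrix.maf()
    hist, edges = np.histogram(maf[~np.isnan(maf)], bins=maf_bins, range=(0.0, 0.5))
    return DiversitySummary(
        n_sites_total=n_sites,
        per_gene=per_gene,
        per_feature=per_feature,
        ts_fraction=ts_fraction(matrix.loci),
        per_accession=per_accession_counts(matrix),
        private=private_variants(matrix, sample_annotations),
        maf_spectrum={
            "bin_edges": [round(float(e), 3) for e in edges],
            "counts": [int(c) for c in hist],
        },
        overall_bp_per_snp=bp_per_snp(n_sites, analyzed_total) if analyzed_total else None,
        analyzed_bp_total=analyzed_total,
    )
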