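"""End-to-end orchestration: family -> motifs -> effects -> diversity ->
structure (-> expression), with TSV/JSON/Newick outputs.

Each stage writes its own table once (write-once outputs; no stage mutates
another stage's inputs); a top-level ``summary.json`` combines the key
numbers, and ``run.log`` records versions, seed and thresholds.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import diversity as _dv
from . import effects as _fx
from . import expression as _ex
from . import family as _fam
from . import motifs as _mot
from . import popstruct as _ps
from .io import read_fasta, read_gff3, read_vcf
from .motifs import P1BS_PATTERN

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run."""

    fasta: Path
    gff3: Path
    vcf: Path
    outdir: Path
    ct_table: Path | None = None
    sample_annotations: Path | None = None  # TSV: sample, status
    tandem_window: int = 200_000
    min_identity: float = 90.0
    maf_min: float = 0.01
    max_missing: float = 0.10
    promoter_len: int = 2000
    motif_pattern: str = P1BS_PATTERN
    reference_genes: tuple = ("actin", "ef1a")
    calibrator_group: str = "control"
    seed: int = 0


def _write_tsv(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "thresholds": {
        "tandem_window": config.tandem_window, "min_identity": config.min_identity,
        "maf_min": config.maf_min, "max_missing": config.max_missing,
        "promoter_len": config.promoter_len, "motif_pattern": config.motif_pattern,
    }}
    log_lines = [
        f"famdiv {__version__} (python {sys.version.split()[0]})",
        f"seed={config.seed}",
        f"thresholds={summary['thresholds']}",
    ]

    stage = "annotation_io"
    try:
        genome = read_fasta(config.fasta)
        models = read_gff3(config.gff3)
        matrix = read_vcf(config.vcf)

        stage = "family_structure"
        cds = {m.gene_id: m.spliced_cds(genome) for m in models}
        identity = _fam.pairwise_identity(cds)
        coords = {m.gene_id: (m.chrom, m.start, m.end) for m in models}
        calls = _fam.classify_family(identity, coords,
                                     tandem_window=config.tandem_window,
                                     min_identity=config.min_identity)
        _write_tsv(_fam.calls_to_rows(calls), out / "family.tsv")
        groups = _fam.cluster_paralogs(identity, config.min_identity)
        summary["family"] = {
            "n_genes": len(models),
            "paralog_groups": groups,
            "n_tandem_pairs": sum(c.relation == "tandem" for c in calls),
            "n_segmental_pairs": sum(c.relation == "segmental" for c in calls),
        }

        stage = "promoter_motifs"
        motif_rows, motif_intervals = _mot.scan_promoters(
            models, genome, config.motif_pattern, config.promoter_len)
        _write_tsv(motif_rows, out / "motifs.tsv")
        summary["motifs"] = {
            "pattern": config.motif_pattern,
            "sites_per_gene": {m.gene_id: len(motif_intervals[m.gene_id])
                               for m in models},
        }

        stage = "diversity_filter"
        filtered = _dv.filter_variants(matrix, config.maf_min, config.max_missing)

        stage = "variant_effects"
        annotations = _fx.annotate_variants(filtered.loci, models, genome,
                                            motif_intervals, config.promoter_len)
        _write_tsv(annotations, out / "effects.tsv")

        stage = "diversity"
        sample_ann = None
        if config.sample_annotations:
            df = pd.read_csv(config.sample_annotations, sep="\t")
            sample_ann = dict(zip(df["sample"], df["status"]))
        div = _dv.summarize(filtered, annotations, models,
                            promoter_len=config.promoter_len,
                            sample_annotations=sample_ann)
        _write_tsv(div.per_gene, out / "diversity_per_gene.tsv")
        _write_tsv(div.per_feature, out / "diversity_per_feature.tsv")
        _write_tsv([{"sample": s, "n_polymorphic": c}
                    for s, c in div.per_accession.items()],
                   out / "diversity_per_accession.tsv")
        _write_tsv(div.private, out / "private_variants.tsv")
        (out / "diversity.json").write_text(json.dumps(div.to_dict(), indent=1))
        summary["diversity"] = {
            "n_sites_pre_filter": matrix.n_loci,
            "n_sites_total": div.n_sites_total,
            "overall_bp_per_snp": div.overall_bp_per_snp,
            "ts_fraction": div.ts_fraction,
            "n_private": len(div.private),
            "n_amino_acid_changing": sum(
                r["consequence"] in ("missense", "nonsense", "stoploss")
                for r in annotations),
        }

        stage = "popstruct"
        dist = _ps.euclidean_distances(filtered)
        pd.DataFrame(dist.d, index=dist.ids, columns=dist.ids).to_csv(
            out / "distances.tsv", sep="\t")
        tree = _ps.neighbor_joining(dist)
        (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
        ord_res = _ps.pcoa(dist)
        coords_df = pd.DataFrame(
            ord_res.coordinates, index=ord_res.ids,
            columns=[f"axis{i + 1}" for i in range(ord_res.coordinates.shape[1])])
        coords_df.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        _write_tsv([{"axis": i + 1, "eigenvalue": float(ev),
                     "variance_fraction": float(vf)}
                    for i, (ev, vf) in enumerate(
                        zip(ord_res.eigenvalues, ord_res.variance_fraction))],
                   out / "pcoa_eigenvalues.tsv")
        summary["popstruct"] = {
            "n_samples": len(dist.ids),
            "pcoa_axis1_variance": float(ord_res.variance_fraction[0]),
            "pcoa_axis2_variance": float(ord_res.variance_fraction[1])
            if len(ord_res.variance_fraction) > 1 else None,
        }

        if config.ct_table is not None:
            stage = "expression_ddct"
            ct = _ex.load_ct_table(config.ct_table)
            targets = sorted(set(ct["gene"]) - set(config.reference_genes))
            results = _ex.relative_expression(ct, targets,
                                              list(config.reference_genes),
                                              config.calibrator_group)
            _write_tsv(_ex.results_to_rows(results), out / "expression.tsv")
            summary["expression"] = {
                "targets": targets,
                "n_panels": len(results),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
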