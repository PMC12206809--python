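"""Synthetic genomes, annotations, variant panels and qPCR Ct tables with
known truth.

The generator emulates the study design of a gene-family diversity survey
in a large-genome cereal: a phosphate-transporter-like family with a
tandem cluster (pairs within the tandem window at high identity) plus
cross-chromosome segmental duplicates; 2-kb promoters with 0-3 planted
P1BS elements; a 94-accession biallelic SNP panel (with a configurable
handful of triallelic loci) with a controlled MAF spectrum, bounded
missingness, ~54% transitions, planted private variants and planted
nonsynonymous CDS changes; and Ct tables for 2 tissues x 2 timepoints x
2 treatments x 3 biological x 2 technical replicates with 2 reference
genes. Every planted fact is recorded in a :class:`TruthSet` resolvable
against the emitted FASTA/GFF3/VCF coordinates, and identical seeds give
byte-identical outputs.

Post-processing guarantees exact truth recovery: accidental motif sites in
promoters are scrubbed, and loci that would be accidentally private get a
second carrier.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import family as _family
from .io import (GeneModel, SequenceRecord, VariantRecord, reverse_complement,
                 write_fasta, write_gff3, write_vcf)
from .motifs import P1BS_PATTERN, _IUPAC_SETS, extract_promoter, scan_motif
from .effects import translate_codon

__all__ = [
    "CtDesign", "SimulationConfig", "TruthSet",
    "simulate_reference", "simulate_variants", "simulate_ct",
    "simulate_bundle", "write_bundle",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# per-feature SNP placement weights, mirroring the observed density ordering
# introns > CDS > UTRs (bp-per-SNP 128 / 187 / 297)
_FEATURE_WEIGHTS = {"intron": 1 / 128, "CDS": 1 / 187,
                    "utr5": 1 / 297, "utr3": 1 / 297, "upstream": 1 / 250}


@dataclass
class CtDesign:
    """Design of the simulated qPCR experiment.

    ``fold_changes`` maps (gene, tissue, timepoint) to the true expression
    fold of the deficient treatment relative to control; ``None`` marks a
    gene not detected in that tissue/timepoint (emitted as empty Ct). The
    default pattern mirrors a phosphate-starvation trial: one induced
    target, one repressed target absent from roots, one late-root-induced
    target.
    """

    tissues: tuple = ("leaf", "root")
    timepoints: tuple = (14, 21)
    treatments: tuple = ("deficient", "control")
    n_bio: int = 3
    n_tech: int = 2
    sigma: float = 0.2
    reference_genes: dict = field(default_factory=lambda: {"actin": 19.0, "ef1a": 21.0})
    target_baselines: dict = field(
        default_factory=lambda: {"pht_induced": 24.0, "pht_repressed": 23.0,
                                 "pht_late": 26.0})
    fold_changes: dict = field(default_factory=lambda: {
        ("pht_induced", "leaf", 14): 4.0, ("pht_induced", "leaf", 21): 3.0,
        ("pht_induced", "root", 14): 4.0, ("pht_induced", "root", 21): 4.0,
        ("pht_repressed", "leaf", 14): 0.25, ("pht_repressed", "leaf", 21): 0.3,
        ("pht_repressed", "root", 14): None, ("pht_repressed", "root", 21): None,
        ("pht_late", "leaf", 14): 1.0, ("pht_late", "leaf", 21): 1.0,
        ("pht_late", "root", 14): 1.0, ("pht_late", "root", 21): 2.5,
    })


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 400_000
    family_size: int = 10
    tandem_cluster_size: int = 4
    tandem_gap_bp: int = 25_000
    tandem_identity: float = 96.5
    segmental_pairs: int = 2
    segmental_identity: float = 92.0
    promoter_len: int = 2000
    motif_pattern: str = P1BS_PATTERN
    promoter_motif_counts: tuple | None = None  # default cycles (2,1,0,3)
    n_samples: int = 94
    n_snps: int = 220
    maf_beta: tuple = (0.5, 5.0)
    maf_clip: tuple = (0.02, 0.5)
    missing_rate: float = 0.05
    ts_fraction: float = 0.54
    n_private: int = 11
    n_multiallelic: int = 2
    n_nonsynonymous: int = 12
    n_subpopulations: int = 0  # 0 = unstructured (Hardy-Weinberg) panel
    subpop_fst: float = 0.2
    ct_design: CtDesign = field(default_factory=CtDesign)

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 0.10:
            raise ValueError("missing_rate must be in [0, 0.10)")
        if self.family_size < self.tandem_cluster_size + 2 * self.segmental_pairs:
            raise ValueError("family_size too small for the requested cluster/pairs")
        if self.n_chromosomes < 3:
            raise ValueError("need >= 3 chromosomes for the default layout")


@dataclass
class TruthSet:
    """Everything the generator planted, keyed by emitted coordinates."""

    gene_roles: dict = field(default_factory=dict)  # gene -> role string
    paralog_groups: list = field(default_factory=list)
    tandem_pairs: list = field(default_factory=list)  # sorted (a, b) tuples
    segmental_pairs: list = field(default_factory=list)
    configured_identity: dict = field(default_factory=dict)  # (a,b) -> target %
    realized_identity: dict = field(default_factory=dict)
    motif_plants: dict = field(default_factory=dict)  # gene -> [(offset, strand, seq)]
    variant_features: dict = field(default_factory=dict)  # (chrom,pos0) -> (feature, gene)
    nonsyn_truth: dict = field(default_factory=dict)  # (chrom,pos0,alt) -> aa_change
    private_truth: dict = field(default_factory=dict)  # (chrom,pos0) -> sample
    multiallelic_sites: list = field(default_factory=list)  # (chrom, pos0)
    allele_freqs: dict = field(default_factory=dict)  # (chrom,pos0,alt) -> drawn q
    sample_status: dict = field(default_factory=dict)  # sample -> improvement status
    subpop_labels: dict = field(default_factory=dict)  # sample -> subpop index
    ct_fold_changes: dict = field(default_factory=dict)  # (gene,tissue,tp) -> fold|None

    def to_json(self, path) -> None:
        def key_str(d, joiner="|"):
            return {joiner.join(map(str, k)) if isinstance(k, tuple) else str(k): v
                    for k, v in d.items()}
        payload = {
            "gene_roles": self.gene_roles,
            "paralog_groups": self.paralog_groups,
            "tandem_pairs": [list(p) for p in self.tandem_pairs],
            "segmental_pairs": [list(p) for p in self.segmental_pairs],
            "configured_identity": key_str(self.configured_identity),
            "realized_identity": key_str(self.realized_identity),
            "motif_plants": self.motif_plants,
            "variant_features": key_str(self.variant_features),
            "nonsyn_truth": key_str(self.nonsyn_truth),
            "private_truth": key_str(self.private_truth),
            "multiallelic_sites": [list(p) for p in self.multiallelic_sites],
            "allele_freqs": key_str(self.allele_freqs),
            "sample_status": self.sample_status,
            "subpop_labels": self.subpop_labels,
            "ct_fold_changes": key_str(self.ct_fold_changes),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# reference genome + annotation
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


@dataclass
class _SenseGene:
    """A gene in sense (5'->3') coordinates before genomic placement."""

    seq: str
    utr5: tuple[int, int]
    utr3: tuple[int, int]
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]  # transcription order, sense coords


def _make_sense_gene(rng) -> _SenseGene:
    utr5_len = int(rng.integers(100, 200))
    utr3_len = int(rng.integers(150, 250))
    n_codons = int(rng.integers(300, 500))
    codons = []
    stops = {"TAA", "TAG", "TGA"}
    while len(codons) < n_codons - 2:
        c = _arr_to_str(_random_seq(rng, 3))
        if c not in stops:
            codons.append(c)
    cds = "ATG" + "".join(codons) + ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    cds_len = len(cds)
    # split CDS across three exons
    b1 = int(rng.integers(cds_len // 5, cds_len // 3))
    b2 = int(rng.integers(cds_len // 2, 4 * cds_len // 5))
    seg_lens = [b1, b2 - b1, cds_len - b2]
    intron_lens = [int(rng.integers(200, 600)) for _ in range(2)]
    introns = [_arr_to_str(_random_seq(rng, n)) for n in intron_lens]
    utr5 = _arr_to_str(_random_seq(rng, utr5_len))
    utr3 = _arr_to_str(_random_seq(rng, utr3_len))

    seq = utr5 + cds[:b1] + introns[0] + cds[b1:b2] + introns[1] + cds[b2:] + utr3
    p = 0
    utr5_iv = (p, p + utr5_len); p += utr5_len
    cds_ivs, exon_ivs = [], []
    exon1_start = 0
    cds_ivs.append((p, p + seg_lens[0])); p += seg_lens[0]
    exon_ivs.append((exon1_start, p))
    p += intron_lens[0]
    cds_ivs.append((p, p + seg_lens[1]))
    exon_ivs.append((p, p + seg_lens[1]))
    p += seg_lens[1] + intron_lens[1]
    cds_ivs.append((p, p + seg_lens[2])); p += seg_lens[2]
    utr3_iv = (p, p + utr3_len)
    exon_ivs.append((cds_ivs[2][0], utr3_iv[1]))
    return _SenseGene(seq, utr5_iv, utr3_iv, exon_ivs, cds_ivs)


def _mutate(rng, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return _arr_to_str(arr)


def _mutated_copy(rng, sense: "_SenseGene", rate: float) -> "_SenseGene":
    """A paralog copy mutated at ``rate`` but keeping start and stop codons."""
    seq = list(_mutate(rng, sense.seq, rate))
    first = sense.cds[0]
    last = sense.cds[-1]
    seq[first[0]:first[0] + 3] = sense.seq[first[0]:first[0] + 3]
    seq[last[1] - 3:last[1]] = sense.seq[last[1] - 3:last[1]]
    return dataclasses.replace(sense, seq="".join(seq))


def _place(sense: _SenseGene, gene_id: str, chrom: str, start: int,
           strand: str) -> GeneModel:
    L = len(sense.seq)

    def conv(iv):
        a, b = iv
        if strand == "+":
            return (start + a, start + b)
        return (start + L - b, start + L - a)

    cds_tx = [conv(iv) for iv in sense.cds]  # transcription order
    phases = []
    cum = 0
    for a, b in cds_tx:
        phases.append((3 - cum % 3) % 3)
        cum += b - a
    cds_segments = sorted(
        (a, b, ph) for (a, b), ph in zip(cds_tx, phases)
    )
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        start=start, end=start + L,
        exons=[conv(iv) for iv in sense.exons],
        cds_segments=cds_segments,
        utr5=[conv(sense.utr5)],
        utr3=[conv(sense.utr3)],
    )


def _expand_iupac(rng, pattern: str) -> str:
    return "".join(
        _IUPAC_SETS[c][int(rng.integers(len(_IUPAC_SETS[c])))] for c in pattern
    )


def _forbidden_bases(pattern: str) -> list[list[str]]:
    """Per position, bases that break both forward and reverse matching.

    A window matches forward iff window[k] is in the pattern-k set, and
    reverse iff window[k] is the complement of a base in the pattern set at
    the mirrored position m-1-k; a base outside both sets kills the site.
    """
    m = len(pattern)
    out = []
    for k in range(m):
        fwd = set(_IUPAC_SETS[pattern[k]])
        rev = {_COMPLEMENT[b] for b in _IUPAC_SETS[pattern[m - 1 - k]]}
        out.append([b for b in "ACGT" if b not in fwd | rev])
    return out


def simulate_reference(config: SimulationConfig, rng=None):
    """Generate genome FASTA + gene models + truth for the family layout.

    Returns ``(genome, models, truth)`` where genome maps chromosome id to
    :class:`SequenceRecord`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_arrays = {c: _random_seq(rng, config.chrom_length_bp) for c in chrom_ids}

    n_cluster = config.tandem_cluster_size
    n_seg = config.segmental_pairs
    gene_ids = [f"pht{i + 1:02d}" for i in range(config.family_size)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(config.family_size)]

    placements: list[tuple[str, str, int, str, _SenseGene]] = []

    # tandem cluster on chr1
    cluster_source = _make_sense_gene(rng)
    r_tandem = (100.0 - config.tandem_identity) / 100.0
    pos = 50_000
    cluster_ids = gene_ids[:n_cluster]
    for i, gid in enumerate(cluster_ids):
        sense = (cluster_source if i == 0
                 else _mutated_copy(rng, cluster_source, r_tandem))
        placements.append((gid, chrom_ids[0], pos, strands[gene_ids.index(gid)], sense))
        pos += len(sense.seq) + config.tandem_gap_bp
        if i > 0:
            truth.configured_identity[(cluster_ids[0], gid)] = config.tandem_identity
    for i in range(n_cluster):
        for j in range(i + 1, n_cluster):
            truth.tandem_pairs.append((cluster_ids[i], cluster_ids[j]))

    # segmental pairs: source on chr2, copy on chr3
    r_seg = (100.0 - config.segmental_identity) / 100.0
    seg_positions_src = [50_000 + k * 100_000 for k in range(n_seg)]
    seg_positions_cpy = [60_000 + k * 100_000 for k in range(n_seg)]
    idx = n_cluster
    for k in range(n_seg):
        src_id, cpy_id = gene_ids[idx], gene_ids[idx + 1]
        idx += 2
        src = _make_sense_gene(rng)
        cpy = _mutated_copy(rng, src, r_seg)
        placements.append((src_id, chrom_ids[1], seg_positions_src[k],
                           strands[gene_ids.index(src_id)], src))
        placements.append((cpy_id, chrom_ids[2], seg_positions_cpy[k],
                           strands[gene_ids.index(cpy_id)], cpy))
        truth.segmental_pairs.append((src_id, cpy_id))
        truth.configured_identity[(src_id, cpy_id)] = config.segmental_identity

    # unrelated singletons, alternating chr2/chr3 beyond the pairs
    extra = gene_ids[idx:]
    for k, gid in enumerate(extra):
        chrom = chrom_ids[1 + k % 2]
        pos = 50_000 + (n_seg + k // 2 + 1) * 100_000
        placements.append((gid, chrom, pos, strands[gene_ids.index(gid)],
                           _make_sense_gene(rng)))

    models: list[GeneModel] = []
    for gid, chrom, start, strand, sense in placements:
        seq = sense.seq if strand == "+" else reverse_complement(sense.seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if start + len(arr) + config.promoter_len >= config.chrom_length_bp:
            raise ValueError(f"gene {gid} does not fit on {chrom}")
        chrom_arrays[chrom][start:start + len(arr)] = arr
        models.append(_place(sense, gid, chrom, start, strand))

    truth.gene_roles = {
        **{g: "tandem_cluster" for g in cluster_ids},
        **{g: "segmental" for pair in truth.segmental_pairs for g in pair},
        **{g: "unrelated" for g in extra},
    }
    truth.paralog_groups = [list(cluster_ids)] + [list(p) for p in truth.segmental_pairs]

    # plant promoter motifs, then scrub accidental sites
    counts_cycle = config.promoter_motif_counts or (2, 1, 0, 3)
    genome = {c: SequenceRecord(c, _arr_to_str(a)) for c, a in chrom_arrays.items()}
    models_by_id = {m.gene_id: m for m in models}
    for i, gid in enumerate(gene_ids):
        n_motifs = counts_cycle[i % len(counts_cycle)]
        model = models_by_id[gid]
        promoter = extract_promoter(model, genome, config.promoter_len)
        prom = list(promoter.seq)
        m = len(config.motif_pattern)
        offsets: list[int] = []
        plants = []
        attempts = 0
        while len(offsets) < n_motifs:
            off = int(rng.integers(0, len(prom) - m + 1))
            if all(abs(off - o) >= m for o in offsets):
                inst = _expand_iupac(rng, config.motif_pattern)
                strand = "+" if len(offsets) % 2 == 0 else "-"
                window = inst if strand == "+" else reverse_complement(inst)
                prom[off:off + m] = list(window)
                offsets.append(off)
                plants.append((off, strand, window))
            attempts += 1
            if attempts > 1000:
                raise RuntimeError("could not place promoter motifs")
        # scrub accidental sites to a fixpoint
        planted = set(offsets)
        protected = {p for o in planted for p in range(o, o + m)}
        forbidden = _forbidden_bases(config.motif_pattern)
        for _ in range(30):
            hits = scan_motif("".join(prom), config.motif_pattern)
            accidental = sorted({h.offset for h in hits} - planted)
            if not accidental:
                break
            for off in accidental:
                for k in range(m):
                    if off + k not in protected and forbidden[k]:
                        b = forbidden[k][int(rng.integers(len(forbidden[k])))]
                        prom[off + k] = b
                        break
                else:
                    raise RuntimeError("accidental motif fully inside planted site")
        else:
            raise RuntimeError("motif scrubbing did not converge")
        truth.motif_plants[gid] = sorted(plants)
        # write the oriented promoter back into the genome
        prom_str = "".join(prom)
        arr = chrom_arrays[model.chrom]
        if model.strand == "+":
            region = prom_str
        else:
            region = reverse_complement(prom_str)
        arr[promoter.start:promoter.end] = np.frombuffer(region.encode(), dtype=np.uint8)
        genome[model.chrom] = SequenceRecord(model.chrom, _arr_to_str(arr))

    # realized identities over spliced CDS for the configured pairs
    for (a, b), target in truth.configured_identity.items():
        truth.realized_identity[(a, b)] = _family.global_align_identity(
            models_by_id[a].spliced_cds(genome), models_by_id[b].spliced_cds(genome))
    return genome, models, truth


# ---------------------------------------------------------------------------
# variant panel
# ---------------------------------------------------------------------------

def _candidate_positions(models: list[GeneModel], promoter_len: int):
    """(chrom, pos, feature, gene) for every analyzable position."""
    cands: dict[tuple[str, int], tuple[str, str]] = {}
    rank = {"CDS": 0, "utr5": 1, "utr3": 1, "intron": 2, "upstream": 3}
    for g in models:
        segs: list[tuple[int, int, str]] = []
        segs += [(s, e, "CDS") for s, e, _ in g.cds_segments]
        segs += [(s, e, "utr5") for s, e in g.utr5]
        segs += [(s, e, "utr3") for s, e in g.utr3]
        exon_pos = set()
        for s, e in g.exons:
            exon_pos.update(range(s, e))
        if g.strand == "+":
            segs.append((g.start - promoter_len, g.start, "upstream"))
        else:
            segs.append((g.end, g.end + promoter_len, "upstream"))
        covered = set()
        for s, e, feat in segs:
            for p in range(s, e):
                covered.add(p)
                key = (g.chrom, p)
                if key not in cands or rank[feat] < rank[cands[key][0]]:
                    cands[key] = (feat, g.gene_id)
        for p in range(g.start, g.end):
            if p not in covered and p not in exon_pos:
                key = (g.chrom, p)
                if key not in cands or rank["intron"] < rank[cands[key][0]]:
                    cands[key] = ("intron", g.gene_id)
    return cands


def _draw_alt(rng, ref: str, ts_target: float) -> tuple[str, bool]:
    is_ts = bool(rng.random() < ts_target)
    if is_ts:
        return _TRANSITION[ref], True
    tv = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return tv[int(rng.integers(2))], False


def _missense_alt(rng, gene: GeneModel, genome, pos: int, ts_target: float):
    """Alt allele at a CDS position that changes the amino acid, or None."""
    cds = gene.spliced_cds(genome)
    off = gene.cds_offset(pos)
    codon_i, within = off // 3, off % 3
    codon = cds[codon_i * 3: codon_i * 3 + 3]
    if len(codon) < 3 or translate_codon(codon) == "*":
        return None
    ref_tx = codon[within]
    options = []
    for alt_tx in "ACGT":
        if alt_tx == ref_tx:
            continue
        alt_codon = codon[:within] + alt_tx + codon[within + 1:]
        aa_ref, aa_alt = translate_codon(codon), translate_codon(alt_codon)
        if aa_ref != aa_alt and aa_alt != "*":
            options.append((alt_tx, f"{aa_ref}{codon_i + 1}{aa_alt}"))
    if not options:
        return None
    preferred = _TRANSITION[ref_tx] if rng.random() < ts_target else None
    for alt_tx, aa in options:
        if alt_tx == preferred:
            choice = (alt_tx, aa)
            break
    else:
        choice = options[int(rng.integers(len(options)))]
    alt_tx, aa = choice
    ref_genomic = genome[gene.chrom].seq[pos]
    alt_genomic = alt_tx if gene.strand == "+" else _COMPLEMENT[alt_tx]
    assert (ref_tx if gene.strand == "+" else _COMPLEMENT[ref_tx]) == ref_genomic
    return alt_genomic, aa


def _improvement_statuses(rng, samples: list[str]) -> dict[str, str]:
    """Assign wild/landrace/cultivar labels (~30/40/24 of a 94 panel)."""
    n = len(samples)
    n_wild = round(n * 30 / 94)
    n_land = round(n * 40 / 94)
    labels = (["wild"] * n_wild + ["landrace"] * n_land
              + ["cultivar"] * (n - n_wild - n_land))
    rng.shuffle(labels)
    return dict(zip(samples, labels))


def simulate_variants(genome, models, truth: TruthSet, config: SimulationConfig,
                      rng=None):
    """Generate the SNP panel; returns (sites, samples) for VCF writing.

    ``sites`` is a list of ``(chrom, pos0, ref, alts, pairs)`` sorted by
    position, ``pairs`` an (n_samples, 2) allele-index array with -1 for
    missing. Truth additions are recorded in ``truth`` in place.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    samples = [f"acc{i + 1:03d}" for i in range(config.n_samples)]
    truth.sample_status = _improvement_statuses(rng, samples)

    if config.n_subpopulations > 1:
        labels = np.sort(np.arange(config.n_samples) % config.n_subpopulations)
        truth.subpop_labels = {s: int(l) for s, l in zip(samples, labels)}
    else:
        labels = None

    cands = _candidate_positions(models, config.promoter_len)
    keys = sorted(cands)
    feats = [cands[k][0] for k in keys]
    if config.n_snps > len(keys):
        raise ValueError(f"n_snps={config.n_snps} exceeds {len(keys)} candidate positions")

    used: set[tuple[str, int]] = set()

    def sample_from(pool_keys, n):
        pool = [k for k in pool_keys if k not in used]
        chosen = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
        used.update(chosen)
        return chosen

    cds_keys = [k for k, f in zip(keys, feats) if f == "CDS"]
    noncds_keys = [k for k, f in zip(keys, feats) if f in ("utr5", "utr3", "intron")]
    neutral_keys = [k for k, f in zip(keys, feats) if f in ("intron", "upstream")]

    # planted nonsynonymous CDS changes (rejected candidates stay excluded
    # from later sampling but never enter the panel)
    nonsyn_sites = []
    nonsyn_alt = {}
    while len(nonsyn_sites) < config.n_nonsynonymous:
        (chrom, pos), = sample_from(cds_keys, 1)
        gene = next(m for m in models if m.gene_id == cands[(chrom, pos)][1])
        res = _missense_alt(rng, gene, genome, pos, config.ts_fraction)
        if res is None:
            continue
        alt, aa = res
        nonsyn_sites.append((chrom, pos))
        nonsyn_alt[(chrom, pos)] = alt
        truth.nonsyn_truth[(chrom, pos, alt)] = aa

    private_keys = sample_from(noncds_keys, config.n_private)
    multi_keys = sample_from(neutral_keys, config.n_multiallelic)
    n_rest = config.n_snps - config.n_nonsynonymous - config.n_private - config.n_multiallelic
    pool = [k for k in keys if k not in used]
    w = np.array([_FEATURE_WEIGHTS[cands[k][0]] for k in pool])
    rest_keys = [pool[i] for i in rng.choice(len(pool), size=n_rest, replace=False,
                                             p=w / w.sum())]
    used.update(rest_keys)
    chosen = set(nonsyn_sites) | set(private_keys) | set(multi_keys) | set(rest_keys)

    def draw_q():
        a, b = config.maf_beta
        lo, hi = config.maf_clip
        return float(np.clip(rng.beta(a, b), lo, hi))

    def hw_dosages(q):
        if labels is None:
            return rng.binomial(2, q, size=config.n_samples).astype(np.int16)
        f = config.subpop_fst
        out = np.empty(config.n_samples, dtype=np.int16)
        for k in range(config.n_subpopulations):
            qk = float(np.clip(rng.beta(q * (1 - f) / f, (1 - q) * (1 - f) / f),
                               0.0, 1.0))
            mask = labels == k
            out[mask] = rng.binomial(2, qk, size=int(mask.sum()))
        return out

    # status-stratified carriers for the private variants (6 wild / 4
    # landrace / 1 cultivar when n_private is 11, else proportional)
    by_status = {"wild": [], "landrace": [], "cultivar": []}
    for s in samples:
        by_status[truth.sample_status[s]].append(s)
    quota = (["wild"] * 6 + ["landrace"] * 4 + ["cultivar"] * 1
             if config.n_private == 11 else
             [("wild", "landrace", "cultivar")[i % 3] for i in range(config.n_private)])
    private_carriers = [
        by_status[st][int(rng.integers(len(by_status[st])))] for st in quota
    ]

    sites = []
    for chrom, pos in sorted(chosen):
        ref = genome[chrom].seq[pos]
        feature, gene_id = cands[(chrom, pos)]
        truth.variant_features[(chrom, pos)] = (feature, gene_id)
        key = (chrom, pos)
        pairs = np.zeros((config.n_samples, 2), dtype=np.int16)

        if key in multi_keys:
            alt_ts = _TRANSITION[ref]
            tv = [b for b in "ACGT" if b not in (ref, alt_ts)]
            alts = [alt_ts, tv[int(rng.integers(2))]]
            q1, q2 = 0.2, 0.1
            for i in range(config.n_samples):
                pairs[i] = sorted(rng.choice([0, 1, 2], size=2,
                                             p=[1 - q1 - q2, q1, q2]))
            truth.allele_freqs[(chrom, pos, alts[0])] = q1
            truth.allele_freqs[(chrom, pos, alts[1])] = q2
            truth.multiallelic_sites.append(key)
        elif key in private_keys:
            alt, _ = _draw_alt(rng, ref, config.ts_fraction)
            alts = [alt]
            carrier = private_carriers[private_keys.index(key)]
            pairs[samples.index(carrier)] = (1, 1)  # hom-alt: MAF 2/(2n) > 0.01
            truth.private_truth[key] = carrier
            truth.allele_freqs[(chrom, pos, alt)] = 1.0 / config.n_samples
        else:
            if key in nonsyn_alt:
                alt = nonsyn_alt[key]
            else:
                alt, _ = _draw_alt(rng, ref, config.ts_fraction)
            alts = [alt]
            q = draw_q()
            truth.allele_freqs[(chrom, pos, alt)] = q
            dos = hw_dosages(q)
            pairs[dos == 1] = (0, 1)
            pairs[dos == 2] = (1, 1)
            miss = rng.random(config.n_samples) < config.missing_rate
            pairs[miss] = (-1, -1)
        sites.append((chrom, pos, ref, alts, pairs))

    _fix_accidental_privates(rng, sites, set(truth.private_truth))
    return sites, samples


def _fix_accidental_privates(rng, sites, private_keys):
    """Give a second carrier to any allele carried by exactly one accession.

    Keeps the planted private set exact: every minor allele outside the
    planted loci ends up in >= 2 carriers (or 0). Homozygous recruits are
    preferred so no other allele loses a carrier; iterated to a fixpoint.
    """
    for _ in range(20):
        changed = False
        for chrom, pos, ref, alts, pairs in sites:
            if (chrom, pos) in private_keys:
                continue
            valid = (pairs >= 0).all(axis=1)
            n_valid = int(valid.sum())
            for allele in range(len(alts) + 1):
                copies = (pairs[valid] == allele).sum()
                if copies == 0 or copies > 2 * n_valid - copies:
                    continue  # absent, or the major allele
                carriers = np.flatnonzero(valid & (pairs == allele).any(axis=1))
                if len(carriers) != 1:
                    continue
                non_carrier = valid & ~(pairs == allele).any(axis=1)
                homo = non_carrier & (pairs[:, 0] == pairs[:, 1])
                pool = np.flatnonzero(homo if homo.any() else non_carrier)
                pick = int(pool[rng.integers(len(pool))])
                pairs[pick, 1] = allele
                changed = True
        if not changed:
            return
    raise RuntimeError("private-variant fixing did not converge")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct(config: SimulationConfig, rng=None, truth: TruthSet | None = None):
    """Simulate a long-format Ct table; returns a pandas DataFrame.

    Reference-gene Cts are constant in expectation across treatments;
    target Cts are shifted by -log2(fold) under the deficient treatment;
    Gaussian noise sigma is applied per technical replicate. Undetected
    gene/tissue/timepoint combinations are emitted with empty Ct.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    d = config.ct_design
    if truth is not None:
        truth.ct_fold_changes = dict(d.fold_changes)
    rows = []
    baselines = {**d.reference_genes, **d.target_baselines}
    for tissue in d.tissues:
        for tp in d.timepoints:
            for treatment in d.treatments:
                for bio in range(1, d.n_bio + 1):
                    sample = f"{tissue}_t{tp}_{treatment}_b{bio}"
                    for gene, base in baselines.items():
                        if gene in d.reference_genes:
                            true_ct = base
                        else:
                            fold = d.fold_changes.get((gene, tissue, tp), 1.0)
                            if fold is None:
                                true_ct = None
                            else:
                                shift = -np.log2(fold) if treatment == "deficient" else 0.0
                                true_ct = base + shift
                        for tech in range(1, d.n_tech + 1):
                            ct = (None if true_ct is None
                                  else true_ct + d.sigma * rng.standard_normal())
                            rows.append({
                                "sample": sample, "gene": gene, "tissue": tissue,
                                "timepoint": tp, "treatment": treatment,
                                "bio_rep": bio, "tech_rep": tech,
                                "ct": round(ct, 4) if ct is not None else None,
                            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig):
    """Run all three generators with seeds derived from ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    s_ref, s_var, s_ct = [np.random.default_rng(s) for s in root.spawn(3)]
    genome, models, truth = simulate_reference(config, s_ref)
    sites, samples = simulate_variants(genome, models, truth, config, s_var)
    ct = simulate_ct(config, s_ct, truth)
    return genome, models, sites, samples, ct, truth


def write_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Simulate and write genome.fa, annotation.gff3, variants.vcf, ct.tsv,
    samples.tsv and truth.json under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models, sites, samples, ct, truth = simulate_bundle(config)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "annotation.gff3",
        "vcf": outdir / "variants.vcf",
        "ct": outdir / "ct.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome.values(), paths["fasta"])
    write_gff3(models, paths["gff3"])
    write_vcf(sites, samples, paths["vcf"])
    ct.to_csv(paths["ct"], sep="\t", index=False)
    with open(paths["samples"], "w") as out:
        out.write("sample\tstatus\tsubpop\n")
        for s in samples:
            out.write(f"{s}\t{truth.sample_status[s]}\t"
                      f"{truth.subpop_labels.get(s, '.')}\n")
    truth.to_json(paths["truth"])
    return paths
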