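# Methods

`famdiv` reimplements, as a tested library, the desk-side analyses used to
characterise a plant gene family and its sequence diversity from standard
files (FASTA, GFF3, VCF, qPCR Ct tables): duplication classification,
promoter cis-element scanning, variant consequence annotation, diversity
accounting over a resequenced panel, distance-based population structure,
and 2^-ΔΔCt relative expression. A synthetic-data generator with a
recorded truth set makes every stage testable without any download. This
note describes the models, the defaults and why, the numerical choices,
and what the synthetic conditions do and do not show about real data.

## Coordinate model

All internal coordinates are 0-based half-open on the forward genomic
strand; GFF3 and VCF (1-based inclusive) are converted at the file
boundary only. Only single-nucleotide variants enter the genotype matrix:
indels/MNPs are skipped and counted, multiallelic SNP records are split
into one biallelic record per alternate allele (each alternate counts as a
polymorphic column; site totals de-duplicate by position). Phased
separators are read as unphased; half-missing genotypes (`./1`) are
treated as fully missing — a conservative choice for low-coverage data
where a half call carries little information.

## Duplication structure

Percent nucleotide identity between family members is the fraction of
identical columns in an optimal Needleman–Wunsch global alignment
(match +1, mismatch −1, linear gap −2 by default), computed over spliced
CDS. Because co-optimal alignments can disagree on the number of identical
columns, the statistic is defined over the optimal-score alignment that
maximises matches and then diagonal steps; this makes the value unique and
lets an independent dynamic program reproduce it exactly. The
implementation encodes the (score, matches, diagonal) lexicographic
objective into a single int64 per cell and runs a vectorised row
recurrence (the linear-gap left dependency is resolved with a running
maximum), so multi-kilobase CDS pairs align in milliseconds.

Two paralogs are called a **tandem** duplication when they are on the same
chromosome, their closest span ends are within the tandem window (default
200 kb) and identity is at least the threshold (default 90%); a
**segmental** duplication when identity passes but the genes are on
different chromosomes or farther apart than the window; **none**
otherwise. Inter-gene distance is the gap between closest span ends, not
midpoints. Paralog groups are single-linkage components over pairs at or
above the identity threshold. An unplaced gene (no chromosome) can only be
called segmental-or-none and the call is flagged.

## Promoter motifs

The promoter is the 2,000 bp immediately upstream of the gene span
(strand-aware: upstream of the span start for `+` genes, reverse
complement of the region past the span end for `−` genes), truncated and
flagged at contig boundaries. The default element is the PHR1-binding
site P1BS with consensus `GNATATNC`, the canonical cis-element through
which the phosphate-starvation regulator PHR1 induces
phosphate-starvation-inducible genes; the pattern is a parameter, not a
constant.

Scanning is set-based per IUPAC code, reports overlapping matches on both
strands with coordinates on the forward axis of the scanned sequence, and
orders hits by offset with `+` before `−`. An `N` in the subject matches
nothing except a pattern `N`, so gappy assemblies do not inflate counts.
One property of P1BS deserves emphasis: the consensus is its own IUPAC
reverse complement, so every forward site is simultaneously a
reverse-strand site at the same offset. Raw hit lists therefore contain
two entries per physical site; site counts (e.g. per-gene tables) use
unique offsets (`count_motif_sites`).

## Variant effects

Every SNP receives exactly one feature class with precedence
CDS > UTR > intron > upstream > intergenic (intron = inside the span but
in no exon; upstream = within the promoter length 5' of the span,
strand-aware). When a site falls in regions of several genes — promoters
inside a tandem cluster — the per-gene report lists it for each gene but
global totals count it once.

Coding consequences substitute the alternate allele within its codon on
the spliced 5'→3' CDS (complementing the allele for `−`-strand genes) and
translate with the standard nuclear code: synonymous, missense, nonsense
(stop gained), stoploss. Amino-acid changes are written `X<pos>Y` with
1-based protein coordinates (`pos = floor(cds_offset/3) + 1`). A CDS whose
length is not divisible by 3 is annotated with a low-confidence flag
rather than rejected; a REF allele that contradicts the genome FASTA is an
error naming the site. Deleteriousness (SIFT-style) is never recomputed;
an optional pass-through column ingests external annotations.

## Diversity accounting

Filtering keeps loci with MAF > 0.01 **and** missing fraction < 0.10
(both strict). MAF is computed by allele counting over non-missing calls
(denominator 2 × called samples). The filter is idempotent and preserves
locus order.

Substitutions are classed transition (purine↔purine, pyrimidine↔
pyrimidine) vs transversion. Densities are reported as integer bp-per-SNP;
a region with no SNPs is reported as "no polymorphism" and never divided
by. A gene's analyzed length is its span plus the 2-kb putative regulatory
region, matching how cumulative panel length is defined (the package's
worked example: 820 SNPs over 185,414 bp → one SNP every 226 bp). A
private variant is a locus whose minor allele (over non-missing calls) is
carried by exactly one accession, het or hom; per-accession polymorphism
counts a locus for a sample when the sample carries any alternate allele
(dosage ≥ 1), with missing calls not counting.

## Population structure

Distances between accessions are Euclidean over dosage vectors with
explicit missing-data handling: `d(i,j) = sqrt((L / L_ij) · Σ (x_i −
x_j)²)` over loci called in both samples, where `L_ij` is the shared-call
count — pairwise-complete analysis rescaled to the panel size so
missingness does not shrink distances. A pair with no shared calls is an
error, not a zero.

The tree is standard Saitou–Nei neighbor joining: repeatedly join the pair
minimising `Q(i,j) = (n−2) d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, with branch
lengths from the usual formulas, ties broken by the lowest index pair
(deterministic for a fixed input order), negative branch lengths clamped
to zero, and the final three nodes resolved around a trifurcating root
(the conventional rooted representation of an unrooted binary tree).
Output is Newick. On additive matrices the generating tree's path-length
matrix is recovered to 1e-9.

Principal coordinates analysis is classical Gower scaling: eigendecompose
`B = −½ J D² J` (J the centering matrix), coordinates are eigenvectors
scaled by the square roots of the positive eigenvalues, and variance
fractions are taken over positive eigenvalues only. Requesting more axes
than positive eigenvalues truncates with a warning.

## Relative expression (2^-ΔΔCt)

Technical replicates are averaged first; multiple reference genes are
combined as the arithmetic mean of their Cts, which is geometric-mean
normalisation in expression space; ΔCt = Ct_target − mean(Ct_refs); ΔΔCt
subtracts the mean ΔCt of the calibrator group (the control treatment of
the same tissue/timepoint), and the per-biological-replicate fold is
2^-ΔΔCt. Because centring happens in log space, the *geometric* mean of
the calibrator group's folds is exactly 1 by construction; the arithmetic
mean ± SEM — what bar plots display — sits slightly above 1 under noise
(Jensen's inequality). Fold changes are invariant to a constant plate
offset added to all Cts, and swapping which group is the calibrator
inverts them. A target undetected in every replicate of a group is
reported as "not detected"; an undetected reference gene is an error.

Significance uses the Kruskal–Wallis rank test with tie correction and a
chi-square p-value by default. At qPCR-typical sizes (3 vs 3) the
permutation null is discrete — the smallest attainable exact p is
2/20 = 0.1 — so the chi-square approximation is slightly anti-conservative
(complete separation gives H = 3.857, p ≈ 0.0495, which the null produces
10% of the time) while an exact test can never reject at 0.05. Both
behaviours are asserted in the test suite, and an exact two-group
permutation option (`exact=True`) is provided for small designs.

## Synthetic data: what it emulates

The generator's defaults are the study conditions the package is validated
under: 3 chromosomes × 400 kb of uniform-composition background; a family
of 10 genes (three exons, explicit UTRs, CDS from ATG to stop) — a tandem
cluster of four genes at 96.5% target identity separated by ~25-kb gaps on
one chromosome, two cross-chromosome segmental pairs at 92%, and two
unrelated genes (pairwise identity far below 80%); paralog copies are
per-site substitution mutants of their source that keep start and stop
codons. Promoters carry 0–3 planted P1BS instances per gene (cycling
2,1,0,3; alternating strands), and any accidental site that background or
copy mutations create is scrubbed by mutating one fixed-consensus base and
rescanning to a fixpoint — planting overwrites background, scrubbing makes
the per-gene truth exact.

The variant panel holds 94 accessions and 220 SNP loci over genes plus
promoters (≈200 bp per SNP at the realized gene sizes), placed with
feature weights that reproduce the intron > CDS > UTR density ordering
(128/187/297 bp-per-SNP). Alternate alleles are transitions with
probability 0.54; allele frequencies are Beta(0.5, 5) clipped to
[0.02, 0.5]; genotypes are Hardy–Weinberg draws (or Balding–Nichols
subpopulation draws, Fst 0.2, in the optional 3-subpopulation mode used
for the ordination separation test); missingness is uniform at 5%
(accessions are labelled wild/landrace/cultivar ~30/40/24). Exactly 11
private loci are planted as a homozygous alternate in a single accession
with no missingness (so their MAF of 2/188 ≈ 0.0106 survives the
MAF > 0.01 filter), stratified 6 wild / 4 landrace / 1 cultivar; exactly
2 triallelic loci and 12 nonsynonymous CDS changes (with recorded
amino-acid notation) are planted. A post-pass recruits a second carrier
for any allele that would otherwise be accidentally private, so the
planted private set is recovered *exactly* downstream.

Ct tables follow the 2 tissues × 2 timepoints × 2 treatments × 3
biological × 2 technical replicate design with two reference genes and
per-technical-replicate Gaussian noise σ = 0.2 cycles. The default fold
pattern mirrors a phosphate-starvation trial: an induced target (3–4×),
a repressed target (0.25–0.3×) absent from roots entirely, and a target
induced only in late roots (2.5×).

Everything is deterministic under a fixed seed (byte-identical files),
with the three generators driven by seeds spawned from one root.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, site-frequency spectra from a real demographic
history, sequencing-error or coverage models, assembly gaps, multiple
transcript isoforms, and primer-efficiency variation. Passing the
recovery tests therefore shows the *bookkeeping and algorithms* are
correct under known truth, not that real-genome counts (which depend on a
specific reference and panel) would be reproduced.

## Validation and problem sizes

Each algorithm is checked against an independent oracle: the motif scanner
against regex expansion on random 10-kb sequences; codon consequences
against full-CDS re-translation (1,000 random coding SNPs); alignment
identity against a plain tuple-valued DP (and neighbor joining/PCoA
against scikit-bio) on random instances; distances against the direct
formula under planted missingness; neighbor joining against hand-built
additive 5-leaf metrics; Kruskal–Wallis against the textbook rank formula.
Parameter-recovery tests run on one seed-fixed bundle at the default
conditions. The ddCt recovery check evaluates the estimator's accuracy —
the Monte-Carlo mean of the recovered fold over 25 independent simulated
experiments must be within 15% of each planted fold — because a single
σ = 0.2, n = 3 experiment has a log2-fold standard deviation of ≈0.14 and
its individual estimate legitimately scatters beyond 15% by chance. The
full suite and the acceptance script each run in well under a minute on
one CPU at these sizes.

## Known limitations

- One transcript per gene (the first mRNA child); isoform-aware
  consequence resolution is out of scope.
- Splice-site and indel consequences are not annotated.
- The alignment identity is CDS-level by default; genomic-span identity
  would include introns and can differ.
- Ordination variance fractions ignore negative eigenvalues; strongly
  non-Euclidean dissimilarities would need a correction (not the case for
  the distances produced here).
- The exact Kruskal–Wallis option covers two groups up to n = 12 total;
  larger designs fall back to the chi-square approximation.
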