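"""Independent reference implementations used only to cross-check famdiv.

Each oracle is deliberately written in a different style from the library
code (plain-Python dynamic programming, regex expansion, whole-sequence
re-translation) so agreement is meaningful.
"""

from __future__ import annotations

import re

from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def nw_identity_oracle(a: str, b: str, match: int = 1, mismatch: int = -1,
                       gap: int = -2) -> float:
    """Tuple-valued Needleman-Wunsch: maximise (score, matches, diag) and
    return matches / columns * 100."""
    la, lb = len(a), len(b)
    # cell value: (score, matches, diagonal steps)
    prev = [(gap * j, 0, 0) for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [(gap * i, 0, 0)] + [None] * lb
        for j in range(1, lb + 1):
            eq = a[i - 1] == b[j - 1]
            ds, dm, dd = prev[j - 1]
            diag = (ds + (match if eq else mismatch), dm + (1 if eq else 0), dd + 1)
            us, um, ud = prev[j]
            up = (us + gap, um, ud)
            ls, lm, ld = cur[j - 1]
            left = (ls + gap, lm, ld)
            cur[j] = max(diag, up, left)
        prev = cur
    score, matches, diag = prev[lb]
    return 100.0 * matches / (la + lb - diag)


def regex_scan_offsets(seq: str, pattern: str) -> tuple[set, set]:
    """(forward_offsets, reverse_offsets) of IUPAC matches via regex lookahead.

    Subject 'N' matches only pattern 'N' (the conservative policy)."""
    comp = str.maketrans("ACGT", "TGCA")

    def classes(pat: str) -> str:
        out = []
        for c in pat:
            bases = IUPAC[c] + ("N" if c == "N" else "")
            out.append(f"[{bases}]")
        return "".join(out)

    fwd = {m.start() for m in re.finditer(f"(?=({classes(pattern)}))", seq)}
    rc_pattern = "".join(IUPAC_RC[c] for c in reversed(pattern))
    rev = {m.start() for m in re.finditer(f"(?=({classes(rc_pattern)}))", seq)}
    return fwd, rev


IUPAC_RC = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


def full_translation_consequence(gene, genome, pos: int, alt: str) -> tuple[str, str | None]:
    """Consequence by rebuilding and translating the whole mutated CDS.

    Returns (consequence, aa_change)."""
    chrom_seq = genome[gene.chrom].seq
    mutated = {gene.chrom: type(genome[gene.chrom])(
        gene.chrom, chrom_seq[:pos] + alt + chrom_seq[pos + 1:])}
    ref_protein = str(Seq(gene.spliced_cds(genome)).translate())
    alt_protein = str(Seq(gene.spliced_cds({**genome, **mutated})).translate())
    if ref_protein == alt_protein:
        return "synonymous", None
    diffs = [i for i, (x, y) in enumerate(zip(ref_protein, alt_protein)) if x != y]
    i = diffs[0]
    x, y = ref_protein[i], alt_protein[i]
    if y == "*":
        kind = "nonsense"
    elif x == "*":
        kind = "stoploss"
    else:
        kind = "missense"
    return kind, f"{x}{i + 1}{y}"


def euclid_oracle(dosages, missing=-1):
    """Direct-formula pairwise-complete scaled Euclidean distances."""
    import math
    n, L = dosages.shape
    d = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            tot, shared = 0.0, 0
            for k in range(L):
                xi, xj = dosages[i, k], dosages[j, k]
                if xi != missing and xj != missing:
                    shared += 1
                    tot += (float(xi) - float(xj)) ** 2
            val = math.sqrt(L / shared * tot)
            d[i][j] = d[j][i] = val
    return d


def kruskal_h_oracle(g1, g2) -> float:
    """Two-group rank-sum H by the textbook formula (no tie correction)."""
    pooled = sorted(list(g1) + list(g2))
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks[pooled[i]] = mid
        i = j
    n = len(pooled)
    r1 = sum(ranks[v] for v in g1)
    r2 = sum(ranks[v] for v in g2)
    return (12.0 / (n * (n + 1))
            * (r1 ** 2 / len(g1) + r2 ** 2 / len(g2)) - 3 * (n + 1))
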