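"""Paralog identity, clustering, and tandem/segmental duplication calls.

Percent nucleotide identity between family members is defined as the number
of identical aligned columns divided by the total number of alignment
columns of an optimal Needleman-Wunsch global alignment (linear gap
penalty). When several alignments share the optimal score the one with the
most identical columns (then the fewest gap columns) defines the identity,
which makes the statistic well-defined and implementation-independent.

Duplication relations follow the classic genomic criteria: two sufficiently
similar paralogs on the same chromosome within a window (default 200 kb)
are tandem duplicates; similar paralogs on different chromosomes, or
further apart than the window, are segmental duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "global_align_identity",
    "IdentityMatrix",
    "pairwise_identity",
    "cluster_paralogs",
    "DuplicationCall",
    "classify_duplication",
    "classify_family",
]

# int64 lexicographic encoding: score is the primary key, then matched
# columns, then diagonal (aligned-pair) steps. Fields below the score key
# are bounded by _B * max_len + max_len, which must stay < _A.
_A = 10 ** 8
_B = 10 ** 4
_MAX_LEN = 9000


def global_align_identity(seq_a: str, seq_b: str, match: int = 1,
                          mismatch: int = -1, gap: int = -2) -> float:
    """Percent identity of an optimal global alignment of two DNA sequences.

    Among all maximum-score alignments the one maximising identical columns
    (then minimising total columns) is used. Returns identity in [0, 100].
    """
    if not seq_a or not seq_b:
        raise ValueError("global_align_identity: empty sequence")
    if len(seq_a) > _MAX_LEN or len(seq_b) > _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} bp not supported")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    la, lb = len(a), len(b)

    gap_step = np.int64(gap) * _A
    # diagonal step contribution for (match / mismatch)
    diag_match = np.int64(match) * _A + _B + 1
    diag_mismatch = np.int64(mismatch) * _A + 1

    j_idx = np.arange(lb + 1, dtype=np.int64)
    prev = j_idx * gap_step  # row 0
    for i in range(1, la + 1):
        sub = np.where(b == a[i - 1], diag_match, diag_mismatch)
        t = np.empty(lb + 1, dtype=np.int64)
        t[0] = np.int64(i) * gap_step
        np.maximum(prev[:-1] + sub, prev[1:] + gap_step, out=t[1:])
        # left scan: cur[j] = max_{k<=j} t[k] + (j-k)*gap_step
        np.subtract(t, j_idx * gap_step, out=t)
        np.maximum.accumulate(t, out=t)
        np.add(t, j_idx * gap_step, out=t)
        prev = t

    final = int(prev[-1])
    rem = final % _A
    matches = rem // _B
    diag = rem % _B
    columns = la + lb - diag
    return 100.0 * matches / columns


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over an ordered gene list."""

    gene_ids: list[str]
    identity: np.ndarray  # (n, n) float, diagonal 100

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=float)
        n = len(self.gene_ids)
        if self.identity.shape != (n, n):
            raise ValueError("identity matrix shape inconsistent with gene list")
        if not np.allclose(self.identity, self.identity.T):
            raise ValueError("identity matrix not symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.identity[i, j])


def pairwise_identity(sequences: dict[str, str], **align_kw) -> IdentityMatrix:
    """All-vs-all global-alignment identity for a family of sequences."""
    ids = list(sequences)
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_align_identity(sequences[ids[i]], sequences[ids[j]], **align_kw)
            m[i, j] = m[j, i] = pid
    return IdentityMatrix(ids, m)


def cluster_paralogs(identity: IdentityMatrix, min_identity: float = 90.0) -> list[list[str]]:
    """Single-linkage paralog groups over edges with identity >= threshold.

    Returns groups (including singletons) sorted by first member's input
    order; members keep input order within a group.
    """
    adj = identity.identity >= min_identity
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for gid, lab in zip(identity.gene_ids, labels):
        groups.setdefault(int(lab), []).append(gid)
    return [groups[k] for k in sorted(groups, key=lambda k: identity.gene_ids.index(groups[k][0]))]


@dataclass
class DuplicationCall:
    """A classified paralog pair with its supporting evidence."""

    gene_a: str
    gene_b: str
    relation: str  # tandem | segmental | none
    identity: float
    chrom_a: str | None
    chrom_b: str | None
    distance_bp: int | None  # None for cross-chromosome or unplaced pairs
    unplaced: bool = False  # True when a gene had no chromosome assignment


def _gene_gap(span_a: tuple[int, int], span_b: tuple[int, int]) -> int:
    """Gap between the closest span ends; 0 for overlapping spans."""
    return max(0, max(span_a[0], span_b[0]) - min(span_a[1], span_b[1]))


def classify_duplication(gene_a: str, gene_b: str, identity: float,
                         coords: dict[str, tuple[str | None, int, int]],
                         tandem_window: int = 200_000,
                         min_identity: float = 90.0) -> DuplicationCall:
    """Classify one paralog pair as tandem, segmental or unrelated.

    ``coords`` maps gene id to (chrom, start, end); chrom None marks an
    unplaced gene, for which only segmental-or-none can be decided (the
    call carries ``unplaced=True``).
    """
    chrom_a, sa, ea = coords[gene_a]
    chrom_b, sb, eb = coords[gene_b]
    if chrom_a is None or chrom_b is None:
        relation = "segmental" if identity >= min_identity else "none"
        return DuplicationCall(gene_a, gene_b, relation, identity,
                               chrom_a, chrom_b, None, unplaced=True)
    if chrom_a != chrom_b:
        distance = None
    else:
        distance = _gene_gap((sa, ea), (sb, eb))
    if identity < min_identity:
        relation = "none"
    elif chrom_a == chrom_b and distance <= tandem_window:
        relation = "tandem"
    else:
        relation = "segmental"
    return DuplicationCall(gene_a, gene_b, relation, identity,
                           chrom_a, chrom_b, distance)


def classify_family(identity: IdentityMatrix,
                    coords: dict[str, tuple[str | None, int, int]],
                    tandem_window: int = 200_000,
                    min_identity: float = 90.0) -> list[DuplicationCall]:
    """Duplication calls for every unordered gene pair of the family."""
    ids = identity.gene_ids
    calls = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            calls.append(classify_duplication(
                ids[i], ids[j], float(identity.identity[i, j]), coords,
                tandem_window=tandem_window, min_identity=min_identity))
    return calls


def calls_to_rows(calls: Sequence[DuplicationCall]) -> list[dict]:
    """Rows for the TSV interface (gene_a, gene_b, identity, chroms, distance, relation)."""
    return [
        {
            "gene_a": c.gene_a, "gene_b": c.gene_b,
            "identity": round(c.identity, 2),
            "chrom_a": c.chrom_a or ".", "chrom_b": c.chrom_b or ".",
            "distance_bp": c.distance_bp if c.distance_bp is not None else ".",
            "relation": c.relation,
        }
        for c in calls
    ]
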