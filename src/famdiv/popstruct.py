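"""Population structure from a genotype matrix.

Euclidean distances with explicit missing-data handling, a Saitou-Nei
neighbor-joining tree, and classical (Gower) principal coordinates
analysis. The distance between accessions i and j is

    d(i,j) = sqrt( (L / L_ij) * sum over shared non-missing loci (x_i - x_j)^2 )

where L is the panel size and L_ij the number of loci called in both
samples (pairwise-complete analysis rescaled to the full panel, so
missingness does not shrink distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "euclidean_distances",
    "PhyloNode",
    "PhyloTree",
    "neighbor_joining",
    "OrdinationResult",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over ordered sample ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal not zero")


def euclidean_distances(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise-complete Euclidean distances between accessions.

    Raises ``ValueError`` when a sample pair shares no called locus.
    """
    X = matrix.dosages.astype(float)
    valid = matrix.dosages != MISSING
    A = np.where(valid, X, 0.0)
    V = valid.astype(float)
    B = A * A
    # sum over shared loci of (xi - xj)^2 expanded with validity masks
    d2 = B @ V.T + V @ B.T - 2.0 * (A @ A.T)
    L_shared = V @ V.T
    if np.any(L_shared[~np.eye(len(V), dtype=bool)] == 0):
        i, j = np.argwhere((L_shared == 0) & ~np.eye(len(V), dtype=bool))[0]
        raise ValueError(
            f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} share no called loci"
        )
    L = matrix.n_loci
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(L_shared > 0, (L / L_shared) * d2, 0.0)
    scaled = np.clip(scaled, 0.0, None)
    np.fill_diagonal(scaled, 0.0)
    d = np.sqrt(scaled)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(matrix.samples), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloNode:
    name: str | None = None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at a trifurcating internal node."""

    root: PhyloNode
    leaf_ids: list[str]

    def to_newick(self) -> str:
        def fmt(node: PhyloNode) -> str:
            if node.is_leaf():
                return node.name or ""
            inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
            return f"({inner})"
        return fmt(self.root) + ";"

    def leaf_distances(self) -> "DistanceMatrix":
        """Path-length (patristic) distance matrix between leaves."""
        idx = {name: i for i, name in enumerate(self.leaf_ids)}
        n = len(self.leaf_ids)
        d = np.zeros((n, n))

        def below(node: PhyloNode) -> list[tuple[int, float]]:
            if node.is_leaf():
                return [(idx[node.name], 0.0)]
            groups = []
            for child, bl in node.children:
                groups.append([(i, dist + bl) for i, dist in below(child)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            d[i, j] = d[j, i] = di + dj
            return [pair for g in groups for pair in g]

        below(self.root)
        return DistanceMatrix(list(self.leaf_ids), d)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined (ties broken by the lowest index pair), branch lengths follow
    the standard formulas and negative lengths are clamped to zero.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[PhyloNode] = [PhyloNode(name=s) for s in dist.ids]
    d = dist.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                val = q[ai, aj]
                if best is None or val < best[0] - 1e-12:
                    best = (val, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        new = PhyloNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to remaining taxa
        k_new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            duk = 0.5 * (d[i, ak] + d[j, ak] - dij)
            d[k_new, ak] = d[ak, k_new] = max(0.0, duk)
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [k_new]

    # resolve the final three nodes around a trifurcating root
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = PhyloNode(children=[
        (nodes[i], max(0.0, li)),
        (nodes[j], max(0.0, lj)),
        (nodes[k], max(0.0, lk)),
    ])
    return PhyloTree(root=root, leaf_ids=list(dist.ids))


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Classical-MDS coordinates with eigenvalues and variance fractions."""

    ids: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # descending, retained (positive) axes
    variance_fraction: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(dist: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J is eigen-decomposed; coordinates are eigenvectors
    scaled by the square roots of the positive eigenvalues. Negative
    eigenvalues are excluded from the variance fractions; asking for more
    axes than there are positive eigenvalues truncates with a warning.
    """
    n = len(dist.ids)
    d2 = dist.d ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(eigval.max(), 1.0))
    n_pos = int((eigval > tol).sum())
    if k is None:
        k = n_pos
    elif k > n_pos:
        warnings.warn(
            f"pcoa: requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = n_pos
    pos_sum = eigval[:n_pos].sum()
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    return OrdinationResult(
        ids=list(dist.ids),
        coordinates=coords,
        eigenvalues=eigval[:k],
        variance_fraction=eigval[:k] / pos_sum if pos_sum > 0 else np.zeros(k),
    )
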