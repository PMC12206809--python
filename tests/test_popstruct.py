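"""Distances, neighbor joining, PCoA."""

import numpy as np
import pytest

from famdiv.io import MISSING, GenotypeMatrix, VariantRecord
from famdiv.popstruct import (DistanceMatrix, euclidean_distances,
                              neighbor_joining, pcoa)

from oracles import euclid_oracle


def _matrix(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    loci = [VariantRecord("chr1", j, "A", "G", j + 1) for j in range(L)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], loci, dosages)


class TestEuclidean:
    def test_identical_rows_zero(self):
        d = euclidean_distances(_matrix([[0, 1, 2], [0, 1, 2]]))
        assert d.d[0, 1] == 0.0

    def test_single_locus_extremes(self):
        d = euclidean_distances(_matrix([[0], [2]]))
        assert d.d[0, 1] == pytest.approx(2.0)

    def test_missing_scaling_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        dos = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.1] = MISSING
        m = _matrix(dos)
        mine = euclidean_distances(m).d
        oracle = euclid_oracle(m.dosages)
        assert np.allclose(mine, np.array(oracle))

    def test_zero_shared_loci_rejected(self):
        dos = np.array([[1, MISSING], [MISSING, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no called loci"):
            euclidean_distances(_matrix(dos))


def _additive_tree_distances():
    """5-leaf unrooted tree with known branch lengths -> additive matrix.

    Topology ((a:2,b:3):1,(c:4,d:1):2,e:5) around an internal edge."""
    ids = list("abcde")
    # path lengths computed by hand from the topology above
    d = {
        ("a", "b"): 5, ("a", "c"): 9, ("a", "d"): 6, ("a", "e"): 8,
        ("b", "c"): 10, ("b", "d"): 7, ("b", "e"): 9,
        ("c", "d"): 5, ("c", "e"): 11, ("d", "e"): 8,
    }
    m = np.zeros((5, 5))
    for (x, y), v in d.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(ids, m)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = list("abc")
        m = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids, m))
        d = tree.leaf_distances()
        assert np.allclose(d.d, m)
        # three-point solution: la=3, lb=2, lc=6
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths == {"a": 3.0, "b": 2.0, "c": 6.0}

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_additive_five_leaf_recovery(self):
        dist = _additive_tree_distances()
        tree = neighbor_joining(dist)
        recon = tree.leaf_distances()
        assert recon.ids == dist.ids
        assert np.allclose(recon.d, dist.d, atol=1e-9)

    def test_leaf_order_permutation_invariance(self):
        dist = _additive_tree_distances()
        rng = np.random.default_rng(4)
        perm = rng.permutation(5)
        ids_p = [dist.ids[i] for i in perm]
        d_p = dist.d[np.ix_(perm, perm)]
        t1 = neighbor_joining(dist).leaf_distances()
        t2 = neighbor_joining(DistanceMatrix(ids_p, d_p)).leaf_distances()
        # compare path-length matrices on a common id order
        order = [t2.ids.index(x) for x in t1.ids]
        assert np.allclose(t1.d, t2.d[np.ix_(order, order)], atol=1e-9)

    def test_matches_scikit_bio_on_random_matrix(self):
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkbioDM
        rng = np.random.default_rng(2)
        X = rng.random((7, 3))
        m = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(7)]
        mine = neighbor_joining(DistanceMatrix(ids, m)).leaf_distances()
        ref = skbio_nj(SkbioDM(m, ids))
        ref_d = np.array([[ref.find(a).distance(ref.find(b)) for b in ids]
                          for a in ids])
        assert np.allclose(mine.d, ref_d, atol=1e-6)

    def test_newick_parses(self):
        import io as _io
        from Bio import Phylo
        tree = neighbor_joining(_additive_tree_distances())
        parsed = Phylo.read(_io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == list("abcde")


class TestPcoa:
    def test_reconstructs_planted_2d_configuration(self):
        rng = np.random.default_rng(12)
        pts = rng.random((10, 2)) * 5
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d), k=2)
        recon = np.sqrt(((res.coordinates[:, None] - res.coordinates[None]) ** 2).sum(-1))
        assert np.allclose(recon, d, atol=1e-8)
        # only two materially positive eigenvalues for a planar configuration
        assert len(res.eigenvalues) == 2

    def test_duplicated_sample_coincident(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 3]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(list("wxyz"), d))
        assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-9)

    def test_requesting_too_many_axes_warns(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        d = np.abs(pts[:, 0][:, None] - pts[:, 0][None])
        with pytest.warns(UserWarning, match="truncating"):
            res = pcoa(DistanceMatrix(list("abc"), d), k=3)
        assert res.coordinates.shape[1] < 3

    def test_eigenvalues_match_scikit_bio(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix as SkbioDM
        rng = np.random.default_rng(8)
        X = rng.random((9, 4))
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        mine = pcoa(DistanceMatrix([f"s{i}" for i in range(9)], d))
        ref = skbio_pcoa(SkbioDM(d, [f"s{i}" for i in range(9)]))
        ref_pos = np.array([e for e in ref.eigvals if e > 1e-10])
        assert np.allclose(np.sort(mine.eigenvalues), np.sort(ref_pos), atol=1e-8)

    def test_euclidean_panel_has_no_material_negative_eigenvalues(self, bundle_dir):
        from famdiv.io import read_vcf
        from famdiv.diversity import filter_variants
        m = filter_variants(read_vcf(bundle_dir["vcf"]))
        # complete-data submatrix is exactly Euclidean-embeddable
        complete = m.subset((m.dosages == MISSING).sum(axis=0) == 0)
        dist = euclidean_distances(complete)
        n = len(dist.ids)
        d2 = dist.d ** 2
        J = np.eye(n) - 1.0 / n
        eig = np.linalg.eigvalsh(-0.5 * J @ d2 @ J)
        assert eig.min() > -1e-8 * eig.max()
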