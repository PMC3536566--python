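"""Distances, neighbor joining, and bootstrap replication."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from geneout.reconstruct import (
    D_MAX,
    Alignment,
    DistanceMatrix,
    NJVectorFactory,
    bootstrap_columns,
    f84_distances,
    jc69_distances,
    neighbor_joining,
    reconstruct_trees,
)
from geneout.treespace import TaxonOrder, dissimilarity_vector

from conftest import random_trees


def _aln(seqs: dict) -> Alignment:
    return Alignment.from_sequences(seqs)


class TestJC69:
    def test_identical_sequences_give_zero(self):
        a = _aln({"x": "ACGTACGT", "y": "ACGTACGT", "z": "ACGTACGT"})
        assert np.all(jc69_distances(a).values == 0)

    def test_ten_percent_mismatch_closed_form(self):
        # d = -(3/4) ln(1 - (4/3) * 0.10) = 0.10733...
        a = _aln({"x": "A" * 100, "y": "A" * 90 + "C" * 10, "z": "A" * 100})
        assert jc69_distances(a).values[0, 1] == pytest.approx(0.1073256327, abs=1e-9)

    def test_saturation_capped(self):
        a = _aln({"x": "AAAA", "y": "CCCC", "z": "AAAA"})
        assert jc69_distances(a).values[0, 1] == D_MAX

    def test_no_comparable_columns_names_pair(self):
        a = _aln({"x": "AC--", "y": "--GT", "z": "ACGT"})
        with pytest.raises(ValueError, match=r"\(x, y\)"):
            jc69_distances(a)

    def test_row_order_invariance(self, rng):
        codes = rng.integers(0, 4, size=(4, 200)).astype(np.uint8)
        a = Alignment(("a", "b", "c", "d"), codes)
        b = a.reordered(("d", "b", "a", "c"))
        da, db = jc69_distances(a), f84_distances(b)
        for i, ti in enumerate(a.taxa):
            for j, tj in enumerate(a.taxa):
                bi, bj = b.taxa.index(ti), b.taxa.index(tj)
                assert f84_distances(a).values[i, j] == pytest.approx(db.values[bi, bj])


class TestF84:
    def test_identical_sequences_give_zero(self):
        a = _aln({"x": "ACGT" * 10, "y": "ACGT" * 10, "z": "ACGT" * 10})
        assert np.all(f84_distances(a).values == 0)

    def test_reduces_to_jc_at_equal_frequencies(self):
        """With equal base frequencies and transitions at one third of the
        differences (the proportion JC69 expects), F84 equals JC69."""
        L = 300
        x = ("ACGT" * (L // 4))
        y = list(x)
        # 12 transitions (A<->G in both directions preserves composition)
        ag = [i for i, ch in enumerate(x) if ch == "A"][:6]
        ga = [i for i, ch in enumerate(x) if ch == "G"][:6]
        for i in ag:
            y[i] = "G"
        for i in ga:
            y[i] = "A"
        # 24 transversions (A<->C and G<->T swaps, balanced)
        ac = [i for i, ch in enumerate(x) if ch == "A"][6:12]
        ca = [i for i, ch in enumerate(x) if ch == "C"][:6]
        gt = [i for i, ch in enumerate(x) if ch == "G"][6:12]
        tg = [i for i, ch in enumerate(x) if ch == "T"][:6]
        for i in ac:
            y[i] = "C"
        for i in ca:
            y[i] = "A"
        for i in gt:
            y[i] = "T"
        for i in tg:
            y[i] = "G"
        a = _aln({"x": x, "y": "".join(y), "z": x})
        d_f84 = f84_distances(a).values[0, 1]
        d_jc = jc69_distances(a).values[0, 1]
        assert d_f84 == pytest.approx(d_jc, abs=1e-9)

    def test_consistent_on_f84_simulated_data(self, rng):
        """Estimates recover a true F84 distance of 0.1 within 3 SE."""
        freqs = np.array([0.3, 0.2, 0.2, 0.3])
        kappa_extra = 2.0  # F84's transition bonus K
        pr, py = freqs[0] + freqs[2], freqs[1] + freqs[3]
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = freqs[j]
                if (i, j) in ((0, 2), (2, 0)):
                    Q[i, j] *= 1 + kappa_extra / pr
                if (i, j) in ((1, 3), (3, 1)):
                    Q[i, j] *= 1 + kappa_extra / py
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -np.dot(freqs, np.diag(Q))
        P = expm(Q * 0.1)
        L = 10_000
        ests = []
        for _ in range(50):
            anc = rng.choice(4, size=L, p=freqs)
            u = rng.random(L)
            der = (P[anc].cumsum(axis=1) < u[:, None]).sum(axis=1)
            third = rng.choice(4, size=L, p=freqs)
            a = Alignment(("x", "y", "z"), np.stack([anc, der, third]).astype(np.uint8))
            ests.append(f84_distances(a).values[0, 1])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.1) < 3 * se + 1e-4


class TestNeighborJoining:
    def test_quartet_exact_recovery(self, quartet):
        d = DistanceMatrix(
            ("a", "b", "c", "d"),
            np.array(
                [[0, 3, 4.5, 5.5], [3, 0, 5.5, 6.5], [4.5, 5.5, 0, 7], [5.5, 6.5, 7, 0]]
            ),
        )
        tree = neighbor_joining(d)
        v = dissimilarity_vector(tree, TaxonOrder(("a", "b", "c", "d")))
        np.testing.assert_allclose(v.values, [3, 4.5, 5.5, 5.5, 6.5, 7])

    def test_three_taxon_star(self):
        d = DistanceMatrix(("a", "b", "c"), np.array([[0.0, 2, 2], [2, 0, 2], [2, 2, 0]]))
        tree = neighbor_joining(d)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.0)

    def test_additive_matrices_recovered_exactly(self):
        """NJ consistency: path distances of the output tree reproduce any
        additive input matrix entry-for-entry."""
        for tree in random_trees(10, seed=7, n_min=5, n_max=10):
            order = TaxonOrder.from_tree(tree)
            v = dissimilarity_vector(tree, order).values
            n = len(order)
            mat = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            mat[iu] = v
            mat += mat.T
            out = neighbor_joining(DistanceMatrix(order.labels, mat))
            np.testing.assert_allclose(
                dissimilarity_vector(out, order).values, v, rtol=1e-9, atol=1e-9
            )

    def test_matches_scikit_bio_topology(self, rng):
        """Independent oracle on noisy (non-additive) distances."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj

        labels = tuple("abcdefg")
        base = dissimilarity_vector(
            random_trees(1, seed=8, n_min=7, n_max=7)[0]
        )
        n = 7
        mat = np.zeros((n, n))
        mat[np.triu_indices(n, 1)] = base.values
        mat += mat.T
        noise = rng.uniform(0.95, 1.05, size=mat.shape)
        mat = mat * (noise + noise.T) / 2
        np.fill_diagonal(mat, 0.0)
        taxa = base.order.labels
        mine = neighbor_joining(DistanceMatrix(taxa, mat))
        theirs = sk_nj(skbio.DistanceMatrix(mat, ids=list(taxa)))
        mine_splits = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in mine.preorder_edge_iter()
            if e.head_node.parent_node
        }
        mine_splits = {
            s for s in mine_splits if 1 < len(s) < n - 1
        }
        their_splits = set()
        for node in theirs.non_tips():
            s = frozenset(t.name for t in node.tips())
            if 1 < len(s) < n - 1:
                their_splits.add(s)
        full = frozenset(taxa)
        norm = lambda ss: {min(s, full - s, key=sorted) for s in ss}
        assert norm(mine_splits) == norm(their_splits)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b", "c"), np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0.0]]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))


class TestBootstrap:
    def test_single_column_identity(self, rng):
        a = _aln({"x": "A", "y": "C", "z": "G"})
        assert bootstrap_columns(a, rng).sequences == a.sequences

    def test_columns_are_resampled_from_input(self, rng):
        a = Alignment(("x", "y", "z"), rng.integers(0, 4, (3, 50)).astype(np.uint8))
        b = bootstrap_columns(a, rng)
        assert b.n_sites == a.n_sites
        in_cols = {tuple(c) for c in a.codes.T}
        assert all(tuple(c) in in_cols for c in b.codes.T)

    def test_uniform_column_frequencies(self, rng):
        a = _aln({"x": "AC", "y": "AC", "z": "AC"})
        first = 0
        reps = 10_000
        for _ in range(reps):
            b = bootstrap_columns(a, rng)
            first += int(np.count_nonzero(b.codes[0] == 0))
        assert first / (2 * reps) == pytest.approx(0.5, abs=0.02)

    def test_constant_columns_fixed_point(self, rng):
        a = _aln({"x": "AAAA", "y": "CCCC", "z": "GGGG"})
        assert bootstrap_columns(a, rng).sequences == a.sequences


class TestReconstructTrees:
    def test_identical_sequences_give_zero_paths(self, rng):
        a = _aln({"x": "ACGT" * 5, "y": "ACGT" * 5, "z": "ACGT" * 5})
        (tree,) = reconstruct_trees(a, 1, "nj-f84", rng)
        v = dissimilarity_vector(tree)
        np.testing.assert_allclose(v.values, 0.0)

    def test_count_and_taxa(self, rng):
        a = _aln({"x": "ACGTAAC", "y": "ACCTAAC", "z": "ACGTTAC", "w": "GCGTAAC"})
        trees = reconstruct_trees(a, 5, "nj-f84", rng)
        assert len(trees) == 5
        for t in trees:
            assert {l.taxon.label for l in t.leaf_node_iter()} == {"x", "y", "z", "w"}

    def test_majority_topology_at_low_noise(self, rng):
        """On long alignments simulated from a fixed resolved tree, the
        majority bootstrap topology equals the generating topology."""
        from geneout.simulate import SubstitutionModel, simulate_alignment

        gen = dendropy.Tree.get(
            data="((a:0.05,b:0.05):0.03,(c:0.05,d:0.05):0.03);", schema="newick"
        )
        model = SubstitutionModel(scaling=1.0)
        aln = simulate_alignment(gen, model, 10_000, rng)
        fac = NJVectorFactory(aln)
        _, ecnt = fac.replicate_vectors(100, rng)
        # in topology ab|cd the a-b edge count is 2; in ac|bd or ad|bc it is 3
        ab_adjacent = np.count_nonzero(ecnt[:, 0] == 2)
        assert ab_adjacent > 50

    def test_unknown_method_rejected(self, rng):
        a = _aln({"x": "ACGT", "y": "ACGT", "z": "ACGT"})
        with pytest.raises(ValueError, match="method"):
            reconstruct_trees(a, 1, "parsimony", rng)

    def test_external_method_requires_command(self, rng):
        a = _aln({"x": "ACGT", "y": "ACGT", "z": "ACGT"})
        with pytest.raises(ValueError, match="external_cmd"):
            reconstruct_trees(a, 1, "external-ml", rng)

    def test_external_hook_parses_newick_and_reports_failure(self, rng, tmp_path):
        a = _aln({"x": "ACGT", "y": "ACGT", "z": "ACGT"})
        (tree,) = reconstruct_trees(
            a, 1, "external-ml", rng, external_cmd="echo '(x:1,y:1,z:1);' # {input}"
        )
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"x", "y", "z"}
        with pytest.raises(RuntimeError, match="exit"):
            reconstruct_trees(a, 1, "external-ml", rng, external_cmd="false # {input}")
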