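"""TN93 distances, neighbor-joining, bootstrap supports and rooting."""

import math

import dendropy
import numpy as np
import pytest

from archhap.archaic import AlignedHaplotypeSet
from archhap.phylo import (
    DistanceMatrix,
    SaturationError,
    base_frequencies,
    bootstrap_supports,
    clade_support,
    distance_matrix,
    nj_tree,
    read_newick,
    root_tree,
    total_tree_length,
    tn93_distance,
    tree_bipartitions,
)

EQUAL_FREQS = np.array([0.25, 0.25, 0.25, 0.25])


def _aln(taxa_seqs):
    taxa = list(taxa_seqs)
    states = np.array([list(s) for s in taxa_seqs.values()], dtype="<U1")
    return AlignedHaplotypeSet(taxa=taxa, sites=None, states=states)


class TestTN93:
    def test_identical_sequences_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT", EQUAL_FREQS) == 0.0

    def test_three_transition_example_against_written_formula(self):
        # 50 bases, 3 A<->G transitions, equal base frequencies
        a = "ACGT" * 12 + "AA"
        b = "GCGT" + "ACGT" * 11 + "GG"  # A->G at positions 0, 48, 49
        p1 = 3 / 50
        # independent evaluation: k1 = 2*gA*gG/gR = 0.25 with equal freqs
        expected = -0.25 * math.log(1 - p1 / 0.25) \
            - 0.25 * math.log(1.0) - 0.25 * math.log(1.0)
        assert tn93_distance(a, b, EQUAL_FREQS) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.25 * math.log(0.76), abs=1e-12)

    def test_k2p_closed_form_in_equal_frequency_limit(self):
        # P1 = P2 = 0.1, Q = 0.08 over 100 sites
        a = list("ACGT" * 25)
        b = a.copy()
        for i in range(10):
            b[4 * i] = "G"  # A->G
        for i in range(10, 20):
            b[4 * i + 1] = "T"  # C->T
        for i in range(17, 25):
            b[4 * i + 2] = "C"  # G->C transversion
        p, q = 0.2, 0.08
        k2p = 0.5 * math.log(1 / (1 - 2 * p - q)) + 0.25 * math.log(1 / (1 - 2 * q))
        assert tn93_distance("".join(a), "".join(b), EQUAL_FREQS) == pytest.approx(
            k2p, abs=1e-9
        )

    def test_cross_checked_against_independent_implementation(self):
        # frozen value computed with R ape's dist.dna(model="TN93") on this pair
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        a = bases[rng.integers(4, size=200)]
        b = a.copy()
        idx = rng.choice(200, size=40, replace=False)
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        tv = {"A": "C", "G": "T", "C": "G", "T": "A"}
        for i in idx[:25]:
            b[i] = ts[b[i]]
        for i in idx[25:]:
            b[i] = tv[b[i]]
        pooled = np.concatenate([a, b])
        freqs = np.array([(pooled == x).mean() for x in "ACGT"])
        d = tn93_distance("".join(a), "".join(b), freqs)
        assert d == pytest.approx(0.237255791480, abs=1e-9)

    def test_symmetry_and_pairwise_deletion(self):
        a, b = "ACGTNNAC", "ACGAACNC"
        d1 = tn93_distance(a, b, EQUAL_FREQS)
        assert d1 == tn93_distance(b, a, EQUAL_FREQS)
        # columns 4,5,6 are excluded; only the T->A at position 3 differs
        assert d1 > 0

    def test_saturation_errors(self):
        with pytest.raises(SaturationError):
            tn93_distance("ACAC" * 20, "CACA" * 20, EQUAL_FREQS)


class TestDistanceMatrix:
    def test_identical_taxa_zero_matrix(self):
        aln = _aln({"a": "ACGTAC", "b": "ACGTAC", "c": "ACGTAC"})
        dm = distance_matrix(aln)
        np.testing.assert_array_equal(dm.d, np.zeros((3, 3)))

    def test_taxon_permutation_permutes_entries(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTAC"
        seqs = {"a": base, "b": base[:-2] + "GG", "c": "G" + base[1:]}
        aln1 = _aln(seqs)
        aln2 = _aln({k: seqs[k] for k in ["c", "a", "b"]})
        dm1 = distance_matrix(aln1)
        dm2 = distance_matrix(aln2).submatrix(["a", "b", "c"])
        np.testing.assert_allclose(dm1.d, dm2.d, atol=1e-15)

    def test_majority_missing_columns_dropped(self):
        aln = _aln({"a": "ANGTACGT", "b": "ANGTACGT", "c": "GNGTACGT"})
        dm = distance_matrix(aln)  # all-N column dropped, the rest compared
        assert np.isfinite(dm.d).all()
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] > 0


def random_additive_tree(rng, n_taxa):
    """Random binary topology with uniform branch lengths; returns
    (edge list [(u, v, length)], leaf labels dict node->name)."""
    edges = []
    next_node = [0]

    def new_node():
        next_node[0] += 1
        return next_node[0] - 1

    center = new_node()
    leaves = {}
    for _ in range(3):
        leaf = new_node()
        edges.append([center, leaf, rng.uniform(0.1, 1.0)])
        leaves[leaf] = f"t{len(leaves)}"
    for _ in range(n_taxa - 3):
        i = int(rng.integers(len(edges)))
        u, v, length = edges.pop(i)
        mid, leaf = new_node(), new_node()
        split = rng.uniform(0.2, 0.8) * length
        edges.append([u, mid, split])
        edges.append([mid, v, length - split])
        edges.append([mid, leaf, rng.uniform(0.1, 1.0)])
        leaves[leaf] = f"t{len(leaves)}"
    return edges, leaves


def path_distance_matrix(edges, leaves):
    adj = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    taxa = [leaves[k] for k in sorted(leaves)]
    nodes = sorted(leaves)
    n = len(nodes)
    d = np.zeros((n, n))
    for i, start in enumerate(nodes):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, other in enumerate(nodes):
            d[i, j] = dist[other]
    return DistanceMatrix(taxa=taxa, d=d)


def true_bipartitions(edges, leaves):
    adj = {}
    for u, v, _ in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    all_taxa = frozenset(leaves.values())
    ref = min(all_taxa)
    out = set()
    for u, v, _ in edges:
        # leaves reachable from v without crossing u
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x in leaves:
                side.add(leaves[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(side)
        if ref in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            out.add(side)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(taxa=["a", "b", "c"],
                            d=np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float))
        tree = nj_tree(dm)
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_four_taxon_additive_matrix_exact(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4):1): internal edge 2 unrooted
        d = np.array([[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(taxa=list("ABCD"), d=d))
        bips = tree_bipartitions(tree)
        assert set(bips) == {frozenset({"C", "D"})}
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        (internal_node,) = bips.values()
        assert internal_node.edge.length == pytest.approx(2.0)

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            edges, leaves = random_additive_tree(rng, 8)
            dm = path_distance_matrix(edges, leaves)
            assert set(tree_bipartitions(nj_tree(dm))) == true_bipartitions(edges, leaves)

    def test_agrees_with_dendropy_nj_on_noisy_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            edges, leaves = random_additive_tree(rng, 7)
            dm = path_distance_matrix(edges, leaves)
            noisy = dm.d + rng.uniform(0, 0.05, dm.d.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            dm_noisy = DistanceMatrix(taxa=dm.taxa, d=noisy)
            mine = set(tree_bipartitions(nj_tree(dm_noisy)))
            csv = "," + ",".join(dm.taxa) + "\n" + "\n".join(
                t + "," + ",".join(f"{x:.12f}" for x in row)
                for t, row in zip(dm.taxa, noisy)
            )
            import io

            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(csv), delimiter=",")
            ref_tree = pdm.nj_tree()
            ref_tree.is_rooted = False
            theirs = {
                bip for bip in _dendropy_bipartitions(ref_tree)
            }
            assert mine == theirs

    def test_negative_branch_lengths_clamped(self):
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]], float)
        tree = nj_tree(DistanceMatrix(taxa=list("ABCD"), d=d))
        assert all((e.length or 0) >= 0 for e in tree.preorder_edge_iter())


def _dendropy_bipartitions(tree):
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(all_taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            out.add(side)
    return out


def _mutated_family(rng, n_taxa, length=60, n_mut=5):
    """Closely related sequences: a shared base with a few substitutions each."""
    bases = np.array(list("ACGT"))
    base = bases[rng.integers(4, size=length)]
    seqs = {}
    for i in range(n_taxa):
        s = base.copy()
        for j in rng.choice(length, size=n_mut, replace=False):
            s[j] = bases[(np.where(bases == s[j])[0][0] + 1 + rng.integers(3)) % 4]
        seqs[f"t{i}"] = "".join(s)
    return seqs


class TestBootstrap:
    def test_unanimous_signal_gets_full_support(self):
        # 108 constant columns + 12 informative ones, all supporting ab|cd
        cycle = "ACGT" * 27
        aln = _aln({
            "a": cycle + "AAAACCCCAAAA", "b": cycle + "AAAACCCCAAAA",
            "c": cycle + "GGGGTTTTCCCC", "d": cycle + "GGGGTTTTCCCC",
        })
        tree = bootstrap_supports(aln, B=100, seed=3)
        assert clade_support(tree, {"a", "b"}) == 100

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        aln = _aln(_mutated_family(rng, 6))
        t1 = bootstrap_supports(aln, B=50, seed=11)
        t2 = bootstrap_supports(aln, B=50, seed=11)
        assert t1.bipartition_supports == t2.bipartition_supports

    def test_supports_invariant_to_taxon_order(self):
        seqs = _mutated_family(np.random.default_rng(13), 6)
        aln1 = _aln(seqs)
        aln2 = _aln(dict(reversed(list(seqs.items()))))
        t1 = bootstrap_supports(aln1, B=30, seed=2)
        t2 = bootstrap_supports(aln2, B=30, seed=2)
        assert t1.bipartition_supports == t2.bipartition_supports


class TestRooting:
    def test_three_leaf_rooting(self):
        dm = DistanceMatrix(taxa=["a", "b", "out"],
                            d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        rooted = root_tree(nj_tree(dm), "out")
        assert rooted.is_rooted
        assert len(rooted.seed_node.child_nodes()) == 2

    def test_root_unroot_involution_preserves_length_and_splits(self):
        rng = np.random.default_rng(31)
        edges, leaves = random_additive_tree(rng, 9)
        dm = path_distance_matrix(edges, leaves)
        tree = nj_tree(dm)
        before = total_tree_length(tree)
        bips_before = set(tree_bipartitions(tree))
        rooted = root_tree(tree, dm.taxa[0])
        rooted.deroot()
        assert total_tree_length(rooted) == pytest.approx(before, abs=1e-9)
        rooted.is_rooted = False
        assert _dendropy_bipartitions(rooted) == bips_before

    def test_missing_outgroup_errors(self):
        dm = DistanceMatrix(taxa=["a", "b", "c"],
                            d=np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float))
        with pytest.raises(ValueError, match="ancestral"):
            root_tree(nj_tree(dm), "ancestral")

    def test_newick_round_trip(self):
        aln = _aln({
            "a": "ACGTACGTAAGG", "b": "ACGTACGTAAGA",
            "c": "GGGTACGTTTGG", "d": "GGGAACGTTTGG", "ancestral": "ACGTACGTTTGG",
        })
        tree = bootstrap_supports(aln, B=20, seed=1)
        rooted = root_tree(tree, "ancestral")
        from archhap.genomic_io import write_newick

        text = write_newick(rooted)
        back = read_newick(text)
        assert write_newick(back) == text
        assert total_tree_length(back) == pytest.approx(total_tree_length(rooted), abs=1e-9)


class TestBaseFrequencies:
    def test_pooled_counts(self):
        aln = _aln({"a": "AACC", "b": "GGNN"})
        np.testing.assert_allclose(base_frequencies(aln), [2 / 6, 2 / 6, 2 / 6, 0])
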