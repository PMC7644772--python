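import math

import dendropy
import numpy as np
import pytest

from barcodefish.core import LabelledSequence
from barcodefish.phylo import (
    DistanceMatrix,
    PhyloConfig,
    bootstrap_tree,
    compute_distance_matrix,
    nj_tree,
    tn93_distance,
)
from barcodefish.simulate import mutate_sequence, random_sequence

from oracles import tn93_oracle


def _seqs(pairs):
    return [LabelledSequence(id=k, residues=v, locus="16S") for k, v in pairs]


def _random_pair(seed, length=500, rate=0.1):
    rng = np.random.default_rng(seed)
    a = random_sequence(length, rng)
    return a, mutate_sequence(a, rate, rng)


class TestTN93:
    def test_identical_sequences_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_saturated_pair_flagged_undefined(self):
        # all transversions: A<->C and G<->T at every site
        a = "ACGT" * 50
        b = "CATG" * 50  # A->C, C->A, G->T, T->G
        assert math.isnan(tn93_distance(a, b))

    def test_matches_independent_formula_oracle(self):
        """One random 500-nt pair: agreement with a separately coded
        evaluation of the Tamura-Nei closed form to 1e-10."""
        a, b = _random_pair(2024)
        assert tn93_distance(a, b) == pytest.approx(
            tn93_oracle(a, b), abs=1e-10
        )

    def test_gamma_variant_matches_oracle(self):
        a, b = _random_pair(7)
        assert tn93_distance(a, b, gamma_shape=0.5) == pytest.approx(
            tn93_oracle(a, b, gamma_shape=0.5), abs=1e-10
        )

    def test_gamma_large_shape_approaches_plain(self):
        a, b = _random_pair(8)
        assert tn93_distance(a, b, gamma_shape=1e7) == pytest.approx(
            tn93_distance(a, b), abs=1e-5
        )

    @pytest.mark.parametrize("rate", [0.02, 0.05, 0.1, 0.2])
    def test_tn93_at_least_p_distance(self, rate):
        from barcodefish.assign import p_distance

        a, b = _random_pair(int(rate * 1000), rate=rate)
        d = tn93_distance(a, b)
        if not math.isnan(d):
            assert d >= p_distance(a, b) - 1e-12

    def test_continuity_as_transition_classes_swap(self):
        """Moving one transition from the purine to the pyrimidine class
        changes the distance only slightly (no discontinuity)."""
        base = list("ACGT" * 125)
        other = base.copy()
        for i in range(0, 40, 4):
            other[i] = "G"  # 10 A->G transitions
        for i in range(101, 141, 4):
            other[i] = "T"  # 10 C->T transitions
        d1 = tn93_distance("".join(base), "".join(other))
        other2 = other.copy()
        other2[36] = "A"       # one fewer A->G
        other2[141 + 4] = "T"  # one more C->T
        d2 = tn93_distance("".join(base), "".join(other2))
        assert abs(d1 - d2) < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tn93_distance("ACG", "ACGT")

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            tn93_distance("NNNN", "ACGT")


def _patristic(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor, n = labels[0], len(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        ls = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(set(labels) - ls) if anchor in ls else ls
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _random_additive_tree(seed: int, n_leaves: int):
    """A random binary tree with positive branch lengths and its exact
    path-length (additive) distance matrix."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = {i: {"leaves": {labels[i]}} for i in range(n_leaves)}
    dist = {frozenset((a, b)): 0.0 for a in labels for b in labels if a != b}
    depth = {label: 0.0 for label in labels}  # distance to current node root
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(active, size=2, replace=False))
        bi, bj = rng.uniform(0.05, 0.3, size=2)
        for a in nodes[i]["leaves"]:
            for b in nodes[j]["leaves"]:
                dist[frozenset((a, b))] = (
                    depth[a] + bi + depth[b] + bj
                )
        for a in nodes[i]["leaves"]:
            depth[a] += bi
        for b in nodes[j]["leaves"]:
            depth[b] += bj
        nodes[nxt] = {"leaves": nodes[i]["leaves"] | nodes[j]["leaves"]}
        active = [a for a in active if a not in (i, j)] + [nxt]
        nxt += 1
    values = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        for b in range(n_leaves):
            if a != b:
                values[a, b] = dist[frozenset((labels[a], labels[b]))]
    return labels, values


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(labels=["A", "B"],
                            values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = nj_tree(dm)
        dists = _patristic(tree)
        assert dists[frozenset(("A", "B"))] == pytest.approx(1.0)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.5)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:2,B:3):1,(C:4,D:5)): path lengths below
        values = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        dm = DistanceMatrix(labels=["A", "B", "C", "D"], values=values)
        tree = nj_tree(dm)
        assert _bipartitions(tree) == {frozenset(("C", "D"))} or \
            _bipartitions(tree) == {frozenset(("A", "B"))}
        dists = _patristic(tree)
        for (i, a) in enumerate("ABCD"):
            for (j, b) in enumerate("ABCD"):
                if i < j:
                    assert dists[frozenset((a, b))] == pytest.approx(
                        values[i, j]
                    )

    @pytest.mark.parametrize("seed,n_leaves", [(1, 5), (2, 6), (3, 7),
                                               (4, 8), (5, 8)])
    def test_random_additive_trees_recovered(self, seed, n_leaves):
        """Additivity guarantees NJ recovers the generating tree exactly."""
        labels, values = _random_additive_tree(seed, n_leaves)
        tree = nj_tree(DistanceMatrix(labels=labels, values=values))
        dists = _patristic(tree)
        for i in range(n_leaves):
            for j in range(i + 1, n_leaves):
                assert dists[frozenset((labels[i], labels[j]))] == \
                    pytest.approx(values[i, j], abs=1e-9)

    def test_equidistant_taxa_zero_internal_branches(self):
        values = np.full((5, 5), 0.4)
        np.fill_diagonal(values, 0.0)
        tree = nj_tree(DistanceMatrix(labels=list("ABCDE"), values=values))
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node and not node.is_leaf():
                assert node.edge.length == pytest.approx(0.0, abs=1e-12)

    def test_undefined_entry_rejected_naming_pair(self):
        values = np.array([[0.0, np.nan], [np.nan, 0.0]])
        dm = DistanceMatrix(labels=["A", "B"], values=values)
        with pytest.raises(ValueError, match="A.*B"):
            nj_tree(dm)

    def test_topology_agrees_with_skbio(self):
        """Independent cross-check: same bipartitions as scikit-bio's NJ
        on a random perturbed-additive matrix."""
        import io

        import skbio

        labels, values = _random_additive_tree(11, 7)
        rng = np.random.default_rng(12)
        noise = rng.uniform(-0.01, 0.01, size=values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        values = values + noise
        ours = nj_tree(DistanceMatrix(labels=labels, values=values))

        sk_dm = skbio.DistanceMatrix(values, ids=labels)
        sk_tree = skbio.tree.nj(sk_dm)
        sk_dendro = dendropy.Tree.get(
            data=str(sk_tree), schema="newick"
        )
        assert _bipartitions(ours) == _bipartitions(sk_dendro)


class TestBootstrap:
    def _congruent_alignment(self, length=60):
        # every column supports the split {A,B} | {C,D}
        half = length // 2
        return _seqs([
            ("A", "A" * half + "G" * half),
            ("B", "A" * half + "G" * half),
            ("C", "C" * half + "T" * half),
            ("D", "C" * half + "T" * half),
        ])

    def test_congruent_alignment_full_support(self):
        tree = bootstrap_tree(
            self._congruent_alignment(),
            PhyloConfig(bootstrap_replicates=200, seed=1, model="p"),
        )
        supports = [n.support for n in tree.preorder_node_iter()
                    if n is not tree.seed_node and not n.is_leaf()]
        assert supports and all(s == 100 for s in supports)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            bootstrap_tree(
                self._congruent_alignment(),
                PhyloConfig(bootstrap_replicates=0, seed=1, model="p"),
            )

    def test_same_seed_same_supports(self, sim_panel):
        _, panel, _ = sim_panel
        cfg = PhyloConfig(bootstrap_replicates=100, seed=5)
        t1 = bootstrap_tree(panel.loci["16S"], cfg)
        t2 = bootstrap_tree(panel.loci["16S"], cfg)
        s1 = sorted(n.support for n in t1.preorder_node_iter()
                    if n is not t1.seed_node and not n.is_leaf())
        s2 = sorted(n.support for n in t2.preorder_node_iter()
                    if n is not t2.seed_node and not n.is_leaf())
        assert s1 == s2

    def test_supports_bounded_and_order_invariant(self, sim_panel):
        _, panel, _ = sim_panel
        seqs = panel.loci["16S"]
        cfg = PhyloConfig(bootstrap_replicates=100, seed=9)

        def support_map(tree):
            out = {}
            for node in tree.preorder_node_iter():
                if node is tree.seed_node or node.is_leaf():
                    continue
                key = frozenset(lf.taxon.label for lf in node.leaf_iter())
                out[key] = node.support
            return out

        m1 = support_map(bootstrap_tree(seqs, cfg))
        m2 = support_map(bootstrap_tree(list(reversed(seqs)), cfg))
        assert all(0 <= s <= 100 for s in m1.values())
        assert m1 == m2  # canonical internal ordering: exact invariance

    def test_true_lineage_split_strongly_supported(self, sim_panel):
        """The simulated two-lineage split gets near-total support."""
        _, panel, _ = sim_panel
        tree = bootstrap_tree(
            panel.loci["16S"], PhyloConfig(bootstrap_replicates=100, seed=3)
        )
        labels = sorted(s.id for s in panel.loci["16S"])
        anchor, n = labels[0], len(labels)
        l1 = frozenset(s.id for s in panel.loci["16S"] if s.lineage == "L1")
        l1_side = frozenset(set(labels) - l1) if anchor in l1 else l1
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf():
                continue
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
            side = frozenset(set(labels) - leaves) if anchor in leaves else leaves
            if side == l1_side:
                assert node.support >= 90
                return
        pytest.fail("lineage split not present in the NJ tree")


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=["A", "B"],
                       values=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(labels=["A", "B"],
                       values=np.array([[1.0, 1.0], [1.0, 0.0]]))


def test_compute_distance_matrix_models(sim_panel):
    _, panel, _ = sim_panel
    seqs = panel.loci["16S"][:4]
    dm_p = compute_distance_matrix(seqs, model="p")
    dm_t = compute_distance_matrix(seqs, model="TN93")
    assert dm_p.values.shape == (4, 4)
    off = ~np.eye(4, dtype=bool)
    assert (dm_t.values[off] >= dm_p.values[off] - 1e-12).all()
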