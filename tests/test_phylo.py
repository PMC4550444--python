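"""Supermatrix assembly, distance models, neighbor joining, bootstrap."""

import math

import dendropy
import numpy as np
import pytest

from mitochar.errors import MitocharError
from mitochar.phylo import (
    PCG_ORDER,
    DistanceMatrix,
    Supermatrix,
    build_supermatrix,
    bootstrap_support,
    nj_tree,
    pairwise_distance,
)
from mitochar.synthetic_data import SimParams, generate_mitogenome, generate_taxon_family


@pytest.fixture(scope="module")
def family4():
    tree = "((A:0.02,B:0.03):0.06,(C:0.04,D:0.02):0.06);"
    genomes, newick = generate_taxon_family(SimParams(seed=7), tree)
    return genomes, newick


class TestBuildSupermatrix:
    def test_width_is_sum_of_gene_widths(self, family4):
        genomes, _ = family4
        sm = build_supermatrix(genomes)
        assert sm.n_columns == sum(b - a for a, b in sm.blocks.values())
        assert set(sm.blocks) == set(PCG_ORDER)
        assert all(len(s) == sm.n_columns for s in sm.sequences)

    def test_missing_gene_raises_naming_taxon_and_gene(self, family4):
        genomes, _ = family4
        name, genome, table = genomes[0]
        from mitochar.mito_io import AnnotationTable

        pruned = AnnotationTable(
            features=[f for f in table.features if f.name != "atp8"],
            genome_length=table.genome_length,
        )
        broken = [(name, genome, pruned)] + list(genomes[1:])
        with pytest.raises(MitocharError, match="atp8"):
            build_supermatrix(broken)

    def test_identical_genomes_give_identical_rows(self, synthetic):
        genome, table, _ = synthetic
        sm = build_supermatrix([("x", genome, table), ("y", genome, table)])
        assert sm.sequences[0] == sm.sequences[1]

    def test_incomplete_stop_remnants_are_trimmed(self, synthetic):
        genome, table, _ = synthetic
        sm = build_supermatrix([("x", genome, table)])
        assert sm.n_columns % 3 == 0


class TestPairwiseDistance:
    def test_identical_rows_are_zero_under_all_models(self, synthetic):
        genome, table, _ = synthetic
        sm = build_supermatrix([("x", genome, table), ("y", genome, table)])
        for model in ("p", "JC69", "K2P"):
            assert pairwise_distance(sm, model)[("x", "y")] == 0.0

    def test_closed_form_quarter_divergence(self):
        sm = Supermatrix(taxa=["a", "b"], sequences=["AAAA", "AAAT"], blocks={})
        assert pairwise_distance(sm, "p")[("a", "b")] == pytest.approx(0.25)
        assert pairwise_distance(sm, "JC69")[("a", "b")] == pytest.approx(
            -0.75 * math.log(1 - 4 * 0.25 / 3)
        )

    def test_k2p_separates_transitions_from_transversions(self):
        # one transition (A<->G) in 10 sites vs one transversion (A<->T)
        s_ts = Supermatrix(taxa=["a", "b"], sequences=["A" * 10, "G" + "A" * 9], blocks={})
        s_tv = Supermatrix(taxa=["a", "b"], sequences=["A" * 10, "T" + "A" * 9], blocks={})
        P, Q = 0.1, 0.1
        d_ts = -0.5 * math.log((1 - 2 * P) * math.sqrt(1.0))
        d_tv = -0.5 * math.log((1 - Q) * math.sqrt(1 - 2 * Q))
        assert pairwise_distance(s_ts, "K2P")[("a", "b")] == pytest.approx(d_ts)
        assert pairwise_distance(s_tv, "K2P")[("a", "b")] == pytest.approx(d_tv)

    def test_saturated_pair_is_flagged(self):
        sm = Supermatrix(taxa=["a", "b", "c"],
                         sequences=["A" * 8, "G" * 8, "A" * 8], blocks={})
        d = pairwise_distance(sm, "JC69")
        assert ("a", "b") in d.undefined_pairs
        assert d[("a", "b")] > d[("a", "c")]

    def test_jc_distance_recovers_simulated_branch_length(self):
        # two taxa at distance 0.1, ~11 kb: the JC69 estimate must fall
        # within 3 standard errors of the truth
        d_true = 0.1
        tree = f"(A:{d_true / 2},B:{d_true / 2});"
        genomes, _ = generate_taxon_family(SimParams(seed=13), tree)
        sm = build_supermatrix(genomes)
        est = pairwise_distance(sm, "JC69")[("A", "B")]
        n = sm.n_columns
        p = 0.75 * (1 - math.exp(-4 * d_true / 3))
        se_p = math.sqrt(p * (1 - p) / n)
        se_d = se_p / (1 - 4 * p / 3)  # delta method
        assert abs(est - d_true) < 3 * se_d

    def test_permutation_equivariance(self, family4):
        genomes, _ = family4
        sm = build_supermatrix(genomes)
        perm = [2, 0, 3, 1]
        sm_p = Supermatrix(
            taxa=[sm.taxa[i] for i in perm],
            sequences=[sm.sequences[i] for i in perm],
            blocks=sm.blocks,
        )
        d = pairwise_distance(sm, "K2P")
        d_p = pairwise_distance(sm_p, "K2P")
        for a in sm.taxa:
            for b in sm.taxa:
                if a != b:
                    assert d[(a, b)] == pytest.approx(d_p[(a, b)])


def _random_additive_matrix(rng, n):
    """Random binary tree with branch lengths -> (taxa, matrix, newick)."""
    taxa = [f"t{k}" for k in range(n)]
    nodes = [(name, None) for name in taxa]
    newicks = {name: name for name in taxa}
    dists = {(a, None): None for a, _ in nodes}
    # build tree by random joins, tracking leaf-to-leaf path lengths
    import itertools

    leaf_depth = {}
    paths = {}
    cluster_leaves = {name: [name] for name in taxa}
    cluster_root_dist = {name: {name: 0.0} for name in taxa}
    active = list(taxa)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la = round(float(rng.uniform(0.05, 1.0)), 3)
        lb = round(float(rng.uniform(0.05, 1.0)), 3)
        new = f"({newicks[a]}:{la},{newicks[b]}:{lb})"
        key = new
        cluster_leaves[key] = cluster_leaves[a] + cluster_leaves[b]
        cluster_root_dist[key] = {}
        for leaf, d in cluster_root_dist[a].items():
            cluster_root_dist[key][leaf] = d + la
        for leaf, d in cluster_root_dist[b].items():
            cluster_root_dist[key][leaf] = d + lb
        for x in cluster_leaves[a]:
            for y in cluster_leaves[b]:
                paths[frozenset((x, y))] = (
                    cluster_root_dist[a][x] + la + cluster_root_dist[b][y] + lb
                )
        active = [c for c in active if c not in (a, b)] + [key]
        newicks[key] = new
    m = np.zeros((n, n))
    for x, y in itertools.combinations(range(n), 2):
        m[x, y] = m[y, x] = paths[frozenset((taxa[x], taxa[y]))]
    return taxa, m, newicks[active[0]] + ";"


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        taxa = ["a", "b", "c"]
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = nj_tree(DistanceMatrix(taxa=taxa, matrix=m))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in t.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(MitocharError):
            nj_tree(DistanceMatrix(taxa=["a", "b"], matrix=np.zeros((2, 2))))

    @pytest.mark.parametrize("n,seed", [(6, 0), (7, 1), (8, 2), (10, 3)])
    def test_additive_matrix_recovered_exactly(self, n, seed):
        rng = np.random.default_rng(seed)
        taxa, m, true_newick = _random_additive_matrix(rng, n)
        est = nj_tree(DistanceMatrix(taxa=taxa, matrix=m))
        tns = dendropy.TaxonNamespace()
        t_true = dendropy.Tree.get(
            data=true_newick, schema="newick", taxon_namespace=tns,
            preserve_underscores=True,
        )
        t_est = dendropy.Tree.get(
            data=est.newick, schema="newick", taxon_namespace=tns,
            preserve_underscores=True,
        )
        t_true.encode_bipartitions()
        t_est.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t_true, t_est)
        assert rf == 0
        # branch lengths: total tree length is preserved under additivity
        assert t_est.length() == pytest.approx(t_true.length(), rel=1e-9)

    def test_two_clean_clades_are_monophyletic(self, family4):
        genomes, _ = family4
        sm = build_supermatrix(genomes)
        t = nj_tree(pairwise_distance(sm, "K2P"))
        assert t.bipartitions() in ({frozenset({"C", "D"})}, {frozenset({"A", "B"})})

    def test_negative_branch_lengths_clamped_with_note(self):
        m = np.array(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.45],
                [0.4, 0.4, 0.0, 0.05],
                [0.4, 0.45, 0.05, 0.0],
            ]
        )
        t = nj_tree(DistanceMatrix(taxa=list("abcd"), matrix=m))
        for leaf in t.tree.leaf_node_iter():
            assert leaf.edge.length >= 0


class TestBootstrap:
    def test_clean_clades_reach_full_support(self, family4):
        genomes, _ = family4
        sm = build_supermatrix(genomes)
        t = bootstrap_support(sm, replicates=25, seed=5)
        labels = [
            n.label
            for n in t.tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert labels and all(lab == "100" for lab in labels)

    def test_zero_replicates_returns_unlabeled_tree(self, family4):
        genomes, _ = family4
        sm = build_supermatrix(genomes)
        t = bootstrap_support(sm, replicates=0, seed=5)
        assert all(
            n.label is None for n in t.tree.preorder_node_iter() if not n.is_leaf()
        )

    def test_same_seed_reproduces_supports(self, family4):
        genomes, _ = family4
        sm = build_supermatrix(genomes)
        t1 = bootstrap_support(sm, replicates=10, seed=42)
        t2 = bootstrap_support(sm, replicates=10, seed=42)
        assert t1.newick == t2.newick


def test_newick_round_trip_is_idempotent(family4):
    genomes, _ = family4
    sm = build_supermatrix(genomes)
    t = nj_tree(pairwise_distance(sm, "K2P"))
    first = t.newick
    reread = dendropy.Tree.get(data=first, schema="newick", preserve_underscores=True)
    second = reread.as_string(schema="newick", suppress_rooting=True).strip()
    reread2 = dendropy.Tree.get(data=second, schema="newick", preserve_underscores=True)
    assert reread2.as_string(schema="newick", suppress_rooting=True).strip() == second
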