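import math
import random

import dendropy
import pytest

from dcjswarm.dcj import dcj_distance
from dcjswarm.median import SolverConfig, make_instance, solve
from dcjswarm.phylo import (
    PhyloTree,
    SearchConfig,
    bipartitions,
    circular_lower_bound,
    enumerate_topologies,
    initialize_internal_genomes,
    matched_root_distance,
    newick_string,
    nj_tree,
    pairwise_distance_matrix,
    read_newick,
    rf_error,
    score_tree,
    search_trees,
    tree_circular_order,
    write_newick,
)
from dcjswarm.simulate import TreeSimConfig, identity_genome, simulate_tree_dataset

from .conftest import linear, random_signed_linear


def quartet(a="A", b="B", c="C", d="D"):
    return PhyloTree.from_edges(
        [("x", a), ("x", b), ("x", "y"), ("y", c), ("y", d)]
    )


SMALL_SEARCH = SearchConfig(solver=SolverConfig(population=8, max_generations=100))


class TestNeighborJoining:
    def test_three_taxa(self):
        t = nj_tree(["A", "B", "C"], [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        assert t.leaves == ["A", "B", "C"]
        assert len(t.internal_nodes) == 1

    def test_additive_quartet_recovered(self):
        # tree ((A,B),(C,D)) with all edges length 1
        dist = [
            [0, 2, 3, 3],
            [2, 0, 3, 3],
            [3, 3, 0, 2],
            [3, 3, 2, 0],
        ]
        t = nj_tree(["A", "B", "C", "D"], dist)
        assert bipartitions(t) == bipartitions(quartet())

    def test_against_dendropy(self, rng):
        # cross-check topology against an independent NJ implementation
        for trial in range(5):
            k = rng.randint(4, 7)
            labels = [f"T{i}" for i in range(k)]
            genomes = {lab: random_signed_linear(30, rng) for lab in labels}
            labs, mat = pairwise_distance_matrix(genomes)
            mine = nj_tree(labs, mat)

            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_csv_of(labs, mat), delimiter=","
            )
            ref = pdm.nj_tree()
            ref_tree = _from_dendropy_topology(ref)
            assert bipartitions(mine) == bipartitions(ref_tree)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B"], [[0, 1], [1, 0]])


def _csv_of(labels, mat):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for lab, row in zip(labels, mat):
        buf.write(lab + "," + ",".join(str(x) for x in row) + "\n")
    buf.seek(0)
    return buf


def _from_dendropy_topology(dt) -> PhyloTree:
    edges = []
    counter = [0]

    def lab(node):
        if node.taxon is not None:
            return node.taxon.label
        if not getattr(node, "_tmp", None):
            counter[0] += 1
            node._tmp = f"_i{counter[0]}"
        return node._tmp

    dt.deroot()
    for e in dt.preorder_edge_iter():
        if e.tail_node is None:
            continue
        edges.append((lab(e.tail_node), lab(e.head_node)))
    return PhyloTree.from_edges(edges)


class TestCircularBound:
    def test_zero_distances(self):
        labels = ["A", "B", "C"]
        assert circular_lower_bound(labels, labels, [[0] * 3] * 3) == 0

    def test_three_leaves_equals_median_lb(self, rng):
        gs = {lab: random_signed_linear(12, rng) for lab in "ABC"}
        labels, mat = pairwise_distance_matrix(gs)
        inst = make_instance(gs["A"], gs["B"], gs["C"])
        assert circular_lower_bound(labels, labels, mat) == inst.median_lb

    def test_bound_below_score(self, rng):
        ds = simulate_tree_dataset(TreeSimConfig(n_leaves=5, n_genes=60, r=3, seed=1))
        leaf_genomes = {lab: ds.genomes[lab] for lab in ds.leaf_labels}
        labels, mat = pairwise_distance_matrix(leaf_genomes)
        tree = PhyloTree.from_edges([(a, b) for a, b, _ in ds.edges])
        score, _ = score_tree(tree, leaf_genomes, SMALL_SEARCH)
        bound = circular_lower_bound(tree_circular_order(tree), labels, mat)
        assert score >= bound


class TestScoring:
    def test_identical_leaves_zero(self):
        g = identity_genome(20)
        tree = quartet()
        score, internals = score_tree(tree, {lab: g for lab in "ABCD"}, SMALL_SEARCH)
        assert score == 0
        assert all(x.partner == g.partner for x in internals.values())

    def test_three_leaf_tree_equals_median(self, rng):
        gs = {lab: random_signed_linear(15, rng) for lab in "ABC"}
        tree = PhyloTree.from_edges([("x", "A"), ("x", "B"), ("x", "C")])
        cfg = SearchConfig(solver=SolverConfig(population=8), seed=5)
        score, internals = score_tree(tree, gs, cfg)
        inst = make_instance(gs["A"], gs["B"], gs["C"])
        assert score >= math.ceil(inst.median_lb)
        assert score == sum(dcj_distance(internals["x"], g) for g in gs.values())

    def test_initialization_nearest_leaves(self):
        g = identity_genome(10)
        tree = quartet()
        internals = initialize_internal_genomes(
            tree, {lab: g for lab in "ABCD"}, SMALL_SEARCH
        )
        assert set(internals) == {"x", "y"}

    def test_simulated_tree_sandwich(self):
        ds = simulate_tree_dataset(TreeSimConfig(n_leaves=6, n_genes=120, r=4, seed=3))
        leaf_genomes = {lab: ds.genomes[lab] for lab in ds.leaf_labels}
        tree = PhyloTree.from_edges([(a, b) for a, b, _ in ds.edges])
        score, _ = score_tree(tree, leaf_genomes, SMALL_SEARCH)
        total_events = sum(c for _, _, c in ds.edges)
        labels, mat = pairwise_distance_matrix(leaf_genomes)
        bound = circular_lower_bound(tree_circular_order(tree), labels, mat)
        assert bound <= score <= total_events


class TestEnumeration:
    @pytest.mark.parametrize("k,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_topology_counts(self, k, count):
        labels = [f"T{i}" for i in range(k)]
        topos = list(enumerate_topologies(labels))
        assert len(topos) == count
        # all distinct by bipartition set
        assert len({bipartitions(t) for t in topos}) == count


class TestSearch:
    def test_identical_leaves_any_topology(self):
        g = identity_genome(12)
        res = search_trees({lab: g for lab in "ABCD"}, SMALL_SEARCH)
        assert res.best_score == 0

    def test_quartet_recovery(self):
        ds = simulate_tree_dataset(TreeSimConfig(n_leaves=4, n_genes=100, r=5, seed=2))
        leaf_genomes = {lab: ds.genomes[lab] for lab in ds.leaf_labels}
        res = search_trees(leaf_genomes, SMALL_SEARCH)
        truth = PhyloTree.from_edges([(a, b) for a, b, _ in ds.edges])
        assert rf_error(res.best_tree, truth) == 0.0

    def test_pruned_equals_exhaustive(self, rng):
        # disable pruning by scoring everything and compare
        ds = simulate_tree_dataset(TreeSimConfig(n_leaves=5, n_genes=60, r=4, seed=8))
        leaf_genomes = {lab: ds.genomes[lab] for lab in ds.leaf_labels}
        res = search_trees(leaf_genomes, SMALL_SEARCH)
        best_unpruned = None
        for topo in enumerate_topologies(list(leaf_genomes)):
            score, _ = score_tree(topo, leaf_genomes, SMALL_SEARCH)
            if best_unpruned is None or score < best_unpruned:
                best_unpruned = score
        assert res.best_score == best_unpruned

    def test_guard_on_large_exhaustive(self):
        g = identity_genome(10)
        genomes = {f"L{i}": g for i in range(10)}
        with pytest.raises(ValueError, match="guard"):
            search_trees(genomes, SearchConfig(exhaustive_guard=9))

    def test_sorted_mode_budget(self):
        ds = simulate_tree_dataset(TreeSimConfig(n_leaves=5, n_genes=50, r=3, seed=4))
        leaf_genomes = {lab: ds.genomes[lab] for lab in ds.leaf_labels}
        cfg = SearchConfig(
            solver=SolverConfig(population=6, max_generations=50),
            mode="lower-bound-sorted",
            time_budget=30.0,
        )
        res = search_trees(leaf_genomes, cfg)
        assert res.best_score >= 0

    def test_sorted_mode_requires_budget(self):
        with pytest.raises(ValueError):
            SearchConfig(mode="lower-bound-sorted")


class TestRfError:
    def test_identical(self):
        assert rf_error(quartet(), quartet()) == 0.0

    def test_five_leaf_one_split_apart(self):
        t1 = PhyloTree.from_edges(
            [("x", "A"), ("x", "B"), ("x", "y"), ("y", "C"), ("y", "z"), ("z", "D"), ("z", "E")]
        )
        t2 = PhyloTree.from_edges(
            [("x", "A"), ("x", "C"), ("x", "y"), ("y", "B"), ("y", "z"), ("z", "D"), ("z", "E")]
        )
        # exactly one internal bipartition differs on each side
        assert rf_error(t1, t2) == pytest.approx((1 + 1) / (2 * 3) * 100)

    def test_symmetric(self, rng):
        labels = [f"T{i}" for i in range(6)]
        topos = list(enumerate_topologies(labels))
        for _ in range(5):
            a = topos[rng.randrange(len(topos))]
            b = topos[rng.randrange(len(topos))]
            assert rf_error(a, b) == rf_error(b, a)

    def test_against_dendropy(self, rng):
        labels = [f"T{i}" for i in range(6)]
        topos = list(enumerate_topologies(labels))
        tns = dendropy.TaxonNamespace()
        for _ in range(5):
            a = topos[rng.randrange(len(topos))]
            b = topos[rng.randrange(len(topos))]
            ta = dendropy.Tree.get(data=newick_string(a), schema="newick", taxon_namespace=tns)
            tb = dendropy.Tree.get(data=newick_string(b), schema="newick", taxon_namespace=tns)
            ta.encode_bipartitions()
            tb.encode_bipartitions()
            sym = dendropy.calculate.treecompare.symmetric_difference(ta, tb)
            assert rf_error(a, b) == pytest.approx(sym / (2 * (6 - 2)) * 100)

    def test_label_mismatch(self):
        with pytest.raises(ValueError):
            rf_error(quartet(), quartet(d="Z"))


class TestNewick:
    def test_three_leaf_round_trip(self, tmp_path):
        t = PhyloTree.from_edges([("x", "A"), ("x", "B"), ("x", "C")])
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert sorted(back.leaves) == ["A", "B", "C"]

    def test_quartet_round_trip(self, tmp_path):
        t = quartet()
        p = tmp_path / "q.nwk"
        write_newick(t, p)
        assert bipartitions(read_newick(p)) == bipartitions(t)

    def test_random_topology_round_trip(self, tmp_path, rng):
        labels = [f"T{i}" for i in range(7)]
        topos = list(enumerate_topologies(labels))
        for i in range(3):
            t = topos[rng.randrange(len(topos))]
            p = tmp_path / f"r{i}.nwk"
            write_newick(t, p)
            assert bipartitions(read_newick(p)) == bipartitions(t)


class TestRootMatching:
    def test_exact_topology_match(self):
        ds = simulate_tree_dataset(TreeSimConfig(n_leaves=5, n_genes=80, r=3, seed=6))
        truth = PhyloTree.from_edges(
            [(a, b) for a, b, _ in ds.edges], genomes=ds.genomes
        )
        # "inferred" tree = truth: matched distance must be 0
        d = matched_root_distance(truth, truth, ds.root_label, ds.genomes[ds.root_label])
        assert d == 0
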