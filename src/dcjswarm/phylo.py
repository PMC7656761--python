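"""Gene-order phylogeny: tree scoring with the median solver, circular
lower bound, neighbor joining, bounded topology search, and RF evaluation.

Scoring follows the iterative framework: seed every internal node with the
median of its three topologically nearest leaves, then sweep the internal
nodes, re-solving the median of each node's three current neighbor genomes
and keeping strict improvements, until a sweep changes nothing.  The tree
score is the sum of DCJ edge lengths.

The circular-ordering bound prunes the topology search: for any circular
leaf ordering induced by a tree's planar embedding, twice the tree score is
at least the sum of consecutive pairwise leaf distances.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import dendropy

from .dcj import dcj_distance
from .genome import Genome
from .median import SolverConfig, make_instance, solve

__all__ = [
    "PhyloTree",
    "SearchConfig",
    "SearchResult",
    "nj_tree",
    "pairwise_distance_matrix",
    "circular_lower_bound",
    "tree_circular_order",
    "initialize_internal_genomes",
    "score_tree",
    "enumerate_topologies",
    "search_trees",
    "rf_error",
    "bipartitions",
    "read_newick",
    "write_newick",
    "matched_root_distance",
]


@dataclass
class PhyloTree:
    """Unrooted binary tree over string-labelled leaves.

    ``adj`` maps every node label to its neighbors; leaves have degree 1,
    internal nodes degree 3.  ``genomes`` optionally assigns genomes to
    nodes (always to leaves when scoring).
    """

    adj: dict[str, tuple[str, ...]]
    genomes: dict[str, Genome] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges: Sequence[tuple[str, str]],
                   genomes: Mapping[str, Genome] | None = None) -> "PhyloTree":
        adj: dict[str, list[str]] = {}
        for a, b in edges:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        return cls({k: tuple(v) for k, v in adj.items()}, dict(genomes or {}))

    @property
    def leaves(self) -> list[str]:
        return sorted(k for k, v in self.adj.items() if len(v) == 1)

    @property
    def internal_nodes(self) -> list[str]:
        return sorted(k for k, v in self.adj.items() if len(v) > 1)

    @property
    def edges(self) -> list[tuple[str, str]]:
        out = []
        for a, nbrs in self.adj.items():
            for b in nbrs:
                if a < b:
                    out.append((a, b))
        return sorted(out)

    def validate_binary(self) -> None:
        for k, v in self.adj.items():
            if len(v) not in (1, 3):
                raise ValueError(f"node {k!r} has degree {len(v)}; tree is not binary")

    def score(self) -> int:
        """Sum of DCJ edge lengths; requires genomes on every node."""
        return sum(dcj_distance(self.genomes[a], self.genomes[b]) for a, b in self.edges)


@dataclass(frozen=True)
class SearchConfig:
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(max_generations=500))
    mode: str = "exhaustive"  # or "lower-bound-sorted"
    time_budget: float | None = None  # seconds, required in sorted mode
    exhaustive_guard: int = 9  # max taxa for exhaustive enumeration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exhaustive", "lower-bound-sorted"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.mode == "lower-bound-sorted" and not (self.time_budget or 0) > 0:
            raise ValueError("sorted mode requires a positive time_budget")


@dataclass
class SearchResult:
    best_tree: PhyloTree
    best_score: int
    scored: int
    pruned: int
    log: list[tuple[int, float, int | None, str]]  # (topology id, bound, score, status)


# -- distance matrices and neighbor joining ------------------------------


def pairwise_distance_matrix(genomes: Mapping[str, Genome]) -> tuple[list[str], list[list[int]]]:
    labels = sorted(genomes)
    k = len(labels)
    mat = [[0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            d = dcj_distance(genomes[labels[i]], genomes[labels[j]])
            mat[i][j] = mat[j][i] = d
    return labels, mat


def nj_tree(labels: Sequence[str], dist: Sequence[Sequence[float]]) -> PhyloTree:
    """Saitou–Nei neighbor joining (topology only)."""
    k = len(labels)
    if k < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = list(labels)
    d = {
        (a, b): float(dist[i][j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }
    edges: list[tuple[str, str]] = []
    next_internal = 1

    while len(nodes) > 3:
        m = len(nodes)
        r = {a: sum(d[(a, b)] for b in nodes if b != a) for a in nodes}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                if best is None or q < best[0]:
                    best = (q, a, b)
        _, a, b = best
        new = f"_nj{next_internal}"
        next_internal += 1
        for c in nodes:
            if c in (a, b):
                continue
            dc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new, c)] = d[(c, new)] = dc
        edges.append((new, a))
        edges.append((new, b))
        nodes.remove(a)
        nodes.remove(b)
        nodes.append(new)
    hub = f"_nj{next_internal}"
    for a in nodes:
        edges.append((hub, a))
    return PhyloTree.from_edges(edges)


# -- circular bound ------------------------------------------------------


def circular_lower_bound(order: Sequence[str], labels: Sequence[str],
                         dist: Sequence[Sequence[float]]) -> float:
    """Half the sum of consecutive pairwise distances along a circular
    leaf ordering; lower-bounds the score of any tree with this embedding."""
    idx = {lab: i for i, lab in enumerate(labels)}
    total = 0.0
    k = len(order)
    for i in range(k):
        a, b = order[i], order[(i + 1) % k]
        total += dist[idx[a]][idx[b]]
    return total / 2


def tree_circular_order(tree: PhyloTree) -> list[str]:
    """Leaves in the order of a deterministic planar (DFS) embedding."""
    leaves = tree.leaves
    if len(leaves) == 1:
        return leaves
    start = tree.internal_nodes[0] if tree.internal_nodes else leaves[0]
    order: list[str] = []
    stack: list[tuple[str, str | None]] = [(start, None)]
    while stack:
        node, parent = stack.pop()
        if len(tree.adj[node]) == 1:
            order.append(node)
        for nb in reversed(sorted(tree.adj[node])):
            if nb != parent:
                stack.append((nb, node))
    return order


# -- tree scoring --------------------------------------------------------


def _path_lengths(tree: PhyloTree, start: str) -> dict[str, int]:
    """Edge-count distances from ``start`` to every node (BFS)."""
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in tree.adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def _solver_for(cfg: SearchConfig, rng: random.Random) -> SolverConfig:
    from dataclasses import replace

    return replace(cfg.solver, seed=rng.randrange(2**31))


def initialize_internal_genomes(
    tree: PhyloTree,
    leaf_genomes: Mapping[str, Genome],
    cfg: SearchConfig,
    rng: random.Random | None = None,
) -> dict[str, Genome]:
    """Seed every internal node with the median of its three topologically
    nearest leaves (ties broken lexicographically by leaf label)."""
    tree.validate_binary()
    rng = rng or random.Random(cfg.seed)
    out: dict[str, Genome] = {}
    for node in tree.internal_nodes:
        dists = _path_lengths(tree, node)
        nearest = sorted(tree.leaves, key=lambda lab: (dists[lab], lab))[:3]
        inst = make_instance(*(leaf_genomes[lab] for lab in nearest))
        out[node] = solve(inst, _solver_for(cfg, rng)).median
    return out


def score_tree(
    tree: PhyloTree,
    leaf_genomes: Mapping[str, Genome],
    cfg: SearchConfig | None = None,
    rng: random.Random | None = None,
    max_sweeps: int = 20,
) -> tuple[int, dict[str, Genome]]:
    """Assign internal genomes and return (tree score, internal genomes).

    Iteratively re-solves the median of each internal node's three current
    neighbor genomes, keeping strict improvements, until a full sweep
    changes nothing (or ``max_sweeps`` is reached).
    """
    cfg = cfg or SearchConfig()
    rng = rng or random.Random(cfg.seed)
    tree.validate_binary()
    genomes: dict[str, Genome] = dict(leaf_genomes)
    genomes.update(initialize_internal_genomes(tree, leaf_genomes, cfg, rng))

    # post-order over internal nodes from a fixed root
    internals = tree.internal_nodes
    root = internals[0]
    order: list[str] = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if node in internals:
            order.append(node)
        for nb in sorted(tree.adj[node]):
            if nb != parent:
                stack.append((nb, node))
    order.reverse()

    for _ in range(max_sweeps):
        improved = False
        for node in order:
            nbrs = [genomes[nb] for nb in sorted(tree.adj[node])]
            cur = sum(dcj_distance(genomes[node], g) for g in nbrs)
            if cur == 0:
                continue
            res = solve(make_instance(*nbrs), _solver_for(cfg, rng))
            if res.score < cur:
                genomes[node] = res.median
                improved = True
        if not improved:
            break

    score = sum(dcj_distance(genomes[a], genomes[b]) for a, b in tree.edges)
    return score, {k: genomes[k] for k in internals}


# -- topology enumeration and search ------------------------------------


def enumerate_topologies(labels: Sequence[str]) -> Iterator[PhyloTree]:
    """All unrooted binary topologies over the labels ((2k-5)!! trees)."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def recurse(edges: list[tuple[str, str]], next_leaf: int, next_internal: int):
        if next_leaf == len(labels):
            yield list(edges)
            return
        leaf = labels[next_leaf]
        hub = f"_t{next_internal}"
        for i in range(len(edges)):
            a, b = edges[i]
            rest = edges[:i] + edges[i + 1 :]
            new_edges = rest + [(a, hub), (hub, b), (hub, leaf)]
            yield from recurse(new_edges, next_leaf + 1, next_internal + 1)

    seed_edges = [("_t0", labels[0]), ("_t0", labels[1]), ("_t0", labels[2])]
    for edges in recurse(seed_edges, 3, 1):
        yield PhyloTree.from_edges(edges)


def search_trees(leaf_genomes: Mapping[str, Genome], cfg: SearchConfig | None = None) -> SearchResult:
    """Bounded search over unrooted binary topologies.

    The neighbor-joining tree is scored first as the best-so-far; candidate
    topologies whose circular-ordering bound exceeds it are pruned.  In
    sorted mode topologies are scored in ascending bound order until the
    time budget runs out.
    """
    cfg = cfg or SearchConfig()
    rng = random.Random(cfg.seed)
    labels, dist = pairwise_distance_matrix(leaf_genomes)
    if len(labels) < 4:
        tree = nj_tree(labels, dist) if len(labels) == 3 else None
        if tree is None:
            raise ValueError("tree search needs >= 3 taxa")
        score, internals = score_tree(tree, leaf_genomes, cfg, rng)
        tree.genomes = {**dict(leaf_genomes), **internals}
        return SearchResult(tree, score, 1, 0, [(0, 0.0, score, "nj")])
    if cfg.mode == "exhaustive" and len(labels) > cfg.exhaustive_guard:
        raise ValueError(
            f"exhaustive search guarded to <= {cfg.exhaustive_guard} taxa; "
            "use mode='lower-bound-sorted'"
        )

    log: list[tuple[int, float, int | None, str]] = []
    njt = nj_tree(labels, dist)
    best_score, internals = score_tree(njt, leaf_genomes, cfg, rng)
    njt.genomes = {**dict(leaf_genomes), **internals}
    best_tree = njt
    nj_bips = bipartitions(njt)
    log.append((-1, circular_lower_bound(tree_circular_order(njt), labels, dist),
                best_score, "nj"))
    scored, pruned = 1, 0

    candidates: list[tuple[float, int, PhyloTree]] = []
    for tid, topo in enumerate(enumerate_topologies(labels)):
        if bipartitions(topo) == nj_bips:
            continue  # already scored as the NJ tree
        bound = circular_lower_bound(tree_circular_order(topo), labels, dist)
        candidates.append((bound, tid, topo))
    if cfg.mode == "lower-bound-sorted":
        candidates.sort(key=lambda t: (t[0], t[1]))

    start_time = time.monotonic()
    for bound, tid, topo in candidates:
        if cfg.mode == "lower-bound-sorted" and time.monotonic() - start_time > cfg.time_budget:
            log.append((tid, bound, None, "budget"))
            break
        if bound > best_score:
            pruned += 1
            log.append((tid, bound, None, "pruned"))
            continue
        score, internals = score_tree(topo, leaf_genomes, cfg, rng)
        scored += 1
        log.append((tid, bound, score, "scored"))
        if score < best_score:
            best_score = score
            topo.genomes = {**dict(leaf_genomes), **internals}
            best_tree = topo
    return SearchResult(best_tree, best_score, scored, pruned, log)


# -- Robinson-Foulds -----------------------------------------------------


def bipartitions(tree: PhyloTree) -> frozenset:
    """Non-trivial bipartitions as canonical frozensets of leaf labels.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf is the canonical representative.
    """
    leaves = set(tree.leaves)
    anchor = min(leaves)
    out = set()
    for a, b in tree.edges:
        if len(tree.adj[a]) == 1 or len(tree.adj[b]) == 1:
            continue  # trivial split
        # collect leaves on b's side of the edge (a, b)
        side = set()
        stack = [(b, a)]
        while stack:
            node, parent = stack.pop()
            if len(tree.adj[node]) == 1:
                side.add(node)
            for nb in tree.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        if anchor in side:
            side = leaves - side
        out.add(frozenset(side))
    return frozenset(out)


def rf_error(inferred: PhyloTree, truth: PhyloTree) -> float:
    """Robinson-Foulds error rate: (FP + FN) / (2 (n - 2)) x 100%."""
    if set(inferred.leaves) != set(truth.leaves):
        raise ValueError("trees have different leaf label sets")
    n = len(truth.leaves)
    if n < 4:
        raise ValueError("RF error needs >= 4 leaves")
    bi = bipartitions(inferred)
    bt = bipartitions(truth)
    fp = len(bi - bt)
    fn = len(bt - bi)
    return (fp + fn) / (2 * (n - 2)) * 100.0


# -- Newick IO (via dendropy) -------------------------------------------


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=taxa)
    internals = tree.internal_nodes
    anchor = internals[0] if internals else tree.leaves[0]
    nodes = {anchor: dt.seed_node}
    dt.seed_node.label = anchor if internals else None
    stack = [(anchor, None)]
    while stack:
        node, parent = stack.pop()
        for nb in sorted(tree.adj[node]):
            if nb == parent:
                continue
            child = nodes[node].new_child()
            if len(tree.adj[nb]) == 1:
                child.taxon = taxa.require_taxon(label=nb)
            else:
                child.label = nb
            nodes[nb] = child
            stack.append((nb, node))
    return dt


def _from_dendropy(dt: dendropy.Tree) -> PhyloTree:
    edges = []
    counter = [0]

    def label_of(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node.label:
            return node.label
        counter[0] += 1
        node.label = f"_n{counter[0]}"
        return node.label

    seed = dt.seed_node
    # suppress a degree-2 seed node (rooted newick of an unrooted tree)
    if len(seed.child_nodes()) == 2 and seed.taxon is None:
        dt.deroot()
    for edge in dt.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        edges.append((label_of(edge.tail_node), label_of(edge.head_node)))
    return PhyloTree.from_edges(edges)


def read_newick(path) -> PhyloTree:
    dt = dendropy.Tree.get(path=str(path), schema="newick",
                           preserve_underscores=True)
    return _from_dendropy(dt)


def write_newick(tree: PhyloTree, path) -> None:
    dt = _to_dendropy(tree)
    dt.write(path=str(path), schema="newick", unquoted_underscores=True,
             suppress_rooting=True)


def newick_string(tree: PhyloTree) -> str:
    return _to_dendropy(tree).as_string(schema="newick", unquoted_underscores=True,
                                        suppress_rooting=True).strip()


# -- evaluation helpers --------------------------------------------------


def _node_signature(tree: PhyloTree, node: str) -> frozenset:
    """Partition of the leaf set induced by deleting an internal node."""
    parts = []
    for nb in tree.adj[node]:
        side = set()
        stack = [(nb, node)]
        while stack:
            cur, parent = stack.pop()
            if len(tree.adj[cur]) == 1:
                side.add(cur)
            for x in tree.adj[cur]:
                if x != parent:
                    stack.append((x, cur))
        parts.append(frozenset(side))
    return frozenset(parts)


def matched_root_distance(
    inferred: PhyloTree, true_tree: PhyloTree, true_root: str, true_root_genome: Genome
) -> int:
    """DCJ distance from the true root genome to the inferred genome at the
    matching internal node (matched by leaf-set partition); falls back to
    the closest internal genome when the topologies disagree at the root."""
    target_sig = _node_signature(true_tree, true_root)
    for node in inferred.internal_nodes:
        if _node_signature(inferred, node) == target_sig:
            return dcj_distance(inferred.genomes[node], true_root_genome)
    return min(
        dcj_distance(inferred.genomes[node], true_root_genome)
        for node in inferred.internal_nodes
    )
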