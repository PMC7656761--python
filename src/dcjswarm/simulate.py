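"""Seeded generators for median-triplet and tree-shaped gene-order datasets.

The ancestor is the identity genome (a single linear chromosome
``1, 2, ..., n``).  Leaves are produced by applying random inversions and
transpositions along edges; event mixes and per-edge counts follow the
evaluation protocols: a fixed count of ``r`` events per triplet edge, and
``round(uniform(0.1 r, 1.9 r))`` events per tree edge.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .genome import Chromosome, Genome, gene_orders_from_genome, genome_from_gene_orders

__all__ = [
    "TripletSimConfig",
    "TreeSimConfig",
    "TripletDataset",
    "TreeDataset",
    "identity_genome",
    "random_inversion",
    "random_transposition",
    "apply_random_events",
    "simulate_triplet",
    "simulate_tree_dataset",
]


def identity_genome(n: int, name: str | None = None) -> Genome:
    """Single linear chromosome (1, 2, ..., n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return genome_from_gene_orders([Chromosome(tuple(range(1, n + 1)))], name)


def _pick_chromosome(chroms: list[Chromosome], rng: random.Random, min_len: int) -> int:
    # weight by number of genes so segments are uniform over the genome
    eligible = [i for i, c in enumerate(chroms) if len(c) >= min_len]
    if not eligible:
        raise ValueError(f"no chromosome with >= {min_len} genes")
    weights = [len(chroms[i]) for i in eligible]
    total = sum(weights)
    r = rng.randrange(total)
    acc = 0
    for i, w in zip(eligible, weights):
        acc += w
        if r < acc:
            return i
    return eligible[-1]


def random_inversion(g: Genome, rng: random.Random) -> Genome:
    """Reverse (and sign-flip) a uniformly chosen segment of one chromosome."""
    chroms = list(gene_orders_from_genome(g))
    ci = _pick_chromosome(chroms, rng, 1)
    genes = list(chroms[ci].genes)
    m = len(genes)
    i = rng.randrange(m)
    j = rng.randrange(m)
    if i > j:
        i, j = j, i
    genes[i : j + 1] = [-x for x in reversed(genes[i : j + 1])]
    chroms[ci] = Chromosome(tuple(genes), chroms[ci].circular)
    return genome_from_gene_orders(chroms, g.name)


def random_transposition(g: Genome, rng: random.Random) -> Genome:
    """Move a uniformly chosen segment to a different position in the same
    chromosome (segment order preserved)."""
    chroms = list(gene_orders_from_genome(g))
    ci = _pick_chromosome(chroms, rng, 3)
    genes = list(chroms[ci].genes)
    m = len(genes)
    while True:
        i = rng.randrange(m)
        j = rng.randrange(m)
        if i > j:
            i, j = j, i
        if j - i + 1 >= m:  # need at least one gene outside the segment
            continue
        # insertion slot among the remaining positions, excluding the
        # original slot (which would be a no-op)
        rest = genes[:i] + genes[j + 1 :]
        slots = [s for s in range(len(rest) + 1) if s != i]
        if not slots:
            continue
        s = slots[rng.randrange(len(slots))]
        genes = rest[:s] + genes[i : j + 1] + rest[s:]
        break
    chroms[ci] = Chromosome(tuple(genes), chroms[ci].circular)
    return genome_from_gene_orders(chroms, g.name)


def apply_random_events(
    g: Genome, count: int, transposition_fraction: float, rng: random.Random
) -> Genome:
    for _ in range(count):
        if transposition_fraction > 0 and rng.random() < transposition_fraction:
            g = random_transposition(g, rng)
        else:
            g = random_inversion(g, rng)
    return g


@dataclass(frozen=True)
class TripletSimConfig:
    n_genes: int = 1000
    r: int = 100  # events per edge
    transposition_fraction: float = 0.0
    seed: int = 0
    poisson_edge_lengths: bool = False  # default: exactly r events per edge

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0 <= self.transposition_fraction <= 1:
            raise ValueError("transposition_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TreeSimConfig:
    n_leaves: int = 12
    n_genes: int = 1000
    r: int = 20  # expected events per edge; actual ~ round(uniform(0.1r, 1.9r))
    transposition_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("n_leaves must be >= 3")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")


@dataclass(frozen=True)
class TripletDataset:
    leaves: tuple[Genome, Genome, Genome]
    true_ancestor: Genome
    config: TripletSimConfig


@dataclass(frozen=True)
class TreeDataset:
    """A simulated unrooted binary tree with every node genome retained.

    ``edges`` is a list of (node, node, event_count); nodes are labels:
    leaves ``L1..Lk``, internals ``N1..N(k-2)``.  The genome-bearing root of
    the simulation is the internal node ``root_label``.
    """

    edges: tuple[tuple[str, str, int], ...]
    genomes: dict[str, Genome]
    leaf_labels: tuple[str, ...]
    root_label: str
    config: TreeSimConfig = field(compare=False)


def simulate_triplet(cfg: TripletSimConfig) -> TripletDataset:
    """Three leaves evolved independently from the identity ancestor."""
    rng = random.Random(cfg.seed)
    ancestor = identity_genome(cfg.n_genes, "ancestor")
    leaves = []
    for i in range(3):
        count = _poisson(cfg.r, rng) if cfg.poisson_edge_lengths else cfg.r
        leaf = apply_random_events(ancestor, count, cfg.transposition_fraction, rng)
        leaves.append(leaf.rename(f"G{i + 1}"))
    return TripletDataset(tuple(leaves), ancestor, cfg)


def _poisson(lam: float, rng: random.Random) -> int:
    # Knuth's method; lam is small in practice
    import math

    limit = math.exp(-lam)
    k, prod = 0, rng.random()
    while prod > limit:
        k += 1
        prod *= rng.random()
    return k


def random_unrooted_topology(n_leaves: int, rng: random.Random) -> list[tuple[str, str]]:
    """Uniform unrooted binary topology by random sequential leaf attachment.

    Returns an edge list over labels L1..Lk (leaves) and N1.. (internals).
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    edges = [("N1", "L1"), ("N1", "L2"), ("N1", "L3")]
    for i in range(4, n_leaves + 1):
        a, b = edges.pop(rng.randrange(len(edges)))
        new_internal = f"N{i - 2}"
        edges += [(a, new_internal), (new_internal, b), (new_internal, f"L{i}")]
    return edges


def simulate_tree_dataset(cfg: TreeSimConfig) -> TreeDataset:
    """Random unrooted binary topology; one internal node carries the
    identity genome and every other node is populated outward along the
    edges, with per-edge event counts drawn uniformly in [0.1r, 1.9r]."""
    rng = random.Random(cfg.seed)
    topo = random_unrooted_topology(cfg.n_leaves, rng)
    lengths = {
        frozenset(e): max(0, round(rng.uniform(0.1 * cfg.r, 1.9 * cfg.r))) for e in topo
    }
    neighbors: dict[str, list[str]] = {}
    for a, b in topo:
        neighbors.setdefault(a, []).append(b)
        neighbors.setdefault(b, []).append(a)

    root = "N1"
    genomes = {root: identity_genome(cfg.n_genes, root)}
    stack = [root]
    while stack:
        node = stack.pop()
        for nb in neighbors[node]:
            if nb in genomes:
                continue
            count = lengths[frozenset((node, nb))]
            genomes[nb] = apply_random_events(
                genomes[node], count, cfg.transposition_fraction, rng
            ).rename(nb)
            stack.append(nb)

    leaf_labels = tuple(sorted((x for x in neighbors if x.startswith("L")),
                               key=lambda s: int(s[1:])))
    edges = tuple((a, b, lengths[frozenset((a, b))]) for a, b in topo)
    return TreeDataset(edges, genomes, leaf_labels, root, cfg)
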