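"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import itertools
import random
from collections import deque

import pytest

from dcjswarm.genome import Chromosome, Genome, genome_from_gene_orders


def linear(*genes: int, name: str | None = None) -> Genome:
    """Single linear chromosome genome."""
    return genome_from_gene_orders([Chromosome(tuple(genes))], name)


def circular(*genes: int, name: str | None = None) -> Genome:
    return genome_from_gene_orders([Chromosome(tuple(genes), circular=True)], name)


def random_signed_linear(n: int, rng: random.Random) -> Genome:
    """Random single-linear-chromosome genome (signed permutation)."""
    perm = list(range(1, n + 1))
    rng.shuffle(perm)
    genes = [g if rng.random() < 0.5 else -g for g in perm]
    return linear(*genes)


def random_genome(n: int, rng: random.Random) -> Genome:
    """Uniformly random genome: a random involution on the 2n extremities
    (pairs become adjacencies, fixed points telomeres)."""
    exts = list(range(2 * n))
    rng.shuffle(exts)
    partner = [-1] * (2 * n)
    while exts:
        a = exts.pop()
        if exts and rng.random() < 0.8:
            b = exts.pop()
            partner[a], partner[b] = b, a
    return Genome.from_partner_list(n, partner)


def all_genomes(n: int):
    """Every genome on n genes (every involution of 2n extremities)."""
    exts = list(range(2 * n))

    def rec(remaining: tuple[int, ...], partner: list[int]):
        if not remaining:
            yield Genome.from_partner_list(n, list(partner))
            return
        a = remaining[0]
        rest = remaining[1:]
        # a as telomere
        yield from rec(rest, partner)
        for i, b in enumerate(rest):
            partner[a], partner[b] = b, a
            yield from rec(rest[:i] + rest[i + 1 :], partner)
            partner[a], partner[b] = -1, -1

    yield from rec(tuple(exts), [-1] * (2 * n))


def all_signed_linear(n: int):
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            yield linear(*[s * g for s, g in zip(signs, perm)])


def bfs_dcj_distance(a: Genome, b: Genome, max_depth: int = 10) -> int:
    """Independent oracle: shortest path over single-DCJ neighbor moves."""
    from dcjswarm.dcj import enumerate_dcj_neighbors

    if a.partner == b.partner:
        return 0
    seen = {a.partner}
    queue = deque([(a, 0)])
    while queue:
        g, d = queue.popleft()
        if d >= max_depth:
            continue
        for h in enumerate_dcj_neighbors(g):
            if h.partner == b.partner:
                return d + 1
            if h.partner not in seen:
                seen.add(h.partner)
                queue.append((h, d + 1))
    raise RuntimeError("BFS oracle exhausted without reaching the target")


def partner_neighbors(partner: tuple[int, ...]):
    """All partner arrays one DCJ away (fast oracle-side neighbor move set,
    independent of the distance formula)."""
    n2 = len(partner)
    elements = []
    seen = set()
    for e, q in enumerate(partner):
        if q == -1:
            elements.append((e,))
        elif e < q:
            elements.append((e, q))
    out = set()

    def emit(repl: dict):
        new = list(partner)
        for k, v in repl.items():
            new[k] = v
        out.add(tuple(new))

    for i, u in enumerate(elements):
        if len(u) == 2:
            a, b = u
            emit({a: -1, b: -1})  # cut
        for v in elements[i + 1 :]:
            if len(u) == 2 and len(v) == 2:
                a, b = u
                c, d = v
                emit({a: c, c: a, b: d, d: b})
                emit({a: d, d: a, b: c, c: b})
            elif len(u) == 2 or len(v) == 2:
                (a, b), (t,) = (u, v) if len(u) == 2 else (v, u)
                emit({a: t, t: a, b: -1})
                emit({b: t, t: b, a: -1})
            else:
                (a,), (b,) = u, v
                emit({a: b, b: a})
    out.discard(partner)
    return out


def bfs_flood(source: tuple[int, ...], max_depth: int) -> dict:
    """Distances from source to every genome within max_depth DCJ ops."""
    dist = {source: 0}
    frontier = [source]
    for depth in range(1, max_depth + 1):
        nxt = []
        for p in frontier:
            for q in partner_neighbors(p):
                if q not in dist:
                    dist[q] = depth
                    nxt.append(q)
        frontier = nxt
        if not frontier:
            break
    return dist


def meet_bfs_distance(a: tuple[int, ...], b: tuple[int, ...], half_depth: int = 2,
                      cap: int = 8) -> int:
    """Independent shortest-path oracle between two partner arrays.

    Floods from ``a`` exhaustively to ``half_depth``, then runs BFS waves
    from ``b``.  Any path of length v has a node at distance
    min(half_depth, v) from ``a``, so after wave j every candidate with
    v <= j + half_depth has been seen; the loop stops exactly then.
    """
    da = bfs_flood(a, half_depth)
    if b in da:
        return da[b]
    best = cap + 1
    db = {b: 0}
    frontier = [b]
    j = 0
    while frontier and best > j + half_depth and j < cap:
        j += 1
        nxt = []
        for p in frontier:
            for q in partner_neighbors(p):
                if q in da:
                    v = j + da[q]
                    if v < best:
                        best = v
                if q not in db:
                    db[q] = j
                    nxt.append(q)
        frontier = nxt
    if best > cap:
        raise RuntimeError("meet-in-the-middle BFS cap exceeded")
    return best


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)


@pytest.fixture
def fig1_pair() -> tuple[Genome, Genome]:
    """The five-gene worked-example pair with C=1, I=2, d=3."""
    return linear(1, 2, 3, 4, 5, name="G1"), linear(3, -2, -1, -4, 5, name="G2")
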