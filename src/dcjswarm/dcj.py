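"""Adjacency graphs, DCJ distance, DCJ operations and sorting-path sampling.

The adjacency graph of two genomes A and B has the elements (adjacencies
and telomeres) of both genomes as vertices and one edge per gene extremity,
joining the A-element and the B-element that contain it.  Its components
are paths and cycles; with C cycles and I odd-length paths the distance is
``n - (C + I/2)``.

Internally components are traversed on the *extremity graph*: nodes are the
``2n`` extremity indices; each genome contributes an edge between the two
extremities of each of its adjacencies.  A component with k extremity nodes
corresponds to an adjacency-graph component with k edges, so cycles map to
cycles and odd paths to components with an odd node count.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import Extremity, Genome, require_same_genes

try:  # optional JIT for the O(n) component walk; pure-Python fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "AdjacencyGraph",
    "DcjOperation",
    "build_adjacency_graph",
    "dcj_distance",
    "apply_dcj",
    "enumerate_dcj_neighbors",
    "optimal_dcj_steps",
    "sample_intermediate",
    "greedy_leafward_walk",
    "sample_sorting_sequence",
]


def _component_counts_kernel(pa, pb):  # pragma: no cover - jitted twin of _component_counts
    n2 = len(pa)
    seen = np.zeros(n2, dtype=np.uint8)
    cycles = 0
    odd_paths = 0
    for s in range(n2):
        if seen[s]:
            continue
        if pa[s] >= 0 and pb[s] >= 0:
            continue
        seen[s] = 1
        size = 1
        use_a = pa[s] >= 0
        cur = s
        while True:
            nxt = pa[cur] if use_a else pb[cur]
            if nxt < 0:
                break
            cur = nxt
            seen[cur] = 1
            size += 1
            use_a = not use_a
        if size % 2 == 1:
            odd_paths += 1
    for s in range(n2):
        if seen[s]:
            continue
        cycles += 1
        cur = s
        use_a = True
        while True:
            seen[cur] = 1
            cur = pa[cur] if use_a else pb[cur]
            use_a = not use_a
            if cur == s and use_a:
                break
    return cycles, odd_paths


def _fix_steps_kernel(pa, pb, k, seed):  # pragma: no cover - jitted twin of _fix_steps
    np.random.seed(seed)
    n2 = pa.shape[0]
    todo = np.empty(n2, dtype=np.int32)
    m = 0
    for p in range(n2):
        q = pb[p]
        if q > p and pa[p] != q:
            todo[m] = p
            m += 1
    for i in range(m - 1, 0, -1):  # Fisher-Yates
        j = np.random.randint(0, i + 1)
        todo[i], todo[j] = todo[j], todo[i]
    ops = 0
    for i in range(m):
        if ops == k:
            return ops
        p = todo[i]
        q = pb[p]
        if pa[p] == q:
            continue
        u = pa[p]
        v = pa[q]
        pa[p] = q
        pa[q] = p
        if u >= 0 and v >= 0:
            pa[u] = v
            pa[v] = u
        elif u >= 0:
            pa[u] = -1
        elif v >= 0:
            pa[v] = -1
        ops += 1
    if ops == k:
        return ops
    m = 0
    for p in range(n2):
        if pb[p] == -1 and pa[p] != -1:
            todo[m] = p
            m += 1
    for i in range(m - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        todo[i], todo[j] = todo[j], todo[i]
    for i in range(m):
        if ops == k:
            return ops
        p = todo[i]
        x = pa[p]
        if x == -1:
            continue
        pa[p] = -1
        pa[x] = -1
        ops += 1
    return ops


def _make_climb_kernel(counts):  # pragma: no cover - jit factory
    def kernel(pa, leaves, steps, seed, general_prob):
        """Greedy sideways walk toward the three leaves.

        Each step proposes one DCJ that is an optimal sorting step toward a
        randomly chosen leaf: either installing one of that leaf's missing
        adjacencies (greedy sampling) or a general component split, which
        can create adjacencies present in no leaf.  Steps that worsen the
        summed distance are reverted; sideways steps are kept.
        """
        np.random.seed(seed)
        n2 = pa.shape[0]
        n = n2 // 2
        f = 0
        for li in range(3):
            c, o = counts(pa, leaves[li])
            f += n - c - o // 2
        for _ in range(steps):
            pb = leaves[np.random.randint(0, 3)]
            p = -1
            qq = -1
            if np.random.random() < general_prob:
                # general split: walk the adjacency-graph component from a
                # random extremity and pick a partner one B-edge past an
                # alternating-walk position (the split orientation that
                # extracts a cycle)
                for _ in range(32):
                    s = np.random.randint(0, n2)
                    if pa[s] >= 0 and pb[s] >= 0:
                        p = s
                        break
                if p < 0:
                    continue
                cand = np.empty(64, dtype=np.int32)
                nc = 0
                cur = p
                use_b = True
                for _ in range(64):
                    nxt = pb[cur] if use_b else pa[cur]
                    if nxt < 0:
                        break
                    cur = nxt
                    if cur == p:
                        break
                    if use_b:
                        cand[nc] = cur
                        nc += 1
                    use_b = not use_b
                if nc == 0:
                    continue
                qq = cand[np.random.randint(0, nc)]
                if qq == pa[p] or qq == p:
                    continue
            else:
                for _ in range(64):  # rejection-sample a missing leaf adjacency
                    s = np.random.randint(0, n2)
                    q = pb[s]
                    if q >= 0 and pa[s] != q:
                        p = s
                        qq = q
                        break
                if p < 0:
                    continue
            u = pa[p]
            v = pa[qq]
            pa[p] = qq
            pa[qq] = p
            if u >= 0 and v >= 0:
                pa[u] = v
                pa[v] = u
            elif u >= 0:
                pa[u] = -1
            elif v >= 0:
                pa[v] = -1
            nf = 0
            for li in range(3):
                c, o = counts(pa, leaves[li])
                nf += n - c - o // 2
            if nf <= f:
                f = nf
            else:  # undo
                pa[p] = u
                pa[qq] = v
                if u >= 0:
                    pa[u] = p
                if v >= 0:
                    pa[v] = qq
        return f

    return kernel


if _njit is not None:
    _component_counts_jit = _njit(cache=False, nogil=True)(_component_counts_kernel)
    _fix_steps_jit = _njit(cache=False, nogil=True)(_fix_steps_kernel)
    _climb_jit = _njit(cache=False, nogil=True)(_make_climb_kernel(_component_counts_jit))
else:  # pragma: no cover
    _component_counts_jit = None
    _fix_steps_jit = None
    _climb_jit = None


def _as_int32(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return np.array(seq, dtype=np.int32)


def _component_counts(pa: Sequence[int], pb: Sequence[int]) -> tuple[int, int]:
    """Count (cycles, odd paths) of the adjacency graph. O(n)."""
    if _component_counts_jit is not None:
        return _component_counts_jit(_as_int32(pa), _as_int32(pb))
    n2 = len(pa)
    seen = bytearray(n2)
    cycles = 0
    odd_paths = 0
    for s in range(n2):
        if seen[s]:
            continue
        a_link = pa[s]
        b_link = pb[s]
        if a_link >= 0 and b_link >= 0:
            continue  # interior node; handled when a path endpoint reaches it
        # s is a path endpoint: walk to the other end, alternating sides
        seen[s] = 1
        size = 1
        use_a = a_link >= 0  # the missing side is where the path ends
        cur = s
        while True:
            nxt = pa[cur] if use_a else pb[cur]
            if nxt < 0:
                break
            cur = nxt
            seen[cur] = 1
            size += 1
            use_a = not use_a
        if size % 2 == 1:
            odd_paths += 1
    for s in range(n2):
        if seen[s]:
            continue
        # remaining components are cycles
        cycles += 1
        cur = s
        use_a = True
        while True:
            seen[cur] = 1
            cur = pa[cur] if use_a else pb[cur]
            use_a = not use_a
            if cur == s and use_a:
                break
    return cycles, odd_paths


@dataclass(frozen=True)
class AdjacencyGraph:
    """Component decomposition of two genomes."""

    n: int
    components: tuple  # of (kind, extremity index chain) with kind in {"cycle","odd_path","even_path"}
    cycles: int
    odd_paths: int

    @property
    def distance(self) -> int:
        assert self.odd_paths % 2 == 0, "odd-path count must be even for equal gene content"
        return self.n - self.cycles - self.odd_paths // 2


def build_adjacency_graph(a: Genome, b: Genome) -> AdjacencyGraph:
    """Build the full component decomposition (explicit chains)."""
    require_same_genes(a, b)
    pa, pb = a.partner, b.partner
    n2 = 2 * a.n
    seen = bytearray(n2)
    components: list[tuple[str, tuple[int, ...]]] = []

    for s in range(n2):
        if seen[s] or (pa[s] >= 0 and pb[s] >= 0):
            continue
        chain = [s]
        seen[s] = 1
        use_a = pa[s] >= 0
        cur = s
        while True:
            nxt = pa[cur] if use_a else pb[cur]
            if nxt < 0:
                break
            cur = nxt
            seen[cur] = 1
            chain.append(cur)
            use_a = not use_a
        kind = "odd_path" if len(chain) % 2 == 1 else "even_path"
        components.append((kind, tuple(chain)))
    for s in range(n2):
        if seen[s]:
            continue
        chain = []
        cur = s
        use_a = True
        while True:
            chain.append(cur)
            seen[cur] = 1
            cur = pa[cur] if use_a else pb[cur]
            use_a = not use_a
            if cur == s and use_a:
                break
        components.append(("cycle", tuple(chain)))

    cycles = sum(1 for k, _ in components if k == "cycle")
    odd = sum(1 for k, _ in components if k == "odd_path")
    return AdjacencyGraph(a.n, tuple(components), cycles, odd)


def dcj_distance(a: Genome, b: Genome) -> int:
    """DCJ distance ``n - (C + I/2)``."""
    require_same_genes(a, b)
    if _component_counts_jit is not None:
        cycles, odd = _component_counts_jit(a.pnp, b.pnp)
    else:
        cycles, odd = _component_counts(a.partner, b.partner)
    assert odd % 2 == 0
    return a.n - cycles - odd // 2


def _dist_partner(pa: Sequence[int], pb: Sequence[int], n: int) -> int:
    cycles, odd = _component_counts(pa, pb)
    return n - cycles - odd // 2


# -- explicit DCJ operations --------------------------------------------


@dataclass(frozen=True)
class DcjOperation:
    """Replace ``operands`` (1 or 2 elements of a genome) with ``products``.

    Covers the four cases: rejoining two adjacencies (two variants),
    rejoining an adjacency with a telomere (two variants), joining two
    telomeres, and cutting an adjacency into two telomeres.
    """

    operands: tuple  # frozensets of Extremity
    products: tuple  # frozensets of Extremity

    def __post_init__(self) -> None:
        op_exts = frozenset().union(*self.operands)
        pr_exts = frozenset().union(*self.products)
        if op_exts != pr_exts:
            raise ValueError("products must cover exactly the operand extremities")

    @property
    def kind(self) -> str:
        sizes = sorted(len(x) for x in self.operands)
        if sizes == [2, 2]:
            return "rejoin-adjacencies"
        if sizes == [1, 2]:
            return "rejoin-adjacency-telomere"
        if sizes == [1, 1]:
            return "join-telomeres"
        return "cut-adjacency"

    @property
    def inverse(self) -> "DcjOperation":
        return DcjOperation(self.products, self.operands)


def apply_dcj(g: Genome, op: DcjOperation) -> Genome:
    """Apply one DCJ operation, returning a new genome."""
    elements = set(g.elements)
    for operand in op.operands:
        if operand not in elements:
            raise ValueError(f"operand {set(operand)} not present in genome")
        elements.remove(operand)
    elements.update(op.products)
    return Genome.from_elements(g.n, elements, g.name)


def enumerate_dcj_neighbors(g: Genome) -> list[Genome]:
    """All distinct genomes reachable by exactly one DCJ operation."""
    elems = sorted(g.elements, key=lambda s: sorted(s))
    out: dict[tuple, Genome] = {}

    def emit(replaced: set, added: list) -> None:
        new = set(g.elements) - replaced | set(added)
        h = Genome.from_elements(g.n, new)
        out[h.partner] = h

    for i, u in enumerate(elems):
        if len(u) == 2:
            x, y = sorted(u)
            emit({u}, [frozenset({x}), frozenset({y})])  # cut
        for v in elems[i + 1 :]:
            if len(u) == 2 and len(v) == 2:
                a, b = sorted(u)
                c, d = sorted(v)
                emit({u, v}, [frozenset({a, c}), frozenset({b, d})])
                emit({u, v}, [frozenset({a, d}), frozenset({b, c})])
            elif len(u) == 2 or len(v) == 2:
                adj, tel = (u, v) if len(u) == 2 else (v, u)
                (t,) = tel
                a, b = sorted(adj)
                emit({u, v}, [frozenset({a, t}), frozenset({b})])
                emit({u, v}, [frozenset({b, t}), frozenset({a})])
            else:
                (a,) = u
                (b,) = v
                emit({u, v}, [frozenset({a, b})])
    out.pop(g.partner, None)  # exclude no-ops (possible via symmetric rejoins)
    return list(out.values())


def _op_from_indices(operands: list[list[int]], products: list[list[int]]) -> DcjOperation:
    to_fs = lambda idxs: frozenset(Extremity.from_index(i) for i in idxs)
    return DcjOperation(tuple(to_fs(o) for o in operands), tuple(to_fs(p) for p in products))


def _even_path_through(pa: Sequence[int], pb: Sequence[int], e: int) -> bool:
    """True if extremity ``e`` (a B-telomere, in an A-adjacency) lies on an
    even-length path of the adjacency graph."""
    # walk away from the B-telomere end; component size parity decides
    size = 1
    cur = e
    use_a = True  # pb[e] == -1, so the path continues on the A side
    while True:
        nxt = pa[cur] if use_a else pb[cur]
        if nxt < 0:
            return size % 2 == 0
        cur = nxt
        size += 1
        use_a = not use_a


def optimal_dcj_steps(current: Genome, target: Genome) -> list[DcjOperation]:
    """Enumerate optimal DCJ operations: each reduces d(current, target) by 1.

    One operation per unsatisfied target element: fixing a target adjacency
    is always optimal; cutting at a target telomere is optimal exactly when
    its component is an even path.
    """
    require_same_genes(current, target)
    pa, pb = current.partner, target.partner
    ops: list[DcjOperation] = []
    n2 = 2 * current.n
    for p in range(n2):
        q = pb[p]
        if q > p and pa[p] != q:  # target adjacency {p,q} missing from current
            u, v = pa[p], pa[q]
            operands = []
            operands.append([p] if u < 0 else [p, u])
            if v == p:  # p,q share an element only if current has {p,q}; excluded
                raise AssertionError
            operands.append([q] if v < 0 else [q, v])
            products = [[p, q]]
            if u >= 0 and v >= 0:
                products.append([u, v])
            elif u >= 0:
                products.append([u])
            elif v >= 0:
                products.append([v])
            ops.append(_op_from_indices(operands, products))
        elif q == -1 and pa[p] != -1 and _even_path_through(pa, pb, p):
            x = pa[p]
            if not (pb[x] == -1 and x < p):  # avoid listing the same cut twice
                ops.append(_op_from_indices([[p, x]], [[p], [x]]))
    return ops


def _fix_steps(pa: list[int], pb: Sequence[int], rng: random.Random, k: int) -> int:
    """Apply up to ``k`` optimal sorting steps to ``pa`` (in place), moving it
    toward ``pb``.  Target adjacencies are fixed in random order, then
    telomere cuts in random order.  Returns the number of steps applied."""
    n2 = len(pa)
    todo = [(p, q) for p in range(n2) if (q := pb[p]) > p and pa[p] != q]
    rng.shuffle(todo)
    ops = 0
    for p, q in todo:
        if ops == k:
            return ops
        if pa[p] == q:
            continue  # satisfied for free by an earlier leftover join
        u, v = pa[p], pa[q]
        pa[p], pa[q] = q, p
        if u >= 0 and v >= 0:
            pa[u], pa[v] = v, u
        elif u >= 0:
            pa[u] = -1
        elif v >= 0:
            pa[v] = -1
        ops += 1
    if ops == k:
        return ops
    tels = [p for p in range(n2) if pb[p] == -1 and pa[p] != -1]
    rng.shuffle(tels)
    for p in tels:
        if ops == k:
            return ops
        x = pa[p]
        if x == -1:
            continue  # already cut from the other side
        pa[p] = -1
        pa[x] = -1
        ops += 1
    return ops


def sample_intermediate(source: Genome, target: Genome, k: int, rng: random.Random) -> Genome:
    """A genome R with ``d(source, R) = k`` and ``d(R, target) = d - k``,
    obtained by applying ``k`` randomly ordered optimal sorting steps."""
    require_same_genes(source, target)
    if k == 0:
        return source
    d = dcj_distance(source, target)
    if not 0 <= k <= d:
        raise ValueError(f"k={k} outside [0, d={d}]")
    if _fix_steps_jit is not None:
        pa = source.pnp.copy()
        applied = _fix_steps_jit(pa, target.pnp, k, rng.randrange(1 << 31))
        assert applied == k
        out = Genome._unchecked(source.n, tuple(pa.tolist()))
        out.__dict__["pnp"] = pa
        return out
    pa = list(source.partner)
    applied = _fix_steps(pa, target.partner, rng, k)
    assert applied == k
    return Genome._unchecked(source.n, tuple(pa))


def greedy_leafward_walk(
    start: Genome,
    leaves: Sequence[Genome],
    steps: int,
    rng: random.Random,
    general_prob: float = 0.3,
) -> tuple[Genome, int]:
    """Plateau walk used as the solver's diversification move.

    Takes up to ``steps`` single optimal DCJ sorting steps, each toward a
    randomly chosen leaf, reverting any step that increases the summed
    distance to the three leaves (sideways steps are kept).  With
    probability ``general_prob`` a step is drawn from the general
    cycle-splitting operations instead of the greedy adjacency installs;
    general splits can create adjacencies present in no leaf, which optimal
    medians routinely require.  Returns ``(genome, summed distance)``.
    """
    assert len(leaves) == 3
    n = start.n
    if _climb_jit is not None:
        stack = np.stack([g.pnp for g in leaves])
        pa = start.pnp.copy()
        f = _climb_jit(pa, stack, steps, rng.randrange(1 << 31), general_prob)
        out = Genome._unchecked(n, tuple(pa.tolist()))
        out.__dict__["pnp"] = pa
        return out, int(f)

    # pure-Python fallback (same proposal scheme, different RNG stream)
    pbs = [g.partner for g in leaves]
    pa = list(start.partner)
    f = sum(_dist_partner(pa, pb, n) for pb in pbs)
    n2 = 2 * n
    for _ in range(steps):
        pb = pbs[rng.randrange(3)]
        p = qq = -1
        if rng.random() < general_prob:
            for _ in range(32):
                s = rng.randrange(n2)
                if pa[s] >= 0 and pb[s] >= 0:
                    p = s
                    break
            if p < 0:
                continue
            cand = []
            cur = p
            use_b = True
            for _ in range(64):
                nxt = pb[cur] if use_b else pa[cur]
                if nxt < 0 or nxt == p:
                    break
                cur = nxt
                if use_b:
                    cand.append(cur)
                use_b = not use_b
            if not cand:
                continue
            qq = cand[rng.randrange(len(cand))]
            if qq == pa[p] or qq == p:
                continue
        else:
            for _ in range(64):
                s = rng.randrange(n2)
                q = pb[s]
                if q >= 0 and pa[s] != q:
                    p, qq = s, q
                    break
            if p < 0:
                continue
        u, v = pa[p], pa[qq]
        pa[p], pa[qq] = qq, p
        if u >= 0 and v >= 0:
            pa[u], pa[v] = v, u
        elif u >= 0:
            pa[u] = -1
        elif v >= 0:
            pa[v] = -1
        nf = sum(_dist_partner(pa, pb2, n) for pb2 in pbs)
        if nf <= f:
            f = nf
        else:
            pa[p], pa[qq] = u, v
            if u >= 0:
                pa[u] = p
            if v >= 0:
                pa[v] = qq
    return Genome._unchecked(n, tuple(pa)), f


def sample_sorting_sequence(
    source: Genome, target: Genome, rng: random.Random
) -> list[Genome]:
    """A full optimal sorting scenario: genomes at distance 1, 2, ..., d from
    ``source`` along one randomly sampled optimal path to ``target``."""
    require_same_genes(source, target)
    d = dcj_distance(source, target)
    out = []
    pa = list(source.partner)
    for _ in range(d):
        applied = _fix_steps(pa, target.partner, rng, 1)
        assert applied == 1
        out.append(Genome._unchecked(source.n, tuple(pa)))
    return out
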