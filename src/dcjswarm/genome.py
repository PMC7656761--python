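"""Signed gene-order genomes and their adjacency-set view.

A genome over genes ``1..n`` is a set of *adjacencies* (unordered pairs of
gene extremities) and *telomeres* (singleton extremities), such that every
extremity appears in exactly one element.  The same object can be viewed as
a collection of signed, linear or circular chromosomes.

Orientation convention (fixed once, used everywhere): a positively signed
gene written left-to-right exposes its *tail* to the left neighbour and its
*head* to the right neighbour, so consecutive ``(+a, +b)`` yields the
adjacency ``{a.h, b.t}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Extremity",
    "Adjacency",
    "Chromosome",
    "Genome",
    "GenomeFormatError",
    "genome_from_gene_orders",
    "gene_orders_from_genome",
    "read_gene_order_file",
    "read_gene_order_text",
    "write_gene_order_file",
    "format_gene_orders",
    "adjacency_set",
]

HEAD = "h"
TAIL = "t"


class GenomeFormatError(ValueError):
    """Raised for malformed gene orders or gene-order files."""


@dataclass(frozen=True, order=True)
class Extremity:
    """One end (head or tail) of a gene."""

    gene: int
    end: str  # "h" or "t"

    def __post_init__(self) -> None:
        if self.gene < 1:
            raise GenomeFormatError(f"gene identifier must be >= 1, got {self.gene}")
        if self.end not in (HEAD, TAIL):
            raise GenomeFormatError(f"extremity end must be 'h' or 't', got {self.end!r}")

    def __str__(self) -> str:
        return f"{self.gene}.{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Extremity":
        gene, _, end = text.partition(".")
        try:
            return cls(int(gene), end)
        except ValueError as exc:
            raise GenomeFormatError(f"cannot parse extremity {text!r}") from exc

    @property
    def index(self) -> int:
        """0-based position in the flat extremity array (head first)."""
        return 2 * (self.gene - 1) + (0 if self.end == HEAD else 1)

    @classmethod
    def from_index(cls, idx: int) -> "Extremity":
        return cls(idx // 2 + 1, HEAD if idx % 2 == 0 else TAIL)


# An adjacency (or telomere) is a frozenset of 1 or 2 extremities.
Adjacency = frozenset


def _check_adjacency(adj: frozenset) -> None:
    if not 1 <= len(adj) <= 2:
        raise GenomeFormatError(f"adjacency must have 1 or 2 extremities, got {set(adj)}")


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of signed gene identifiers."""

    genes: tuple[int, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise GenomeFormatError("empty chromosome")
        for g in self.genes:
            if g == 0:
                raise GenomeFormatError("gene identifier 0 is invalid")
        object.__setattr__(self, "genes", tuple(int(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def _head(g: int) -> int:
    return 2 * (g - 1)


def _tail(g: int) -> int:
    return 2 * (g - 1) + 1


def _left_extremity(signed: int) -> int:
    """Extremity facing the left neighbour of a signed gene."""
    return _tail(signed) if signed > 0 else _head(-signed)


def _right_extremity(signed: int) -> int:
    """Extremity facing the right neighbour of a signed gene."""
    return _head(signed) if signed > 0 else _tail(-signed)


@dataclass(frozen=True)
class Genome:
    """Immutable genome over genes ``1..n``.

    Internally stored as a *partner array* of length ``2n``: entry ``e``
    holds the extremity index paired with ``e`` in an adjacency, or ``-1``
    when ``e`` is a telomere.  Extremity ``e`` encodes gene ``e//2 + 1``,
    head when ``e`` is even, tail when odd.
    """

    n: int
    partner: tuple[int, ...]
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.partner) != 2 * self.n:
            raise GenomeFormatError(
                f"partner array length {len(self.partner)} != 2n = {2 * self.n}"
            )
        p = self.partner
        for e, q in enumerate(p):
            if q == -1:
                continue
            if not 0 <= q < 2 * self.n or q == e or p[q] != e:
                raise GenomeFormatError(f"inconsistent partner array at extremity {e}")

    @cached_property
    def pnp(self) -> np.ndarray:
        """Partner array as an int32 numpy array (cached; used by hot paths)."""
        return np.array(self.partner, dtype=np.int32)

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_partner_list(cls, n: int, partner: Sequence[int], name: str | None = None) -> "Genome":
        return cls(n, tuple(partner), name)

    @classmethod
    def _unchecked(cls, n: int, partner: tuple[int, ...], name: str | None = None) -> "Genome":
        # hot-path constructor: caller guarantees a consistent partner array
        self = object.__new__(cls)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "partner", partner)
        object.__setattr__(self, "name", name)
        return self

    @classmethod
    def from_elements(cls, n: int, elements: Iterable[frozenset], name: str | None = None) -> "Genome":
        partner = [-2] * (2 * n)
        for adj in elements:
            _check_adjacency(adj)
            exts = sorted(adj)
            idxs = [x.index for x in exts]
            for i in idxs:
                if not 0 <= i < 2 * n:
                    raise GenomeFormatError(f"extremity {Extremity.from_index(i)} out of range for n={n}")
                if partner[i] != -2:
                    raise GenomeFormatError(
                        f"extremity {Extremity.from_index(i)} appears in more than one element"
                    )
            if len(idxs) == 1:
                partner[idxs[0]] = -1
            else:
                partner[idxs[0]], partner[idxs[1]] = idxs[1], idxs[0]
        missing = [e for e, q in enumerate(partner) if q == -2]
        if missing:
            names = ", ".join(str(Extremity.from_index(e)) for e in missing[:5])
            raise GenomeFormatError(f"extremities not covered: {names}")
        return cls(n, tuple(partner), name)

    # -- views ----------------------------------------------------------

    @property
    def elements(self) -> frozenset:
        """All adjacencies and telomeres as frozensets of :class:`Extremity`."""
        out = set()
        for e, q in enumerate(self.partner):
            if q == -1:
                out.add(frozenset({Extremity.from_index(e)}))
            elif e < q:
                out.add(frozenset({Extremity.from_index(e), Extremity.from_index(q)}))
        return frozenset(out)

    def telomeres(self) -> frozenset:
        return frozenset(
            frozenset({Extremity.from_index(e)})
            for e, q in enumerate(self.partner)
            if q == -1
        )

    def rename(self, name: str | None) -> "Genome":
        return Genome(self.n, self.partner, name)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        chroms = gene_orders_from_genome(self)
        parts = []
        for c in chroms:
            tail = "@" if c.circular else "$"
            parts.append(" ".join(str(g) for g in c.genes) + " " + tail)
        label = f" {self.name!r}" if self.name else ""
        return f"<Genome{label} n={self.n} {' | '.join(parts)}>"


def genome_from_gene_orders(
    chromosomes: Sequence[Chromosome], name: str | None = None
) -> Genome:
    """Build a :class:`Genome` from signed gene-order chromosomes.

    Gene identifiers across all chromosomes must form the set ``1..n``
    with no repeats.
    """
    seen: set[int] = set()
    for chrom in chromosomes:
        for g in chrom.genes:
            mag = abs(g)
            if mag in seen:
                raise GenomeFormatError(f"duplicate gene {mag}")
            seen.add(mag)
    if not seen:
        raise GenomeFormatError("genome has no genes")
    n = max(seen)
    if seen != set(range(1, n + 1)):
        missing = sorted(set(range(1, n + 1)) - seen)
        raise GenomeFormatError(f"gene identifiers must form 1..n; missing {missing[:5]}")

    partner = [-1] * (2 * n)

    def join(a: int, b: int) -> None:
        partner[a], partner[b] = b, a

    for chrom in chromosomes:
        gs = chrom.genes
        for left, right in zip(gs, gs[1:]):
            join(_right_extremity(left), _left_extremity(right))
        if chrom.circular:
            if len(gs) == 1:
                g = abs(gs[0])
                join(_head(g), _tail(g))
            else:
                join(_right_extremity(gs[-1]), _left_extremity(gs[0]))
        # linear chromosomes leave both outer extremities as telomeres
    return Genome.from_partner_list(n, partner, name)


def gene_orders_from_genome(g: Genome) -> list[Chromosome]:
    """Decompose a genome into chromosomes (deterministic ordering).

    Linear chromosomes are reported first, each starting from its
    smallest-indexed telomere; circular chromosomes start at their smallest
    gene, oriented positively.
    """
    p = g.partner
    n2 = 2 * g.n
    seen = [False] * n2
    linear: list[Chromosome] = []
    circular: list[Chromosome] = []

    def walk(start: int) -> list[int]:
        """Walk a chromosome starting at extremity `start` (its outer end)."""
        genes = []
        cur = start
        while True:
            gene = cur // 2 + 1
            sign = 1 if cur % 2 == 1 else -1  # entered at tail => read head-first => positive
            genes.append(sign * gene)
            seen[cur] = True
            other = cur ^ 1  # the opposite extremity of the same gene
            seen[other] = True
            nxt = p[other]
            if nxt == -1 or seen[nxt]:
                return genes
            cur = nxt

    for start in range(n2):
        if not seen[start] and p[start] == -1:
            linear.append(Chromosome(tuple(walk(start)), circular=False))
    for start in range(n2):
        if not seen[start]:
            # circular: start at the tail of the smallest unvisited gene so
            # that it is read positively
            circular.append(Chromosome(tuple(walk(start | 1)), circular=True))
    return linear + circular


def adjacency_set(g: Genome) -> frozenset:
    """Two-extremity elements only (telomeres excluded); used by adjacency accuracy."""
    return frozenset(
        frozenset({Extremity.from_index(e), Extremity.from_index(q)})
        for e, q in enumerate(g.partner)
        if q > e
    )


# -- gene-order file format ---------------------------------------------
#
# Lines beginning ">" start a genome and carry its name; whitespace
# separated signed integers form chromosomes; "$" closes a linear
# chromosome, "@" a circular one; "#" starts a comment line; a new header
# or end of file closes the current genome.


def _parse_lines(lines: Iterable[str]) -> Iterator[Genome]:
    name: str | None = None
    chroms: list[Chromosome] = []
    current: list[int] = []
    in_genome = False
    lineno = 0

    def flush_genome() -> Genome:
        nonlocal chroms, current
        if current:
            chroms.append(Chromosome(tuple(current), circular=False))
            current = []
        if not chroms:
            raise GenomeFormatError(f"genome {name!r} has no chromosomes (line {lineno})")
        genome = genome_from_gene_orders(chroms, name)
        chroms = []
        return genome

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if in_genome:
                yield flush_genome()
            name = line[1:].strip() or None
            in_genome = True
            continue
        if not in_genome:
            raise GenomeFormatError(f"line {lineno}: gene data before any '>' header")
        for tok in line.split():
            if tok == "$":
                if not current:
                    raise GenomeFormatError(f"line {lineno}: '$' closes an empty chromosome")
                chroms.append(Chromosome(tuple(current), circular=False))
                current = []
            elif tok == "@":
                if not current:
                    raise GenomeFormatError(f"line {lineno}: '@' closes an empty chromosome")
                chroms.append(Chromosome(tuple(current), circular=True))
                current = []
            else:
                try:
                    current.append(int(tok))
                except ValueError as exc:
                    raise GenomeFormatError(f"line {lineno}: malformed token {tok!r}") from exc
    if in_genome:
        yield flush_genome()


def read_gene_order_text(text: str) -> list[Genome]:
    return list(_parse_lines(text.splitlines()))


def read_gene_order_file(path) -> list[Genome]:
    """Read all genomes from a gene-order file."""
    with open(path, "r", encoding="utf-8") as fh:
        return list(_parse_lines(fh))


def format_gene_orders(genomes: Sequence[Genome]) -> str:
    out: list[str] = []
    for i, g in enumerate(genomes):
        out.append(f">{g.name or f'genome{i + 1}'}")
        for chrom in gene_orders_from_genome(g):
            mark = "@" if chrom.circular else "$"
            out.append(" ".join(str(x) for x in chrom.genes) + f" {mark}")
    return "\n".join(out) + "\n"


def write_gene_order_file(genomes: Sequence[Genome], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_gene_orders(genomes))


def require_same_genes(a: Genome, b: Genome) -> None:
    if a.n != b.n:
        raise GenomeFormatError(f"genomes have different gene counts: {a.n} vs {b.n}")
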