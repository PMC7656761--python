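"""Discrete quantum-behaved particle-swarm solver for the DCJ median problem.

Given three genomes, find a genome minimizing the sum of its three DCJ
distances (the median score).  Particles are candidate median genomes; all
moves are random walks along optimal DCJ sorting paths:

* the population is seeded from a pool of 36·M sorting-path intermediates
  between the input genomes;
* the mean-best genome (``mbest``) is picked by two successive fitness
  averages (first over all personal bests, then over the better half);
* each particle's local attractor (``pid``) is a fractional sorting-path
  sample from its personal best toward the global best;
* a particle position is updated in two stages, sorting a random number of
  steps toward ``mbest`` and then toward ``pid``, each guarded by a strict
  fitness improvement test.

The search stops when the best score reaches the circular-ordering lower
bound ``(d12 + d13 + d23)/2`` or an iteration cap is hit.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .dcj import dcj_distance, greedy_leafward_walk, sample_intermediate
from .genome import Genome, format_gene_orders, require_same_genes

__all__ = [
    "MedianInstance",
    "SolverConfig",
    "Particle",
    "SwarmState",
    "MedianResult",
    "make_instance",
    "fitness",
    "build_initial_pool",
    "initialize_population",
    "select_cbest",
    "select_mbest",
    "update_pbest",
    "update_pid",
    "update_xid",
    "solve",
]

DEFAULT_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class MedianInstance:
    """Three genomes with cached pairwise distances and the lower bound."""

    g1: Genome
    g2: Genome
    g3: Genome
    d12: int
    d13: int
    d23: int

    @property
    def median_lb(self) -> float:
        """Circular-ordering lower bound (d12 + d13 + d23) / 2."""
        return (self.d12 + self.d13 + self.d23) / 2

    @property
    def genomes(self) -> tuple[Genome, Genome, Genome]:
        return (self.g1, self.g2, self.g3)

    def digest(self) -> str:
        text = format_gene_orders([self.g1, self.g2, self.g3])
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def make_instance(g1: Genome, g2: Genome, g3: Genome) -> MedianInstance:
    require_same_genes(g1, g2)
    require_same_genes(g1, g3)
    return MedianInstance(
        g1, g2, g3,
        dcj_distance(g1, g2), dcj_distance(g1, g3), dcj_distance(g2, g3),
    )


def fitness(gm: Genome, inst: MedianInstance) -> int:
    """Median score: sum of DCJ distances from ``gm`` to the three genomes."""
    return (
        dcj_distance(inst.g1, gm)
        + dcj_distance(inst.g2, gm)
        + dcj_distance(inst.g3, gm)
    )


@dataclass(frozen=True)
class SolverConfig:
    population: int = 20
    max_generations: int = 2150
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    mu: float = 0.5  # fixed by the discrete variant; kept for completeness
    seed: int = 0
    lb_stop: bool = True
    iter_cap_factor: float = 1.5
    cap_mode: str = "min"  # "min" (default) or "max" of the two caps
    escape_after: int | None = 1  # stagnation generations before the leaf-ward
    # perturbation fires; None disables it (the swarm then freezes once the
    # population collapses onto gbest)
    escape_fraction: float = 0.15  # step budget of one escape, as a fraction of d
    general_split_fraction: float = 0.3  # share of escape steps drawn from
    # general cycle-splitting operations rather than greedy adjacency installs

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if self.cap_mode not in ("min", "max"):
            raise ValueError("cap_mode must be 'min' or 'max'")


@dataclass
class Particle:
    x: Genome
    fx: int
    pbest: Genome
    fpbest: int
    pid: Genome | None = None
    fpid: int | None = None


@dataclass
class SwarmState:
    particles: list[Particle]
    t: int = 0
    history: list[int] = field(default_factory=list)

    @property
    def gbest_index(self) -> int:
        return min(range(len(self.particles)), key=lambda i: (self.particles[i].fpbest, i))

    @property
    def gbest(self) -> Genome:
        return self.particles[self.gbest_index].pbest

    @property
    def fgbest(self) -> int:
        return self.particles[self.gbest_index].fpbest


@dataclass(frozen=True)
class MedianResult:
    median: Genome
    score: int
    generations: int
    history: tuple[int, ...]
    median_lb: float

    def to_json_dict(self, inst: MedianInstance, cfg: SolverConfig) -> dict:
        from .genome import gene_orders_from_genome

        return {
            "instance_digest": inst.digest(),
            "config": {
                "population": cfg.population,
                "max_generations": cfg.max_generations,
                "fractions": list(cfg.fractions),
                "seed": cfg.seed,
                "lb_stop": cfg.lb_stop,
                "iter_cap_factor": cfg.iter_cap_factor,
                "cap_mode": cfg.cap_mode,
            },
            "seed": cfg.seed,
            "score": self.score,
            "median_lb": self.median_lb,
            "generations": self.generations,
            "history": list(self.history),
            "median_gene_order": [
                {"genes": list(c.genes), "circular": c.circular}
                for c in gene_orders_from_genome(self.median)
            ],
        }

    def to_json(self, inst: MedianInstance, cfg: SolverConfig) -> str:
        return json.dumps(self.to_json_dict(inst, cfg), indent=2)


# -- initialization ------------------------------------------------------


def build_initial_pool(
    inst: MedianInstance, cfg: SolverConfig, rng: random.Random
) -> list[Genome]:
    """The 36·M candidate pool: for each of M repetitions, each ordered pair
    of distinct input genomes, and each fraction, one sorting-path sample."""
    genomes = inst.genomes
    dists = {
        (0, 1): inst.d12, (1, 0): inst.d12,
        (0, 2): inst.d13, (2, 0): inst.d13,
        (1, 2): inst.d23, (2, 1): inst.d23,
    }
    pool: list[Genome] = []
    for _ in range(cfg.population):
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                d = dists[(i, j)]
                for f in cfg.fractions:
                    k = min(max(_round_half_up(f * d), 0), d)
                    pool.append(sample_intermediate(genomes[i], genomes[j], k, rng))
    return pool


def initialize_population(
    inst: MedianInstance, cfg: SolverConfig, rng: random.Random
) -> list[Genome]:
    """Each particle draws its initial position uniformly (with replacement)
    from the 36·M pool."""
    pool = build_initial_pool(inst, cfg, rng)
    return [pool[rng.randrange(len(pool))] for _ in range(cfg.population)]


# -- mbest selection by two averages ------------------------------------


def select_cbest(fitness_values: Sequence[int]) -> int:
    """Index of the particle whose fitness is closest to the population mean.

    Ties break toward lower fitness, then lower index.
    """
    if not fitness_values:
        raise ValueError("empty population")
    mean = sum(fitness_values) / len(fitness_values)
    return min(
        range(len(fitness_values)),
        key=lambda i: (abs(fitness_values[i] - mean), fitness_values[i], i),
    )


def select_mbest(cbest_index: int, fitness_values: Sequence[int]) -> int:
    """Second averaging step: among the candidates strictly better than
    ``cbest`` plus ``cbest`` itself, the one closest to their mean fitness."""
    fc = fitness_values[cbest_index]
    candidates = [i for i, f in enumerate(fitness_values) if f < fc]
    if not candidates:
        return cbest_index
    candidates.append(cbest_index)
    mean2 = sum(fitness_values[i] for i in candidates) / len(candidates)
    return min(
        candidates,
        key=lambda i: (abs(fitness_values[i] - mean2), fitness_values[i], i),
    )


# -- per-generation updates ---------------------------------------------


def update_pbest(state: SwarmState) -> None:
    """Keep each particle's personal best (strict improvement only)."""
    for p in state.particles:
        if p.fx < p.fpbest:
            p.pbest = p.x
            p.fpbest = p.fx


def update_pid(
    p: Particle,
    gbest: Genome,
    fgbest: int,
    inst: MedianInstance,
    cfg: SolverConfig,
    rng: random.Random,
) -> tuple[Genome, int]:
    """Local attractor: a fraction-of-the-way sorting sample from the
    particle's personal best toward the global best (if strictly better)."""
    if fgbest >= p.fpbest:
        return p.pbest, p.fpbest
    d = dcj_distance(p.pbest, gbest)
    if d == 0:
        return p.pbest, p.fpbest
    f = cfg.fractions[rng.randrange(len(cfg.fractions))]
    k = min(max(_round_half_up(f * d), 1), d)
    pid = sample_intermediate(p.pbest, gbest, k, rng)
    return pid, fitness(pid, inst)


def update_xid(
    p: Particle,
    mbest: Genome,
    fmbest: int,
    inst: MedianInstance,
    cfg: SolverConfig,
    rng: random.Random,
) -> tuple[Genome, int]:
    """Two-stage position update: random sorting steps toward ``mbest``,
    then toward the particle's attractor ``pid``; each stage fires only when
    its target has strictly better fitness."""
    x, fx = p.x, p.fx
    if fmbest < fx:
        d = dcj_distance(x, mbest)
        if d > 0:
            k = rng.randint(1, d)
            x = sample_intermediate(x, mbest, k, rng)
            fx = fitness(x, inst)
    if p.fpid is not None and p.fpid < fx:
        d = dcj_distance(x, p.pid)
        if d > 0:
            k = rng.randint(1, d)
            x = sample_intermediate(x, p.pid, k, rng)
            fx = fitness(x, inst)
    return x, fx


def _escape(
    p: Particle,
    inst: MedianInstance,
    cfg: SolverConfig,
    rng: random.Random,
    intensity: int = 1,
) -> None:
    """Leaf-ward diversification: a short walk of random sorting steps toward
    randomly chosen input genomes, reverting steps that worsen the median
    score (keeps the swarm from freezing once the population collapses onto
    gbest, while drifting across score plateaus).  ``intensity`` scales the
    step budget when the search has been stagnant for a long time."""
    mean_d = (inst.d12 + inst.d13 + inst.d23) / 3
    steps = max(1, round(cfg.escape_fraction * mean_d)) * intensity
    p.x, p.fx = greedy_leafward_walk(
        p.x, inst.genomes, steps, rng, cfg.general_split_fraction
    )


# -- main loop -----------------------------------------------------------


def effective_iteration_cap(inst: MedianInstance, cfg: SolverConfig) -> int:
    lb_cap = math.ceil(cfg.iter_cap_factor * inst.median_lb)
    cap = min(cfg.max_generations, lb_cap) if cfg.cap_mode == "min" else max(
        cfg.max_generations, lb_cap
    )
    return max(cap, 1)


def solve(inst: MedianInstance, cfg: SolverConfig | None = None) -> MedianResult:
    """Run the swarm median search; fully reproducible from ``cfg.seed``."""
    cfg = cfg or SolverConfig()
    rng = random.Random(cfg.seed)
    lb_int = math.ceil(inst.median_lb)
    cap = effective_iteration_cap(inst, cfg)

    xs = initialize_population(inst, cfg, rng)
    particles = [Particle(x, fitness(x, inst), x, 0) for x in xs]
    for p in particles:
        p.fpbest = p.fx
    state = SwarmState(particles)
    state.history.append(state.fgbest)
    stagnant = 0

    while state.t < cap:
        if cfg.lb_stop and state.fgbest <= lb_int:
            break
        state.t += 1
        fvals = [p.fpbest for p in particles]
        mi = select_mbest(select_cbest(fvals), fvals)
        mbest, fmbest = particles[mi].pbest, particles[mi].fpbest
        gi = state.gbest_index
        gbest, fgbest = particles[gi].pbest, particles[gi].fpbest

        for p in particles:
            p.pid, p.fpid = update_pid(p, gbest, fgbest, inst, cfg, rng)
            p.x, p.fx = update_xid(p, mbest, fmbest, inst, cfg, rng)

        prev = state.fgbest
        update_pbest(state)
        if cfg.escape_after is not None:
            stagnant = stagnant + 1 if state.fgbest == prev else 0
            if stagnant >= cfg.escape_after:
                for p in particles:
                    _escape(p, inst, cfg, rng)
                stagnant = 0
        state.history.append(state.fgbest)

    gi = state.gbest_index
    return MedianResult(
        median=particles[gi].pbest,
        score=particles[gi].fpbest,
        generations=state.t,
        history=tuple(state.history),
        median_lb=inst.median_lb,
    )
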