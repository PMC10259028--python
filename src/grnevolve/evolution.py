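"""Genetic algorithm over virtual organisms with coupled sequence/regulatory mutation.

Each generation: survivors are chosen (either the fittest proportion p —
"high pressure" truncation selection — or a uniformly random proportion p —
"relaxed", the neutral control), and N clonal haploid offspring are
produced round-robin from the survivors.  Reproduction mutates the genome
under the Jukes-Cantor point process, and every synonymous or
nonsynonymous event triggers exactly one regulatory mutation in the same
gene, judged against the *parent's* expression matrix.  Offspring develop
and are scored immediately, so expression and fitness are always
consistent with the genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .development import develop, ExpressionMatrix
from .fitness import FitnessBreakdown, FitnessConfig, evaluate_fitness
from .genome import (
    NONSENSE,
    Genome,
    apply_mutations,
    coding_mask,
    init_genome,
    sample_point_mutations,
)
from .regulatory import (
    RegInitConfig,
    RegulatoryParams,
    apply_regulatory_mutation,
    init_regulatory,
)

__all__ = [
    "EvolutionParams",
    "Organism",
    "Population",
    "TraceRecord",
    "reproduce_organism",
    "select_survivors",
    "next_generation",
    "run_branch",
]

HIGH_PRESSURE = "high_pressure"
RELAXED = "relaxed"


@dataclass(frozen=True)
class EvolutionParams:
    """All per-branch parameters of a run.

    ``mu`` is the per-base per-generation point-mutation probability; ``p``
    the surviving proportion; ``strategy`` is ``"high_pressure"``
    (truncation selection on total fitness) or ``"relaxed"`` (random
    survival, the neutral control); ``m`` the number of developmental steps.
    """

    n_genes: int = 5
    gene_length: int = 3000
    mu: float = 5.33333e-6
    p: float = 0.1
    strategy: str = HIGH_PRESSURE
    N: int = 100
    m: int = 20
    seed_quantity: float = 1.0
    fitness_cfg: FitnessConfig = field(default_factory=FitnessConfig)
    reg_cfg: RegInitConfig = field(default_factory=RegInitConfig)

    def __post_init__(self):
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"selection proportion must be in (0, 1], got {self.p}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.mu}")
        if self.N < 1:
            raise ValueError("population size must be >= 1")
        if self.strategy not in (HIGH_PRESSURE, RELAXED):
            raise ValueError(f"unknown selection strategy {self.strategy!r}")

    @property
    def n_survivors(self) -> int:
        return max(1, math.ceil(self.p * self.N))

    def with_overrides(self, **kwargs) -> "EvolutionParams":
        return replace(self, **kwargs)


class Organism:
    """A genome + regulatory genotype with its developed phenotype and fitness."""

    __slots__ = ("genome", "regulatory", "expression", "fitness")

    def __init__(
        self,
        genome: Genome,
        regulatory: RegulatoryParams,
        params: EvolutionParams,
        expression: ExpressionMatrix | None = None,
        fitness: FitnessBreakdown | None = None,
    ):
        self.genome = genome
        self.regulatory = regulatory
        if expression is None:
            expression = develop(
                coding_mask(genome), regulatory, params.m, params.seed_quantity
            )
            fitness = evaluate_fitness(expression, params.fitness_cfg)
        self.expression = expression
        self.fitness = fitness

    @classmethod
    def random(cls, params: EvolutionParams, rng: np.random.Generator) -> "Organism":
        genome = init_genome(params.n_genes, params.gene_length, rng)
        regulatory = init_regulatory(params.n_genes, params.reg_cfg, rng)
        return cls(genome, regulatory, params)

    def copy(self) -> "Organism":
        return Organism.__new__(Organism).__init_copy__(self)

    def __init_copy__(self, other: "Organism") -> "Organism":
        self.genome = other.genome.copy()
        self.regulatory = other.regulatory.copy()
        self.expression = other.expression.copy()
        self.fitness = other.fitness
        return self


@dataclass
class Population:
    """Fixed-size population plus cumulative mutation bookkeeping.

    ``event_counts`` accumulates, across all reproductions in the
    population's history, the number of sequence events by classification
    and the number of regulatory-parameter changes (``reg_changes``) —
    the ledger for the 1-1 sequence/regulation coupling.
    """

    organisms: list[Organism]
    generation_index: int = 0
    event_counts: dict[str, int] = field(
        default_factory=lambda: {
            "synonymous": 0,
            "nonsynonymous": 0,
            "nonsense": 0,
            "reg_changes": 0,
        }
    )

    @property
    def size(self) -> int:
        return len(self.organisms)

    def total_fitnesses(self) -> np.ndarray:
        return np.array([o.fitness.total for o in self.organisms])

    def copy(self) -> "Population":
        return Population(
            [o.copy() for o in self.organisms],
            self.generation_index,
            dict(self.event_counts),
        )


def reproduce_organism(
    parent: Organism,
    params: EvolutionParams,
    rng: np.random.Generator,
    counts: dict[str, int] | None = None,
) -> Organism:
    """Produce one clonal haploid offspring of ``parent``.

    The child genome receives freshly sampled point mutations; each
    synonymous/nonsynonymous event triggers one regulatory mutation in its
    gene against the parent's expression matrix; nonsense events leave the
    regulatory genotype untouched.  The child's expression and fitness are
    recomputed; the parent is unmodified.
    """
    events = sample_point_mutations(parent.genome, params.mu, rng)
    genome = apply_mutations(parent.genome, events) if events else parent.genome.copy()
    regulatory = parent.regulatory
    for ev in events:
        if counts is not None:
            counts[ev.classification] += 1
        if ev.classification == NONSENSE:
            continue
        regulatory, _target = apply_regulatory_mutation(
            regulatory, ev.gene_index, ev.classification, parent.expression, params.reg_cfg, rng
        )
        if counts is not None:
            counts["reg_changes"] += 1
    if regulatory is parent.regulatory:
        regulatory = parent.regulatory.copy()
    return Organism(genome, regulatory, params)


def select_survivors(
    pop: Population, params: EvolutionParams, rng: np.random.Generator
) -> list[Organism]:
    """Choose the k = ceil(pN) survivors of one generation.

    High pressure keeps the k highest total fitnesses, breaking ties
    uniformly at random; relaxed keeps k organisms sampled uniformly
    without replacement.
    """
    k = max(1, math.ceil(params.p * pop.size))
    if params.strategy == RELAXED:
        idx = rng.choice(pop.size, size=k, replace=False)
    else:
        fit = pop.total_fitnesses()
        # random tie-break: sort by (-fitness, random key)
        order = np.lexsort((rng.random(pop.size), -fit))
        idx = order[:k]
    return [pop.organisms[i] for i in idx]


def next_generation(
    pop: Population, params: EvolutionParams, rng: np.random.Generator
) -> Population:
    """One GA step: select survivors, refill to N offspring round-robin."""
    survivors = select_survivors(pop, params, rng)
    k = len(survivors)
    counts = dict(pop.event_counts)
    offspring = [
        reproduce_organism(survivors[i % k], params, rng, counts)
        for i in range(params.N)
    ]
    return Population(offspring, pop.generation_index + 1, counts)


@dataclass(frozen=True)
class TraceRecord:
    """Population summary at one traced generation."""

    generation: int
    mean_total: float
    mean_boundedness: float
    mean_participation: float
    mean_stability: float
    fraction_mature: float
    gene_participation: tuple[float, ...]


def _trace(pop: Population) -> TraceRecord:
    orgs = pop.organisms
    expressed = np.array([o.expression.expressed_mask() for o in orgs])
    return TraceRecord(
        generation=pop.generation_index,
        mean_total=float(np.mean([o.fitness.total for o in orgs])),
        mean_boundedness=float(np.mean([o.fitness.boundedness for o in orgs])),
        mean_participation=float(np.mean([o.fitness.participation for o in orgs])),
        mean_stability=float(np.mean([o.fitness.stability for o in orgs])),
        fraction_mature=float(np.mean([o.fitness.maturity for o in orgs])),
        gene_participation=tuple(float(v) for v in expressed.mean(axis=0)),
    )


def run_branch(
    founders: Population,
    generations: int,
    params: EvolutionParams,
    rng: np.random.Generator,
    trace_every: int = 100,
) -> tuple[Population, list[TraceRecord]]:
    """Iterate the GA for ``generations`` steps, tracing every ``trace_every``.

    The trace includes the founder state (branch-local generation 0), every
    multiple of ``trace_every``, and the final generation.
    """
    if generations < 0:
        raise ValueError("generation count must be nonnegative")
    pop = founders
    trace = [_trace(pop)]
    for g in range(1, generations + 1):
        pop = next_generation(pop, params, rng)
        if g % trace_every == 0 or g == generations:
            trace.append(_trace(pop))
    return pop, trace
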