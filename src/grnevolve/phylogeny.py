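"""Branch-by-branch evolution of populations along a user-defined phylogeny.

Branch lengths of the input Newick tree are generation counts (nonnegative
integers) — time and mutation rate are deliberately separate parameters.
The root population is founded from independent random organisms; at every
split the end-of-branch population is deep-copied into each child branch,
so sister lineages share their ancestor's exact state.  Evolutionary,
regulatory and fitness parameters can be overridden per branch.  Each
branch draws from its own RNG stream, derived deterministically from the
master seed and the branch's position in the tree, so results are
independent of traversal order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ConfigurationError, NewickParseError
from .evolution import (
    EvolutionParams,
    Organism,
    Population,
    TraceRecord,
    run_branch,
)
from .genome import Genome
from .regulatory import RegulatoryParams

__all__ = [
    "BranchNode",
    "PhylogenyPlan",
    "LineageResult",
    "PhylogenyRun",
    "parse_newick_generations",
    "found_population",
    "run_phylogeny",
    "derive_rng",
]


@dataclass
class BranchNode:
    """One branch of the plan: the edge leading into this node."""

    name: str
    generations: int
    children: list["BranchNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class PhylogenyPlan:
    """Rooted tree whose branch lengths are generation counts."""

    root: BranchNode
    overrides: dict[str, dict] = field(default_factory=dict)

    @property
    def tip_labels(self) -> list[str]:
        tips: list[str] = []

        def walk(node: BranchNode):
            if node.is_tip:
                tips.append(node.name)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return tips

    def branch_names(self) -> list[str]:
        names: list[str] = []

        def walk(node: BranchNode):
            names.append(node.name)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return names

    def total_generations(self) -> int:
        def walk(node: BranchNode) -> int:
            return node.generations + sum(walk(ch) for ch in node.children)

        return walk(self.root)


def _branch_length_to_generations(length, label: str) -> int:
    if length is None:
        return 0
    if length < 0:
        raise NewickParseError(f"negative branch length {length} on branch {label!r}")
    if float(length) != int(length):
        raise NewickParseError(
            f"branch length {length} on branch {label!r} is not an integer "
            "generation count"
        )
    return int(length)


def parse_newick_generations(text: str, overrides: dict[str, dict] | None = None) -> PhylogenyPlan:
    """Parse a Newick string into a plan; branch lengths = generation counts."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    counter = [0]

    def convert(node) -> BranchNode:
        if node.taxon is not None:
            name = node.taxon.label
        elif node.label:
            name = node.label
        else:
            name = f"node{counter[0]}"
            counter[0] += 1
        gens = _branch_length_to_generations(node.edge.length, name)
        return BranchNode(name, gens, [convert(ch) for ch in node.child_nodes()])

    root = convert(tree.seed_node)
    tips = []

    def collect(n):
        if n.is_tip:
            tips.append(n.name)
        for ch in n.children:
            collect(ch)

    collect(root)
    if len(set(tips)) != len(tips):
        raise NewickParseError("tip labels must be unique")
    plan = PhylogenyPlan(root, overrides or {})
    known = set(plan.branch_names())
    for name in plan.overrides:
        if name not in known:
            raise ConfigurationError(f"override references unknown branch {name!r}")
    return plan


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    """Deterministic named RNG substream from the master seed.

    The token tuple (e.g. a branch's path of child indices) is hashed, so
    streams are reproducible and independent of traversal order.
    """
    digest = hashlib.sha256(repr(tokens).encode()).digest()
    salt = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), salt]))


def found_population(params: EvolutionParams, rng: np.random.Generator) -> Population:
    """Found a population of N independent random organisms, developed and scored."""
    return Population([Organism.random(params, rng) for _ in range(params.N)])


@dataclass
class LineageResult:
    """End state of one tip lineage."""

    tip_label: str
    population: Population
    representative_genome: Genome
    representative_regulatory: RegulatoryParams
    trace: list[TraceRecord]
    participation: tuple[float, ...]


@dataclass
class PhylogenyRun:
    """All per-tip results plus the traces of every branch (internal ones too)."""

    lineages: dict[str, LineageResult]
    branch_traces: dict[str, list[TraceRecord]]


def _merge_params(base: EvolutionParams, override: dict | None) -> EvolutionParams:
    if not override:
        return base
    try:
        return base.with_overrides(**override)
    except TypeError as exc:
        raise ConfigurationError(f"invalid branch override: {exc}") from exc


def _representative(pop: Population) -> Organism:
    # fittest organism; deterministic first-index tie-break for reporting
    fit = pop.total_fitnesses()
    return pop.organisms[int(np.argmax(fit))]


def run_phylogeny(
    plan: PhylogenyPlan,
    base_params: EvolutionParams,
    master_seed: int,
    trace_every: int = 100,
) -> PhylogenyRun:
    """Evolve a founder population along every branch of the plan.

    Depth-first traversal: each branch evolves a deep copy of its parent
    branch's final population for its own generation count, under the base
    parameters merged with any per-branch override.
    """
    lineages: dict[str, LineageResult] = {}
    traces: dict[str, list[TraceRecord]] = {}

    def visit(node: BranchNode, founders: Population, path: tuple[int, ...]):
        params = _merge_params(base_params, plan.overrides.get(node.name))
        rng = derive_rng(master_seed, "branch", path)
        pop, trace = run_branch(founders, node.generations, params, rng, trace_every)
        traces[node.name] = trace
        if node.is_tip:
            rep = _representative(pop)
            lineages[node.name] = LineageResult(
                tip_label=node.name,
                population=pop,
                representative_genome=rep.genome,
                representative_regulatory=rep.regulatory,
                trace=trace,
                participation=trace[-1].gene_participation,
            )
        for i, child in enumerate(node.children):
            visit(child, pop.copy(), path + (i,))

    founders = found_population(base_params, derive_rng(master_seed, "founder"))
    visit(plan.root, founders, ())
    return PhylogenyRun(lineages, traces)
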