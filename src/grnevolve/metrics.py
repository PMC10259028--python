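"""Validation metrics: sequence distances, neutral expectations, participation.

The headline calibration check of the simulator is that, with selection
disabled, the Jukes-Cantor-corrected distance between two tip sequences
matches the neutral expectation mu x (generations on the connecting path),
i.e. realized patristic distances equal the rate-time product.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import SaturationError
from .development import is_expressed
from .evolution import Population
from .genome import Genome, count_stop_codons
from .phylogeny import LineageResult

__all__ = [
    "p_distance",
    "jc_distance",
    "expected_neutral_divergence",
    "genome_jc_distance",
    "gene_participation",
    "stop_codon_report",
]


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, Genome):
        return seq.codes.reshape(-1)
    if isinstance(seq, str):
        return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.asarray(seq).reshape(-1)


def p_distance(seq_a, seq_b) -> float:
    """Fraction of differing sites between two equal-length sequences.

    Accepts DNA strings, base-code arrays, or whole :class:`Genome` objects
    (compared site-wise over the concatenated genes).
    """
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.size != b.size:
        raise ValueError(f"sequence lengths differ: {a.size} vs {b.size}")
    return float(np.count_nonzero(a != b) / a.size)


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction: d = -(3/4) ln(1 - 4p/3) substitutions/site."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"p-distance {p} outside the JC domain [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def genome_jc_distance(genome_a: Genome, genome_b: Genome) -> float:
    """Genome-wide JC-corrected distance between two genomes."""
    return jc_distance(p_distance(genome_a, genome_b))


def expected_neutral_divergence(mu: float, generations: int) -> float:
    """Neutral expectation mu x generations, in substitutions per site."""
    if mu < 0 or generations < 0:
        raise ValueError("mu and generations must be nonnegative")
    return mu * generations


def neutral_calibration_replicate(
    mu: float,
    generations_per_lineage: int,
    master_seed: int,
    n_genes: int = 5,
    gene_length: int = 3000,
    m: int = 10,
) -> float:
    """One replicate of the neutral calibration experiment.

    A single founder genome evolves along two independent lineages of
    ``generations_per_lineage`` generations under random survival (no
    selection) with the regulatory coupling active; returns the genome-wide
    JC-corrected distance between the two tips.  Its expectation is
    mu x (2 x generations_per_lineage).
    """
    from .evolution import EvolutionParams
    from .phylogeny import parse_newick_generations, run_phylogeny

    params = EvolutionParams(
        n_genes=n_genes,
        gene_length=gene_length,
        mu=mu,
        p=1.0,
        strategy="relaxed",
        N=1,
        m=m,
    )
    g = generations_per_lineage
    plan = parse_newick_generations(f"(A:{g},B:{g});")
    run = run_phylogeny(plan, params, master_seed, trace_every=max(1, g))
    return genome_jc_distance(
        run.lineages["A"].representative_genome,
        run.lineages["B"].representative_genome,
    )


def gene_participation(pop: Population, gene: int) -> float:
    """Fraction of the population in which ``gene`` is expressed."""
    return float(
        np.mean([is_expressed(o.expression, gene) for o in pop.organisms])
    )


def stop_codon_report(
    results: dict[str, LineageResult], gene: int
) -> dict[str, int]:
    """Per-tip in-frame stop-codon counts for one gene's representative sequence."""
    return {
        tip: count_stop_codons(res.representative_genome.codes[gene])
        for tip, res in results.items()
    }
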