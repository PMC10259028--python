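"""Genome sampling, Jukes-Cantor point mutation, and codon classification."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from grnevolve import (
    Genome,
    apply_mutations,
    classify_mutation,
    coding_mask,
    count_stop_codons,
    init_genome,
    sample_point_mutations,
)
from grnevolve.genome import NONSENSE, NONSYNONYMOUS, SYNONYMOUS, _ALPHABET

STOPS = {"TAA", "TAG", "TGA"}
ALL_CODONS = [a + b + c for a in _ALPHABET for b in _ALPHABET for c in _ALPHABET]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOPS]


def codons_of(seq: str):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@pytest.mark.parametrize("n,l", [(5, 3000), (1, 3), (3, 12)])
def test_init_genome_dimensions_and_open_reading_frames(rng, n, l):
    g = init_genome(n, l, rng)
    assert g.n_genes == n and g.gene_length == l
    for i in range(n):
        assert count_stop_codons(g.gene(i)) == 0


@pytest.mark.parametrize("n,l", [(0, 3), (1, 0), (1, 4), (1, 3001)])
def test_init_genome_rejects_invalid_dimensions(rng, n, l):
    with pytest.raises(ValueError):
        init_genome(n, l, rng)


def test_codon_sampling_uniform_over_sense_codons(rng):
    """Founder codons are uniform over the 61 sense codons (chi-square, a=0.01)."""
    g = init_genome(1, 3 * 100_000, rng)
    counts = {c: 0 for c in SENSE_CODONS}
    for codon in codons_of(g.gene(0)):
        counts[codon] += 1
    chi2 = stats.chisquare(list(counts.values()))
    assert chi2.pvalue > 0.01


def test_zero_rate_gives_no_events(rng):
    g = init_genome(2, 30, rng)
    assert sample_point_mutations(g, 0.0, rng) == []


def test_certain_mutation_hits_every_position_once(rng):
    g = init_genome(2, 30, rng)
    events = sample_point_mutations(g, 1.0, rng)
    assert len(events) == g.total_length
    seen = {(e.gene_index, e.position_in_gene) for e in events}
    assert len(seen) == g.total_length
    assert all(e.old_base != e.new_base for e in events)


def test_event_count_matches_binomial_expectation(rng):
    """Mean and variance of events/generation match Binomial(n*l, mu)."""
    g = init_genome(5, 3000, rng)
    mu = 5.33333e-6
    reps = 100_000
    counts = np.array([len(sample_point_mutations(g, mu, rng)) for _ in range(reps)])
    expected_mean = g.total_length * mu  # 0.08
    se = np.sqrt(expected_mean / reps)  # Poisson-limit SE for both moments
    assert abs(counts.mean() - expected_mean) < 3 * se
    assert abs(counts.var() - expected_mean * (1 - mu)) < 3 * se


def test_replacement_base_uniform_over_other_three(rng):
    g = Genome.from_sequences(["AAA" * 400])
    repl = []
    for _ in range(3000):
        repl += [e.new_base for e in sample_point_mutations(g, 5e-3, rng)]
    counts = [repl.count(b) for b in "CGT"]
    assert repl.count("A") == 0
    assert stats.chisquare(counts).pvalue > 0.01


@pytest.mark.parametrize(
    "old,new,expected",
    [
        ("AAA", "AAG", SYNONYMOUS),  # Lys -> Lys
        ("TGG", "TGA", NONSENSE),  # Trp -> stop
        ("AAA", "ACA", NONSYNONYMOUS),  # Lys -> Thr
    ],
)
def test_classify_mutation_examples(old, new, expected):
    assert classify_mutation(old, new) == expected


@pytest.mark.parametrize("old,new", [("AAA", "AAA"), ("AAA", "ACG"), ("AAX", "AAA")])
def test_classify_mutation_contract_violations(old, new):
    with pytest.raises(ValueError):
        classify_mutation(old, new)


def test_classification_matches_translation_oracle():
    """Every single-step change from a sense codon agrees with brute-force
    translation through the standard genetic code (61 x 9 pairs)."""
    checked = 0
    for old in SENSE_CODONS:
        for pos in range(3):
            for base in _ALPHABET:
                if base == old[pos]:
                    continue
                new = old[:pos] + base + old[pos + 1 :]
                aa_old = str(Seq(old).translate())
                aa_new = str(Seq(new).translate())
                if aa_new == "*":
                    want = NONSENSE
                elif aa_new == aa_old:
                    want = SYNONYMOUS
                else:
                    want = NONSYNONYMOUS
                assert classify_mutation(old, new) == want
                checked += 1
    assert checked == 61 * 9


def test_sampled_events_are_classified_like_the_oracle(rng):
    """Event classification equals re-classification from the sequences."""
    g = init_genome(3, 300, rng)
    events = sample_point_mutations(g, 0.02, rng)
    assert events, "expected some events at this rate"
    # replay sequentially to reproduce each event's pre-mutation codon
    current = g
    for ev in events:
        start = (ev.position_in_gene // 3) * 3
        old_codon = current.gene(ev.gene_index)[start : start + 3]
        mutated = apply_mutations(current, [ev])
        new_codon = mutated.gene(ev.gene_index)[start : start + 3]
        assert classify_mutation(old_codon, new_codon) == ev.classification
        current = mutated


def test_coding_mask_flags_in_frame_stops():
    g = Genome.from_sequences(["ATGTGAAAA", "ATGAAAAAA"])
    assert coding_mask(g).tolist() == [0.0, 1.0]


def test_coding_mask_is_pure_function_of_sequence():
    """A stop codon introduced then reverted restores the mask to 1."""
    g = Genome.from_sequences(["TGGAAA"])  # Trp Lys
    assert coding_mask(g).tolist() == [1.0]
    broken = Genome.from_sequences(["TGAAAA"])  # Trp->stop via G->A at pos 2
    assert coding_mask(broken).tolist() == [0.0]
    reverted = Genome.from_sequences(["TGGAAA"])
    assert coding_mask(reverted).tolist() == [1.0]


@pytest.mark.parametrize(
    "seq,count",
    [("ATGAAAGGG", 0), ("TAATAGTGA", 3), ("AAATAAAAA", 1)],
)
def test_count_stop_codons(seq, count):
    assert count_stop_codons(seq) == count


def test_apply_mutations_round_trip(rng):
    g = init_genome(2, 60, rng)
    events = sample_point_mutations(g, 0.1, rng)
    mutated = apply_mutations(g, events)
    # the original genome is untouched
    assert g == init_genome(2, 60, np.random.default_rng(1234))
    for ev in events:
        assert mutated.gene(ev.gene_index)[ev.position_in_gene] == ev.new_base
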