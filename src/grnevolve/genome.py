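"""Multi-gene coding genomes evolving under a Jukes-Cantor point-mutation process.

A genome is an ordered set of ``n`` protein-coding genes of equal length
``l`` (a multiple of 3), stored internally as an ``(n, l)`` array of base
codes 0..3 (A, C, G, T).  Founding genomes are sampled codon-by-codon,
uniformly over the 61 sense codons of the standard genetic code, so every
founder gene is an intact open reading frame.

Point mutations hit each base independently with probability ``mu`` per
generation, and the replacement base is uniform over the other three
nucleotides (Jukes-Cantor).  Each event is classified as synonymous,
nonsynonymous, or nonsense against the codon it lands in, read immediately
before that event is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "Genome",
    "MutationEvent",
    "init_genome",
    "sample_point_mutations",
    "apply_mutations",
    "classify_mutation",
    "coding_mask",
    "count_stop_codons",
    "SYNONYMOUS",
    "NONSYNONYMOUS",
    "NONSENSE",
]

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONSENSE = "nonsense"

_ALPHABET = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_ALPHABET)}

# Amino-acid (or '*') per codon index 16*b0 + 4*b1 + b2, standard genetic code.
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_AA = np.empty(64, dtype="<U1")
for _i0, _b0 in enumerate(_ALPHABET):
    for _i1, _b1 in enumerate(_ALPHABET):
        for _i2, _b2 in enumerate(_ALPHABET):
            _codon = _b0 + _b1 + _b2
            _idx = 16 * _i0 + 4 * _i1 + _i2
            _AA[_idx] = "*" if _codon in _STANDARD.stop_codons else _STANDARD.forward_table[_codon]

_SENSE_CODON_IDX = np.flatnonzero(_AA != "*")  # the 61 sense codons
_IS_STOP = _AA == "*"


@dataclass(frozen=True)
class MutationEvent:
    """A single point mutation, located and classified.

    ``gene_index`` and ``position_in_gene`` are 0-based; ``classification``
    is one of :data:`SYNONYMOUS`, :data:`NONSYNONYMOUS`, :data:`NONSENSE`.
    """

    gene_index: int
    position_in_gene: int
    old_base: str
    new_base: str
    classification: str


class Genome:
    """``n`` equal-length coding genes stored as an ``(n, l)`` base-code array."""

    __slots__ = ("codes",)

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or codes.shape[0] < 1:
            raise ValueError("genome requires a 2-D (n_genes, length) array with n >= 1")
        if codes.shape[1] % 3 != 0 or codes.shape[1] < 3:
            raise ValueError("gene length must be a positive multiple of 3")
        self.codes = codes

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "Genome":
        """Build a genome from equal-length A/C/G/T gene strings."""
        rows = []
        for seq in sequences:
            try:
                rows.append([_BASE_CODE[b] for b in seq.upper()])
            except KeyError as exc:
                raise ValueError(f"invalid nucleotide {exc} in sequence") from exc
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("all genes must have the same length")
        return cls(np.array(rows, dtype=np.uint8))

    @property
    def n_genes(self) -> int:
        return self.codes.shape[0]

    @property
    def gene_length(self) -> int:
        return self.codes.shape[1]

    @property
    def total_length(self) -> int:
        return self.codes.size

    def gene(self, i: int) -> str:
        """Return gene ``i`` as an A/C/G/T string."""
        return "".join(_ALPHABET[b] for b in self.codes[i])

    def sequences(self) -> list[str]:
        return [self.gene(i) for i in range(self.n_genes)]

    def copy(self) -> "Genome":
        return Genome(self.codes.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and np.array_equal(self.codes, other.codes)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Genome(n_genes={self.n_genes}, gene_length={self.gene_length})"


def _codon_indices(codes: np.ndarray) -> np.ndarray:
    """Map an (..., 3k) base-code array to (..., k) codon indices."""
    tri = codes.reshape(*codes.shape[:-1], -1, 3).astype(np.int64)
    return 16 * tri[..., 0] + 4 * tri[..., 1] + tri[..., 2]


def init_genome(n: int, l: int, rng: np.random.Generator) -> Genome:
    """Sample a founder genome of ``n`` genes x ``l`` bp.

    Codons are drawn i.i.d. uniformly over the 61 sense codons, so no
    founder gene contains an in-frame stop codon.
    """
    if n < 1:
        raise ValueError("need at least one gene")
    if l < 3 or l % 3 != 0:
        raise ValueError(f"gene length must be a positive multiple of 3, got {l}")
    codons = rng.choice(_SENSE_CODON_IDX, size=(n, l // 3))
    codes = np.empty((n, l // 3, 3), dtype=np.uint8)
    codes[..., 0] = codons // 16
    codes[..., 1] = (codons // 4) % 4
    codes[..., 2] = codons % 4
    return Genome(codes.reshape(n, l))


def _classify_codes(old_codon_idx: int, new_codon_idx: int) -> str:
    if _IS_STOP[new_codon_idx]:
        return NONSENSE
    if _AA[old_codon_idx] == _AA[new_codon_idx]:
        return SYNONYMOUS
    return NONSYNONYMOUS


def classify_mutation(old_codon: str, new_codon: str) -> str:
    """Classify a single-base codon change under the standard genetic code.

    Returns :data:`NONSENSE` if the new codon is a stop, :data:`SYNONYMOUS`
    if both encode the same amino acid, :data:`NONSYNONYMOUS` otherwise.
    The codons must be valid DNA triplets differing at exactly one position.
    """
    if len(old_codon) != 3 or len(new_codon) != 3:
        raise ValueError("codons must be length-3 strings")
    try:
        old = [_BASE_CODE[b] for b in old_codon.upper()]
        new = [_BASE_CODE[b] for b in new_codon.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide in codon: {exc}") from exc
    n_diff = sum(a != b for a, b in zip(old, new))
    if n_diff != 1:
        raise ValueError(
            f"codons must differ at exactly one position, got {n_diff} "
            f"({old_codon!r} -> {new_codon!r})"
        )
    return _classify_codes(16 * old[0] + 4 * old[1] + old[2], 16 * new[0] + 4 * new[1] + new[2])


def sample_point_mutations(
    genome: Genome, mu: float, rng: np.random.Generator
) -> list[MutationEvent]:
    """Sample one generation of point mutations; the genome is not modified.

    Each base mutates independently with probability ``mu``; replacement
    bases are uniform over the other three nucleotides.  Events are returned
    in genome order and each is classified against the codon state just
    before that event (so two hits in one codon see each other).
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mutation probability must be in [0, 1], got {mu}")
    total = genome.total_length
    k = int(rng.binomial(total, mu))
    if k == 0:
        return []
    positions = np.sort(rng.choice(total, size=k, replace=False))
    offsets = rng.integers(1, 4, size=k)  # old + 1..3 (mod 4) is uniform over the others
    l = genome.gene_length
    scratch = genome.codes.copy()
    events: list[MutationEvent] = []
    for pos, off in zip(positions, offsets):
        g, p = divmod(int(pos), l)
        old = int(scratch[g, p])
        new = int((old + off) % 4)
        start = (p // 3) * 3
        old_cod = scratch[g, start : start + 3].astype(np.int64)
        old_idx = 16 * old_cod[0] + 4 * old_cod[1] + old_cod[2]
        scratch[g, p] = new
        new_cod = scratch[g, start : start + 3].astype(np.int64)
        new_idx = 16 * new_cod[0] + 4 * new_cod[1] + new_cod[2]
        events.append(
            MutationEvent(
                gene_index=g,
                position_in_gene=p,
                old_base=_ALPHABET[old],
                new_base=_ALPHABET[new],
                classification=_classify_codes(old_idx, new_idx),
            )
        )
    return events


def apply_mutations(genome: Genome, events: Iterable[MutationEvent]) -> Genome:
    """Return a new genome with the sampled events written in, in order."""
    codes = genome.codes.copy()
    for ev in events:
        codes[ev.gene_index, ev.position_in_gene] = _BASE_CODE[ev.new_base]
    return Genome(codes)


def coding_mask(genome: Genome) -> np.ndarray:
    """Per-gene 0/1 vector: 0 iff the gene carries an in-frame stop codon.

    Recomputed from the current sequence, so a stop codon reverted by a
    later mutation restores the gene's mask to 1.
    """
    stops = _IS_STOP[_codon_indices(genome.codes)]
    return np.where(stops.any(axis=1), 0.0, 1.0)


def count_stop_codons(gene) -> int:
    """Number of in-frame stop codons (TAA/TAG/TGA) in a gene.

    Accepts a DNA string or a 1-D base-code array.
    """
    if isinstance(gene, str):
        codes = np.array([_BASE_CODE[b] for b in gene.upper()], dtype=np.uint8)
    else:
        codes = np.asarray(gene, dtype=np.uint8)
    if codes.size % 3 != 0:
        raise ValueError("gene length must be a multiple of 3")
    return int(_IS_STOP[_codon_indices(codes)].sum())
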