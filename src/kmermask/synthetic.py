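"""Seeded synthetic genomes with planted repeats and ground truth.

The generator emulates the three ingredients the detector cares about: a
Markov-chain background (order and composition configurable), interspersed
repeat families (one consensus per family, each copy independently mutated
with substitutions and short indels), and tandem arrays (a motif repeated
in adjacent, independently mutated copies).  "Exon" stretches are unique
sequences, rejection-sampled against internal k-mer reuse, so that
exon-avoidance specificity has a meaningful ceiling on fixtures.

Every planted interval is recorded exactly as placed, elements never
overlap, and the whole construction is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import GenomeSequence, Region, digits_to_residues
from .evaluation import AnnotationSet
from .kmer_scoring import MarkovBackground, sample_background

__all__ = [
    "SimulationError",
    "FamilySpec",
    "TandemSpec",
    "ExonSpec",
    "SimulationSpec",
    "default_spec",
    "background_only_spec",
    "mutate",
    "simulate",
]

_BASES = "ACGT"
_UNIQUENESS_K = 13


class SimulationError(ValueError):
    """The requested genome cannot be packed as specified."""


@dataclass(frozen=True)
class FamilySpec:
    """An interspersed repeat family: consensus length, copies, mutation rates."""

    length: int = 500
    copies: int = 200
    divergence: float = 0.05
    indel_rate: float = 0.01
    class_tag: str = "te"


@dataclass(frozen=True)
class TandemSpec:
    """A tandem array: motif (or its length), copy count, per-copy divergence."""

    motif_length: int = 25
    copies: int = 20
    divergence: float = 0.05
    class_tag: str = "tr"
    motif: str | None = None


@dataclass(frozen=True)
class ExonSpec:
    """Unique non-repetitive stretches standing in for coding regions."""

    count: int = 20
    min_length: int = 300
    max_length: int = 800


@dataclass(frozen=True)
class SimulationSpec:
    genome_length: int = 1_000_000
    background_order: int = 3
    gc: float = 0.5
    dirichlet_alpha: float = 5.0
    families: tuple[FamilySpec, ...] = (FamilySpec(),)
    tandems: tuple[TandemSpec, ...] = tuple(TandemSpec() for _ in range(50))
    exons: ExonSpec = ExonSpec()
    seed: int = 0
    seq_name: str = "sim"


def default_spec(seed: int = 0, genome_length: int = 1_000_000,
                 scale: float = 1.0) -> SimulationSpec:
    """The standard study conditions: a 1 Mb genome over an order-3
    background carrying 200 copies of a 500 bp family at 5 % divergence and
    50 tandem arrays.  ``scale`` shrinks the element counts together with a
    smaller ``genome_length`` so that the planted density stays constant.
    """
    spec = SimulationSpec(genome_length=genome_length, seed=seed)
    if scale != 1.0:
        families = tuple(
            replace(f, copies=max(1, round(f.copies * scale)))
            for f in spec.families
        )
        n_tandems = max(1, round(len(spec.tandems) * scale))
        exons = replace(spec.exons,
                        count=max(1, round(spec.exons.count * scale)))
        spec = replace(spec, families=families,
                       tandems=spec.tandems[:n_tandems], exons=exons)
    return spec


def background_only_spec(seed: int = 0,
                         genome_length: int = 1_000_000) -> SimulationSpec:
    """Same background chain and length, but nothing planted (the
    false-positive floor of a detector)."""
    return replace(default_spec(seed=seed, genome_length=genome_length),
                   families=(), tandems=(), exons=ExonSpec(count=0))


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return digits_to_residues(rng.integers(0, 4, size=length, dtype=np.int8))


def mutate(sequence: str, divergence: float, indel_rate: float,
           rng: np.random.Generator | int) -> str:
    """Mutate one repeat copy.

    Substitutions hit each base independently with probability
    ``divergence`` (uniform over the three alternatives); indel events start
    at each position with probability ``indel_rate``, are insertions or
    deletions with equal odds, and have geometric lengths with mean 2.
    """
    for name, rate in (("divergence", divergence), ("indel_rate", indel_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out: list[str] = []
    i = 0
    n = len(sequence)
    while i < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            size = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                out.append(_random_dna(size, rng))
            else:
                i += size
                continue
        base = sequence[i]
        if divergence > 0 and rng.random() < divergence:
            choice = int(rng.integers(0, 3))
            alternatives = _BASES.replace(base, "") if base in _BASES else _BASES
            base = alternatives[choice % len(alternatives)]
        out.append(base)
        i += 1
    return "".join(out)


def _background_chain(spec: SimulationSpec,
                      rng: np.random.Generator) -> MarkovBackground:
    """Draw a seeded order-o chain around the requested GC content.

    Per-context conditionals come from a Dirichlet centred on the base
    composition; the concentration controls how structured (non-iid) the
    background is.
    """
    n_contexts = 4 ** spec.background_order
    at = (1.0 - spec.gc) / 2.0
    gc = spec.gc / 2.0
    base_weights = np.array([at, gc, gc, at])
    alpha = 4.0 * spec.dirichlet_alpha * base_weights
    conditional = rng.dirichlet(alpha, size=n_contexts)
    context_freq = np.full(n_contexts, 1.0 / n_contexts)
    return MarkovBackground(
        order=spec.background_order,
        conditional=conditional,
        context_freq=context_freq,
        total_positions=spec.genome_length,
    )


def _unique_stretch(length: int, rng: np.random.Generator,
                    used_words: set[str], max_tries: int = 50) -> str:
    """A random stretch none of whose k-words repeats internally or reuses a
    word already claimed by another element."""
    for _ in range(max_tries):
        candidate = _random_dna(length, rng)
        words = {
            candidate[i : i + _UNIQUENESS_K]
            for i in range(len(candidate) - _UNIQUENESS_K + 1)
        }
        if (len(words) == len(candidate) - _UNIQUENESS_K + 1
                and not words & used_words):
            used_words |= words
            return candidate
    raise SimulationError("could not sample a unique exon stretch")


def simulate(spec: SimulationSpec) -> tuple[
        list[GenomeSequence], AnnotationSet, AnnotationSet]:
    """Build the genome, the repeat ground truth, and the exon annotation.

    Elements (family copies, tandem arrays, exons) are generated first, then
    placed at uniform-random non-overlapping positions by cutting the
    background into gaps; the background in between is sampled from the
    chain.  Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(int(spec.seed))
    chain = _background_chain(spec, rng)

    elements: list[tuple[str, str | None]] = []  # (sequence, truth tag)
    used_words: set[str] = set()
    for family in spec.families:
        consensus = _random_dna(family.length, rng)
        for _ in range(family.copies):
            copy = mutate(consensus, family.divergence, family.indel_rate, rng)
            elements.append((copy, family.class_tag))
    for tandem in spec.tandems:
        motif = tandem.motif or _random_dna(tandem.motif_length, rng)
        array = "".join(
            mutate(motif, tandem.divergence, 0.0, rng)
            for _ in range(tandem.copies)
        )
        elements.append((array, tandem.class_tag))
    exon_lengths = rng.integers(
        spec.exons.min_length, spec.exons.max_length + 1,
        size=spec.exons.count,
    )
    for length in exon_lengths:
        elements.append((_unique_stretch(int(length), rng, used_words), "exon"))

    planted = sum(len(seq) for seq, _ in elements)
    if planted >= spec.genome_length:
        raise SimulationError(
            f"planted material ({planted} bp across {len(spec.families)} "
            f"families, {len(spec.tandems)} tandem arrays and "
            f"{spec.exons.count} exons) does not fit in a "
            f"{spec.genome_length} bp genome"
        )

    order = rng.permutation(len(elements))
    background_total = spec.genome_length - planted
    cuts = np.sort(rng.integers(0, background_total + 1, size=len(elements)))
    gaps = np.diff(np.concatenate(([0], cuts, [background_total])))

    background = sample_background(chain, background_total, rng)
    parts: list[str] = []
    truth: list[Region] = []
    exons: list[Region] = []
    position = 0
    bg_cursor = 0
    for slot, element_index in enumerate(order):
        gap = int(gaps[slot])
        parts.append(background[bg_cursor : bg_cursor + gap])
        bg_cursor += gap
        position += gap
        seq, tag = elements[int(element_index)]
        region = Region(spec.seq_name, position, position + len(seq),
                        "repeat" if tag != "exon" else "nonrepeat", tag)
        if tag == "exon":
            exons.append(region)
        else:
            truth.append(region)
        parts.append(seq)
        position += len(seq)
    parts.append(background[bg_cursor:])
    genome = GenomeSequence(spec.seq_name, "".join(parts))
    assert len(genome) == spec.genome_length
    truth.sort(key=lambda r: r.start)
    exons.sort(key=lambda r: r.start)
    return (
        [genome],
        AnnotationSet(truth, name="planted"),
        AnnotationSet(exons, name="exons"),
    )
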