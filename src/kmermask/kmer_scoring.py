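"""Genome-wide k-mer counting and background-adjusted scoring.

Every DNA word of length k is indexed by its quaternary number (A, C, G, T
mapped to the digits 0, 1, 2, 3, leftmost base most significant), so the
counts of all 4**k words live in one dense table and consecutive window
indices roll forward by Horner's rule.

Observed counts are then adjusted against a Markov chain of order ``o``
trained on the same genome: a word seen at most twice scores zero, as does a
word whose observed count does not exceed the count the chain expects; every
other word scores observed minus expected.  The adjustment suppresses both
compositional bias and low-copy duplication (e.g. ohnologous genes in a
polyploid genome), so only genuine repetition yields positive scores.

The per-position score of a nucleotide is the adjusted count of the word
starting there; positions where no valid window starts score zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GenomeSequence, sequence_digits

__all__ = [
    "InvalidKmerError",
    "TableCapacityError",
    "KmerTable",
    "MarkovBackground",
    "ScoreTrack",
    "DEFAULT_MAX_TABLE_ENTRIES",
    "encode_kmer",
    "rolling_indices",
    "count_kmers",
    "train_background",
    "word_probability",
    "expected_count",
    "adjust_counts",
    "score_sequence",
    "choose_k",
    "sample_background",
]

DEFAULT_MAX_TABLE_ENTRIES = 4 ** 14


class InvalidKmerError(ValueError):
    """A word contains a base other than A/C/G/T."""


class TableCapacityError(ValueError):
    """The dense 4**k table would exceed the configured memory cap."""


@dataclass
class KmerTable:
    """Dense table over all 4**k words, keyed by quaternary index."""

    k: int
    values: np.ndarray
    n_windows: int
    adjusted: bool = False


@dataclass
class MarkovBackground:
    """Maximum-likelihood Markov chain of a fixed order.

    ``conditional[c, b]`` is P(base b | preceding context c); contexts never
    observed carry the uniform distribution.  ``context_freq`` holds the
    empirical frequencies of the order-length contexts, used as the leading
    factor of a word's chain probability.  ``total_positions`` is the number
    of valid windows the expectation is scaled by.
    """

    order: int
    conditional: np.ndarray
    context_freq: np.ndarray
    total_positions: int


@dataclass
class ScoreTrack:
    """Per-position adjusted-count scores aligned 1:1 to a sequence."""

    seq_name: str
    scores: np.ndarray


def _as_sequences(genome) -> list[GenomeSequence]:
    if isinstance(genome, GenomeSequence):
        return [genome]
    return list(genome)


def encode_kmer(word: str) -> int:
    """Quaternary index of a word; leftmost base is most significant."""
    digits = sequence_digits(word)
    if digits.size == 0:
        raise InvalidKmerError("empty word")
    if (digits < 0).any():
        raise InvalidKmerError(f"ambiguous base in word {word!r}")
    index = 0
    for digit in digits:
        index = (index << 2) | int(digit)
    return index


def rolling_indices(seq, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Start positions and quaternary indices of every all-valid k-window.

    Indices are computed incrementally over the whole digit array (Horner's
    rule, vectorised over window offsets); windows containing an invalid base
    are dropped, which is equivalent to restarting after each invalid base.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(seq, GenomeSequence):
        digits = seq.digits
    else:
        digits = np.asarray(seq, dtype=np.int8)
    n = digits.size
    empty = np.empty(0, dtype=np.int64)
    if n < k:
        return empty, empty
    d = digits.astype(np.int64)
    index = d[: n - k + 1].copy()
    for j in range(1, k):
        index <<= 2
        index += d[j : j + n - k + 1]
    invalid = np.concatenate(([0], np.cumsum(d < 0)))
    starts = np.nonzero(invalid[k:] - invalid[:-k] == 0)[0]
    return starts, index[starts]


def count_kmers(genome, k: int,
                max_entries: int = DEFAULT_MAX_TABLE_ENTRIES) -> KmerTable:
    """Observed counts of all k-words across every record, forward strand."""
    if 4 ** k > max_entries:
        raise TableCapacityError(
            f"4^{k} = {4 ** k} entries exceed the cap of {max_entries}; "
            "use a smaller k or raise max_entries"
        )
    values = np.zeros(4 ** k, dtype=np.int64)
    n_windows = 0
    for seq in _as_sequences(genome):
        _, indices = rolling_indices(seq, k)
        if indices.size:
            values += np.bincount(indices, minlength=4 ** k)
            n_windows += indices.size
    if n_windows == 0:
        raise ValueError(f"no valid {k}-mer window in the input")
    return KmerTable(k=k, values=values, n_windows=n_windows)


def _count_valid_windows(seqs: Sequence[GenomeSequence], length: int) -> int:
    total = 0
    for seq in seqs:
        starts, _ = rolling_indices(seq, length)
        total += starts.size
    return total


def train_background(genome, order: int, k: int | None = None) -> MarkovBackground:
    """Fit an order-``order`` chain on the valid stretches of the genome.

    ``k`` fixes ``total_positions`` to the number of valid k-windows so that
    expected counts are on the same scale as observed k-mer counts; without
    it the (order+1)-window count is used.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    seqs = _as_sequences(genome)
    n_contexts = 4 ** order
    step_counts = np.zeros(n_contexts * 4, dtype=np.int64)
    for seq in seqs:
        _, indices = rolling_indices(seq, order + 1)
        if indices.size:
            step_counts += np.bincount(indices, minlength=n_contexts * 4)
    if step_counts.sum() == 0:
        raise ValueError(
            f"no valid stretch longer than order {order} in the input"
        )
    step_counts = step_counts.reshape(n_contexts, 4)
    row_totals = step_counts.sum(axis=1, keepdims=True)
    conditional = np.where(
        row_totals > 0, step_counts / np.maximum(row_totals, 1), 0.25
    )
    if order == 0:
        context_freq = np.array([1.0])
    else:
        ctx_counts = np.zeros(n_contexts, dtype=np.int64)
        for seq in seqs:
            _, indices = rolling_indices(seq, order)
            if indices.size:
                ctx_counts += np.bincount(indices, minlength=n_contexts)
        context_freq = ctx_counts / ctx_counts.sum()
    if k is not None:
        total_positions = _count_valid_windows(seqs, k)
    else:
        total_positions = int(step_counts.sum())
    return MarkovBackground(
        order=order,
        conditional=conditional,
        context_freq=context_freq,
        total_positions=total_positions,
    )


def word_probability(word: str, background: MarkovBackground) -> float:
    """Chain probability of a word: P(prefix) * prod P(base | context)."""
    digits = sequence_digits(word)
    if (digits < 0).any():
        raise InvalidKmerError(f"ambiguous base in word {word!r}")
    o = background.order
    if digits.size <= o:
        raise ValueError(f"word length must exceed the order {o}")
    context = 0
    for digit in digits[:o]:
        context = (context << 2) | int(digit)
    prob = float(background.context_freq[context]) if o > 0 else 1.0
    mask = (1 << (2 * o)) - 1
    for digit in digits[o:]:
        prob *= float(background.conditional[context, int(digit)])
        context = ((context << 2) | int(digit)) & mask
    return prob


def expected_count(word: str, background: MarkovBackground) -> float:
    """Expected genome-wide count of a word under the background chain."""
    return background.total_positions * word_probability(word, background)


def _batch_probabilities(indices: np.ndarray, k: int,
                         background: MarkovBackground) -> np.ndarray:
    o = background.order
    mask = (1 << (2 * o)) - 1
    if o > 0:
        context = indices >> (2 * (k - o))
        prob = background.context_freq[context].copy()
    else:
        context = np.zeros(indices.size, dtype=np.int64)
        prob = np.ones(indices.size)
    for j in range(o, k):
        digit = (indices >> (2 * (k - 1 - j))) & 3
        prob *= background.conditional[context, digit]
        context = ((context << 2) | digit) & mask
    return prob


def adjust_counts(observed: KmerTable,
                  background: MarkovBackground) -> KmerTable:
    """Apply the three-clause count adjustment.

    adjusted(w) = 0                      if observed(w) <= 2
                = 0                      if observed(w) <= expected(w)
                = observed(w) - expected(w)   otherwise
    """
    if observed.adjusted:
        raise ValueError("table is already adjusted")
    obs = observed.values
    adjusted = np.zeros(obs.size, dtype=np.float64)
    selected = np.nonzero(obs >= 3)[0]
    if selected.size:
        expected = background.total_positions * _batch_probabilities(
            selected, observed.k, background
        )
        surplus = obs[selected] - expected
        keep = obs[selected] > expected
        adjusted[selected[keep]] = surplus[keep]
    return KmerTable(
        k=observed.k,
        values=adjusted,
        n_windows=observed.n_windows,
        adjusted=True,
    )


def score_sequence(seq: GenomeSequence, table: KmerTable) -> ScoreTrack:
    """Per-position score track: adjusted count of the word starting there."""
    if not table.adjusted:
        raise ValueError("score_sequence requires an adjusted table")
    scores = np.zeros(len(seq), dtype=np.float64)
    starts, indices = rolling_indices(seq, table.k)
    if starts.size:
        scores[starts] = table.values[indices]
    return ScoreTrack(seq_name=seq.name, scores=scores)


def choose_k(total_valid_bases: int, min_k: int = 8, max_k: int = 16,
             max_entries: int = DEFAULT_MAX_TABLE_ENTRIES) -> int:
    """Default word length: log4 of the valid genome size, rounded, clamped.

    Rounding to the nearest integer keeps the chance expectation of a random
    word between 1/2 and 2 occurrences, so genuine repetition stands out
    while single-copy sequence scores zero.  Clamping to [min_k, max_k]
    keeps the table tractable on small inputs and informative on large
    ones; the memory cap wins over the clamp.
    """
    if total_valid_bases < 1:
        raise ValueError("genome has no valid bases")
    k = int(math.floor(math.log(total_valid_bases, 4) + 0.5))
    k = min(max(k, min_k), max_k)
    while 4 ** k > max_entries and k > 1:
        k -= 1
    return k


def sample_background(background: MarkovBackground, length: int,
                      rng: np.random.Generator) -> str:
    """Draw one sequence of the given length from the chain.

    The initial context is drawn from the empirical context frequencies;
    subsequent bases follow the conditional distributions.
    """
    if length <= 0:
        return ""
    o = background.order
    n_contexts = 4 ** o
    cumulative = np.cumsum(background.conditional, axis=1)
    cumulative[:, -1] = 1.0
    rows = cumulative.tolist()
    out = np.empty(length, dtype=np.int8)
    if o > 0:
        freq = background.context_freq / background.context_freq.sum()
        context = int(rng.choice(n_contexts, p=freq))
        lead = min(o, length)
        for j in range(lead):
            out[j] = (context >> (2 * (o - 1 - j))) & 3
        start = lead
    else:
        context = 0
        start = 0
    mask = n_contexts - 1
    draws = rng.random(length - start)
    for i in range(start, length):
        row = rows[context]
        x = draws[i - start]
        if x < row[0]:
            base = 0
        elif x < row[1]:
            base = 1
        elif x < row[2]:
            base = 2
        else:
            base = 3
        out[i] = base
        context = ((context << 2) | base) & mask
    from .genome_io import digits_to_residues

    return digits_to_residues(out)
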