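import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmermask.genome_io import GenomeSequence
from kmermask.kmer_scoring import (
    InvalidKmerError,
    KmerTable,
    MarkovBackground,
    TableCapacityError,
    adjust_counts,
    choose_k,
    count_kmers,
    encode_kmer,
    expected_count,
    rolling_indices,
    score_sequence,
    train_background,
    word_probability,
)

ALPHABET = "ACGT"


def direct_window_indices(text, k):
    """Brute-force oracle: per-window direct encoding with validity skip."""
    out = []
    for i in range(len(text) - k + 1):
        window = text[i : i + k]
        if set(window) <= set(ALPHABET):
            out.append((i, encode_kmer(window)))
    return out


class TestEncoding:
    @pytest.mark.parametrize(
        "word,index",
        [("AAA", 0), ("TTT", 63), ("CGT", 1 * 16 + 2 * 4 + 3), ("A", 0), ("T", 3)],
    )
    def test_known_indices(self, word, index):
        assert encode_kmer(word) == index

    def test_ambiguous_base_rejected(self):
        with pytest.raises(InvalidKmerError):
            encode_kmer("ACN")

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_bijective_over_all_words(self, k):
        indices = {
            encode_kmer("".join(word))
            for word in itertools.product(ALPHABET, repeat=k)
        }
        assert indices == set(range(4 ** k))

    def test_rolling_matches_direct_small_example(self):
        starts, indices = rolling_indices(GenomeSequence("s", "ACGT"), 2)
        assert starts.tolist() == [0, 1, 2]
        assert indices.tolist() == [1, 6, 11]

    def test_rolling_skips_windows_with_invalid_base(self):
        starts, indices = rolling_indices(GenomeSequence("s", "ACNGT"), 2)
        assert starts.tolist() == [0, 3]
        assert indices.tolist() == [encode_kmer("AC"), encode_kmer("GT")]

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_rolling_matches_direct_exhaustively(self, k):
        # One text containing every word: the de-Bruijn-ish concatenation of
        # all 4**k words still exercises every index through the rolling path.
        text = "".join(
            "".join(word) for word in itertools.product(ALPHABET, repeat=k)
        )
        expected = direct_window_indices(text, k)
        starts, indices = rolling_indices(GenomeSequence("s", text), k)
        assert list(zip(starts.tolist(), indices.tolist())) == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        text=st.text(alphabet="ACGTN", min_size=1, max_size=200),
        k=st.integers(min_value=1, max_value=12),
    )
    def test_rolling_matches_direct_property(self, text, k):
        starts, indices = rolling_indices(GenomeSequence("s", text), k)
        assert list(zip(starts.tolist(), indices.tolist())) == (
            direct_window_indices(text, k)
        )


class TestCounting:
    def test_overlapping_windows(self):
        table = count_kmers(GenomeSequence("s", "AAAA"), 2)
        assert table.values[encode_kmer("AA")] == 3
        assert table.values.sum() == 3

    def test_single_full_length_word(self):
        table = count_kmers(GenomeSequence("s", "ACGT"), 4)
        assert np.count_nonzero(table.values) == 1
        assert table.values[encode_kmer("ACGT")] == 1

    def test_total_equals_valid_window_count(self, genome_factory):
        genome = genome_factory(2000)
        table = count_kmers(genome, 6)
        starts, _ = rolling_indices(genome, 6)
        assert table.values.sum() == starts.size == table.n_windows

    def test_counts_pooled_across_records(self, genome_factory):
        a, b = genome_factory(300, "a"), genome_factory(300, "b")
        pooled = count_kmers([a, b], 5)
        assert pooled.values.sum() == (
            count_kmers(a, 5).values.sum() + count_kmers(b, 5).values.sum()
        )

    def test_capacity_cap(self):
        with pytest.raises(TableCapacityError, match="smaller k"):
            count_kmers(GenomeSequence("s", "ACGT" * 10), 12, max_entries=4 ** 8)


class TestBackground:
    def test_degenerate_composition(self):
        bg = train_background(GenomeSequence("s", "A" * 50), 2)
        assert bg.conditional[encode_kmer("AA"), 0] == 1.0

    def test_order_zero_uniform_composition(self):
        bg = train_background(GenomeSequence("s", "ACGTACGT"), 0)
        np.testing.assert_allclose(bg.conditional[0], [0.25] * 4)

    def test_order_one_hand_counts(self):
        # AAAC: context A is followed by A twice and C once.
        bg = train_background(GenomeSequence("s", "AAAC"), 1)
        assert bg.conditional[0, 0] == pytest.approx(2 / 3)
        assert bg.conditional[0, 1] == pytest.approx(1 / 3)

    def test_rows_are_distributions(self, genome_factory):
        bg = train_background(genome_factory(5000), 3)
        np.testing.assert_allclose(bg.conditional.sum(axis=1), 1.0, atol=1e-9)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            train_background(GenomeSequence("s", "ACGT"), -1)

    def test_invalid_bases_break_training_stretches(self):
        # Transitions across the N must not be counted.
        bg = train_background(GenomeSequence("s", "AANCC"), 1)
        assert bg.conditional[0, 1] == 0.0  # no A->C step observed
        assert bg.conditional[1, 1] == 1.0  # C->C observed once


class TestExpectedCounts:
    def test_uniform_closed_form(self):
        bg = train_background(GenomeSequence("s", "ACGTACGT"), 0, k=2)
        # 7 valid 2-windows, each word probability 1/16.
        for word in ("AA", "AC", "GT", "TT"):
            assert expected_count(word, bg) == pytest.approx(7 / 16)

    def test_degenerate_chain(self):
        bg = train_background(GenomeSequence("s", "A" * 100), 2, k=5)
        assert expected_count("AAAAA", bg) == pytest.approx(96)
        assert expected_count("AACAA", bg) == 0.0

    def test_matches_independent_dict_chain(self, rng):
        # Independent oracle: a literal dict-based chain trained by counting.
        text = "".join(rng.choice(list(ALPHABET), size=200))
        order, k = 2, 5
        bg = train_background(GenomeSequence("s", text), order, k=k)

        context_counts, step_counts = {}, {}
        for i in range(len(text) - order):
            ctx, nxt = text[i : i + order], text[i + order]
            step_counts[(ctx, nxt)] = step_counts.get((ctx, nxt), 0) + 1
            context_counts[ctx] = context_counts.get(ctx, 0) + 1
        prefix_counts = {}
        for i in range(len(text) - order + 1):
            ctx = text[i : i + order]
            prefix_counts[ctx] = prefix_counts.get(ctx, 0) + 1
        n_prefixes = sum(prefix_counts.values())

        for word in ("ACGTA", "TTTTT", text[37 : 37 + k]):
            prob = prefix_counts.get(word[:order], 0) / n_prefixes
            for j in range(order, k):
                ctx = word[j - order : j]
                steps = context_counts.get(ctx, 0)
                prob *= (
                    step_counts.get((ctx, word[j]), 0) / steps
                    if steps else 0.25
                )
            assert word_probability(word, bg) == pytest.approx(prob, abs=1e-12)
            assert expected_count(word, bg) == pytest.approx(
                (len(text) - k + 1) * prob, abs=1e-9
            )


def uniform_background(expected_value, k=2):
    """Order-0 uniform chain whose expectation for every k-word is fixed."""
    return MarkovBackground(
        order=0,
        conditional=np.full((1, 4), 0.25),
        context_freq=np.array([1.0]),
        total_positions=expected_value * 4 ** k,
    )


class TestAdjustment:
    @pytest.mark.parametrize(
        "observed,expected,adjusted",
        [
            (0, 0.1, 0.0),
            (1, 0.1, 0.0),
            (2, 0.1, 0.0),  # words seen once or twice always score zero
            (3, 3.5, 0.0),  # observed <= expected scores zero
            (3, 3.0, 0.0),
            (3, 2.0, 1.0),
            (5, 2.0, 3.0),  # observed - expected otherwise
            (100, 0.5, 99.5),
        ],
    )
    def test_three_clause_rule(self, observed, expected, adjusted):
        table = KmerTable(
            k=2,
            values=np.full(16, observed, dtype=np.int64),
            n_windows=observed * 16,
        )
        out = adjust_counts(table, uniform_background(expected))
        np.testing.assert_allclose(out.values, adjusted)

    def test_duplicated_text_scores_all_zero(self, rng):
        # Two exact copies of a k-mer-unique random text: every word occurs
        # exactly twice, so the whole adjusted table is zero.
        half = "".join(rng.choice(list(ALPHABET), size=400))
        genome = [GenomeSequence("copy1", half), GenomeSequence("copy2", half)]
        k = 10
        observed = count_kmers(genome, k)
        assert observed.values.max() == 2  # the text is k-mer unique
        background = train_background(genome, 2, k=k)
        adjusted = adjust_counts(observed, background)
        assert not adjusted.values.any()

    def test_polyploid_copies_absorbed_by_background(self, rng):
        # c exact copies of a unique text with an order >= uniqueness
        # context: the chain captures the duplication, so gene-like words
        # score about zero on average.
        # Keep the text short enough that order-length contexts are
        # essentially unique within one copy, as the argument requires.
        text = "".join(rng.choice(list(ALPHABET), size=250))
        genome = GenomeSequence("s", text * 4)
        k, order = 8, 6
        observed = count_kmers(genome, k)
        background = train_background(genome, order, k=k)
        adjusted = adjust_counts(observed, background)
        present = observed.values >= 3
        mean_adjusted = adjusted.values[present].mean()
        mean_observed = observed.values[present].mean()
        assert mean_adjusted < 0.1 * mean_observed

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        observed=st.lists(
            st.integers(min_value=0, max_value=50), min_size=16, max_size=16
        ),
        expected=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_adjustment_bounds_and_monotonicity(self, observed, expected):
        table = KmerTable(
            k=2, values=np.array(observed, dtype=np.int64), n_windows=1
        )
        out = adjust_counts(table, uniform_background(expected)).values
        assert (out >= 0).all()
        assert (out <= table.values).all()
        # non-decreasing in observed at fixed expectation
        order = np.argsort(table.values)
        assert (np.diff(out[order]) >= -1e-12).all()


class TestScoring:
    def adjusted_table(self, k, mapping):
        values = np.zeros(4 ** k)
        for word, value in mapping.items():
            values[encode_kmer(word)] = value
        return KmerTable(k=k, values=values, n_windows=1, adjusted=True)

    def test_sequence_shorter_than_k_scores_zero(self):
        track = score_sequence(
            GenomeSequence("s", "AC"), self.adjusted_table(3, {})
        )
        assert track.scores.tolist() == [0.0, 0.0]

    def test_last_k_minus_one_positions_zero(self):
        table = self.adjusted_table(3, {"AAA": 7.0})
        track = score_sequence(GenomeSequence("s", "AAAAAA"), table)
        assert track.scores.tolist() == [7, 7, 7, 7, 0, 0]

    def test_invalid_windows_score_zero(self):
        table = self.adjusted_table(2, {"AA": 5.0})
        track = score_sequence(GenomeSequence("s", "AANAA"), table)
        assert track.scores.tolist() == [5, 0, 0, 5, 0]

    def test_unadjusted_table_rejected(self):
        raw = KmerTable(k=2, values=np.zeros(16), n_windows=1)
        with pytest.raises(ValueError):
            score_sequence(GenomeSequence("s", "ACGT"), raw)


class TestChooseK:
    def test_megabase_genome(self):
        assert choose_k(1_000_000) == 10

    def test_clamped_low_for_small_inputs(self):
        assert choose_k(1000) == 8

    def test_clamped_high_for_huge_inputs(self):
        assert choose_k(10 ** 12, max_entries=4 ** 16) == 16

    def test_memory_cap_wins(self):
        assert choose_k(10 ** 12, max_entries=4 ** 12) == 12
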