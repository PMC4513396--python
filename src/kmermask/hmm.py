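"""Two-track log-level HMM: self-trained segmentation of score tracks.

Each position's score is collapsed to a discrete output level, the ceiling
of its log base t (scores <= 0 map to level 0).  Every level owns two
states: one on the non-repeat track and one on the repeat track, so the
state count is twice the number of levels.  Output probabilities are unit
(a state emits exactly its own level), which makes the model a segmenter:
at every position only the two states matching the observed level are
reachable and the transition structure alone decides which track the
Viterbi path follows.

Priors and transitions are learned by counting over the auto-labeled
candidate and non-repeat regions, with add-one pseudocounts so that no
transition is impossible during decoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import Region
from .kmer_scoring import ScoreTrack
from .labeling import LabeledRegions

__all__ = [
    "TrainingError",
    "HmmModel",
    "output_level",
    "output_levels",
    "build_model",
    "train",
    "viterbi",
    "decode_regions",
]

NONREPEAT, REPEAT = 0, 1

# Guard against log(t**m, t) landing a hair above the integer.
_CEIL_EPS = 1e-9


class TrainingError(RuntimeError):
    """No labeled regions were available to train on."""


def _ceil_log(value: float, base: float) -> int:
    return int(math.ceil(math.log(value, base) - _CEIL_EPS))


def output_level(score: float, t: float) -> int:
    """Discrete output level: ceil(log_t(score)) for positive scores, else 0.

    Scores in (0, 1] round up to at most 0, so the level is floored at 0.
    """
    if t <= 1:
        raise ValueError("log base t must exceed 1")
    if score <= 0:
        return 0
    return max(0, _ceil_log(score, t))


def output_levels(scores: np.ndarray, t: float,
                  n_levels: int | None = None) -> np.ndarray:
    """Vectorised :func:`output_level`, optionally clipped to a model's range."""
    if t <= 1:
        raise ValueError("log base t must exceed 1")
    scores = np.asarray(scores, dtype=np.float64)
    levels = np.zeros(scores.size, dtype=np.int64)
    positive = scores > 0
    if positive.any():
        raw = np.ceil(np.log(scores[positive]) / math.log(t) - _CEIL_EPS)
        levels[positive] = np.maximum(raw, 0).astype(np.int64)
    if n_levels is not None:
        np.clip(levels, 0, n_levels - 1, out=levels)
    return levels


@dataclass
class HmmModel:
    """State set, priors and transitions of the two-track level HMM.

    States are indexed track-major: the non-repeat states come first
    (indices 0 .. n_levels-1, one per level), then the repeat states.
    """

    t: float
    n_levels: int
    prior_counts: np.ndarray
    transition_counts: np.ndarray
    log_priors: np.ndarray | None = None
    log_transitions: np.ndarray | None = None
    trained: bool = False

    @property
    def n_states(self) -> int:
        return 2 * self.n_levels

    def state_index(self, track: int, level: int) -> int:
        return track * self.n_levels + level

    @property
    def priors(self) -> np.ndarray:
        return self.prior_counts / self.prior_counts.sum()

    @property
    def transitions(self) -> np.ndarray:
        return self.transition_counts / self.transition_counts.sum(
            axis=1, keepdims=True
        )

    def finalize(self) -> None:
        self.log_priors = np.log(self.priors)
        self.log_transitions = np.log(self.transitions)
        self.trained = True


def build_model(max_score: float, t: float) -> HmmModel:
    """Untrained model sized for the maximum score found in the genome.

    Levels run 0..ceil(log_t(max_score)); level 0 exists because the output
    mapping sends every non-positive score there.  Priors and transitions
    start at the add-one pseudocount mass.
    """
    if t <= 1:
        raise ValueError("log base t must exceed 1")
    if max_score <= 0:
        n_levels = 1
    else:
        n_levels = max(1, _ceil_log(max_score, t)) + 1
    n_states = 2 * n_levels
    return HmmModel(
        t=t,
        n_levels=n_levels,
        prior_counts=np.ones(n_states),
        transition_counts=np.ones((n_states, n_states)),
    )


def train(model: HmmModel,
          labeled: Iterable[tuple[ScoreTrack, LabeledRegions]]) -> HmmModel:
    """Learn priors and transitions from auto-labeled regions.

    Each labeled position maps to the state (region label, output level of
    its raw score).  Priors count first states of regions; transitions count
    successive state pairs inside each region, plus one transition between
    the adjoining states of consecutive labeled regions so that the
    repeat/non-repeat switching rates are data driven.
    """
    n_regions = 0
    L = model.n_levels
    n_states = model.n_states
    for track, labels in labeled:
        regions: Sequence[Region] = (
            labels.regions if isinstance(labels, LabeledRegions)
            else sorted(labels, key=lambda r: r.start)
        )
        if not regions:
            continue
        levels = output_levels(track.scores, model.t, L)
        previous_last: int | None = None
        for region in regions:
            track_id = REPEAT if region.label == "repeat" else NONREPEAT
            states = track_id * L + levels[region.start : region.end]
            model.prior_counts[states[0]] += 1
            if states.size > 1:
                pair_index = states[:-1] * n_states + states[1:]
                model.transition_counts += np.bincount(
                    pair_index, minlength=n_states * n_states
                ).reshape(n_states, n_states)
            if previous_last is not None:
                model.transition_counts[previous_last, states[0]] += 1
            previous_last = int(states[-1])
            n_regions += 1
    if n_regions == 0:
        raise TrainingError(
            "no labeled regions to train on; review the threshold t and the "
            "mask width"
        )
    model.finalize()
    return model


def viterbi(model: HmmModel, track: ScoreTrack) -> np.ndarray:
    """Most probable state path for a score track.

    With unit output probabilities the path at each position is confined to
    the two states matching the observed level, so the recursion keeps two
    live hypotheses (non-repeat track / repeat track).  Ties prefer the
    lower state index, i.e. the non-repeat track.
    """
    if not model.trained:
        raise ValueError("model must be trained before decoding")
    levels = output_levels(track.scores, model.t, model.n_levels)
    n = levels.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    L = model.n_levels
    lt = model.log_transitions
    nr_states = levels
    rp_states = levels + L
    # Per-step transition scores for the four (prev track, next track) pairs.
    a00 = lt[nr_states[:-1], nr_states[1:]].tolist()
    a01 = lt[nr_states[:-1], rp_states[1:]].tolist()
    a10 = lt[rp_states[:-1], nr_states[1:]].tolist()
    a11 = lt[rp_states[:-1], rp_states[1:]].tolist()
    dp0 = float(model.log_priors[nr_states[0]])
    dp1 = float(model.log_priors[rp_states[0]])
    back0 = bytearray(n)
    back1 = bytearray(n)
    for i in range(n - 1):
        c00 = dp0 + a00[i]
        c10 = dp1 + a10[i]
        if c00 >= c10:
            new0, b0 = c00, 0
        else:
            new0, b0 = c10, 1
        c01 = dp0 + a01[i]
        c11 = dp1 + a11[i]
        if c01 >= c11:
            new1, b1 = c01, 0
        else:
            new1, b1 = c11, 1
        dp0, dp1 = new0, new1
        back0[i + 1] = b0
        back1[i + 1] = b1
    tracks = np.empty(n, dtype=np.int64)
    current = NONREPEAT if dp0 >= dp1 else REPEAT
    for i in range(n - 1, 0, -1):
        tracks[i] = current
        current = back0[i] if current == NONREPEAT else back1[i]
    tracks[0] = current
    return tracks * L + levels


def path_log_probability(model: HmmModel, track: ScoreTrack,
                         states: np.ndarray) -> float:
    """Log probability of a given level-consistent state path."""
    states = np.asarray(states)
    logp = float(model.log_priors[states[0]])
    if states.size > 1:
        logp += float(model.log_transitions[states[:-1], states[1:]].sum())
    return logp


def decode_regions(model: HmmModel, path: np.ndarray, k: int,
                   seq_name: str, seq_length: int | None = None) -> list[Region]:
    """Final repeat intervals from a state path.

    Maximal runs of repeat-track states become regions; each end is extended
    by k-1 positions (the tail of the last repeated word), clipped to the
    sequence, and abutting or overlapping regions are merged.
    """
    path = np.asarray(path)
    n = path.size
    if seq_length is None:
        seq_length = n
    repeat_flags = path >= model.n_levels
    from .labeling import _bool_runs

    merged: list[tuple[int, int]] = []
    for start, end in _bool_runs(repeat_flags):
        end = min(end + k - 1, seq_length)
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return [Region(seq_name, start, end, "repeat") for start, end in merged]
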