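"""Candidate labeling: Gaussian smoothing, peak finding, delineation.

The raw score track is noisy at single-base resolution, so each position is
replaced by the Gaussian-weighted mean of its neighbourhood (mask width
about 7 sigma, so essentially the whole bell is covered).  Local maxima of
the smoothed track are then found with the discrete second-derivative test:
a maximum lies between two consecutive points where the first-derivative
approximation changes sign from + to - and the second-derivative
approximation is negative.

Delineation turns the smoothed track into self-generated training labels:
runs of smoothed scores at or above the low-score threshold t, bridged
across sub-mask-width gaps and containing at least one maximum, become
candidate repetitive regions; runs below t at least one mask width long
become potential non-repetitive regions; short ambiguous leftovers stay
unlabeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import Region

__all__ = [
    "GaussianMask",
    "SmoothedTrack",
    "LabeledRegions",
    "build_mask",
    "smooth",
    "derivatives",
    "local_maxima",
    "delineate",
]


@dataclass
class GaussianMask:
    """Precomputed symmetric Gaussian weights centred on the mask midpoint."""

    sigma: float
    weights: np.ndarray

    @property
    def width(self) -> int:
        return self.weights.size

    @property
    def half_width(self) -> int:
        return (self.weights.size - 1) // 2


@dataclass
class SmoothedTrack:
    seq_name: str
    values: np.ndarray


@dataclass
class LabeledRegions:
    """Auto-generated labels for one sequence.

    ``maxima`` keeps only the detected local maxima that seeded a candidate;
    every candidate contains at least one of them, and candidates never
    overlap non-repeat regions.
    """

    candidates: list[Region] = field(default_factory=list)
    nonrepeats: list[Region] = field(default_factory=list)
    maxima: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def regions(self) -> list[Region]:
        return sorted(self.candidates + self.nonrepeats, key=lambda r: r.start)


def build_mask(sigma: float) -> GaussianMask:
    """Gaussian mask of width round(7*sigma), forced odd.

    Seven standard deviations cover essentially the whole distribution
    (3.5 sigma on each side of the centre).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    width = int(math.floor(7 * sigma + 0.5))
    if width % 2 == 0:
        width += 1
    width = max(width, 1)
    half = width // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    weights = np.exp(-(x ** 2) / (2.0 * sigma * sigma))
    weights /= math.sqrt(2.0 * math.pi) * sigma
    return GaussianMask(sigma=sigma, weights=weights)


def _values_of(track) -> tuple[str, np.ndarray]:
    if hasattr(track, "scores"):
        return track.seq_name, np.asarray(track.scores, dtype=np.float64)
    if hasattr(track, "values"):
        return track.seq_name, np.asarray(track.values, dtype=np.float64)
    return "", np.asarray(track, dtype=np.float64)


def smooth(track, mask: GaussianMask) -> SmoothedTrack:
    """Mask-weighted mean of the scores covered by the mask at each position.

    Near sequence ends the mask is truncated to in-bounds positions and the
    divisor is the truncated weight sum, so constants stay fixed points of
    the smoother everywhere.
    """
    name, scores = _values_of(track)
    n = scores.size
    if n == 0:
        return SmoothedTrack(name, scores.copy())
    half = mask.half_width
    numerator = np.convolve(scores, mask.weights)[half : half + n]
    denominator = np.convolve(np.ones(n), mask.weights)[half : half + n]
    return SmoothedTrack(name, numerator / denominator)


def derivatives(smoothed, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Discrete first/second derivative approximations over window w.

    f'(i)  = sum(s[i-w..i-1]) - sum(s[i+1..i+w])
    f''(i) = sum(s[i-w..i-1]) + sum(s[i+1..i+w]) - 2*w*s[i]

    Positions within w of either end are undefined and returned as NaN.
    """
    if w < 1:
        raise ValueError("derivative window w must be >= 1")
    _, values = _values_of(smoothed)
    n = values.size
    first = np.full(n, np.nan)
    second = np.full(n, np.nan)
    if n < 2 * w + 1:
        return first, second
    prefix = np.concatenate(([0.0], np.cumsum(values)))
    i = np.arange(w, n - w)
    left = prefix[i] - prefix[i - w]
    right = prefix[i + w + 1] - prefix[i + 1]
    first[i] = left - right
    second[i] = left + right - 2.0 * w * values[i]
    return first, second


def local_maxima(smoothed, w: int) -> np.ndarray:
    """Positions of smoothed-track local maxima by the second-derivative test.

    The first derivative is considered zero where its sign flips between two
    consecutive defined points; of such a pair the position with the smaller
    (more negative) second derivative is reported, the left one on ties, and
    only if that second derivative is negative.
    """
    _, values = _values_of(smoothed)
    first, second = derivatives(values, w)
    sign = np.sign(first)
    # Any strict +/- flip is a zero crossing; the curvature condition below
    # keeps maxima and rejects minima.
    crossing = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if crossing.size == 0:
        return np.empty(0, dtype=np.int64)
    left_d2 = second[crossing]
    right_d2 = second[crossing + 1]
    positions = np.where(left_d2 <= right_d2, crossing, crossing + 1)
    curvature = np.minimum(left_d2, right_d2)
    return positions[curvature < 0].astype(np.int64)


def _bool_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) spans of maximal True runs."""
    if flags.size == 0:
        return []
    edges = np.diff(flags.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    starts = starts.tolist()
    ends = ends.tolist()
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(flags.size)
    return list(zip(starts, ends))


def delineate(smoothed, maxima: np.ndarray, t: float, mask_width: int,
              seq_name: str | None = None) -> LabeledRegions:
    """Delineate candidate repetitive and potential non-repetitive regions.

    Candidates are maximal runs of smoothed scores >= t, merged across
    below-threshold gaps shorter than the mask width, and kept only when
    they contain at least one local maximum.  Non-repeat regions are runs of
    scores < t at least one mask width long; they cannot intersect any
    candidate.  Everything else is left unlabeled.
    """
    if t <= 1:
        raise ValueError("threshold t must exceed 1 (it is also the HMM log base)")
    if mask_width < 1:
        raise ValueError("mask_width must be >= 1")
    name, values = _values_of(smoothed)
    if seq_name is not None:
        name = seq_name
    maxima = np.sort(np.asarray(maxima, dtype=np.int64))
    high = values >= t
    merged: list[tuple[int, int]] = []
    for start, end in _bool_runs(high):
        if merged and start - merged[-1][1] < mask_width:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    candidates: list[Region] = []
    kept_maxima: list[int] = []
    for start, end in merged:
        lo = np.searchsorted(maxima, start, side="left")
        hi = np.searchsorted(maxima, end, side="left")
        if hi > lo:
            candidates.append(Region(name, start, end, "repeat"))
            kept_maxima.extend(maxima[lo:hi].tolist())
    nonrepeats = [
        Region(name, start, end, "nonrepeat")
        for start, end in _bool_runs(values < t)
        if end - start >= mask_width
    ]
    return LabeledRegions(
        candidates=candidates,
        nonrepeats=nonrepeats,
        maxima=np.asarray(kept_maxima, dtype=np.int64),
    )
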