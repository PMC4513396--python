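"""Tandem periodicity of a DNA stretch.

A minisatellite is a motif repeated in adjacent, slightly diverged copies;
its period shows up as the smallest shift under which the sequence largely
matches itself.  This is a deliberately small self-alignment utility for
inspecting tandem candidates, not a general tandem-repeat finder.
"""

from __future__ import annotations

import numpy as np

from .genome_io import GenomeSequence, sequence_digits

__all__ = ["self_match_fraction", "best_period", "complete_periods"]


def _digits(seq) -> np.ndarray:
    if isinstance(seq, GenomeSequence):
        return seq.digits
    if isinstance(seq, np.ndarray):
        return seq
    return sequence_digits(str(seq))


def self_match_fraction(seq, shift: int) -> float:
    """Fraction of positions where the sequence matches itself shifted."""
    digits = _digits(seq)
    if not 0 < shift < digits.size:
        raise ValueError(f"shift must be in (0, {digits.size})")
    a = digits[shift:]
    b = digits[:-shift]
    comparable = (a >= 0) & (b >= 0)
    if not comparable.any():
        return 0.0
    return float((a[comparable] == b[comparable]).mean())


def best_period(seq, min_period: int = 2, max_period: int = 100,
                min_identity: float = 0.8) -> int | None:
    """Smallest shift at which the sequence matches itself well.

    Returns the smallest period in [min_period, max_period] whose
    self-match fraction reaches ``min_identity`` (so multiples of the true
    period are not reported), or None if the stretch is not tandem-like.
    """
    digits = _digits(seq)
    upper = min(max_period, digits.size - 1)
    for period in range(min_period, upper + 1):
        if self_match_fraction(digits, period) >= min_identity:
            return period
    return None


def complete_periods(seq, period: int) -> int:
    """How many complete periods of the given length tile the sequence."""
    digits = _digits(seq)
    if period < 1:
        raise ValueError("period must be >= 1")
    return digits.size // period
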