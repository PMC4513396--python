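"""Evaluation measures for repeat predictions.

Base-level sensitivity per repeat class (SN), exon-avoidance specificity
(SP_exon), percentage of the genome predicted repetitive (PP), false
positive length on a Markov-simulated random genome (FPL), and potential
repeats (PR: predicted bases absent from the reference annotation).  All
interval arithmetic is on unions of half-open intervals, so overlapping
annotations are never double counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GenomeSequence, Region, merge_regions, total_length
from .kmer_scoring import sample_background, train_background

__all__ = [
    "CLASSES",
    "AnnotationSet",
    "EvaluationReport",
    "overlap_bp",
    "sensitivity",
    "specificity_exon",
    "percentage_predicted",
    "random_genome",
    "false_positive_length",
    "potential_repeats",
    "evaluate",
]

CLASSES = ("te", "tr", "low", "other")


@dataclass
class AnnotationSet:
    """Reference intervals with a class tag per region."""

    regions: list[Region] = field(default_factory=list)
    name: str = "truth"

    def for_class(self, tag: str | None) -> list[Region]:
        if tag is None or tag == "all":
            return list(self.regions)
        return [r for r in self.regions if r.tag == tag]

    @property
    def total_bp(self) -> int:
        return total_length(self.regions)


def overlap_bp(a: Iterable[Region], b: Iterable[Region]) -> int:
    """Total intersected length in bp between two interval sets."""
    merged_a = merge_regions(a)
    merged_b = merge_regions(b)
    total = 0
    for name, ivs_a in merged_a.items():
        ivs_b = merged_b.get(name)
        if not ivs_b:
            continue
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i][0], ivs_b[j][0])
            hi = min(ivs_a[i][1], ivs_b[j][1])
            if hi > lo:
                total += hi - lo
            if ivs_a[i][1] <= ivs_b[j][1]:
                i += 1
            else:
                j += 1
    return total


def sensitivity(pred: Iterable[Region], truth: AnnotationSet,
                cls: str | None = None) -> float:
    """SN_class = 100 * O / R over the union of truth intervals of a class.

    Returns NaN (undefined, not zero) when the class has no annotated bases.
    """
    truth_regions = truth.for_class(cls)
    reference = total_length(truth_regions)
    if reference == 0:
        return math.nan
    return 100.0 * overlap_bp(pred, truth_regions) / reference


def specificity_exon(pred: Iterable[Region], exons: AnnotationSet) -> float:
    """SP_exon = 100 - 100 * O / E: the share of coding bases avoided."""
    exon_bp = exons.total_bp
    if exon_bp == 0:
        return math.nan
    return 100.0 - 100.0 * overlap_bp(pred, exons.regions) / exon_bp


def percentage_predicted(pred: Iterable[Region],
                         genome: Sequence[GenomeSequence]) -> float:
    """Percentage of valid genome bases predicted to be repeats."""
    denominator = sum(seq.n_valid for seq in genome)
    if denominator == 0:
        raise ValueError("genome has no valid bases")
    return 100.0 * total_length(pred) / denominator


def random_genome(genome: Sequence[GenomeSequence], order: int,
                  seed: int) -> list[GenomeSequence]:
    """Length-matched random genome from per-sequence Markov chains.

    Each output sequence is sampled from a chain of the given order trained
    on the corresponding input sequence alone, so the random genome matches
    the real one in local composition but carries no planted repetition
    beyond what the chain reproduces.
    """
    out = []
    for i, seq in enumerate(genome):
        background = train_background([seq], order)
        rng = np.random.default_rng([int(seed), i])
        residues = sample_background(background, len(seq), rng)
        out.append(GenomeSequence(f"{seq.name}_random", residues))
    return out


def false_positive_length(pred_on_random: Iterable[Region],
                          truth_filter: AnnotationSet | None = None) -> int:
    """Total detected bases on a random genome, in bp.

    When a reference annotation of the random genome is supplied, bases it
    covers are subtracted (they are plausible chance repeats); without it
    the value is the unfiltered FPL.
    """
    pred_on_random = list(pred_on_random)
    detected = total_length(pred_on_random)
    if truth_filter is not None:
        detected -= overlap_bp(pred_on_random, truth_filter.regions)
    return detected


def potential_repeats(pred: Iterable[Region], truth: AnnotationSet) -> int:
    """Predicted bases not covered by the reference annotation, in bp."""
    pred = list(pred)
    return total_length(pred) - overlap_bp(pred, truth.regions)


@dataclass
class EvaluationReport:
    """Table-1-style summary of one prediction set."""

    sn_by_class: dict[str, float]
    sn_all: float
    sp_exon: float
    pp: float
    fpl: int | None
    pr: int

    COLUMNS = ("SN_te", "SN_tr", "SN_low", "SN_other", "SN_all",
               "SP_exon", "PP", "FPL", "PR")

    def row(self) -> list[str]:
        def fmt(x) -> str:
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return "NA"
            if isinstance(x, float):
                return f"{x:.1f}"
            return str(x)

        values = [self.sn_by_class.get(c, math.nan) for c in CLASSES]
        values += [self.sn_all, self.sp_exon, self.pp, self.fpl, self.pr]
        return [fmt(v) for v in values]

    def to_tsv(self, path=None) -> str:
        text = "\t".join(self.COLUMNS) + "\n" + "\t".join(self.row()) + "\n"
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text


def evaluate(pred: Iterable[Region], truth: AnnotationSet,
             exons: AnnotationSet | None = None,
             genome: Sequence[GenomeSequence] | None = None,
             fpl: int | None = None) -> EvaluationReport:
    """Compute the full report for one prediction set.

    ``fpl`` is passed in by the caller because it requires a separate
    detector run on a random genome.
    """
    pred = list(pred)
    sn_by_class = {cls: sensitivity(pred, truth, cls) for cls in CLASSES}
    sn_all = sensitivity(pred, truth, "all")
    sp = specificity_exon(pred, exons) if exons is not None else math.nan
    pp = percentage_predicted(pred, genome) if genome is not None else math.nan
    pr = potential_repeats(pred, truth)
    return EvaluationReport(
        sn_by_class=sn_by_class,
        sn_all=sn_all,
        sp_exon=sp,
        pp=pp,
        fpl=fpl,
        pr=pr,
    )
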