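"""End-to-end detection: score, label, self-train, scan, mask.

The pipeline is deterministic: nothing in detection draws random numbers.
Multi-record inputs are pooled for counting, background training and HMM
training (one genome, one model), while score tracks, labels and regions
stay per record.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GenomeSequence, Region
from .kmer_scoring import (
    DEFAULT_MAX_TABLE_ENTRIES,
    KmerTable,
    MarkovBackground,
    ScoreTrack,
    adjust_counts,
    choose_k,
    count_kmers,
    score_sequence,
    train_background,
)
from .labeling import LabeledRegions, build_mask, delineate, local_maxima, smooth
from .hmm import HmmModel, build_model, decode_regions, train, viterbi

__all__ = ["PipelineConfig", "DetectionResult", "detect", "scan",
           "save_model", "load_model"]

logger = logging.getLogger("kmermask")

MODEL_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable detection parameters.

    k            word length; default floor(log4(valid bases)), clamped to
                 [min_k, max_k] and to the table memory cap
    order        Markov background order (clamped below k)
    mask_width   Gaussian mask width in bp (sigma = mask_width / 7)
    deriv_window derivative approximation window w
    threshold    low-score threshold t; doubles as the HMM log base
    mode         'genome' for assembled input, 'reads' for unassembled
                 short reads (identical machinery; k is derived from the
                 total base count across reads and each read is scored and
                 decoded independently)
    """

    k: int | None = None
    order: int = 6
    mask_width: int = 40
    deriv_window: int = 10
    threshold: float = 2.0
    mode: str = "genome"
    min_k: int = 8
    max_k: int = 16
    max_table_entries: int = DEFAULT_MAX_TABLE_ENTRIES

    def __post_init__(self) -> None:
        if self.mode not in ("genome", "reads"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold <= 1:
            raise ValueError("threshold t must exceed 1")

    @property
    def sigma(self) -> float:
        return self.mask_width / 7.0


@dataclass
class DetectionResult:
    """Everything one detection run produced."""

    k: int
    order: int
    config: PipelineConfig
    table: KmerTable
    background: MarkovBackground
    model: HmmModel
    score_tracks: list[ScoreTrack]
    labels: list[LabeledRegions]
    repeats: list[Region]

    @property
    def candidates(self) -> list[Region]:
        return [r for lab in self.labels for r in lab.candidates]

    @property
    def nonrepeats(self) -> list[Region]:
        return [r for lab in self.labels for r in lab.nonrepeats]


def _stage(name: str, started: float) -> float:
    now = time.perf_counter()
    logger.info("%s: %.2f s", name, now - started)
    return now


def detect(genome: Sequence[GenomeSequence],
           config: PipelineConfig | None = None) -> DetectionResult:
    """Run the full self-training pipeline on a genome."""
    config = config or PipelineConfig()
    seqs = list(genome)
    tick = time.perf_counter()

    total_valid = sum(seq.n_valid for seq in seqs)
    k = config.k or choose_k(total_valid, config.min_k, config.max_k,
                             config.max_table_entries)
    order = config.order
    if order >= k:
        order = k - 1
        logger.warning("background order clamped to %d (must be < k=%d)",
                       order, k)
    logger.info("genome: %d record(s), %d valid bases; k=%d, order=%d",
                len(seqs), total_valid, k, order)

    observed = count_kmers(seqs, k, config.max_table_entries)
    background = train_background(seqs, order, k=k)
    table = adjust_counts(observed, background)
    tick = _stage("scoring table", tick)

    tracks = [score_sequence(seq, table) for seq in seqs]
    tick = _stage("score tracks", tick)

    mask = build_mask(config.sigma)
    labels: list[LabeledRegions] = []
    for track in tracks:
        smoothed = smooth(track, mask)
        maxima = local_maxima(smoothed.values, config.deriv_window)
        labels.append(
            delineate(smoothed.values, maxima, config.threshold,
                      mask.width, seq_name=track.seq_name)
        )
    n_candidates = sum(len(lab.candidates) for lab in labels)
    logger.info("labeling: %d candidate region(s), %d non-repeat region(s)",
                n_candidates, sum(len(lab.nonrepeats) for lab in labels))
    tick = _stage("labeling", tick)

    max_score = max((float(t.scores.max()) if t.scores.size else 0.0)
                    for t in tracks)
    model = build_model(max_score, config.threshold)
    train(model, zip(tracks, labels))
    tick = _stage("training (%d states)" % model.n_states, tick)

    repeats: list[Region] = []
    for seq, track in zip(seqs, tracks):
        path = viterbi(model, track)
        repeats.extend(
            decode_regions(model, path, k, seq.name, seq_length=len(seq))
        )
    logger.info("scanning: %d final repeat region(s)", len(repeats))
    _stage("scanning", tick)

    return DetectionResult(
        k=k, order=order, config=config, table=table, background=background,
        model=model, score_tracks=tracks, labels=labels, repeats=repeats,
    )


def scan(genome: Sequence[GenomeSequence],
         result: "DetectionResult") -> list[Region]:
    """Apply an existing scoring table and trained model to sequences."""
    repeats: list[Region] = []
    for seq in genome:
        track = score_sequence(seq, result.table)
        path = viterbi(result.model, track)
        repeats.extend(
            decode_regions(result.model, path, result.k, seq.name,
                           seq_length=len(seq))
        )
    return repeats


def save_model(result: DetectionResult, path) -> None:
    """Persist the adjusted table, background and trained HMM.

    A single .npz container with a JSON metadata entry; ``scan`` on the same
    input reproduces ``detect``'s regions bit for bit.
    """
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": result.k,
        "order": result.order,
        "threshold": result.config.threshold,
        "n_levels": result.model.n_levels,
        "n_windows": result.table.n_windows,
        "total_positions": result.background.total_positions,
    }
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        table_values=result.table.values,
        conditional=result.background.conditional,
        context_freq=result.background.context_freq,
        prior_counts=result.model.prior_counts,
        transition_counts=result.model.transition_counts,
    )


def load_model(path) -> DetectionResult:
    """Load a persisted model into a scan-ready (input-free) result."""
    with np.load(path) as data:
        meta = json.loads(data["meta"].tobytes().decode())
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta['format_version']}"
            )
        table = KmerTable(k=int(meta["k"]), values=data["table_values"],
                          n_windows=int(meta["n_windows"]), adjusted=True)
        background = MarkovBackground(
            order=int(meta["order"]),
            conditional=data["conditional"],
            context_freq=data["context_freq"],
            total_positions=int(meta["total_positions"]),
        )
        model = HmmModel(
            t=float(meta["threshold"]),
            n_levels=int(meta["n_levels"]),
            prior_counts=data["prior_counts"],
            transition_counts=data["transition_counts"],
        )
    model.finalize()
    config = PipelineConfig(k=table.k, order=background.order,
                            threshold=model.t)
    return DetectionResult(
        k=table.k, order=background.order, config=config, table=table,
        background=background, model=model, score_tracks=[], labels=[],
        repeats=[],
    )
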