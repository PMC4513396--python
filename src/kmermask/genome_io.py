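"""Sequence and interval I/O.

Sequences are held as uppercase text plus a per-position validity mask that
is true only for the unambiguous bases A, C, G and T.  IUPAC ambiguity codes
(including N) are kept in the text but excluded from every k-mer window.

Intervals are 0-based half-open internally and in BED output; the
human-readable ``coords`` dialect is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastaFormatError",
    "RegionError",
    "GenomeSequence",
    "Region",
    "sequence_digits",
    "read_fasta",
    "write_fasta",
    "masked_residues",
    "write_masked_fasta",
    "write_regions",
    "read_regions",
    "merge_regions",
    "total_length",
]

# A,C,G,T (either case) -> 0..3; every other byte -> -1 (invalid for k-mers).
_DIGIT_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _DIGIT_LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _DIGIT_LUT[_b] = _i

_DIGIT_TO_BASE = "ACGT"


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class RegionError(ValueError):
    """Raised for invalid genomic intervals."""


def sequence_digits(residues: str) -> np.ndarray:
    """Map residues to quaternary digits (A,C,G,T -> 0,1,2,3; other -> -1)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _DIGIT_LUT[raw]


def digits_to_residues(digits: np.ndarray) -> str:
    """Inverse of :func:`sequence_digits` for valid digits only."""
    lut = np.frombuffer(_DIGIT_TO_BASE.encode(), dtype=np.uint8)
    return lut[np.asarray(digits)].tobytes().decode("ascii")


@dataclass
class GenomeSequence:
    """A named DNA text plus a validity mask for ambiguous bases."""

    name: str
    residues: str
    digits: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if self.digits is None:
            self.digits = sequence_digits(self.residues)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.digits >= 0

    @property
    def n_valid(self) -> int:
        return int((self.digits >= 0).sum())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval.

    ``label`` distinguishes repeat from non-repeat intervals; ``tag`` carries
    an optional annotation class (te, tr, low, other, exon).
    """

    seq_name: str
    start: int
    end: int
    label: str = "repeat"
    tag: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionError(
                f"invalid interval {self.seq_name}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length


def read_fasta(path) -> list[GenomeSequence]:
    """Read all records of a FASTA file, in file order.

    Residues are uppercased; the validity mask is computed on the fly.
    Raises :class:`FastaFormatError` naming the offending line for input that
    is empty or does not start with a FASTA header.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty file, no FASTA records")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records")
    return [GenomeSequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(named_seqs: Iterable[tuple[str, str]], path) -> None:
    """Write (name, residues) pairs as FASTA, preserving case."""
    records = [
        SeqRecord(Seq(residues), id=name, description="")
        for name, residues in named_seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def _regions_by_name(regions: Iterable[Region]) -> dict[str, list[Region]]:
    grouped: dict[str, list[Region]] = {}
    for region in regions:
        grouped.setdefault(region.seq_name, []).append(region)
    for name in grouped:
        grouped[name].sort(key=lambda r: (r.start, r.end))
    return grouped


def masked_residues(seq: GenomeSequence, regions: Sequence[Region],
                    mode: str = "soft") -> str:
    """Apply repeat masking to one sequence.

    Soft mode lowercases repeat positions; hard mode replaces them with N.
    """
    if mode not in ("soft", "hard"):
        raise ValueError(f"unknown masking mode {mode!r}")
    raw = bytearray(seq.residues.encode("ascii"))
    for region in regions:
        if region.end > len(raw):
            raise RegionError(
                f"region {region.seq_name}:{region.start}-{region.end} exceeds "
                f"sequence length {len(raw)}"
            )
        if mode == "soft":
            raw[region.start:region.end] = (
                raw[region.start:region.end].lower()
            )
        else:
            raw[region.start:region.end] = b"N" * region.length
    return raw.decode("ascii")


def write_masked_fasta(seqs: Sequence[GenomeSequence],
                       repeats: Iterable[Region], path,
                       mode: str = "soft") -> None:
    """Write sequences with repeat intervals soft- or hard-masked."""
    grouped = _regions_by_name(repeats)
    known = {seq.name for seq in seqs}
    unknown = set(grouped) - known
    if unknown:
        raise KeyError(
            f"regions reference unknown sequence(s): {sorted(unknown)}"
        )
    write_fasta(
        ((seq.name, masked_residues(seq, grouped.get(seq.name, ()), mode))
         for seq in seqs),
        path,
    )


def write_regions(regions: Sequence[Region], path, dialect: str = "bed") -> None:
    """Write intervals as 3/4-column BED or as 1-based ``name:start-end``."""
    if dialect not in ("bed", "coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as handle:
        for region in regions:
            if dialect == "bed":
                fields = [region.seq_name, str(region.start), str(region.end)]
                if region.tag is not None:
                    fields.append(region.tag)
                handle.write("\t".join(fields) + "\n")
            else:
                handle.write(
                    f"{region.seq_name}:{region.start + 1}-{region.end}\n"
                )


def read_regions(path, label: str = "repeat") -> list[Region]:
    """Read a BED file (3 columns, optional 4th class column) into Regions."""
    regions: list[Region] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionError(f"{path}: line {lineno}: need >= 3 columns")
            tag = fields[3] if len(fields) > 3 else None
            regions.append(
                Region(fields[0], int(fields[1]), int(fields[2]), label, tag)
            )
    regions.sort(key=lambda r: (r.seq_name, r.start, r.end))
    return regions


def bundled_novel_repeats() -> list[GenomeSequence]:
    """The two bundled worked-example sequences.

    A 233 bp centromeric novel repeat (human chr10) and a 1105 bp telomeric
    minisatellite (human chr18), both discovered de novo in hg38.
    """
    from importlib.resources import files

    path = files("kmermask").joinpath("data/novel_repeats.fa")
    with path.open() as handle:
        return [
            GenomeSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]


def merge_regions(regions: Iterable[Region]) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per sequence, as sorted disjoint (start, end) pairs."""
    merged: dict[str, list[tuple[int, int]]] = {}
    for name, group in _regions_by_name(regions).items():
        out: list[tuple[int, int]] = []
        for region in group:
            if out and region.start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], region.end))
            else:
                out.append((region.start, region.end))
        merged[name] = out
    return merged


def total_length(regions: Iterable[Region]) -> int:
    """Total base count covered by the union of the given intervals."""
    return sum(
        end - start
        for ivs in merge_regions(regions).values()
        for start, end in ivs
    )
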