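"""Sequence and interval I/O: FASTA/BED reading and writing, coordinate-safe windowing.

Coordinates are 0-based half-open everywhere inside the package; human-readable
reports elsewhere print 1-based inclusive. The nucleotide alphabet is
{A, C, G, T, N}; lower-case (soft-masked) input is normalized to upper case on
load, and N is carried through (the scanner treats it as a mismatch at every
consensus position, so ambiguous sequence can never gain a site call).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed FASTA/BED content (names the offending record/line)."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A, C, G, T, N}, upper-cased."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise FormatError("sequence identifier must be non-empty")
        residues = self.residues.upper()
        bad = set(residues) - ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(residues) if c in bad)
            raise FormatError(
                f"illegal character {residues[pos]!r} at position {pos + 1} "
                f"in record {self.identifier!r}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def reverse_complement(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    residues = residues.upper()
    bad = set(residues) - ALPHABET
    if bad:
        raise FormatError(f"illegal character(s) {sorted(bad)} in sequence")
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(
    path: str | Path, exclude_softmasked: bool = False
) -> list[NucSequence]:
    """Read a multi-record FASTA into NucSequence objects.

    Residues are upper-cased; characters outside {A,C,G,T,N} and duplicate
    identifiers are rejected with a FormatError naming the record. With
    exclude_softmasked, lower-case (repeat-masked) bases become N, so no
    motif window overlapping them can ever be called.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if exclude_softmasked:
            raw = "".join("N" if c.islower() else c for c in raw)
        records.append(NucSequence(rec.id, raw))
    return records


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extract_window(seq: NucSequence, interval: GenomicInterval) -> NucSequence:
    """Extract interval [start, end) from seq; minus strand returns the
    reverse complement. The new identifier records the source coordinates."""
    if interval.end > len(seq):
        raise FormatError(
            f"interval {interval.start}-{interval.end} out of bounds for "
            f"{seq.identifier!r} (length {len(seq)})"
        )
    sub = seq.residues[interval.start : interval.end]
    if interval.strand == "-":
        sub = reverse_complement(sub)
    ident = f"{seq.identifier}:{interval.start}-{interval.end}({interval.strand})"
    return NucSequence(ident, sub)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab-separated, 0-based half-open)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    scores: Sequence[int] | None = None,
) -> None:
    """Write BED6; score defaults to 0."""
    if scores is not None and len(scores) != len(intervals):
        raise ValueError("scores length must match intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def validate_file(path: str | Path, fmt: str) -> int:
    """Validate a FASTA or BED file; returns the record count or raises."""
    if fmt == "fasta":
        return len(read_fasta(path))
    if fmt == "bed":
        return len(read_bed(path))
    raise ValueError(f"unknown format {fmt!r}")
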