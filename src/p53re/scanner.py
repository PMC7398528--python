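"""Degenerate p53 response-element scanner.

A canonical p53 response element is two copies of the decamer half-site
RRRCWWGYYY separated by 0-13 bp of spacer (R = purine, Y = pyrimidine,
W = A/T). The scanner matches half-sites on both strands under a per-half
mismatch budget, then pairs half-sites across the spacer range under a total
budget. Because RRRCWWGYYY is its own reverse complement, a window that
matches identically on both strands is reported once, on the plus strand.

N never satisfies a consensus symbol, so sites are never called on ambiguous
sequence. All coordinates are plus-strand, 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import GenomicInterval, NucSequence, reverse_complement

IUPAC_MAP: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class ConsensusPattern:
    """The degenerate half-site, spacer range, and mismatch budgets.

    Defaults describe the canonical p53 element: half-site RRRCWWGYYY,
    spacer 0-13 bp, at most 2 mismatches per half and 3 in total.
    """

    half_site: str = "RRRCWWGYYY"
    spacer_min: int = 0
    spacer_max: int = 13
    max_mm_per_half: int = 2
    max_mm_total: int = 3

    def __post_init__(self) -> None:
        if len(self.half_site) != 10:
            raise ValueError("half_site must be a decamer")
        for sym in self.half_site:
            if sym not in IUPAC_MAP:
                raise ValueError(f"unknown IUPAC symbol {sym!r}")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if self.max_mm_per_half < 0 or self.max_mm_total < 0:
            raise ValueError("mismatch budgets must be >= 0")

    @property
    def half_len(self) -> int:
        return len(self.half_site)


@dataclass(frozen=True)
class HalfSiteMatch:
    """One decamer hit.

    offset is the 0-based plus-strand position of the window; observed is the
    plus-strand window sequence; mismatch_positions are 1-based positions in
    consensus orientation (for minus-strand hits, position 1 is the 3' end of
    the plus-strand window).
    """

    offset: int
    strand: str
    observed: str
    mismatch_count: int
    mismatch_positions: frozenset[int]


@dataclass(frozen=True)
class P53ResponseElement:
    """A paired full site: two half-site hits separated by a spacer."""

    half1: HalfSiteMatch
    half2: HalfSiteMatch
    spacer_length: int
    total_mismatches: int
    interval: GenomicInterval
    label: str | None = None

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def match_half_site(window: str, pattern: ConsensusPattern) -> HalfSiteMatch:
    """Match a decamer window against the half-site consensus (plus strand).

    Position i (1-based) mismatches iff window[i-1] is outside the allowed
    base set of consensus symbol i; N is outside every set.
    """
    window = window.upper()
    if len(window) != pattern.half_len:
        raise ValueError(
            f"window length {len(window)} != half-site length {pattern.half_len}"
        )
    mism = frozenset(
        i + 1
        for i, (base, sym) in enumerate(zip(window, pattern.half_site))
        if base not in IUPAC_MAP[sym]
    )
    return HalfSiteMatch(0, "+", window, len(mism), mism)


def _match_at(window: str, pattern: ConsensusPattern, offset: int,
              strand: str) -> HalfSiteMatch:
    probe = window if strand == "+" else reverse_complement(window)
    m = match_half_site(probe, pattern)
    return HalfSiteMatch(offset, strand, window, m.mismatch_count,
                         m.mismatch_positions)


def scan_half_sites(
    seq: NucSequence, pattern: ConsensusPattern
) -> list[HalfSiteMatch]:
    """All decamer windows on both strands with mismatch_count <= budget.

    Minus-strand hits are reported at their plus-strand interval. A window
    whose two orientations give the same mismatch count and (reflected)
    mismatch positions — always the case for the self-reverse-complementary
    default consensus — is reported once, strand '+'.
    """
    k = pattern.half_len
    hits: list[HalfSiteMatch] = []
    residues = seq.residues
    for off in range(len(residues) - k + 1):
        window = residues[off : off + k]
        plus = _match_at(window, pattern, off, "+")
        minus = _match_at(window, pattern, off, "-")
        plus_ok = plus.mismatch_count <= pattern.max_mm_per_half
        minus_ok = minus.mismatch_count <= pattern.max_mm_per_half
        if plus_ok:
            hits.append(plus)
        if minus_ok:
            # the minus orientation duplicates the plus report when its
            # mismatch set is the reflection of the plus set
            reflected = frozenset(k + 1 - p for p in minus.mismatch_positions)
            duplicate = plus_ok and reflected == plus.mismatch_positions
            if not duplicate:
                hits.append(minus)
    return hits


def pair_full_sites(
    halves: Sequence[HalfSiteMatch], pattern: ConsensusPattern,
    chrom: str = "seq",
) -> list[P53ResponseElement]:
    """Pair half-sites across the spacer range under the total budget.

    Every ordered pair (half1 upstream of half2 on the plus strand) with
    spacer in [spacer_min, spacer_max] and summed mismatches <= max_mm_total
    becomes an element. Sorted by (total mismatches, spacer length, start).
    """
    k = pattern.half_len
    by_offset: dict[int, list[HalfSiteMatch]] = {}
    for h in sorted(halves, key=lambda m: (m.offset, m.strand)):
        by_offset.setdefault(h.offset, []).append(h)
    elements: list[P53ResponseElement] = []
    seen: set[tuple] = set()
    for off1 in sorted(by_offset):
        for h1 in by_offset[off1]:
            lo = off1 + k + pattern.spacer_min
            hi = off1 + k + pattern.spacer_max
            for off2 in range(lo, hi + 1):
                for h2 in by_offset.get(off2, ()):
                    total = h1.mismatch_count + h2.mismatch_count
                    if total > pattern.max_mm_total:
                        continue
                    key = (off1, h1.strand, off2, h2.strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    spacer = off2 - (off1 + k)
                    interval = GenomicInterval(chrom, off1, off2 + k, "+")
                    elements.append(
                        P53ResponseElement(h1, h2, spacer, total, interval)
                    )
    elements.sort(key=lambda e: (e.total_mismatches, e.spacer_length, e.start))
    return elements


def scan_response_elements(
    seq: NucSequence,
    pattern: ConsensusPattern | None = None,
    non_overlapping: bool = False,
) -> list[P53ResponseElement]:
    """Scan a sequence for full p53 response elements.

    Composition of scan_half_sites and pair_full_sites. With
    non_overlapping, a greedy pass over the (mismatch, spacer, start)-ranked
    list keeps each element only if it does not overlap an already-kept one.
    """
    pattern = pattern or ConsensusPattern()
    halves = scan_half_sites(seq, pattern)
    elements = pair_full_sites(halves, pattern, chrom=seq.identifier)
    if non_overlapping:
        kept: list[P53ResponseElement] = []
        for el in elements:
            if not any(el.interval.overlaps(k.interval) for k in kept):
                kept.append(el)
        elements = kept
    return elements


def bed_score(element: P53ResponseElement) -> int:
    """BED score: 1000 - 100 per mismatch, clamped to [0, 1000]."""
    return max(0, min(1000, 1000 - 100 * element.total_mismatches))


def elements_to_bed(
    elements: Sequence[P53ResponseElement], path
) -> None:
    from .sequence_io import write_bed

    intervals = [
        replace(e.interval, name=e.label or f"RE_{i + 1}")
        for i, e in enumerate(elements)
    ]
    write_bed(intervals, path, scores=[bed_score(e) for e in elements])


def elements_to_table(elements: Sequence[P53ResponseElement]) -> pd.DataFrame:
    """Per-element report mirroring figure-style annotation: observed halves,
    spacer, mismatch counts and 1-based mismatch positions.

    start/end columns are printed 1-based inclusive."""
    rows = []
    for i, e in enumerate(elements):
        rows.append(
            {
                "name": e.label or f"RE_{i + 1}",
                "chrom": e.interval.chrom,
                "start": e.start + 1,
                "end": e.end,
                "half1_seq": e.half1.observed,
                "half1_strand": e.half1.strand,
                "half1_mm": e.half1.mismatch_count,
                "half1_mm_pos": ",".join(map(str, sorted(e.half1.mismatch_positions))),
                "spacer": e.spacer_length,
                "half2_seq": e.half2.observed,
                "half2_strand": e.half2.strand,
                "half2_mm": e.half2.mismatch_count,
                "half2_mm_pos": ",".join(map(str, sorted(e.half2.mismatch_positions))),
                "total_mm": e.total_mismatches,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "chrom", "start", "end", "half1_seq", "half1_strand",
            "half1_mm", "half1_mm_pos", "spacer", "half2_seq", "half2_strand",
            "half2_mm", "half2_mm_pos", "total_mm",
        ],
    )
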