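"""ChIP-seq coverage normalization and promoter occupancy reporting.

Consumes pre-computed per-base/per-interval coverage (bedGraph) with a
declared total mapped-read count; never aligns reads or calls peaks. Depth
is rescaled to a fixed library size of 10 million mapped reads so tracks
from different libraries are comparable, and target-promoter occupancy is
expressed relative to a positive-control locus (e.g. the CDKN1A/p21
promoter, bound by p53 wherever p53 is active).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .scanner import P53ResponseElement
from .sequence_io import FormatError, GenomicInterval

TARGET_DEPTH = 10_000_000


@dataclass(frozen=True)
class CoverageTrack:
    """Piecewise-constant coverage: non-overlapping intervals with depth."""

    intervals: tuple[tuple[GenomicInterval, float], ...]
    total_reads: int
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv, depth in self.intervals:
            if depth < 0:
                raise ValueError(f"negative depth at {iv.chrom}:{iv.start}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda v: v.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping coverage intervals on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    @property
    def scale_factor(self) -> float:
        return TARGET_DEPTH / self.total_reads


@dataclass(frozen=True)
class OccupancyReport:
    locus: str
    window: GenomicInterval
    max_signal: float
    mean_signal: float
    control_locus: str
    control_max: float
    ratio_to_control: float | None
    enriched: bool


def read_bedgraph(path: str | Path, total_reads: int) -> CoverageTrack:
    """Read a 4-column bedGraph (chrom, start, end, depth)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                start, end = int(fields[1]), int(fields[2])
                depth = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            entries.append((GenomicInterval(fields[0], start, end), depth))
    return CoverageTrack(tuple(entries), total_reads)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, depth in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{depth:.6g}\n")


def normalize_to_10M(track: CoverageTrack) -> CoverageTrack:
    """Rescale every depth by 10^7 / total_reads; errors on re-application."""
    if track.normalized:
        raise ValueError("track is already normalized")
    f = track.scale_factor
    return replace(
        track,
        intervals=tuple((iv, depth * f) for iv, depth in track.intervals),
        normalized=True,
    )


def window_signal(
    track: CoverageTrack, window: GenomicInterval
) -> tuple[float, float]:
    """(max, length-weighted mean) depth over the window; uncovered bases
    count as depth 0. A window on an absent chromosome warns and returns
    (0, 0)."""
    if not track.normalized:
        raise ValueError("normalize the track before querying signal")
    chroms = {iv.chrom for iv, _ in track.intervals}
    if window.chrom not in chroms:
        warnings.warn(
            f"chromosome {window.chrom!r} absent from coverage track",
            stacklevel=2,
        )
        return 0.0, 0.0
    covered = 0
    total = 0.0
    max_depth = 0.0
    for iv, depth in track.intervals:
        if iv.chrom != window.chrom:
            continue
        lo = max(iv.start, window.start)
        hi = min(iv.end, window.end)
        if lo >= hi:
            continue
        covered += hi - lo
        total += depth * (hi - lo)
        max_depth = max(max_depth, depth)
    if covered < len(window):
        max_depth = max(max_depth, 0.0)
    return max_depth, total / len(window)


def occupancy_report(
    track: CoverageTrack,
    target_window: GenomicInterval,
    control_window: GenomicInterval,
    target_label: str = "target",
    control_label: str = "control",
    enrichment_ratio: float = 0.1,
) -> OccupancyReport:
    """Occupancy of the target window relative to the control-locus maximum.

    enriched means ratio_to_control >= enrichment_ratio. If the control has
    no signal the ratio is undefined (None) and enriched is False.
    """
    t_max, t_mean = window_signal(track, target_window)
    c_max, _ = window_signal(track, control_window)
    ratio = t_max / c_max if c_max > 0 else None
    if ratio is None:
        warnings.warn("control window has zero coverage; ratio undefined",
                      stacklevel=2)
    return OccupancyReport(
        locus=target_label,
        window=target_window,
        max_signal=t_max,
        mean_signal=t_mean,
        control_locus=control_label,
        control_max=c_max,
        ratio_to_control=ratio,
        enriched=ratio is not None and ratio >= enrichment_ratio,
    )


def report_to_frame(report: OccupancyReport) -> pd.DataFrame:
    w = report.window
    return pd.DataFrame(
        [
            {
                "locus": report.locus,
                "window": f"{w.chrom}:{w.start + 1}-{w.end}",
                "max_signal": report.max_signal,
                "mean_signal": report.mean_signal,
                "control_locus": report.control_locus,
                "control_max": report.control_max,
                "ratio_to_control": (
                    "" if report.ratio_to_control is None
                    else report.ratio_to_control
                ),
                "enriched": report.enriched,
            }
        ]
    )


def overlap_elements_with_peaks(
    elements: Sequence[P53ResponseElement],
    peaks: Sequence[GenomicInterval],
) -> list[tuple[P53ResponseElement, list[GenomicInterval]]]:
    """Annotate each element with the peaks it overlaps (half-open
    semantics, same sequence namespace). Sorted sweep over start positions."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda v: (v.start, v.end))
    out: list[tuple[P53ResponseElement, list[GenomicInterval]]] = []
    for el in elements:
        hits: list[GenomicInterval] = []
        for p in by_chrom.get(el.interval.chrom, []):
            if p.start >= el.interval.end:
                break
            if el.interval.overlaps(p):
                hits.append(p)
        out.append((el, hits))
    return out
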