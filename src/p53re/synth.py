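"""Synthetic promoters, orthologous species cohorts, and coverage tracks
with known ground truth.

The generator exists so every pipeline stage is testable without external
downloads: background sequence of configurable length and GC content,
planted full response elements with stated per-half mismatch counts and
spacer lengths, orthologous "species" derived by per-base substitution and
short-indel divergence with optional targeted ablation of planted sites,
and piecewise-constant coverage tracks with triangular peaks. All
randomness flows from one integer seed.

The divergence model is deliberately simple (i.i.d. substitutions, indels
of length 1-3); it tests plumbing, not molecular evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .chip import CoverageTrack
from .scanner import (
    IUPAC_MAP,
    ConsensusPattern,
    scan_response_elements,
)
from .sequence_io import GenomicInterval, NucSequence

BASES = "ACGT"


@dataclass(frozen=True)
class PlantedSiteSpec:
    """One full element to write into a background: position, spacer length
    (0-13), mismatch count per half, and a label (e.g. BS1)."""

    position: int
    spacer_length: int
    mm_half1: int = 0
    mm_half2: int = 0
    label: str = "BS"

    @property
    def length(self) -> int:
        return 20 + self.spacer_length

    @property
    def total_mismatches(self) -> int:
        return self.mm_half1 + self.mm_half2


@dataclass(frozen=True)
class PlantedSiteTruth:
    """Ground truth for one planted (or diverged) site."""

    label: str
    interval: GenomicInterval | None
    spacer_length: int
    mm_half1: int
    mm_half2: int
    sequence: str
    present: bool = True

    @property
    def total_mismatches(self) -> int:
        return self.mm_half1 + self.mm_half2


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    ablate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    promoter_length: int = 1200
    gc_fraction: float = 0.5
    planted: tuple[PlantedSiteSpec, ...] = ()
    species: tuple[SpeciesSpec, ...] = ()
    seed: int = 0


def realize_half_site(
    pattern: ConsensusPattern, n_mismatches: int, rng: np.random.Generator
) -> str:
    """Draw a decamer with exactly n_mismatches violated consensus positions.

    Violated positions are chosen uniformly without replacement; at each one
    the base is uniform over the disallowed set, elsewhere uniform over the
    allowed set.
    """
    k = pattern.half_len
    if not (0 <= n_mismatches <= k):
        raise ValueError(f"n_mismatches must be in [0, {k}]")
    bad_pos = set(rng.choice(k, size=n_mismatches, replace=False).tolist())
    out = []
    for i, sym in enumerate(pattern.half_site):
        allowed = sorted(IUPAC_MAP[sym])
        if i in bad_pos:
            pool = sorted(set(BASES) - set(allowed))
            if not pool:
                raise ValueError(
                    f"symbol {sym!r} allows every base; cannot mismatch"
                )
        else:
            pool = allowed
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def generate_background(
    length: int, gc_fraction: float, rng: np.random.Generator
) -> NucSequence:
    """I.i.d. background: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    p = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    draws = rng.choice(4, size=length, p=p)
    return NucSequence("background", "".join(BASES[i] for i in draws))


def plant_sites(
    background: NucSequence,
    planted: Sequence[PlantedSiteSpec],
    pattern: ConsensusPattern,
    rng: np.random.Generator,
    identifier: str | None = None,
) -> tuple[NucSequence, list[PlantedSiteTruth]]:
    """Write full elements into the background; returns sequence + truth.

    Each site is realize_half_site(mm_half1) + random spacer +
    realize_half_site(mm_half2) at the stated position. Sites must fit and
    be mutually disjoint.
    """
    ordered = sorted(planted, key=lambda s: s.position)
    for s in ordered:
        if not (pattern.spacer_min <= s.spacer_length <= pattern.spacer_max):
            raise ValueError(
                f"spacer {s.spacer_length} outside pattern range for {s.label}"
            )
        if s.position < 0 or s.position + s.length > len(background):
            raise ValueError(f"site {s.label} does not fit in background")
    for a, b in zip(ordered, ordered[1:]):
        if a.position + a.length > b.position:
            raise ValueError(
                f"planted sites {a.label} and {b.label} overlap"
            )
    residues = list(background.residues)
    truth: list[PlantedSiteTruth] = []
    ident = identifier or background.identifier
    for s in planted:
        h1 = realize_half_site(pattern, s.mm_half1, rng)
        spacer = "".join(BASES[rng.integers(4)] for _ in range(s.spacer_length))
        h2 = realize_half_site(pattern, s.mm_half2, rng)
        site_seq = h1 + spacer + h2
        residues[s.position : s.position + s.length] = site_seq
        truth.append(
            PlantedSiteTruth(
                label=s.label,
                interval=GenomicInterval(
                    ident, s.position, s.position + s.length, "+", s.label
                ),
                spacer_length=s.spacer_length,
                mm_half1=s.mm_half1,
                mm_half2=s.mm_half2,
                sequence=site_seq,
            )
        )
    return NucSequence(ident, "".join(residues)), truth


def _site_survives(
    residues: str, interval: GenomicInterval, pattern: ConsensusPattern
) -> bool:
    """Direct recheck: does a full element within budget survive at the
    (possibly shifted) locus?"""
    window = residues[interval.start : interval.end]
    if len(window) < 2 * pattern.half_len:
        return False
    probe = NucSequence("probe", window)
    return bool(scan_response_elements(probe, pattern))


def diverge_species(
    reference: NucSequence,
    spec: SpeciesSpec,
    truth: Sequence[PlantedSiteTruth],
    pattern: ConsensusPattern,
    rng: np.random.Generator,
) -> tuple[NucSequence, list[PlantedSiteTruth]]:
    """Derive one species' promoter from the reference.

    Sites named in spec.ablate are first overwritten with uniform random
    sequence; then every base mutates independently (substitution uniform
    over the 3 alternatives) and initiates an indel with the stated rate
    (insertion or deletion, equally likely, length 1-3 uniform). The
    returned truth carries each site's new projected interval and a
    present/absent verdict from direct rescanning of the projected locus.
    """
    residues = list(reference.residues)
    for t in truth:
        if t.label in spec.ablate and t.interval is not None:
            for i in range(t.interval.start, t.interval.end):
                residues[i] = BASES[rng.integers(4)]
    new_seq: list[str] = []
    # new_pos[i] = index of reference base i in the derived sequence (None if deleted)
    new_pos: list[int | None] = [None] * len(residues)
    i = 0
    while i < len(residues):
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion before base i
                for _ in range(length):
                    new_seq.append(BASES[rng.integers(4)])
            else:  # deletion of bases i..i+length-1
                i += length
                continue
        base = residues[i]
        if spec.substitution_rate > 0 and rng.random() < spec.substitution_rate:
            base = sorted(set(BASES) - {base})[rng.integers(3)]
        new_pos[i] = len(new_seq)
        new_seq.append(base)
        i += 1
    derived = NucSequence(spec.name, "".join(new_seq))
    new_truth: list[PlantedSiteTruth] = []
    for t in truth:
        if t.interval is None:
            new_truth.append(t)
            continue
        mapped = [
            new_pos[i]
            for i in range(t.interval.start, t.interval.end)
            if new_pos[i] is not None
        ]
        if not mapped or t.label in spec.ablate:
            ablated_iv = None
            if mapped:
                ablated_iv = GenomicInterval(
                    spec.name, mapped[0], mapped[-1] + 1, "+", t.label
                )
            new_truth.append(
                PlantedSiteTruth(
                    t.label, ablated_iv, t.spacer_length, t.mm_half1,
                    t.mm_half2,
                    derived.residues[mapped[0]: mapped[-1] + 1] if mapped else "",
                    present=(
                        _site_survives(derived.residues, ablated_iv, pattern)
                        if ablated_iv is not None else False
                    ),
                )
            )
            continue
        iv = GenomicInterval(spec.name, mapped[0], mapped[-1] + 1, "+", t.label)
        seq = derived.residues[iv.start : iv.end]
        new_truth.append(
            PlantedSiteTruth(
                t.label, iv, t.spacer_length, t.mm_half1, t.mm_half2, seq,
                present=_site_survives(derived.residues, iv, pattern),
            )
        )
    return derived, new_truth


@dataclass(frozen=True)
class Cohort:
    reference: NucSequence
    reference_truth: tuple[PlantedSiteTruth, ...]
    species: tuple[NucSequence, ...]
    species_truth: dict[str, tuple[PlantedSiteTruth, ...]]


def generate_cohort(
    spec: CohortSpec, pattern: ConsensusPattern | None = None,
    reference_name: str = "reference",
) -> Cohort:
    """Reference promoter with planted sites plus diverged species set.

    The seed in the spec fixes every output byte.
    """
    pattern = pattern or ConsensusPattern()
    rng = np.random.default_rng(spec.seed)
    background = generate_background(spec.promoter_length, spec.gc_fraction, rng)
    reference, truth = plant_sites(
        background, spec.planted, pattern, rng, identifier=reference_name
    )
    species_seqs: list[NucSequence] = []
    species_truth: dict[str, tuple[PlantedSiteTruth, ...]] = {}
    for sp in spec.species:
        seq, t = diverge_species(reference, sp, truth, pattern, rng)
        species_seqs.append(seq)
        species_truth[sp.name] = tuple(t)
    return Cohort(reference, tuple(truth), tuple(species_seqs), species_truth)


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a CohortSpec from YAML (schema mirrors the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    planted = tuple(PlantedSiteSpec(**p) for p in raw.get("planted", []))
    species = tuple(
        SpeciesSpec(
            name=s["name"],
            substitution_rate=s.get("substitution_rate", 0.0),
            indel_rate=s.get("indel_rate", 0.0),
            ablate=tuple(s.get("ablate", [])),
        )
        for s in raw.get("species", [])
    )
    return CohortSpec(
        promoter_length=raw.get("promoter_length", 1200),
        gc_fraction=raw.get("gc_fraction", 0.5),
        planted=planted,
        species=species,
        seed=raw.get("seed", 0),
    )


def synth_coverage(
    windows: Sequence[tuple[GenomicInterval, float]],
    background_depth: float,
    total_reads: int,
    rng: np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[CoverageTrack, list[tuple[GenomicInterval, float]]]:
    """Piecewise-constant coverage with triangular peaks over jittered
    background.

    Each (window, peak_height) adds a symmetric triangle rising from the
    background to peak_height at the window center. Background per-base
    depth is Poisson(background_depth). Returns the raw (unnormalized)
    track and the peak truth list.
    """
    for _, h in windows:
        if h < background_depth:
            raise ValueError("peak heights must be >= background depth")
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for iv, _ in windows:
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end + 100)
    entries: list[tuple[GenomicInterval, float]] = []
    for chrom in sorted(lengths):
        L = lengths[chrom]
        depth = rng.poisson(background_depth, size=L).astype(float)
        for iv, h in windows:
            if iv.chrom != chrom:
                continue
            span = len(iv)
            center = (iv.start + iv.end - 1) / 2
            for pos in range(iv.start, iv.end):
                frac = 1.0 - abs(pos - center) / (span / 2)
                depth[pos] = max(
                    depth[pos], background_depth + (h - background_depth) * frac
                )
        # run-length encode equal consecutive depths
        start = 0
        for pos in range(1, L + 1):
            if pos == L or depth[pos] != depth[start]:
                if depth[start] > 0:
                    entries.append(
                        (GenomicInterval(chrom, start, pos), float(depth[start]))
                    )
                start = pos
    track = CoverageTrack(tuple(entries), total_reads)
    return track, [(iv, h) for iv, h in windows]
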