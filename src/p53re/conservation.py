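"""Cross-species site projection and conservation scoring, and site-swap
construct design.

A reference promoter (mouse, in the motivating analysis) is globally aligned
to each other species' promoter window; each reference response element is
projected through the alignment, the projected window (plus a small slack to
absorb indels) is rescanned with the consensus pattern, and the site is
called present iff a full element within the mismatch budget survives at the
projected locus. Site swaps replace a segment of one species' promoter with
another species' element sequence — the in-silico analogue of reporter
mutagenesis constructs (BS1mut / BS2mut / BS1/2mut).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scanner import (
    ConsensusPattern,
    P53ResponseElement,
    scan_response_elements,
)
from .sequence_io import GenomicInterval, NucSequence


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment with gapped strings of equal length."""

    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class SiteConservationRecord:
    """A reference site projected into one species' promoter.

    mm_to_consensus is the best full-element mismatch total found in the
    projected window (None if no element within budget, or if the locus is
    deleted in the species). mm_to_reference counts substitution columns
    between the aligned site region of reference and species; indel columns
    are reported separately.
    """

    species: str
    site_label: str
    projected_interval: GenomicInterval | None
    projected_sequence: str
    mm_to_consensus: int | None
    mm_to_reference: int
    indel_columns: int
    present: bool
    deleted: bool = False


@dataclass(frozen=True)
class MutantConstruct:
    """A promoter with one or more site swaps applied.

    swaps records (wild-type target interval, replacement, donor label);
    sequence outside the swapped intervals is identical to wild type.
    """

    name: str
    sequence: NucSequence
    swaps: tuple[tuple[GenomicInterval, str, str], ...]


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def global_align(
    ref: NucSequence, query: NucSequence, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with linear gap cost.

    Traceback ties are broken deterministically: diagonal, then up (gap in
    query), then left (gap in reference).
    """
    params = params or AlignParams()
    a, b = ref.residues, query.residues
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = np.arange(m + 1) * params.gap
    score[:, 0] = np.arange(n + 1) * params.gap
    sub = np.where(
        np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(b.encode(), dtype=np.uint8)[None, :],
        params.match,
        params.mismatch,
    )
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + params.gap
        row = score[i]
        prev_best = np.maximum(diag, up)
        # left moves depend on the current row, so fill sequentially
        acc = row[0]
        for j in range(1, m + 1):
            acc = max(prev_best[j - 1], acc + params.gap)
            row[j] = acc
    # traceback: diagonal > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            score[i, j], score[i - 1, j - 1] + sub[i - 1, j - 1]
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + params.gap):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return PairwiseAlignment(
        ref.identifier,
        query.identifier,
        "".join(reversed(out_a)),
        "".join(reversed(out_b)),
        float(score[n, m]),
        params,
    )


def project_interval(
    aln: PairwiseAlignment, ref_interval: GenomicInterval
) -> tuple[GenomicInterval | None, bool]:
    """Project a reference interval through the alignment onto the query.

    Returns (query interval, deleted flag). A projection falling entirely in
    a query gap yields (None, True). Projection is monotone: ordered,
    non-overlapping reference intervals project to ordered, non-overlapping
    query intervals.
    """
    ref_len = sum(1 for c in aln.aligned_ref if c != "-")
    if ref_interval.end > ref_len:
        raise ValueError(
            f"interval end {ref_interval.end} beyond reference span {ref_len}"
        )
    ri = qi = 0
    q_start: int | None = None
    q_end: int | None = None
    insert_point = 0
    for rc, qc in zip(aln.aligned_ref, aln.aligned_query):
        in_site = rc != "-" and ref_interval.start <= ri < ref_interval.end
        if in_site and qc != "-":
            if q_start is None:
                q_start = qi
            q_end = qi + 1
        if rc != "-":
            if ri < ref_interval.start:
                insert_point = qi + (0 if qc == "-" else 1)
            ri += 1
        if qc != "-":
            qi += 1
        if ri >= ref_interval.end and q_start is not None:
            break
    if q_start is None:
        return None, True
    return (
        GenomicInterval(aln.query_id, q_start, q_end, ref_interval.strand,
                        ref_interval.name),
        False,
    )


# ---------------------------------------------------------------------------
# Conservation assessment
# ---------------------------------------------------------------------------

def _aligned_site_columns(
    aln: PairwiseAlignment, ref_interval: GenomicInterval
) -> list[tuple[str, str]]:
    cols = []
    ri = 0
    for rc, qc in zip(aln.aligned_ref, aln.aligned_query):
        if rc != "-":
            if ref_interval.start <= ri < ref_interval.end:
                cols.append((rc, qc))
            ri += 1
        elif cols and ri < ref_interval.end:
            # insertion inside the site region
            cols.append((rc, qc))
    return cols


def assess_site_conservation(
    ref_site: P53ResponseElement,
    ref_promoter: NucSequence,
    species_promoter: NucSequence,
    pattern: ConsensusPattern | None = None,
    slack: int = 5,
    alignment: PairwiseAlignment | None = None,
    site_label: str | None = None,
) -> SiteConservationRecord:
    """Project one reference site into a species promoter and score it.

    The promoters are globally aligned (or a precomputed alignment is
    reused), the site interval is projected, the projected window +- slack
    bp is rescanned with the pattern, and presence means a full element
    within max_mm_total survives there.
    """
    pattern = pattern or ConsensusPattern()
    label = site_label or ref_site.label or "site"
    aln = alignment or global_align(ref_promoter, species_promoter)
    proj, deleted = project_interval(aln, ref_site.interval)
    cols = _aligned_site_columns(aln, ref_site.interval)
    mm_ref = sum(
        1 for rc, qc in cols if rc != "-" and qc != "-" and rc != qc
    )
    indels = sum(1 for rc, qc in cols if rc == "-" or qc == "-")
    if deleted or proj is None:
        return SiteConservationRecord(
            species_promoter.identifier, label, None, "", None,
            mm_ref, indels, present=False, deleted=True,
        )
    w_start = max(0, proj.start - slack)
    w_end = min(len(species_promoter), proj.end + slack)
    window = NucSequence(
        f"{species_promoter.identifier}:{w_start}-{w_end}",
        species_promoter.residues[w_start:w_end],
    )
    hits = scan_response_elements(window, pattern)
    best = min((e.total_mismatches for e in hits), default=None)
    return SiteConservationRecord(
        species=species_promoter.identifier,
        site_label=label,
        projected_interval=proj,
        projected_sequence=species_promoter.residues[proj.start : proj.end],
        mm_to_consensus=best,
        mm_to_reference=mm_ref,
        indel_columns=indels,
        present=best is not None,
        deleted=False,
    )


def conservation_table(
    ref_promoter: NucSequence,
    ref_sites: Sequence[P53ResponseElement],
    species_promoters: Sequence[NucSequence],
    pattern: ConsensusPattern | None = None,
    slack: int = 5,
) -> tuple[list[SiteConservationRecord], pd.DataFrame]:
    """One SiteConservationRecord per (species, reference site).

    The DataFrame mirrors figure-style rows: species, site, projected
    sequence, mismatch annotations, presence. Promoters are aligned once per
    species and reused across sites."""
    if not species_promoters:
        raise ValueError("need at least one species promoter")
    pattern = pattern or ConsensusPattern()
    records: list[SiteConservationRecord] = []
    for sp in species_promoters:
        aln = global_align(ref_promoter, sp)
        for k, site in enumerate(ref_sites):
            label = site.label or f"BS{k + 1}"
            records.append(
                assess_site_conservation(
                    site, ref_promoter, sp, pattern, slack,
                    alignment=aln, site_label=label,
                )
            )
    rows = [
        {
            "species": r.species,
            "site": r.site_label,
            "projected_start": (r.projected_interval.start + 1
                                if r.projected_interval else ""),
            "projected_end": (r.projected_interval.end
                              if r.projected_interval else ""),
            "projected_sequence": r.projected_sequence,
            "mm_to_consensus": "" if r.mm_to_consensus is None else r.mm_to_consensus,
            "mm_to_reference": r.mm_to_reference,
            "indel_columns": r.indel_columns,
            "present": r.present,
            "deleted": r.deleted,
        }
        for r in records
    ]
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Site-swap constructs
# ---------------------------------------------------------------------------

def swap_site(
    wild_type: NucSequence,
    target: GenomicInterval,
    replacement: str,
    name: str,
    donor_label: str = "donor",
) -> MutantConstruct:
    """Replace target [start, end) of the wild type with replacement."""
    return swap_sites(wild_type, [(target, replacement, donor_label)], name)


def swap_sites(
    wild_type: NucSequence,
    swaps: Sequence[tuple[GenomicInterval, str, str]],
    name: str,
) -> MutantConstruct:
    """Apply several swaps at once; targets are wild-type coordinates and
    must be mutually disjoint (applied right-to-left, so the result is
    independent of swap order)."""
    for iv, _, _ in swaps:
        if iv.end > len(wild_type):
            raise ValueError(
                f"swap target {iv.start}-{iv.end} out of bounds for "
                f"{wild_type.identifier!r}"
            )
    ordered = sorted(swaps, key=lambda s: s[0].start)
    for (a, _, _), (b, _, _) in zip(ordered, ordered[1:]):
        if a.end > b.start:
            raise ValueError(
                f"overlapping swap targets {a.start}-{a.end} and "
                f"{b.start}-{b.end}"
            )
    residues = wild_type.residues
    for iv, repl, _ in reversed(ordered):
        repl_seq = NucSequence("repl", repl).residues
        residues = residues[: iv.start] + repl_seq + residues[iv.end :]
    return MutantConstruct(
        name,
        NucSequence(name, residues),
        tuple((iv, NucSequence("r", repl).residues, donor)
              for iv, repl, donor in ordered),
    )


def primer_arms(
    construct: MutantConstruct, arm_length: int = 25
) -> list[tuple[str, str, str]]:
    """Suggested overlap-extension primer arms for each swap: the replaced
    region plus arm_length bp of flank on each side, forward and reverse
    complement. No thermodynamic optimization."""
    from .sequence_io import reverse_complement

    arms = []
    residues = construct.sequence.residues
    shift = 0
    for iv, repl, donor in construct.swaps:
        new_start = iv.start + shift
        new_end = new_start + len(repl)
        lo = max(0, new_start - arm_length)
        hi = min(len(residues), new_end + arm_length)
        fwd = residues[lo:hi]
        arms.append((donor, fwd, reverse_complement(fwd)))
        shift += len(repl) - len(iv)
    return arms
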