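"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by literal enumeration, staying
independent of the library code paths it checks (only shared vocabulary
like the IUPAC base sets is reused, since that is a definition, not an
algorithm).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def mismatch_positions(window: str, half_site: str) -> set[int]:
    """1-based consensus positions violated by the window (N never matches)."""
    return {
        i + 1
        for i, (b, sym) in enumerate(zip(window, half_site))
        if b == "N" or b not in IUPAC[sym]
    }


def enumerate_half_sites(seq: str, half_site: str, max_mm: int):
    """Literal enumeration of every (offset, strand) decamer window.

    Returns tuples (offset, strand, mismatch_count, frozenset positions),
    with the single-report rule for windows matching identically (reflected
    mismatch set) on both strands.
    """
    k = len(half_site)
    out = []
    for off in range(len(seq) - k + 1):
        window = seq[off : off + k]
        plus = mismatch_positions(window, half_site)
        minus = mismatch_positions(revcomp(window), half_site)
        plus_ok = len(plus) <= max_mm
        minus_ok = len(minus) <= max_mm
        if plus_ok:
            out.append((off, "+", len(plus), frozenset(plus)))
        if minus_ok:
            reflected = frozenset(k + 1 - p for p in minus)
            if not (plus_ok and reflected == frozenset(plus)):
                out.append((off, "-", len(minus), frozenset(minus)))
    return out


def enumerate_elements(
    seq: str,
    half_site: str = "RRRCWWGYYY",
    spacer_min: int = 0,
    spacer_max: int = 13,
    max_mm_half: int = 2,
    max_mm_total: int = 3,
):
    """Literal enumeration of every (offset1, strand1, offset2, strand2,
    spacer) full-element combination. Returns a set of keys
    (off1, strand1, off2, strand2, spacer, total)."""
    k = len(half_site)
    halves = enumerate_half_sites(seq, half_site, max_mm_half)
    out = set()
    for off1, s1, mm1, _ in halves:
        for off2, s2, mm2, _ in halves:
            spacer = off2 - (off1 + k)
            if not (spacer_min <= spacer <= spacer_max):
                continue
            if mm1 + mm2 > max_mm_total:
                continue
            out.add((off1, s1, off2, s2, spacer, mm1 + mm2))
    return out


def brute_force_alignment_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Optimal global alignment score by exhaustive recursion (tiny inputs)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a):
            return (len(b) - j) * gap
        if j == len(b):
            return (len(a) - i) * gap
        diag = rec(i + 1, j + 1) + (match if a[i] == b[j] else mismatch)
        return max(diag, rec(i + 1, j) + gap, rec(i, j + 1) + gap)

    return rec(0, 0)


def naive_upgma_heights(dist: np.ndarray, names: list[str]) -> list[float]:
    """Average-linkage merge heights by direct recomputation from leaf
    distances (O(n^3)); returns the sorted list of merge distances.

    Distance ties are broken by the lexicographically smallest pair of
    cluster names (a cluster is named by its smallest member), the declared
    tie-break of the clustering under test."""
    clusters: dict[str, list[int]] = {nm: [i] for i, nm in enumerate(names)}
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = float(
                    np.mean(
                        [dist[x, y] for x in clusters[a] for y in clusters[b]]
                    )
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[min(a, b)] = merged
    return sorted(heights)


def per_base_signal(track_intervals, window_chrom, window_start, window_end):
    """Expand a coverage track to a per-base vector over the window and
    recompute (max, mean) directly; uncovered bases are depth 0."""
    vec = np.zeros(window_end - window_start)
    for iv, depth in track_intervals:
        if iv.chrom != window_chrom:
            continue
        lo = max(iv.start, window_start)
        hi = min(iv.end, window_end)
        if lo < hi:
            vec[lo - window_start : hi - window_start] = depth
    return float(vec.max(initial=0.0)), float(vec.mean()) if len(vec) else 0.0


def quadratic_overlaps(element_intervals, peaks):
    """All-pairs half-open overlap between element intervals and peaks."""
    out = []
    for ei, el in enumerate(element_intervals):
        hits = [
            pi
            for pi, p in enumerate(peaks)
            if p.chrom == el.chrom and el.start < p.end and p.start < el.end
        ]
        out.append((ei, tuple(hits)))
    return out


def perfect_site_survival_probability(
    sub_rate: float, max_mm_half: int = 2, max_mm_total: int = 3
) -> float:
    """Exact survival probability of a planted perfect element under i.i.d.
    substitution, by enumeration over the 20 informative consensus positions.

    Per half-site RRRCWWGYYY: 8 two-base symbols (a substitution keeps the
    match with probability 1/3) and 2 single-base symbols (any substitution
    breaks the match). Survival = P(mm in each half <= max_mm_half and
    total <= max_mm_total).
    """
    p_two = sub_rate * 2 / 3  # two-base symbol becomes a mismatch
    p_one = sub_rate  # single-base symbol becomes a mismatch

    # distribution of mismatch count in one half-site
    half = np.zeros(11)
    half[0] = 1.0
    for _ in range(8):
        nxt = np.zeros(11)
        nxt[1:] += half[:-1] * p_two
        nxt += half * (1 - p_two)
        half = nxt
    for _ in range(2):
        nxt = np.zeros(11)
        nxt[1:] += half[:-1] * p_one
        nxt += half * (1 - p_one)
        half = nxt

    total = 0.0
    for m1 in range(max_mm_half + 1):
        for m2 in range(max_mm_half + 1):
            if m1 + m2 <= max_mm_total:
                total += half[m1] * half[m2]
    return float(total)
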