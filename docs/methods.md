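# Methods

## The response-element model

A canonical p53 response element is modelled as two copies of the
degenerate decamer half-site `RRRCWWGYYY` separated by a spacer of
`spacer_min`–`spacer_max` bp (defaults 0 and 13). Matching is literal
set-membership per position against the IUPAC base sets (R={A,G}, Y={C,T},
W={A,T}); there is no position-weight-matrix scoring, no background model,
and no p-value calibration — by design, since the analysis this package
supports is a direct sequence comparison against the consensus.

Mismatch tolerance is a ceiling, not a requirement: a window may violate at
most `max_mm_per_half` consensus positions per half-site (default 2) and
the pair at most `max_mm_total` in total (default 3). These defaults are a
package design choice: they are permissive enough to call weak but real
sites annotated with a few highlighted mismatches, while a random decamer
matches the half-site with probability small enough that full-element calls
on 1 kb background are rare. Both budgets, the spacer range and the
half-site string are configurable on `ConsensusPattern`.

**N policy.** `N` fails every consensus symbol, so sites are never called
on ambiguous or (optionally) soft-masked sequence. `read_fasta(...,
exclude_softmasked=True)` converts lower-case bases to `N` for exactly this
purpose; by default soft-masked sequence is scanned like any other.

**Strands and deduplication.** `RRRCWWGYYY` is its own reverse complement,
so every window has the same mismatch count in both orientations and a
reflected mismatch-position set. A window whose two orientations agree in
this way is reported once, on the plus strand; for user-supplied
non-palindromic half-sites the two orientations are reported separately.
Half-site pairing ignores strand (for the palindromic consensus the
distinction is empty), always takes half1 as the upstream decamer in
plus-strand coordinates, and reports elements in plus-strand BED
coordinates.

**Overlaps and ranking.** All alternative pairings are reported by default
(no exclusion rule is part of the model). With `non_overlapping=True` a
greedy pass ranked by (total mismatches, spacer length, leftmost start)
keeps a best-first non-overlapping subset; the ranking makes the output
deterministic.

## Cross-species projection

Promoter windows are assumed pre-trimmed to comparable regions around the
transcription start site; the window choice is the caller's (the analysis
that motivated the package never fixed one, so none is inferred). Whole
windows are aligned with a hand-rolled Needleman–Wunsch (match +1,
mismatch −1, linear gap −2) whose traceback breaks ties deterministically:
diagonal, then up (gap in query), then left. The explicit implementation
exists because the tie-break is part of the contract — library aligners
return some optimal alignment, not a reproducible one; they are used as
score oracles in the tests instead.

A reference site is projected by walking alignment columns; a projection
that falls entirely in a query gap is flagged deleted. The projected window
is widened by `slack` bp on each side (default 5) before rescanning, to
absorb small indels that shift the site without destroying it. Presence
means the rescan finds a full element within the total budget; the
mismatch count of the best such element is reported as `mm_to_consensus`.
`mm_to_reference` counts substitution columns only between the aligned site
regions; indel columns are counted separately so the substitution number
stays comparable to per-base mismatch highlighting.

## Species classification

With sites BS1 and BS2 as two binary characters, each species row maps to
one of four classes (both / BS1_only / BS2_only / none). The dendrogram
uses simple-matching distance (fraction of differing cells) and UPGMA with
lexicographic tie-breaking (clusters named by their smallest member; the
lexicographically smallest pair wins among equal distances), so output is
independent of input order. Node height is half the average pairwise
distance, giving an ultrametric tree. Two binary characters cannot resolve
a phylogeny; the tree is a classification display, nothing more.

## Coverage and occupancy

Coverage arrives as bedGraph plus a declared total mapped-read count; the
module never touches reads or calls peaks. Normalization multiplies every
depth by 10⁷/total_reads — exactly linear, the identity at 10 M reads, and
guarded against double application. Window signal is (max, length-weighted
mean) with uncovered bases counted as depth 0. Occupancy is the ratio of
target-window maximum to control-window maximum; `enriched` means the
ratio is at least `enrichment_ratio` (default 0.1) of the control maximum.
The 0.1 default is declared, not derived — no numeric cutoff is recoverable
from visual peak comparisons — and a zero-signal control yields an
undefined ratio with a warning rather than a verdict.

## Synthetic data: what it emulates, what it does not

The generator states a world in which every downstream verdict is known:

- **Background**: i.i.d. bases at a given GC fraction (default 0.5, default
  promoter length 1200 bp — a typical proximal-promoter window).
- **Planted sites**: exact per-half mismatch counts (violating positions
  and bases drawn uniformly) and stated spacer lengths, written at
  non-overlapping positions; the truth table records exact intervals.
- **Species**: i.i.d. per-base substitutions (uniform over the three
  alternatives) and indel initiation (insertion or deletion equally likely,
  length 1–3 uniform) at stated per-base rates; listed sites can be ablated
  by overwriting with uniform random sequence. Divergence-rate defaults in
  the shipped configurations are 1–3% — the scale of closely related
  mammalian promoter divergence — and the projection slack must absorb the
  default indel rates. Presence in the derived species is recomputed by
  direct rescanning at the mapped locus, so the truth table stays honest
  even when a substitution happens to create or rescue a site. Note that
  ablation writes *random* sequence: with the default budgets a short
  random window occasionally contains a legal weak element, so an ablated
  site is absent with high probability, not certainty — the truth table,
  not the ablation list, is ground truth.
- **Coverage**: Poisson-jittered background (default depth 2) with
  triangular peaks; shipped configurations use peak heights of 100–150,
  i.e. 50–75× background, matching the separation of a strong promoter
  peak from noise. Marginal peaks near the enrichment threshold are
  deliberately not part of the stated world.

The generator is not an evolutionary model (no rate heterogeneity, no
selection, no realistic indel-length distribution) and not a read
simulator. A green round-trip test therefore establishes that the plumbing
— coordinates, budgets, projections, verdicts — is exact, not that the
pipeline would behave identically on real genomes with repeats,
composition bias, and alignment ambiguity.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; tables print 1-based
  inclusive starts. Overlap is strictly half-open: a shared boundary is not
  an overlap.
- Empty sequences scan to empty results; alignment of an empty sequence is
  an error (there is no meaningful projection).
- Ultrametricity tolerance in tests is 1e−9; UPGMA tie comparisons use a
  1e−12 guard so float noise cannot reorder merges.
- Multiple swaps are applied right-to-left in wild-type coordinates, making
  the double-swap construct independent of swap order; overlapping targets
  are rejected.
- BED score for an element is 1000 − 100 × total mismatches, clamped to
  [0, 1000].

## Known limitations

- Projection relies on one global alignment of the whole window; distant
  species with large rearrangements would need anchored or local
  alignment, which is out of scope.
- The scanner is exhaustive and exact but O(length × spacer range) with a
  Python inner loop — fine for promoter windows, not built for whole
  genomes.
- The mutagenesis helper emits primer arms (swapped region ± 25 bp) without
  any melting-temperature or secondary-structure checks; primers are a lab
  artifact, not part of the model.
- The four-way classification is defined only for the site pair (BS1, BS2);
  other site sets raise rather than guessing a mapping.
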