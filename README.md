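# p53re

Tools for asking whether a gene's promoter can respond to the transcription
factor p53 in one species but not another — the situation seen for PIERCE1
(C9orf116), a p53 target in mouse whose human ortholog ignores p53 because
the binding sites themselves, not the protein, differ between species.

The package is aimed at regulatory-genomics analysts who want to:

1. **Scan promoters for p53 response elements.** p53 binds two copies of the
   degenerate decamer half-site `RRRCWWGYYY` (R = purine, Y = pyrimidine,
   W = A/T) separated by a spacer of 0–13 bp:
   `RRRCWWGYYY (N)0–13 RRRCWWGYYY`. The scanner matches half-sites on both
   strands under a per-half mismatch budget (default 2) and pairs them
   across the spacer range under a total budget (default 3).
2. **Project sites across species.** Promoter windows are globally aligned
   (Needleman–Wunsch, match +1 / mismatch −1 / gap −2), reference site
   coordinates are projected through the alignment, and the projected
   window (± 5 bp slack) is rescanned: a site is *present* in a species iff
   a full element within budget survives at the projected locus.
3. **Classify species** by which sites survive (both / BS1 only / BS2 only /
   none) and draw a UPGMA dendrogram on simple-matching distances, exported
   as Newick.
4. **Design site-swap constructs** — replace a segment of one species'
   promoter with another species' element (the in-silico analogue of
   BS1mut/BS2mut reporter mutagenesis) and verify by rescanning.
5. **Quantify ChIP occupancy** from bedGraph coverage: depth is normalized
   to a fixed library size of 10 million mapped reads, and target-promoter
   signal is expressed relative to a positive-control locus such as the
   CDKN1A (p21) promoter.
6. **Generate synthetic ground truth** — promoters with planted elements,
   diverged "species" cohorts with optional site ablation, and coverage
   tracks with planted peaks — so every stage is testable offline.

## Worked example

Scan the packaged BS2 mutagenesis primer (one of the overlap-extension
primers that introduce the mouse binding sites into the human promoter) for
full response elements:

```python
from p53re import NucSequence, scan_response_elements
from p53re.scanner import elements_to_table
from p53re.primers import BS2_FORWARD

elements = scan_response_elements(NucSequence("BS2_fwd_primer", BS2_FORWARD))
print(elements_to_table(elements).to_string(index=False))
```

```
name          chrom  start  end  half1_seq half1_strand  half1_mm half1_mm_pos  spacer  half2_seq half2_strand  half2_mm half2_mm_pos  total_mm
RE_1 BS2_fwd_primer     11   31 AGACTTGCCT            +         0                    1 CAGCTAGCTG            +         2         1,10         2
```

One full element is found: a perfect upstream half-site `AGACTTGCCT`
(positions 11–20, 1-based), a 1 bp spacer, and a downstream half-site
`CAGCTAGCTG` carrying 2 mismatches to the consensus (at half-site positions
1 and 10), for a total of 2 mismatches — within the default budget of 3.

The same machinery drives the cross-species table: scan a reference
promoter, then `conservation_table(ref, sites, species_promoters)` reports,
for every (species, site) pair, the projected sequence, its mismatches to
the consensus and to the reference, and a presence verdict;
`build_presence_matrix` → `categorize` → `cluster_species` turn those
verdicts into the four-way species classification and a Newick dendrogram.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script runs the whole pipeline from scratch on seeded synthetic data:
it generates a mouse-like reference promoter with planted BS1/BS2 elements
and a five-species cohort (rodent-like species diverged neutrally,
human/dog/guinea-pig-like species with both sites ablated), scans and
labels the elements, builds the conservation table, classification, and
dendrogram, swaps both reference sites into the "human" promoter and
rescans the construct, and contrasts a mouse-like coverage configuration
(peaks at target and control) with a human-like one (control peak only)
after 10 M-read normalization. A summary is printed and the results JSON is
written to `--out`.
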