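"""Presence/absence classification of species by binding-site survival, and
a binary-character UPGMA dendrogram with Newick export.

The two characters are the BS1 and BS2 response elements of the reference
promoter; each species' row records whether the site survives at the
projected locus. With two binary characters the dendrogram is a
classification device, not an evolutionary inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .conservation import SiteConservationRecord

CATEGORIES = ("both", "BS1_only", "BS2_only", "none")

# display colors matching the four classes of the presence dendrogram
CATEGORY_COLORS = {
    "both": "red",
    "BS1_only": "yellow",
    "BS2_only": "light blue",
    "none": "deep blue",
}


@dataclass(frozen=True)
class PresenceMatrix:
    """Species x site boolean table."""

    species: tuple[str, ...]
    sites: tuple[str, ...]
    cells: tuple[tuple[bool, ...], ...]  # row per species

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in presence matrix")
        for row in self.cells:
            if len(row) != len(self.sites):
                raise ValueError("ragged presence matrix")

    def row(self, species: str) -> tuple[bool, ...]:
        return self.cells[self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.cells), index=list(self.species), columns=list(self.sites)
        )


@dataclass(frozen=True)
class SpeciesCategory:
    species: str
    category: str


def build_presence_matrix(
    records: Sequence[SiteConservationRecord],
    sites: Sequence[str] = ("BS1", "BS2"),
) -> PresenceMatrix:
    """Assemble records into a matrix; every (species, site) pair must be
    covered exactly once."""
    cells: dict[tuple[str, str], bool] = {}
    species_order: list[str] = []
    for r in records:
        key = (r.species, r.site_label)
        if key in cells:
            raise ValueError(f"duplicate record for {key}")
        cells[key] = r.present
        if r.species not in species_order:
            species_order.append(r.species)
    rows = []
    for sp in species_order:
        row = []
        for site in sites:
            if (sp, site) not in cells:
                raise ValueError(f"missing record for ({sp!r}, {site!r})")
            row.append(cells[(sp, site)])
        rows.append(tuple(row))
    extra = set(cells) - {(sp, s) for sp in species_order for s in sites}
    if extra:
        raise ValueError(f"records for unknown sites: {sorted(extra)}")
    return PresenceMatrix(tuple(species_order), tuple(sites), tuple(rows))


def categorize(matrix: PresenceMatrix) -> list[SpeciesCategory]:
    """Map each species row to one of the four presence classes.

    Defined only for the site pair (BS1, BS2): (T,T) -> both,
    (T,F) -> BS1_only, (F,T) -> BS2_only, (F,F) -> none.
    """
    if tuple(matrix.sites) != ("BS1", "BS2"):
        raise ValueError(
            f"categories are defined for sites (BS1, BS2), got {matrix.sites}"
        )
    mapping = {
        (True, True): "both",
        (True, False): "BS1_only",
        (False, True): "BS2_only",
        (False, False): "none",
    }
    return [
        SpeciesCategory(sp, mapping[tuple(row)])
        for sp, row in zip(matrix.species, matrix.cells)
    ]


def categories_to_frame(cats: Sequence[SpeciesCategory]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [c.species for c in cats],
            "category": [c.category for c in cats],
            "color": [CATEGORY_COLORS[c.category] for c in cats],
        }
    )


def simple_matching_distance(
    row_a: Sequence[bool], row_b: Sequence[bool]
) -> float:
    """Fraction of characters on which the two rows differ."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    return sum(a != b for a, b in zip(row_a, row_b)) / len(row_a)


def cluster_species(matrix: PresenceMatrix) -> str:
    """UPGMA on simple-matching distances; returns Newick with branch lengths.

    Agglomeration ties are broken by the lexicographically smallest pair of
    cluster names (each cluster named by its smallest member), so output is
    independent of input species order. Node height is half the average
    pairwise distance between the merged clusters; the tree is ultrametric.
    """
    if len(matrix.species) < 2:
        raise ValueError("need at least 2 species to cluster")
    # active clusters: name -> (members, newick, height)
    clusters: dict[str, tuple[list[str], str, float]] = {
        sp: ([sp], sp, 0.0) for sp in matrix.species
    }
    rows = {sp: matrix.row(sp) for sp in matrix.species}

    def leaf_dist(a: str, b: str) -> float:
        return simple_matching_distance(rows[a], rows[b])

    def cluster_dist(ca: str, cb: str) -> float:
        ma, mb = clusters[ca][0], clusters[cb][0]
        return sum(leaf_dist(a, b) for a in ma for b in mb) / (len(ma) * len(mb))

    while len(clusters) > 1:
        names = sorted(clusters)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = cluster_dist(a, b)
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        assert best is not None
        d, a, b = best
        height = d / 2.0
        (ma, na, ha), (mb, nb, hb) = clusters[a], clusters[b]
        newick = f"({na}:{height - ha:.10g},{nb}:{height - hb:.10g})"
        new_name = min(a, b)
        del clusters[a], clusters[b]
        clusters[new_name] = (ma + mb, newick, height)
    (_, newick, _), = clusters.values()
    return newick + ";"
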