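import numpy as np
import pytest

from oracles import (
    enumerate_elements,
    perfect_site_survival_probability,
)
from p53re import (
    ConsensusPattern,
    GenomicInterval,
    NucSequence,
    diverge_species,
    generate_background,
    generate_cohort,
    normalize_to_10M,
    occupancy_report,
    plant_sites,
    realize_half_site,
    scan_response_elements,
    synth_coverage,
)
from p53re.scanner import match_half_site
from p53re.synth import (
    CohortSpec,
    PlantedSiteSpec,
    SpeciesSpec,
    load_cohort_spec,
)


class TestRealizeHalfSite:
    def test_round_trip_all_counts(self, pattern):
        rng = np.random.default_rng(7)
        for n in range(11):
            for _ in range(100):
                site = realize_half_site(pattern, n, rng)
                assert match_half_site(site, pattern).mismatch_count == n

    def test_out_of_range(self, pattern, rng):
        with pytest.raises(ValueError):
            realize_half_site(pattern, 11, rng)


class TestBackground:
    def test_length_zero(self, rng):
        assert generate_background(0, 0.5, rng).residues == ""

    def test_gc_one(self, rng):
        s = generate_background(500, 1.0, rng).residues
        assert set(s) <= {"G", "C"}

    def test_gc_within_binomial_bound(self, rng):
        # 100 kb draw: sd of GC fraction ~ 0.0016, so 1% is > 6 sigma
        s = generate_background(100_000, 0.4, rng).residues
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.4) < 0.01


class TestPlantSites:
    def test_empty_planted_list(self, rng, pattern):
        bg = generate_background(100, 0.5, rng)
        seq, truth = plant_sites(bg, [], pattern, rng)
        assert seq.residues == bg.residues and truth == []

    def test_truth_invariants(self, rng, pattern):
        bg = generate_background(400, 0.5, rng)
        planted = [
            PlantedSiteSpec(30, 5, 1, 2, "BS1"),
            PlantedSiteSpec(200, 0, 0, 0, "BS2"),
        ]
        seq, truth = plant_sites(bg, planted, pattern, rng)
        for spec, t in zip(planted, truth):
            iv = t.interval
            assert len(iv) == 20 + t.spacer_length
            assert seq.residues[iv.start : iv.end] == t.sequence
            assert t.total_mismatches == spec.mm_half1 + spec.mm_half2

    def test_overlapping_sites_rejected(self, rng, pattern):
        bg = generate_background(200, 0.5, rng)
        with pytest.raises(ValueError, match="overlap"):
            plant_sites(
                bg,
                [PlantedSiteSpec(10, 0, 0, 0, "a"),
                 PlantedSiteSpec(25, 0, 0, 0, "b")],
                pattern, rng,
            )

    def test_scanner_recovers_planted_and_background_matches_oracle(
        self, pattern
    ):
        rng = np.random.default_rng(11)
        bg = generate_background(300, 0.5, rng)
        seq, truth = plant_sites(
            bg, [PlantedSiteSpec(100, 3, 0, 0, "BS1")], pattern, rng
        )
        got = {
            (e.half1.offset, e.half2.offset)
            for e in scan_response_elements(seq, pattern)
        }
        want = {
            (k[0], k[2]) for k in enumerate_elements(seq.residues)
        }
        assert got == want
        assert (100, 113) in got  # the planted pair, exact coordinates


class TestDivergeSpecies:
    def make(self, pattern, seed=3):
        rng = np.random.default_rng(seed)
        bg = generate_background(600, 0.45, rng)
        seq, truth = plant_sites(
            bg,
            [PlantedSiteSpec(100, 2, 0, 0, "BS1"),
             PlantedSiteSpec(400, 7, 0, 0, "BS2")],
            pattern, rng,
        )
        return seq, truth, rng

    def test_zero_rates_identity(self, pattern):
        seq, truth, rng = self.make(pattern)
        sp = SpeciesSpec("twin")
        derived, new_truth = diverge_species(seq, sp, truth, pattern, rng)
        assert derived.residues == seq.residues
        assert all(t.present for t in new_truth)
        assert [t.interval.start for t in new_truth] == [100, 400]

    def test_ablate_all(self, pattern):
        seq, truth, rng = self.make(pattern)
        sp = SpeciesSpec("lost", ablate=("BS1", "BS2"))
        _, new_truth = diverge_species(seq, sp, truth, pattern, rng)
        assert all(not t.present for t in new_truth)

    def test_indels_shift_coordinates_consistently(self, pattern):
        seq, truth, rng = self.make(pattern)
        sp = SpeciesSpec("indel", substitution_rate=0.0, indel_rate=0.02)
        derived, new_truth = diverge_species(seq, sp, truth, pattern, rng)
        for t in new_truth:
            if t.interval is not None:
                assert derived.residues[t.interval.start : t.interval.end] \
                    == t.sequence

    def test_survival_fraction_matches_enumeration(self, pattern):
        """Fraction of perfect planted sites surviving 2% substitution,
        against the exact per-site probability from enumeration over the 20
        informative consensus positions."""
        p_expected = perfect_site_survival_probability(0.02)
        survived = total = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            bg = generate_background(300, 0.5, rng)
            seq, truth = plant_sites(
                bg, [PlantedSiteSpec(120, 4, 0, 0, "BS1")], pattern, rng
            )
            sp = SpeciesSpec("s", substitution_rate=0.02)
            _, new_truth = diverge_species(seq, sp, truth, pattern, rng)
            total += 1
            survived += int(new_truth[0].present)
        p_hat = survived / total
        sd = np.sqrt(p_expected * (1 - p_expected) / total)
        # 4 sigma plus slack for in-window rescue pairings
        assert abs(p_hat - p_expected) < 4 * sd + 0.02


class TestCohort:
    SPEC = CohortSpec(
        promoter_length=800,
        gc_fraction=0.5,
        planted=(
            PlantedSiteSpec(150, 2, 0, 0, "BS1"),
            PlantedSiteSpec(500, 9, 1, 0, "BS2"),
        ),
        species=(
            SpeciesSpec("rat", substitution_rate=0.01),
            SpeciesSpec("human", substitution_rate=0.01,
                        ablate=("BS1", "BS2")),
        ),
        seed=42,
    )

    def test_seed_fixes_every_byte(self):
        a = generate_cohort(self.SPEC)
        b = generate_cohort(self.SPEC)
        assert a.reference.residues == b.reference.residues
        assert [s.residues for s in a.species] == [
            s.residues for s in b.species
        ]
        assert a.species_truth == b.species_truth

    def test_truth_structure(self):
        c = generate_cohort(self.SPEC)
        assert {s.identifier for s in c.species} == {"rat", "human"}
        assert all(not t.present for t in c.species_truth["human"])

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "cohort.yaml"
        cfg.write_text(
            "promoter_length: 800\n"
            "gc_fraction: 0.5\n"
            "seed: 42\n"
            "planted:\n"
            "  - {position: 150, spacer_length: 2, label: BS1}\n"
            "  - {position: 500, spacer_length: 9, mm_half1: 1, label: BS2}\n"
            "species:\n"
            "  - {name: rat, substitution_rate: 0.01}\n"
            "  - {name: human, substitution_rate: 0.01,\n"
            "     ablate: [BS1, BS2]}\n"
        )
        spec = load_cohort_spec(cfg)
        assert spec == self.SPEC


class TestSynthCoverage:
    def test_flat_background(self, rng):
        track, truth = synth_coverage(
            [], background_depth=3.0, total_reads=5_000_000, rng=rng,
            chrom_lengths={"chr1": 500},
        )
        assert truth == []
        depths = [d for _, d in track.intervals]
        assert depths and max(depths) < 20  # Poisson(3) jitter stays low

    def test_peak_only_at_control_round_trip(self, rng, pattern):
        control = GenomicInterval("chr1", 100, 200)
        target = GenomicInterval("chr1", 400, 500)
        track, _ = synth_coverage(
            [(control, 150.0)], background_depth=2.0, total_reads=5_000_000,
            rng=rng, chrom_lengths={"chr1": 600},
        )
        rep = occupancy_report(normalize_to_10M(track), target, control)
        assert not rep.enriched

    def test_peak_at_both_round_trip(self, rng):
        control = GenomicInterval("chr1", 100, 200)
        target = GenomicInterval("chr1", 400, 500)
        track, truth = synth_coverage(
            [(control, 150.0), (target, 100.0)], background_depth=2.0,
            total_reads=5_000_000, rng=rng, chrom_lengths={"chr1": 600},
        )
        rep = occupancy_report(normalize_to_10M(track), target, control)
        assert rep.enriched
        assert {iv.start for iv, _ in truth} == {100, 400}

    def test_height_below_background_rejected(self, rng):
        with pytest.raises(ValueError):
            synth_coverage(
                [(GenomicInterval("chr1", 0, 50), 1.0)],
                background_depth=2.0, total_reads=1000, rng=rng,
            )
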