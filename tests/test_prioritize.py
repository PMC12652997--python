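"""Recessive-variant prioritization cascade and interval filtering."""

import numpy as np
import pytest

import ffpebench as fb
from ffpebench.prioritize import (
    TIERS,
    CohortSpec,
    IntervalSet,
    filter_autosomes,
    filter_interval,
    filter_protein_changing,
    prioritize,
    private_hom_alt,
    shared_private,
)

from conftest import make_callset


def k(pos, contig="chr1", ref="A", alt="G"):
    return fb.AlleleKey(contig, pos, ref, alt)


def cohort_from(control_entries, case_samples=("case1",)):
    controls = make_callset([f"c{i}" for i in range(len(control_entries[0][4]))]
                            if control_entries else ["c0"],
                            control_entries, provenance="controls")
    return CohortSpec(tuple(case_samples), controls)


class TestPrivateHomAlt:
    def make_case(self, gt="1/1"):
        return make_callset(["case1"], [("chr1", 10, "A", "G", [gt])], "cases")

    def test_retained_when_all_controls_hom_ref(self):
        cohort = cohort_from([("chr1", 10, "A", "G", ["0/0", "0/0"])])
        assert private_hom_alt(self.make_case(), "case1", cohort) == {k(10)}

    def test_excluded_by_single_het_control(self):
        cohort = cohort_from([("chr1", 10, "A", "G", ["0/0", "0/1"])])
        assert private_hom_alt(self.make_case(), "case1", cohort) == set()

    def test_missing_control_genotypes_allowed(self):
        cohort = cohort_from([("chr1", 10, "A", "G", ["0/0", "./."])])
        assert private_hom_alt(self.make_case(), "case1", cohort) == {k(10)}

    def test_key_absent_from_control_vcf_is_missing(self):
        cohort = cohort_from([("chr2", 99, "C", "T", ["0/0"])])
        assert private_hom_alt(self.make_case(), "case1", cohort) == {k(10)}

    def test_het_case_not_a_candidate(self):
        cohort = cohort_from([("chr1", 10, "A", "G", ["0/0"])])
        assert private_hom_alt(self.make_case("0/1"), "case1", cohort) == set()

    def test_case_control_overlap_rejected(self):
        controls = make_callset(["case1"], [("chr1", 1, "A", "G", ["0/0"])])
        with pytest.raises(ValueError):
            CohortSpec(("case1",), controls)


class TestSharedPrivate:
    def test_identical_sets(self):
        s = {k(1), k(2)}
        assert shared_private([s, set(s)]) == s

    def test_disjoint_sets_empty(self):
        assert shared_private([{k(1)}, {k(2)}]) == set()

    def test_three_way_hand_enumeration(self):
        a = {k(1), k(2), k(3), k(4)}
        b = {k(2), k(3), k(5)}
        c = {k(3), k(4), k(2), k(6)}
        assert shared_private([a, b, c]) == {k(2), k(3)}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            shared_private([])


class TestAnnotationFilters:
    def test_protein_changing_keeps_moderate_and_high(self):
        cs = make_callset(["s"], [
            ("chr1", 1, "A", "G", ["1/1"], {"impact": fb.Impact.HIGH}),
            ("chr1", 2, "A", "G", ["1/1"], {"impact": fb.Impact.MODERATE}),
            ("chr1", 3, "A", "G", ["1/1"], {"impact": fb.Impact.LOW}),
            ("chr1", 4, "A", "G", ["1/1"], {"impact": None}),
        ])
        keys = {r.key for r in cs}
        assert filter_protein_changing(keys, cs) == {k(1), k(2)}

    def test_autosome_filter(self):
        keys = {k(1, "chr1"), k(2, "chrX"), k(3, "chrUn_scaffold1")}
        assert filter_autosomes(keys, ["chr1", "chr2"]) == {k(1, "chr1")}

    def test_empty_autosome_list_rejected(self):
        with pytest.raises(ValueError):
            filter_autosomes({k(1)}, [])


class TestIntervalFilter:
    def test_boundaries_inclusive(self):
        iv = IntervalSet([("chr1", 100, 200)])
        assert filter_interval({k(100), k(200)}, iv) == {k(100), k(200)}
        assert filter_interval({k(99), k(201)}, iv) == set()

    def test_overlapping_intervals_merge(self):
        iv = IntervalSet([("chr1", 1, 10), ("chr1", 5, 20), ("chr1", 21, 30)])
        assert iv.intervals == [("chr1", 1, 30)]
        assert iv.total_span == 30

    def test_span_across_contigs(self):
        iv = IntervalSet([("chr1", 1, 10), ("chr2", 1, 5)])
        assert iv.total_span == 15

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        """filter_interval equals a plain point-in-interval scan."""
        rng = np.random.default_rng(seed)
        contigs = ["chr1", "chr2", "chr3"]
        spans = [(contigs[rng.integers(3)], int(s := rng.integers(1, 500)),
                  int(s + rng.integers(0, 100))) for _ in range(8)]
        iv = IntervalSet(spans)
        keys = {k(int(rng.integers(1, 600)), contigs[rng.integers(3)]) for _ in range(50)}
        expected = {key for key in keys
                    if any(c == key.contig and s <= key.pos <= e for c, s, e in spans)}
        assert filter_interval(keys, iv) == expected


class TestPrioritizeCascade:
    def planted_setup(self, seed=0, n_controls=50):
        genome = fb.GenomeModel.toy()
        interval = [("chr3", 2_000_000, 4_000_000)]
        case_cs, control_cs, planted = fb.generate_cohort(
            genome, n_controls=n_controls, seed=seed, n_background=400,
            interval=interval)
        cohort = CohortSpec(tuple(case_cs.samples), control_cs)
        iv = IntervalSet(interval)
        return case_cs, cohort, iv, genome.autosomes, planted

    def test_planted_variant_survives_all_tiers(self):
        case_cs, cohort, iv, autosomes, planted = self.planted_setup(seed=42)
        report = prioritize(case_cs, cohort, iv, autosomes)
        assert planted in report.final_shared_keys

    def test_zero_controls_private_equals_hom_alt_tier(self):
        case_cs, _, iv, autosomes, _ = self.planted_setup(seed=1)
        empty_controls = fb.CallSet([], provenance="none")
        cohort = CohortSpec(tuple(case_cs.samples), empty_controls)
        report = prioritize(case_cs, cohort, iv, autosomes)
        for case in report.case_samples:
            assert report.per_case_counts[case]["private"] == \
                report.per_case_counts[case]["total_hom_alt"]

    def test_single_carrier_control_kills_planted(self):
        case_cs, cohort, iv, autosomes, planted = self.planted_setup(seed=2)
        # make one control a het carrier of the planted allele
        rec = cohort.control_callset.records[planted]
        gts = list(rec.genotypes)
        gts[0] = fb.genotype(0, 1)
        rec.genotypes = tuple(gts)
        report = prioritize(case_cs, cohort, iv, autosomes)
        assert planted not in report.shared_keys["private"]
        assert planted not in report.final_shared_keys

    @pytest.mark.parametrize("seed", range(4))
    def test_tier_monotonicity_and_shared_bound(self, seed):
        case_cs, cohort, iv, autosomes, _ = self.planted_setup(seed=10 + seed)
        report = prioritize(case_cs, cohort, iv, autosomes)
        for case in report.case_samples:
            counts = [report.per_case_counts[case][t] for t in TIERS]
            assert counts == sorted(counts, reverse=True)
        for tier in TIERS:
            assert report.shared_counts[tier] <= min(
                report.per_case_counts[c][tier] for c in report.case_samples)

    def test_adding_controls_never_grows_private_tier(self):
        """Monotonicity in cohort size: more controls can only shrink tiers."""
        genome = fb.GenomeModel.toy()
        case_cs, control_cs, _ = fb.generate_cohort(
            genome, n_controls=60, seed=3, n_background=400)
        iv = IntervalSet([("chr1", 1, 10_000_000)])
        prev = None
        for n in (5, 20, 60):
            sub = control_cs.with_samples(control_cs.samples[:n])
            cohort = CohortSpec(tuple(case_cs.samples), sub)
            report = prioritize(case_cs, cohort, iv, genome.autosomes)
            counts = {c: report.per_case_counts[c]["private"] for c in report.case_samples}
            if prev is not None:
                assert all(counts[c] <= prev[c] for c in counts)
            prev = counts

    def test_report_frame_shape(self):
        case_cs, cohort, iv, autosomes, _ = self.planted_setup(seed=4)
        df = prioritize(case_cs, cohort, iv, autosomes).to_frame()
        assert list(df["tier"]) == list(TIERS)
        assert set(df.columns) == {"tier", *cohort.case_samples, "shared"}
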