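"""Synthetic-data generator: determinism, calibration, parameter recovery."""

import math

import numpy as np
import pytest
from scipy import integrate, stats as sps

import ffpebench as fb
from ffpebench.io import write_vcf
from ffpebench.simulate import beta_for_het_hom
from ffpebench.stats import DEAMINATION_CLASSES, SPECTRUM_CLASSES


def ts_tv_se(ratio, n):
    """Delta-method SE of a Ts/Tv estimate from n binomial class draws."""
    p = ratio / (1 + ratio)
    return math.sqrt(p * (1 - p) / n) / (1 - p) ** 2


class TestGenerateTruth:
    def test_empty_params_give_empty_callset(self, genome):
        cs = fb.generate_truth(genome, fb.TruthParams(n_snv=0, n_indel=0, seed=1))
        assert len(cs) == 0

    def test_deterministic_bytes(self, tmp_path, genome):
        params = fb.TruthParams(n_snv=300, n_indel=100, seed=99)
        for name in ("a", "b"):
            write_vcf(fb.generate_truth(genome, params), tmp_path / f"{name}.vcf.gz",
                      genome=genome)
        assert (tmp_path / "a.vcf.gz").read_bytes() == (tmp_path / "b.vcf.gz").read_bytes()

    def test_too_many_variants_rejected(self):
        tiny = fb.GenomeModel((fb.Contig("c", 10),))
        with pytest.raises(ValueError):
            fb.generate_truth(tiny, fb.TruthParams(n_snv=100, n_indel=0, seed=1))

    def test_ts_tv_within_three_se(self, medium_truth):
        s = fb.summarize_callset(medium_truth)
        assert abs(s.ts_tv - 2.1) <= 3 * ts_tv_se(2.1, s.n_snv)

    def test_del_ins_within_three_se(self, medium_truth):
        s = fb.summarize_callset(medium_truth)
        # same delta-method bound with the deletion fraction
        assert abs(s.del_ins - 1.04) <= 3 * ts_tv_se(1.04, s.n_indel)

    def test_het_hom_near_target(self, medium_truth):
        # bootstrap-free sanity bound: ratio of ~25k counts, generous 3-SE-ish window
        s = fb.summarize_callset(medium_truth)
        assert s.het_hom_mean == pytest.approx(1.35, rel=0.05)

    def test_every_record_segregates(self, small_truth):
        from ffpebench.variants import GenotypeClass, genotype_class

        for rec in small_truth:
            assert any(genotype_class(g) in (GenotypeClass.HET, GenotypeClass.HOM_ALT)
                       for g in rec.genotypes)

    def test_multiallelic_fraction_realized(self, genome):
        cs = fb.generate_truth(genome, fb.TruthParams(
            n_snv=2_000, n_indel=0, multiallelic_fraction=0.05, seed=21))
        assert fb.multiallelic_site_count(cs) == round(0.05 * 2_000)

    def test_keys_are_canonical(self, small_truth):
        from ffpebench.variants import validate_key

        for key in small_truth.keys():
            validate_key(key)


class TestBetaCalibration:
    def test_closed_form_matches_quadrature(self):
        """2b/(a+1) equals the quadrature value of E[2f(1-f)]/E[f^2]."""
        for target in (0.5, 1.35, 2.0):
            a, b = beta_for_het_hom(target)
            pdf = sps.beta(a, b).pdf
            num = integrate.quad(lambda f: 2 * f * (1 - f) * pdf(f), 0, 1)[0]
            den = integrate.quad(lambda f: f * f * pdf(f), 0, 1)[0]
            assert num / den == pytest.approx(target, rel=1e-6)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            beta_for_het_hom(0.0)


class TestSimulateCaller:
    def test_perfect_caller_reproduces_truth(self, small_truth, genome):
        q = fb.simulate_caller(small_truth, fb.CallerProfile(
            fn_rate=0, fp_rate=0, genotype_error_rate=0, seed=1), genome)
        for s in small_truth.samples:
            c = fb.compare_sample(small_truth, q, s)
            assert c.fp == c.fn == 0 and c.concordant == c.tp

    def test_recall_recovery(self, medium_truth, genome):
        q = fb.simulate_caller(medium_truth, fb.CallerProfile(
            fn_rate=0.05, fp_rate=0, genotype_error_rate=0, seed=2), genome)
        c = fb.compare_sample(medium_truth, q, "sample1")
        m = fb.performance_metrics(c)
        se = math.sqrt(0.05 * 0.95 / c.truth_total)
        assert abs(m.recall - 0.95) <= 3 * se

    def test_genotype_concordance_recovery(self, medium_truth, genome):
        e = 0.02
        q = fb.simulate_caller(medium_truth, fb.CallerProfile(
            fn_rate=0, fp_rate=0, genotype_error_rate=e, seed=3), genome)
        c = fb.compare_sample(medium_truth, q, "sample2")
        m = fb.performance_metrics(c)
        se = math.sqrt(e * (1 - e) / c.tp)
        assert abs(m.genotype_concordance - (1 - e)) <= 3 * se

    def test_fp_count_and_precision(self, medium_truth, genome):
        fp_rate = 0.04
        q = fb.simulate_caller(medium_truth, fb.CallerProfile(
            fn_rate=0, fp_rate=fp_rate, genotype_error_rate=0, seed=4), genome)
        n_fp = round(fp_rate * len(medium_truth))
        assert len(q) == len(medium_truth) + n_fp
        c = fb.compare_sample(medium_truth, q, "sample1")
        assert c.fp == n_fp  # every FP is genotyped non-ref in every sample
        assert fb.performance_metrics(c).precision == pytest.approx(
            c.tp / (c.tp + n_fp))

    def test_fp_positions_never_collide_with_truth(self, small_truth, genome):
        q = fb.simulate_caller(small_truth, fb.CallerProfile(
            fn_rate=0, fp_rate=0.2, genotype_error_rate=0, seed=5), genome)
        fp_keys = set(q.keys()) - set(small_truth.keys())
        truth_pos = {(key.contig, key.pos) for key in small_truth.keys()}
        assert all((key.contig, key.pos) not in truth_pos for key in fp_keys)


class TestInjectFfpe:
    def test_zero_rate_leaves_query_unchanged(self, small_truth, genome):
        out = fb.inject_ffpe_artifacts(small_truth, fb.FFPEArtifactProfile(
            deamination_multiplier=5, extra_fp_rate=0, seed=1), genome)
        assert set(out.keys()) == set(small_truth.keys())

    def test_unit_multiplier_uniform_inflation(self, medium_truth, genome):
        out = fb.inject_ffpe_artifacts(medium_truth, fb.FFPEArtifactProfile(
            deamination_multiplier=1.0, extra_fp_rate=0.2, seed=2), genome)
        a = fb.substitution_spectrum(medium_truth, "sample1", genome.genome_size)
        b = fb.substitution_spectrum(out, "sample1", genome.genome_size)
        contrast = fb.spectrum_contrast(a, b)
        m_hat = fb.deamination_multiplier_estimate(contrast)
        assert m_hat == pytest.approx(1.0, abs=0.3)

    def test_multiplier_recovery_within_three_poisson_se(self, medium_truth, genome):
        m_true, e = 5.0, 0.2
        out = fb.inject_ffpe_artifacts(medium_truth, fb.FFPEArtifactProfile(
            deamination_multiplier=m_true, extra_fp_rate=e, seed=3), genome)
        a = fb.substitution_spectrum(medium_truth, "sample1", genome.genome_size)
        b = fb.substitution_spectrum(out, "sample1", genome.genome_size)
        contrast = fb.spectrum_contrast(a, b)
        m_hat = fb.deamination_multiplier_estimate(contrast)
        # Poisson SE of the excess-ratio estimator, propagated per class group
        deam_n = [a.count_of(c) for c in DEAMINATION_CLASSES]
        other_n = [a.count_of(c) for c in SPECTRUM_CLASSES if c not in DEAMINATION_CLASSES]
        var_deam = sum(m_true * e * n for n in deam_n) / sum(deam_n) ** 2
        var_other = sum(e * n for n in other_n) / sum(other_n) ** 2
        se = math.sqrt(var_deam / e**2 + (m_true / e) ** 2 * var_other)
        assert abs(m_hat - m_true) <= 3 * se

    def test_extras_are_snvs_at_fresh_positions(self, small_truth, genome):
        out = fb.inject_ffpe_artifacts(small_truth, fb.FFPEArtifactProfile(
            deamination_multiplier=3, extra_fp_rate=0.3, seed=4), genome)
        new = set(out.keys()) - set(small_truth.keys())
        assert new and all(len(k.ref) == len(k.alt) == 1 for k in new)


class TestGenerateCohort:
    def test_zero_controls(self, genome):
        cases, controls, planted = fb.generate_cohort(genome, n_controls=0, seed=1,
                                                      n_background=100)
        assert len(controls.samples) == 0 and len(controls) == 0
        assert planted in cases

    def test_deterministic(self, genome):
        a = fb.generate_cohort(genome, n_controls=10, seed=7, n_background=100)
        b = fb.generate_cohort(genome, n_controls=10, seed=7, n_background=100)
        assert a[2] == b[2]
        assert set(a[0].keys()) == set(b[0].keys())
        assert all(a[1].records[key].genotypes == b[1].records[key].genotypes
                   for key in a[1].keys())

    def test_planted_genotype_contract(self, genome):
        cases, controls, planted = fb.generate_cohort(genome, n_controls=40, seed=9,
                                                      n_background=200)
        assert all(g.allele_indices == (1, 1) for g in cases.records[planted].genotypes)
        for g in controls.records[planted].genotypes:
            assert g.allele_indices in ((0, 0), (None, None))
        assert cases.records[planted].impact is fb.Impact.HIGH

    def test_negative_controls_rejected(self, genome):
        with pytest.raises(ValueError):
            fb.generate_cohort(genome, n_controls=-1, seed=1)

    def test_planted_inside_requested_interval(self, genome):
        interval = [("chr2", 1_000_000, 1_500_000)]
        _, _, planted = fb.generate_cohort(genome, n_controls=5, seed=11,
                                           n_background=50, interval=interval)
        assert planted.contig == "chr2"
        assert 1_000_000 <= planted.pos <= 1_500_000


class TestRoundTripThroughVcf:
    def test_generated_callsets_survive_vcf_cycle(self, tmp_path, genome, small_truth):
        """Generator output -> VCF -> read_vcf loses nothing the analyses use."""
        from ffpebench.io import read_vcf

        path = tmp_path / "gen.vcf.gz"
        write_vcf(small_truth, path, genome=genome)
        back = read_vcf(path)
        s1, s2 = fb.summarize_callset(small_truth), fb.summarize_callset(back)
        assert (s1.n_snv, s1.n_indel, s1.ts, s1.tv) == (s2.n_snv, s2.n_indel, s2.ts, s2.tv)
        assert s1.het_hom_per_sample == s2.het_hom_per_sample
        assert s1.n_multiallelic_sites == s2.n_multiallelic_sites
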