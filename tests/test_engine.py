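"""Read-engine behavior: sampling, carriage rules, errors, determinism."""

import math

import numpy as np
import pysam
import pytest
from scipy.stats import binom

from conftest import flip_base
from tumorsim.engine import FragmentSampler, generate_sample, insert_pmf
from tumorsim.fixtures import FixtureSpec, make_models_direct, make_reference, make_targets
from tumorsim.models import PositionErrorModel, QualityModel, ReadDepthModel
from tumorsim.profiles import (
    NORMAL,
    GenomeProfile,
    PhasedSNP,
    SamplePlan,
    SomaticCNA,
    SomaticPM,
    resolve_segments,
)


def ci99(n, p):
    """99% binomial envelope for an observed proportion."""
    lo, hi = binom.interval(0.99, n, p)
    return lo / n, hi / n


def read_fastq(path):
    recs = []
    with open(path) as fh:
        while True:
            name = fh.readline().strip()
            if not name:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            recs.append((name[1:], seq, qual))
    return recs


def parse_name(name):
    sample, serial, chrom, start, insert, strand = name.split("/")[0].split(":")
    return chrom, int(start), int(insert), strand


@pytest.fixture(scope="module")
def engine_panel(tmp_path_factory):
    d = tmp_path_factory.mktemp("engine")
    spec = FixtureSpec(
        n_chromosomes=1, chromosome_length=20_000, n_targets=4,
        target_length=500, insert_mean=300.0, insert_sd=20.0,
        read_length=100, constant_quality=93, seed=5,
    )
    ref = make_reference(spec, str(d / "ref.fa"))
    targets = make_targets(spec)
    models = make_models_direct(spec, targets)
    return spec, ref, targets, models, d


def _snp(fasta_path, chrom, pos, phase):
    with pysam.FastaFile(fasta_path) as fa:
        ref = fa.fetch(chrom, pos, pos + 1).upper()
    return PhasedSNP(chrom, pos, ref, flip_base(ref), phase)


def _pm(fasta_path, chrom, pos, allele, mult, clone, clonality):
    with pysam.FastaFile(fasta_path) as fa:
        ref = fa.fetch(chrom, pos, pos + 1).upper()
    return SomaticPM(chrom, pos, ref, flip_base(ref), allele, mult, clone, clonality)


class TestFragmentSampler:
    def test_coverage_factor_doubles_sampling_rate(self, engine_panel):
        spec, ref, targets, (rdm, qm, pbe), d = engine_panel
        c0, s0, e0 = targets.regions[0]
        cna = SomaticCNA(c0, s0, e0, 2, 2, "c1", 1.0)  # factor 2 on target 0
        plan = SamplePlan(tumor_content=1.0, n_reads=1, read_length=100, seed=1)
        segs = resolve_segments([cna], targets, 1.0)
        sampler = FragmentSampler(rdm, segs, plan)
        rng = np.random.default_rng(17)
        n = 30_000
        hits = sum(
            1 for _ in range(n) if sampler.sample(rng).start < e0
        )
        p = 2.0 / (2.0 + 3.0)  # one doubled target among four uniform ones
        lo, hi = ci99(n, p)
        assert lo <= hits / n <= hi

    def test_zero_tumor_content_draws_only_normal_cells(self, engine_panel):
        spec, ref, targets, (rdm, qm, pbe), d = engine_panel
        plan = SamplePlan(tumor_content=0.0, n_reads=1, read_length=100, seed=1)
        segs = resolve_segments([], targets, 0.0)
        sampler = FragmentSampler(rdm, segs, plan)
        rng = np.random.default_rng(3)
        draws = [sampler.sample(rng) for _ in range(4000)]
        assert all(dr.population == NORMAL for dr in draws)
        frac_a = sum(dr.haplotype == "A" for dr in draws) / len(draws)
        lo, hi = ci99(len(draws), 0.5)
        assert lo <= frac_a <= hi

    def test_constant_insert_model_yields_constant_draws(self, engine_panel):
        spec, ref, targets, (rdm, qm, pbe), d = engine_panel
        rdm_fixed = ReadDepthModel(
            targets=targets, weights=[w.copy() for w in rdm.weights],
            insert_mean=300.0, insert_sd=0.0, paired=True,
            read_length_observed=100,
        )
        plan = SamplePlan(tumor_content=0.0, n_reads=1, read_length=100, seed=1)
        sampler = FragmentSampler(rdm_fixed, resolve_segments([], targets, 0.0), plan)
        rng = np.random.default_rng(4)
        assert {sampler.sample(rng).insert_length for _ in range(200)} == {300}

    def test_truncated_insert_pmf_sums_to_one(self):
        vals, pmf = insert_pmf(300.0, 20.0, 100)
        assert pmf.sum() == pytest.approx(1.0)
        assert vals.min() >= 100


class TestHaplotypeAndPMCarriage:
    def test_snp_carried_only_by_matching_haplotype(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        c0, s0, e0 = targets.regions[0]
        snp_b = _snp(ref, c0, s0 + 250, "B")
        # LOH of haplotype A: every tumor read is haplotype B at this locus
        cna = SomaticCNA(c0, s0, e0, 0, 1, "c1", 1.0)
        profile = GenomeProfile(snps=[snp_b], cnas=[cna])
        plan = SamplePlan(sample_name="s", tumor_content=1.0,
                         target_mean_coverage=150, read_length=100, seed=9)
        rep = generate_sample(models, profile, plan, ref, str(tmp_path / "s"))
        (row,) = rep["snps"]
        assert row["depth"] > 50
        assert row["observed_baf_alt"] == pytest.approx(1.0)
        # and the opposite phase never shows the alt
        profile_a = GenomeProfile(snps=[_snp(ref, c0, s0 + 250, "A")], cnas=[cna])
        rep = generate_sample(models, profile_a, plan, ref, str(tmp_path / "sa"))
        assert rep["snps"][0]["observed_baf_alt"] == pytest.approx(0.0)

    def test_pm_multiplicity_limits_carriage(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        c0, s0, e0 = targets.regions[1]
        # clonal (2,0): one of two A copies mutated -> VAF exactly 1/2 of reads
        cna = SomaticCNA(c0, s0, e0, 2, 0, "c1", 1.0)
        pm = _pm(ref, c0, s0 + 250, "A", 1, "c1", 1.0)
        profile = GenomeProfile(cnas=[cna], pms=[pm])
        plan = SamplePlan(sample_name="s", tumor_content=1.0,
                         target_mean_coverage=300, read_length=100, seed=21)
        rep = generate_sample(models, profile, plan, ref, str(tmp_path / "s"))
        (row,) = rep["pms"]
        lo, hi = ci99(row["depth"], 0.5)
        assert lo <= row["observed_vaf"] <= hi
        # multiplicity 2 of 2 -> every tumor read carries it
        pm2 = _pm(ref, c0, s0 + 250, "A", 2, "c1", 1.0)
        profile2 = GenomeProfile(cnas=[cna], pms=[pm2])
        rep2 = generate_sample(models, profile2, plan, ref, str(tmp_path / "s2"))
        assert rep2["pms"][0]["observed_vaf"] == pytest.approx(1.0)

    def test_subclonal_pm_without_cna(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        c0, s0, e0 = targets.regions[2]
        pm = _pm(ref, c0, s0 + 250, "B", 1, "solo", 0.5)
        profile = GenomeProfile(pms=[pm])
        plan = SamplePlan(sample_name="s", tumor_content=0.5,
                         target_mean_coverage=400, read_length=100, seed=33)
        rep = generate_sample(models, profile, plan, ref, str(tmp_path / "s"))
        (row,) = rep["pms"]
        lo, hi = ci99(row["depth"], 0.125)  # 0.5 * 0.5 * 1 / 2
        assert lo <= row["observed_vaf"] <= hi

    def test_matched_control_ignores_somatic_events(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        c0, s0, e0 = targets.regions[0]
        cna = SomaticCNA(c0, s0, e0, 3, 0, "c1", 1.0)
        pm = _pm(ref, c0, s0 + 100, "A", 1, "c1", 1.0)
        profile = GenomeProfile(cnas=[cna], pms=[pm])
        plan = SamplePlan(sample_name="ctrl", sample_kind="matched_control",
                         tumor_content=0.9, target_mean_coverage=120,
                         read_length=100, seed=2)
        rep = generate_sample(models, profile, plan, ref, str(tmp_path / "c"))
        assert all(s["coverage_factor"] == pytest.approx(1.0) for s in rep["segments"])
        assert rep["pms"] == []


class TestQualityAndErrors:
    def _mismatch_rate(self, fastq, fasta_path, read_length):
        """Mismatches vs reference for forward-emitted single-end reads."""
        mism = total = 0
        with pysam.FastaFile(fasta_path) as fa:
            for name, seq, qual in read_fastq(fastq):
                chrom, start, insert, strand = parse_name(name)
                assert strand == "+"
                ref = fa.fetch(chrom, start, start + read_length).upper()
                mism += sum(a != b for a, b in zip(seq, ref))
                total += read_length
        return mism, total

    def _gen(self, tmp_path, spec, ref, targets, models, n_reads, seed=7):
        plan = SamplePlan(sample_name="q", tumor_content=0.0, n_reads=n_reads,
                         read_length=100, paired=False, strand_bias=1.0, seed=seed)
        generate_sample(models, GenomeProfile(), plan, ref, str(tmp_path / "q"))
        return str(tmp_path / "q.fastq")

    def test_q10_point_mass_gives_ten_percent_errors(self, tmp_path):
        spec = FixtureSpec(n_chromosomes=1, chromosome_length=20_000, n_targets=2,
                           target_length=500, read_length=100,
                           constant_quality=10, seed=6)
        ref = make_reference(spec, str(tmp_path / "r.fa"))
        targets = make_targets(spec)
        models = make_models_direct(spec, targets)
        fq = self._gen(tmp_path, spec, ref, targets, models, n_reads=2000)
        mism, total = self._mismatch_rate(fq, ref, 100)
        lo, hi = binom.interval(0.999, total, 0.1)
        assert lo / total <= mism / total <= hi / total

    def test_q93_point_mass_passes_sequence_through(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel  # constant Q93
        fq = self._gen(tmp_path, spec, ref, targets, models, n_reads=1000)
        mism, total = self._mismatch_rate(fq, ref, 100)
        assert mism <= 1  # 1e5 bases at error rate 1e-9.3

    def test_degenerate_pbe_site_always_substitutes(self, engine_panel, tmp_path):
        spec, ref, targets, (rdm, qm, _), d = engine_panel
        c0, s0, e0 = targets.regions[0]
        pos = s0 + 250
        with pysam.FastaFile(ref) as fa:
            ref_base = fa.fetch(c0, pos, pos + 1).upper()
        alt = flip_base(ref_base)
        pbe = PositionErrorModel(sites={(c0, pos): (1.0, {alt: 1.0})})
        fq = self._gen(tmp_path, spec, ref, targets, (rdm, qm, pbe), n_reads=3000)
        seen = 0
        for name, seq, qual in read_fastq(fq):
            chrom, start, insert, strand = parse_name(name)
            if chrom == c0 and start <= pos < start + 100:
                assert seq[pos - start] == alt
                seen += 1
        assert seen > 50

    def test_emitted_qualities_follow_cycle_histogram(self, tmp_path):
        spec = FixtureSpec(n_chromosomes=1, chromosome_length=20_000, n_targets=2,
                           target_length=500, read_length=100,
                           quality_profile="ramp", ramp_start=38, ramp_end=20, seed=8)
        ref = make_reference(spec, str(tmp_path / "r.fa"))
        targets = make_targets(spec)
        models = make_models_direct(spec, targets)
        fq = self._gen(tmp_path, spec, ref, targets, models, n_reads=200)
        expected = np.round(np.linspace(38, 20, 100)).astype(int)
        for name, seq, qual in read_fastq(fq)[:50]:
            np.testing.assert_array_equal(
                np.array([ord(c) - 33 for c in qual]), expected
            )


class TestGenerateSample:
    def test_read_budget_is_exact(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        plan = SamplePlan(sample_name="n", tumor_content=0.0, n_reads=1000,
                         read_length=100, paired=False, seed=1)
        generate_sample(models, GenomeProfile(), plan, ref, str(tmp_path / "n"))
        assert len(read_fastq(str(tmp_path / "n.fastq"))) == 1000

    def test_paired_output_has_matching_mates(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        plan = SamplePlan(sample_name="p", tumor_content=0.0, n_reads=500,
                         read_length=100, paired=True, seed=1)
        generate_sample(models, GenomeProfile(), plan, ref, str(tmp_path / "p"))
        r1 = read_fastq(str(tmp_path / "p_R1.fastq"))
        r2 = read_fastq(str(tmp_path / "p_R2.fastq"))
        assert len(r1) == len(r2) == 500
        for (n1, s1, q1), (n2, s2, q2) in zip(r1, r2):
            assert n1[:-2] == n2[:-2]
            assert n1.endswith("/1") and n2.endswith("/2")
            assert len(s1) == len(q1) == 100

    def test_determinism_across_worker_counts(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        c0, s0, e0 = targets.regions[0]
        profile = GenomeProfile(
            snps=[_snp(ref, c0, s0 + 200, "B")],
            cnas=[SomaticCNA(c0, s0, e0, 2, 1, "c1", 0.7)],
        )
        plan = SamplePlan(sample_name="d", tumor_content=0.6, n_reads=1500,
                         read_length=100, paired=True, seed=42)
        generate_sample(models, profile, plan, ref, str(tmp_path / "w1"), workers=1)
        generate_sample(models, profile, plan, ref, str(tmp_path / "w4"), workers=4)
        for mate in ("_R1.fastq", "_R2.fastq"):
            b1 = open(str(tmp_path / ("w1" + mate)), "rb").read()
            b4 = open(str(tmp_path / ("w4" + mate)), "rb").read()
            assert b1 == b4

    def test_strand_bias_controls_forward_fraction(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        plan = SamplePlan(sample_name="s", tumor_content=0.0, n_reads=20_000,
                         read_length=100, paired=False, strand_bias=0.7, seed=5)
        rep = generate_sample(models, GenomeProfile(), plan, ref, str(tmp_path / "s"))
        lo, hi = ci99(20_000, 0.7)
        assert lo <= rep["forward_fraction"] <= hi

    def test_insert_statistics_are_recovered(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        plan = SamplePlan(sample_name="i", tumor_content=0.0, n_reads=20_000,
                         read_length=100, paired=True, seed=13)
        rep = generate_sample(models, GenomeProfile(), plan, ref, str(tmp_path / "i"))
        assert rep["insert_mean_realized"] == pytest.approx(300.0, rel=0.01)
        assert rep["insert_sd_realized"] == pytest.approx(20.0, rel=0.05)

    def test_requested_coverage_is_met(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        plan = SamplePlan(sample_name="c", tumor_content=0.0,
                         target_mean_coverage=200, read_length=100,
                         paired=True, seed=3)
        rep = generate_sample(models, GenomeProfile(), plan, ref, str(tmp_path / "c"))
        assert rep["realized_on_target_coverage"] == pytest.approx(200, rel=0.02)

    def test_segment_coverage_tracks_dosage(self, engine_panel, tmp_path):
        spec, ref, targets, models, d = engine_panel
        c0, s0, e0 = targets.regions[0]
        cna = SomaticCNA(c0, s0, e0, 2, 1, "c1", 1.0)  # factor 1.5
        plan = SamplePlan(sample_name="t", tumor_content=1.0,
                         target_mean_coverage=250, read_length=100, seed=4)
        rep = generate_sample(models, GenomeProfile(cnas=[cna]), plan, ref,
                              str(tmp_path / "t"))
        # fragment allocation follows the dosage-modulated weights: the
        # amplified target draws 1.5/(1.5+3) of fragments, others 1/4.5
        n = rep["n_fragments"]
        for row in rep["segments"]:
            p = row["coverage_factor"] / 4.5
            lo, hi = ci99(n, p)
            assert lo <= row["n_fragments"] / n <= hi
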