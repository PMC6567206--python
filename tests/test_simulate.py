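"""Breeding simulator: parental genomes, meiosis, schemes, VCF emission."""

import numpy as np
import pytest

from mabc.profile import classify_sites, profile_summary
from mabc.simulate import (
    DONOR,
    RECURRENT,
    GenomeConfig,
    NoiseModel,
    SchemeSpec,
    SelectionError,
    SimulatedIndividual,
    constant_haplotype,
    emit_vcf,
    make_parental_genomes,
    meiosis,
    progeny_dosage,
    run_scheme,
    true_donor_segments,
    true_recovery,
)
from mabc.variants import apply_site_filters, read_multisample_variants, select_informative_sites

from .conftest import ROLE_MAP

SMALL = GenomeConfig(
    chrom_lengths={"chr01": 20_000_000, "chr02": 18_000_000, "chr03": 16_000_000},
)
SMALL_SCHEME = SchemeSpec(target_chrom="chr02", target_pos=9_000_000)
SIM_ROLES = {"donor_parent": "donor", "recurrent_parent": "recurrent", "progeny": "progeny"}


class TestParentalGenomes:
    def test_deterministic_under_seed(self):
        maps = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=500)
            maps.append(mm)
        a, b = maps
        for chrom in a.chrom_order:
            assert np.array_equal(a.positions[chrom], b.positions[chrom])
            assert a.ref[chrom] == b.ref[chrom] and a.alt[chrom] == b.alt[chrom]

    def test_marker_count_and_ordering(self):
        rng = np.random.default_rng(1)
        mm, donor, recurrent = make_parental_genomes(SMALL, rng, n_markers=600)
        assert mm.n_markers == 600
        for chrom in mm.chrom_order:
            pos = mm.positions[chrom]
            assert np.all(np.diff(pos) > 0)
            assert pos[0] >= 1 and pos[-1] <= SMALL.chrom_lengths[chrom]
            # parents are fully divergent
            assert all(r != a for r, a in zip(mm.ref[chrom], mm.alt[chrom]))

    def test_density_scales_with_genome(self):
        rng = np.random.default_rng(2)
        mm, _, _ = make_parental_genomes(SMALL, rng, density=1 / 3000)
        assert mm.n_markers == pytest.approx(54_000 / 3, rel=0.01)

    def test_zero_density_warns_but_valid(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning):
            mm, _, _ = make_parental_genomes(SMALL, rng, density=0.0)
        assert mm.n_markers == 0

    def test_parents_are_opposite_homozygotes(self):
        rng = np.random.default_rng(4)
        mm, donor, recurrent = make_parental_genomes(SMALL, rng, n_markers=100)
        assert true_recovery(recurrent, mm) == 1.0
        assert true_recovery(donor, mm) == 0.0


class TestMeiosis:
    def test_zero_genetic_length_returns_parental_haplotype(self):
        cfg = GenomeConfig(chrom_lengths={"chr01": 1_000_000}, kb_per_cm=1e12)
        f1 = SimulatedIndividual(
            haplotypes={
                "chr01": (
                    constant_haplotype(1_000_000, DONOR),
                    constant_haplotype(1_000_000, RECURRENT),
                )
            }
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            gamete = meiosis(f1, cfg, rng)["chr01"]
            assert len(gamete.origins) == 1
            assert gamete.origins[0] in (DONOR, RECURRENT)

    def test_homozygote_gamete_constant_regardless_of_crossovers(self):
        cfg = GenomeConfig(chrom_lengths={"chr01": 40_000_000})  # 100 cM
        hom = SimulatedIndividual(
            haplotypes={
                "chr01": (
                    constant_haplotype(40_000_000, DONOR),
                    constant_haplotype(40_000_000, DONOR),
                )
            }
        )
        rng = np.random.default_rng(1)
        for _ in range(50):
            gamete = meiosis(hom, cfg, rng)["chr01"]
            assert list(gamete.origins) == [DONOR]

    def test_crossover_count_poisson_mean(self):
        # 100 cM chromosome: crossover count ~ Poisson(1); with an F1 diploid
        # every crossover switches origin, so segments-1 counts crossovers
        cfg = GenomeConfig(chrom_lengths={"chr01": 40_000_000}, kb_per_cm=400)
        f1 = SimulatedIndividual(
            haplotypes={
                "chr01": (
                    constant_haplotype(40_000_000, DONOR),
                    constant_haplotype(40_000_000, RECURRENT),
                )
            }
        )
        rng = np.random.default_rng(2)
        n = 10_000
        mean_xo = np.mean(
            [len(meiosis(f1, cfg, rng)["chr01"].breaks) - 1 for _ in range(n)]
        )
        assert abs(mean_xo - 1.0) < 3 * np.sqrt(1.0 / n)


class TestScheme:
    def test_f1_is_heterozygous_everywhere(self):
        rng = np.random.default_rng(5)
        mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=300)
        f1 = run_scheme(
            SchemeSpec(n_backcross=0, n_self=0, target_chrom="chr02",
                       target_pos=9_000_000),
            SMALL, rng,
        )
        assert all(np.all(d == 1) for d in progeny_dosage(f1, mm).values())
        assert true_recovery(f1, mm) == 0.5

    def test_final_individual_donor_hom_at_target(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            ind = run_scheme(SMALL_SCHEME, SMALL, rng)
            h1, h2 = ind.haplotypes["chr02"]
            pos0 = SMALL_SCHEME.target_pos - 1
            assert int(h1.origin_at(pos0)) == DONOR
            assert int(h2.origin_at(pos0)) == DONOR

    def test_pedigree_log_records_generations(self):
        rng = np.random.default_rng(7)
        ind = run_scheme(SMALL_SCHEME, SMALL, rng)
        assert ind.pedigree[0].startswith("F1")
        assert ind.pedigree[-1].startswith("BC3F2")

    def test_selection_failure_is_explicit(self):
        rng = np.random.default_rng(0)  # first BC1 gamete lacks the donor target
        with pytest.raises(SelectionError):
            run_scheme(SchemeSpec(max_attempts=1), GenomeConfig(), rng)

    def test_target_off_genome_raises(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            run_scheme(SchemeSpec(target_chrom="chr99"), SMALL, rng)

    def test_het_fraction_halves_per_selfing(self):
        # no-selection BC3F1 vs BC3F2 vs BC3F3: het marker fraction 2^-(3+s)
        rng = np.random.default_rng(9)
        mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=1000)
        reps = 150
        for n_self, expected in [(0, 0.125), (1, 0.0625), (2, 0.03125)]:
            fractions = []
            for _ in range(reps):
                ind = run_scheme(
                    SchemeSpec(n_self=n_self, select=False,
                               target_chrom="chr02", target_pos=9_000_000),
                    SMALL, rng,
                )
                dosage = np.concatenate(list(progeny_dosage(ind, mm).values()))
                fractions.append(float(np.mean(dosage == 1)))
            fractions = np.asarray(fractions)
            se = fractions.std(ddof=1) / np.sqrt(reps)
            assert abs(fractions.mean() - expected) < 3 * se + 1e-9


class TestTruth:
    def test_true_donor_segments_match_dosage(self):
        rng = np.random.default_rng(10)
        mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=3000)
        ind = run_scheme(SMALL_SCHEME, SMALL, rng)
        segments = true_donor_segments(ind)
        dosage = progeny_dosage(ind, mm)
        for chrom in mm.chrom_order:
            in_segment = np.zeros(len(mm.positions[chrom]), dtype=bool)
            for c, s, e in segments:
                if c == chrom:
                    pos0 = mm.positions[chrom] - 1
                    in_segment |= (pos0 >= s) & (pos0 < e)
            assert np.array_equal(in_segment, dosage[chrom] == 2)


class TestEmission:
    def test_byte_identical_under_same_seed(self):
        texts = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=800)
            ind = run_scheme(SMALL_SCHEME, SMALL, rng)
            em = emit_vcf(ind, mm, SMALL, NoiseModel.default_noisy(), rng,
                          metadata={"seed": 11})
            texts.append(em.text)
        assert texts[0] == texts[1]

    def test_zero_noise_emission_is_lossless(self, tmp_path):
        rng = np.random.default_rng(12)
        mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=2000)
        ind = run_scheme(SMALL_SCHEME, SMALL, rng)
        em = emit_vcf(ind, mm, SMALL, NoiseModel(), rng)
        for flags in (em.missing, em.low_depth, em.low_quality,
                      em.ab_skewed_het, em.multiallelic, em.genotype_error):
            assert not flags.any()
        path = tmp_path / "sim.vcf"
        path.write_text(em.text)
        sites = list(read_multisample_variants(str(path), SIM_ROLES))
        assert len(sites) == 2000
        passing, tally = apply_site_filters(sites)
        assert tally.removed_total() == 0
        informative, dropped = select_informative_sites(passing)
        assert dropped == 0
        classified = classify_sites(informative)
        # text round trip reproduces the true dosage at every marker
        dosage_by_key = {
            (c, int(p)): int(d)
            for c, p, d in zip(em.chrom, em.pos, em.truth_dosage)
        }
        from mabc.profile import GenotypeClass

        expected_class = {0: GenotypeClass.RECURRENT_HOM, 1: GenotypeClass.HET,
                          2: GenotypeClass.DONOR_HOM}
        for site in classified:
            assert site.genotype_class is expected_class[dosage_by_key[(site.chrom, site.pos)]]
        # and the estimator equals the marker-dosage truth exactly
        summary = profile_summary(classified)
        assert summary.recovery_rate == true_recovery(ind, mm)

    def test_snp_indel_flags_match_alleles(self, tmp_path):
        rng = np.random.default_rng(13)
        mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=500, indel_fraction=0.3)
        ind = run_scheme(SMALL_SCHEME, SMALL, rng)
        em = emit_vcf(ind, mm, SMALL, NoiseModel(), rng)
        path = tmp_path / "sim.vcf"
        path.write_text(em.text)
        sites = {(s.chrom, s.pos): s for s in read_multisample_variants(str(path), SIM_ROLES)}
        for chrom in mm.chrom_order:
            for j, pos in enumerate(mm.positions[chrom]):
                site = sites[(chrom, int(pos))]
                expected = "INDEL" if mm.is_indel[chrom][j] else "SNP"
                assert site.variant_class == expected

    def test_missing_rate_binomial(self, tmp_path):
        rng = np.random.default_rng(14)
        mm, _, _ = make_parental_genomes(SMALL, rng, n_markers=5000)
        ind = run_scheme(SMALL_SCHEME, SMALL, rng)
        em = emit_vcf(ind, mm, SMALL, NoiseModel(missing_rate=0.1), rng)
        path = tmp_path / "sim.vcf"
        path.write_text(em.text)
        _, tally = apply_site_filters(read_multisample_variants(str(path), SIM_ROLES))
        n, p = 5000, 0.1
        assert abs(tally.removed["missing"] - n * p) < 3 * np.sqrt(n * p * (1 - p))
        assert tally.removed["missing"] == int(em.missing.sum())
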