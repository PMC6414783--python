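"""Synthetic-cohort generator: determinism, LD structure, discordance
processes, allele-count distributions and the read-mapping bias model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asecow.correlation import ld_r2
from asecow.synthetic import (
    ConfigError,
    SimConfig,
    SimulatedRead,
    generate_cohort,
    plant_seed_site,
    simulate_allele_counts,
    simulate_het_site_reads,
    simulate_read_mapping,
)


class TestConfig:
    def test_defaults_are_valid(self):
        cfg = SimConfig()
        assert cfg.n_individuals == 19

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_individuals": 1}, "n_individuals"),
            ({"depth_mean": 0}, "depth_mean"),
            ({"ase_fraction": 1.5}, "ase_fraction"),
            ({"overdispersion": -0.1}, "overdispersion"),
            ({"alt_allele_freq_range": (0.9, 0.1)}, "alt_allele_freq_range"),
            ({"cis_effect_size": 0}, "cis_effect_size"),
            ({"chrom_lengths": {}}, "chrom_lengths"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs)


class TestCohort:
    def test_same_seed_reproduces_identically(self):
        cfg = SimConfig(n_snps=50, seed=3)
        a, b = generate_cohort(cfg), generate_cohort(SimConfig(n_snps=50, seed=3))
        pd.testing.assert_frame_equal(a.dna_dosage, b.dna_dosage)
        pd.testing.assert_frame_equal(a.allele_counts, b.allele_counts)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        assert a.mirnas == b.mirnas
        c = generate_cohort(SimConfig(n_snps=50, seed=4))
        assert not a.dna_dosage.equals(c.dna_dosage)

    def test_clean_config_gives_full_concordance(self, clean_cohort):
        assert clean_cohort.dna_dosage.equals(clean_cohort.rna_dosage)

    def test_truth_labels_cover_every_site(self, small_cohort):
        assert set(small_cohort.truth["snp_id"]) == set(small_cohort.snps["snp_id"])

    def test_imprinted_sites_are_dna_het_rna_hom(self, small_cohort):
        truth = small_cohort.truth.set_index("snp_id")
        imprinted = truth.index[truth["imprinted"]]
        assert len(imprinted) > 0
        for snp in imprinted:
            het = small_cohort.dna_dosage.loc[snp] == 1
            rna = small_cohort.rna_dosage.loc[snp][het]
            assert (rna != 1).all()

    def test_edited_sites_are_dna_hom_rna_het(self):
        cohort = generate_cohort(
            SimConfig(n_snps=100, p_editing=0.3, p_imprinting=0, p_genotype_error=0, seed=2)
        )
        truth = cohort.truth.set_index("snp_id")
        edited = truth.index[truth["edited"]]
        assert len(edited) > 0
        for snp in edited:
            hom = cohort.dna_dosage.loc[snp] != 1
            assert (cohort.rna_dosage.loc[snp][hom] == 1).all()

    def test_every_site_is_polymorphic(self, small_cohort):
        assert (small_cohort.dna_dosage.nunique(axis=1) > 1).all()

    def test_ld_blocks_high_within_low_between(self):
        cfg = SimConfig(
            n_snps=100, ld_block_size=10, n_individuals=60,
            chrom_lengths={"1": 1_000_000}, seed=5,
        )
        cohort = generate_cohort(cfg)
        G = cohort.dna_dosage.to_numpy(dtype=float)
        blocks = cohort.snps["block"].to_numpy()
        within, between = [], []
        for i in range(len(G) - 1):
            r2 = ld_r2(G[i], G[i + 1])
            if np.isnan(r2):
                continue
            (within if blocks[i] == blocks[i + 1] else between).append(r2)
        assert np.mean(within) > 0.35
        assert np.mean(between) < 0.15
        assert np.mean(within) > np.mean(between) + 0.3

    def test_true_ase_sites_show_configured_imbalance(self):
        # ~500 true-ASE het sites at depth 200: mean alt fraction within 0.6 +/- 0.02
        cfg = SimConfig(
            n_snps=600, p_ase_site=1.0, ase_fraction=0.6, depth_mean=200,
            depth_dispersion=0.0, p_imprinting=0, p_editing=0, p_genotype_error=0,
            chrom_lengths={"1": 5_000_000}, seed=6,
        )
        cohort = generate_cohort(cfg)
        het = cohort.dna_dosage.reset_index(names="snp_id").melt(
            id_vars="snp_id", var_name="individual", value_name="d"
        )
        het = het[het["d"] == 1].merge(cohort.snps[["snp_id", "chrom", "pos"]], on="snp_id")
        counts = cohort.allele_counts.merge(het, on=["chrom", "pos", "individual"])
        assert len(counts) > 500
        frac = counts["alt_count"] / (counts["ref_count"] + counts["alt_count"])
        assert frac.mean() == pytest.approx(0.6, abs=0.02)

    def test_cis_effect_scales_expression_with_dosage(self):
        cfg = SimConfig(
            n_snps=20, n_transcripts=10, cis_effect_size=2.0,
            expression_dispersion=0.01, n_individuals=60, seed=8,
        )
        cohort = generate_cohort(cfg)
        tm = cohort.transcript_map.set_index("transcript")["snp_id"]
        ratios = []
        for t in cohort.expression.index:
            dosage = cohort.dna_dosage.loc[tm[t]]
            expr = cohort.expression.loc[t]
            by_dose = expr.groupby(dosage).mean()
            if 0 in by_dose.index and 1 in by_dose.index:
                ratios.append(by_dose[1] / by_dose[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_counts_only_where_depth_positive(self, small_cohort):
        totals = small_cohort.allele_counts["ref_count"] + small_cohort.allele_counts["alt_count"]
        assert (totals > 0).all()


class TestAlleleCounts:
    def test_het_counts_conserve_depth(self):
        rng = np.random.default_rng(0)
        ac = simulate_allele_counts(1, 100, 0.5, 0.0, rng)
        assert ac.ref_count + ac.alt_count == 100

    def test_hom_reference_with_no_error(self):
        rng = np.random.default_rng(0)
        ac = simulate_allele_counts(0, 50, 0.5, 0.0, rng, base_error=0.0)
        assert (ac.ref_count, ac.alt_count) == (50, 0)
        ac = simulate_allele_counts(2, 50, 0.5, 0.0, rng, base_error=0.0)
        assert (ac.ref_count, ac.alt_count) == (0, 50)

    def test_binomial_concentration_at_high_depth(self):
        # depth 10^4 at fraction 0.75: sd ~ 0.0043, so within [0.73, 0.77]
        rng = np.random.default_rng(1)
        ac = simulate_allele_counts(1, 10_000, 0.75, 0.0, rng)
        assert 0.73 <= ac.alt_count / 10_000 <= 0.77

    def test_overdispersion_inflates_variance(self):
        rng = np.random.default_rng(2)
        pure = [simulate_allele_counts(1, 100, 0.5, 0.0, rng).alt_count for _ in range(800)]
        over = [simulate_allele_counts(1, 100, 0.5, 0.3, rng).alt_count for _ in range(800)]
        assert np.var(over) > 2 * np.var(pure)

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_allele_counts(1, 10, 0.5, -0.5, np.random.default_rng(0))

    @given(depth=st.integers(0, 500), frac=st.floats(0, 1), rho=st.floats(0, 0.9))
    @settings(max_examples=60, deadline=None)
    def test_count_conservation_always(self, depth, frac, rho):
        rng = np.random.default_rng(42)
        ac = simulate_allele_counts(1, depth, frac, rho, rng)
        assert ac.ref_count + ac.alt_count == depth
        assert ac.ref_count >= 0 and ac.alt_count >= 0


class TestReadMapping:
    def test_unmasked_strict_discards_alt_reads(self):
        rng = np.random.default_rng(0)
        reference, site, reads, ref_a, alt_a = simulate_het_site_reads(200, rng)
        ac = simulate_read_mapping(reference, site, reads, ref_a, alt_a, masked=False, max_mismatches=0)
        assert ac.alt_count == 0
        assert ac.ref_count > 0

    def test_masked_retains_both_alleles(self):
        rng = np.random.default_rng(0)
        reference, site, reads, ref_a, alt_a = simulate_het_site_reads(2000, rng)
        ac = simulate_read_mapping(reference, site, reads, ref_a, alt_a, masked=True, max_mismatches=0)
        total = ac.ref_count + ac.alt_count
        assert total == 2000
        frac = ac.alt_count / total
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / total) + 0.02

    def test_one_extra_mismatch_interacts_with_threshold(self):
        # each read carries one non-site mismatch: with threshold 1 unmasked,
        # ref reads (1 mismatch) survive, alt reads (2) do not; masked keeps both
        rng = np.random.default_rng(3)
        reference, site, reads, ref_a, alt_a = simulate_het_site_reads(
            400, rng, extra_mismatch=True
        )
        unmasked = simulate_read_mapping(reference, site, reads, ref_a, alt_a, False, max_mismatches=1)
        assert unmasked.alt_count == 0 and unmasked.ref_count > 0
        masked = simulate_read_mapping(reference, site, reads, ref_a, alt_a, True, max_mismatches=1)
        assert masked.ref_count + masked.alt_count == 400
        strict = simulate_read_mapping(reference, site, reads, ref_a, alt_a, False, max_mismatches=0)
        assert strict.ref_count + strict.alt_count == 0

    def test_read_not_overlapping_site_is_an_error(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_read_mapping("ACGTACGT", 6, [SimulatedRead("ACGT", 0)], "C", "T", False)


class TestPlantSeedSite:
    MIRNA = "TGAGGTAGTAGGTTGTATAGT"

    def test_sequences_differ_at_single_offset(self):
        utr = "A" * 80
        ref, alt, off = plant_seed_site(utr, self.MIRNA, 10)
        assert len(ref) == len(alt) == 80
        diffs = [i for i, (a, b) in enumerate(zip(ref, alt)) if a != b]
        assert diffs == [off]
        assert 10 <= off < 10 + len(self.MIRNA)

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            plant_seed_site("A" * 30, self.MIRNA, 20)

    def test_broken_by_choices_are_mirrored(self):
        utr = "C" * 100
        ref_a, alt_a, off_a = plant_seed_site(utr, self.MIRNA, 5, broken_by="alt")
        ref_r, alt_r, off_r = plant_seed_site(utr, self.MIRNA, 5, broken_by="ref")
        assert off_a == off_r
        assert ref_a == alt_r and alt_a == ref_r
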