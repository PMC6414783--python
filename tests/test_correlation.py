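"""Normalisation, LD, Spearman correlation and the per-transcript Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from asecow.correlation import (
    bonferroni_per_transcript,
    expressed_transcripts,
    genotype_expression_correlations,
    ld_partners,
    ld_r2,
    median_of_ratios_normalize,
    spearman_correlation,
)


class TestNormalization:
    def test_identical_columns_are_left_unchanged(self):
        m = pd.DataFrame({"a": [10, 100, 7], "b": [10, 100, 7], "c": [10, 100, 7]})
        factors, norm = median_of_ratios_normalize(m)
        assert factors.to_numpy() == pytest.approx([1, 1, 1])
        pd.testing.assert_frame_equal(norm, m.astype(float))

    def test_doubled_column_gets_double_factor(self):
        rng = np.random.default_rng(1)
        base = rng.integers(5, 500, size=100)
        m = pd.DataFrame({"a": base, "b": 2 * base})
        factors, norm = median_of_ratios_normalize(m)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        assert norm["a"].to_numpy() == pytest.approx(norm["b"].to_numpy())

    def test_hand_computed_three_by_two(self):
        # geometric means: sqrt(200), sqrt(20000), sqrt(2e6); every ratio in a
        # column is identical so the median equals it: 1/sqrt(2) and sqrt(2)
        m = pd.DataFrame([[10, 20], [100, 200], [1000, 2000]], columns=["a", "b"])
        factors, norm = median_of_ratios_normalize(m)
        assert factors["a"] == pytest.approx(1 / np.sqrt(2))
        assert factors["b"] == pytest.approx(np.sqrt(2))
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        assert norm["a"].to_numpy() == pytest.approx(norm["b"].to_numpy())

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(1, 1000, size=(50, 5)).astype(float))
        _, norm = median_of_ratios_normalize(m)
        factors2, _ = median_of_ratios_normalize(norm)
        assert factors2.to_numpy() == pytest.approx(np.ones(5), abs=1e-9)

    def test_size_factors_agree_with_deseq2_implementation(self):
        """Independent cross-check against pydeseq2's size-factor routine
        (up to its overall scale convention)."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 800, size=(60, 6)))
        ours, _ = median_of_ratios_normalize(counts)
        _, theirs = deseq2_norm(counts.T)  # samples x genes
        theirs = np.asarray(theirs, dtype=float)
        theirs = theirs / np.exp(np.log(theirs).mean())
        assert ours.to_numpy() == pytest.approx(theirs, rel=5e-3)

    def test_no_all_positive_transcript_is_an_error(self):
        m = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="positive"):
            median_of_ratios_normalize(m)


def test_expressed_transcript_filter():
    m = pd.DataFrame(
        {
            "i1": [1, 1, 0, 0],
            "i2": [2, 1, 0, 0],
            "i3": [3, 0, 0, 0],
            "i4": [0, 0, 0, 5],
        },
        index=["in3", "in2", "zero", "in1"],
    )
    assert list(expressed_transcripts(m, min_individuals=3)) == ["in3"]
    assert list(expressed_transcripts(m, min_individuals=1)) == ["in3", "in2", "in1"]


class TestLDR2:
    def test_self_and_relabel_give_one(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        g1 = np.array([0, 0, 1, 1, 2, 2])
        g2 = np.array([0, 1, 0, 1, 2, 2])
        # deviations (-1,-1,0,0,1,1) and (-1,0,-1,0,1,1): cov 3, var 4 each
        assert ld_r2(g1, g2) == pytest.approx((3 / 4) ** 2)

    def test_constant_vector_is_nan_not_zero(self):
        assert np.isnan(ld_r2(np.array([1, 1, 1, 1]), np.array([0, 1, 2, 1])))

    def test_missing_handled_pairwise(self):
        g1 = np.array([0.0, 1, 2, np.nan, 0])
        g2 = np.array([0.0, 1, 2, 2, -1])
        assert ld_r2(g1, g2) == pytest.approx(1.0)

    @given(st.lists(st.integers(0, 2), min_size=4, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, dosages):
        rng = np.random.default_rng(0)
        g1 = np.array(dosages, dtype=float)
        g2 = rng.integers(0, 3, size=len(g1)).astype(float)
        a, b = ld_r2(g1, g2), ld_r2(g2, g1)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(b)
            assert 0 <= a <= 1 + 1e-12
            assert ld_r2(2 - g1, g2) == pytest.approx(a)


class TestLDPartners:
    def make_genotypes(self):
        g = pd.DataFrame(
            {
                "snpA": [0, 0, 1, 1, 2, 2],
                "snpB": [0, 0, 1, 1, 2, 2],       # perfect LD with A, same chrom
                "snpC": [0, 0, 1, 1, 2, 2],       # same genotypes, other chrom
                "snpD": [0, 1, 0, 2, 1, 2],       # weak LD
                "snpE": [0, 0, 1, 1, 2, -1],      # missing genotype
            }
        ).T
        chrom = pd.Series({"snpA": "1", "snpB": "1", "snpC": "2", "snpD": "1", "snpE": "1"})
        return g, chrom

    def test_intra_chromosomal_only_and_self_included(self):
        g, chrom = self.make_genotypes()
        partners = ld_partners(["snpA"], g, chrom, r2_min=0.75)
        got = set(partners["partner"])
        assert "snpA" in got and "snpB" in got
        assert "snpC" not in got  # different chromosome
        assert "snpD" not in got  # below threshold
        assert "snpE" not in got  # incomplete genotypes
        assert partners.set_index("partner").loc["snpA", "r2"] == 1.0

    def test_threshold_is_inclusive(self):
        # r close to sqrt(0.75): construct r2 slightly above/below by direct search
        g1 = np.array([0, 0, 1, 1, 2, 2, 0, 2])
        g2a = np.array([0, 0, 1, 2, 2, 2, 0, 2])
        r2 = ld_r2(g1, g2a)
        g = pd.DataFrame({"a": g1, "b": g2a}).T
        chrom = pd.Series({"a": "1", "b": "1"})
        partners = ld_partners(["a"], g, chrom, r2_min=r2)  # exactly at threshold
        assert "b" in set(partners["partner"])
        partners = ld_partners(["a"], g, chrom, r2_min=r2 + 1e-9)
        assert "b" not in set(partners["partner"])


class TestSpearman:
    def test_monotone_relations(self):
        d = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1, 0, 2])
        rho, p = spearman_correlation(d, d * 10 + np.linspace(0, 0.5, len(d)))
        assert rho > 0.9
        rho, _ = spearman_correlation(d, -d * 3.0)
        assert rho == pytest.approx(-1.0, abs=1e-9) or rho < -0.9

    def test_constant_input_flagged(self):
        rho, p = spearman_correlation(np.ones(6), np.arange(6))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation(np.array([0, 1, 2]), np.array([1.0, 2, 3]))

    def test_exact_small_n_matches_full_enumeration_probability(self):
        # n=5 strictly monotone: only 2 of 5! orderings reach |rho|=1 -> p=2/120
        rho, p = spearman_correlation(
            np.array([0, 1, 2, 3, 4]), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        )
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_large_n_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=19).astype(float)
        y = d * 0.8 + rng.normal(0, 1.2, size=19)
        rho, p = spearman_correlation(d, y)
        draws = 20000
        perm_rhos = np.array(
            [stats.spearmanr(rng.permutation(d), y).statistic for _ in range(draws)]
        )
        p_mc = np.mean(np.abs(perm_rhos) >= abs(rho) - 1e-12)
        mc_sd = np.sqrt(p_mc * (1 - p_mc) / draws)
        assert p == pytest.approx(p_mc, abs=max(4 * mc_sd, 0.01))

    def test_group_ordered_expression_gives_negative_rho(self):
        # genotype groups 8/7/4 with mean expression decreasing in dosage
        rng = np.random.default_rng(8)
        dosage = np.repeat([0, 1, 2], [8, 7, 4]).astype(float)
        means = {0: 404.0, 1: 323.0, 2: 214.0}
        expr = np.array([means[d] for d in dosage]) + rng.normal(0, 20, size=19)
        rho, p = spearman_correlation(dosage, expr)
        assert rho < -0.6
        assert p < 0.05


class TestBonferroni:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["snp", "transcript", "rho", "p_value"])

    def test_single_test_q_equals_p(self):
        out = bonferroni_per_transcript(self.make([("s1", "t1", 0.9, 0.01)]))
        assert out.loc[0, "q_value"] == pytest.approx(0.01)
        assert bool(out.loc[0, "significant"])

    def test_multiplicity_and_cap(self):
        rows = [(f"s{i}", "t1", 0.7, 0.01) for i in range(4)]
        rows.append(("s9", "t2", 0.9, 0.4))
        for _ in range(4):
            rows.append((f"x{_}", "t2", 0.9, 0.4))
        out = bonferroni_per_transcript(self.make(rows)).set_index("snp")
        assert out.loc["s0", "q_value"] == pytest.approx(0.04)
        assert bool(out.loc["s0", "significant"])
        assert out.loc["s9", "q_value"] == 1.0  # 5 * 0.4 capped
        assert not out.loc["s9", "significant"]

    def test_rho_threshold_applies(self):
        out = bonferroni_per_transcript(self.make([("s1", "t1", 0.5, 0.001)]))
        assert not bool(out.loc[0, "significant"])


def test_correlation_pairs_follow_ld_partner_table():
    g = pd.DataFrame(
        {"ase1": [0, 0, 1, 1, 2, 2], "ld1": [0, 0, 1, 1, 2, 2], "far": [2, 0, 1, 0, 2, 1]}
    ).T
    chrom = pd.Series({"ase1": "1", "ld1": "1", "far": "1"})
    partners = ld_partners(["ase1"], g, chrom, r2_min=0.75)
    expr = pd.DataFrame(
        {"t1": [10.0, 11, 20, 21, 30, 31]}, index=[f"i{k}" for k in range(6)]
    ).T
    expr.columns = list(range(6))
    res = genotype_expression_correlations(
        partners, g, expr, pd.Series({"ase1": "t1"})
    )
    assert set(res["snp"]) == {"ase1", "ld1"}
    assert (res["rho"] > 0.9).all()
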