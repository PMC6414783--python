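"""Genotype-expression correlation for candidate cis-regulatory variants.

An ASE SNP marks a transcript as allelically imbalanced but need not be the
causative variant; the causative polymorphism may only be in linkage
disequilibrium (LD) with it.  This stage therefore

1. normalises the raw transcript count matrix by median-of-ratios size
   factors,
2. keeps transcripts expressed in at least ``min_individuals`` animals,
3. collects intra-chromosomal LD partners of each ASE SNP at dosage
   r^2 >= 0.75 (each SNP partners itself at r^2 = 1),
4. computes Spearman's rank correlation between each partner's genotype
   dosage vector and the transcript's normalised expression, and
5. applies a per-transcript Bonferroni correction; a pair is significant
   when |rho| > 0.6 and the adjusted p ("q-value" in the study's usage,
   not an FDR) is < 0.05.

LD is measured on unphased genotype dosages (composite r^2), which
approximates haplotype r^2 under Hardy-Weinberg equilibrium; no phase is
modelled.  Only SNPs genotyped in every individual enter correlation
testing, matching the complete-genotype requirement of the study design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_R2_MIN = 0.75
DEFAULT_RHO_MIN = 0.6
DEFAULT_Q_MAX = 0.05
EXACT_PERM_MAX_N = 9


def median_of_ratios_normalize(raw_counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalised matrix.

    ``raw_counts`` is transcripts x individuals.  For each transcript with a
    positive geometric mean across individuals, the ratio of each sample's
    count to that geometric mean is formed; a sample's size factor is the
    median of those ratios, and its column is divided by it.  Size factors
    are rescaled to geometric mean 1 (the absolute scale of normalised
    counts is arbitrary), which makes normalisation idempotent.
    """
    if raw_counts.shape[1] < 2:
        raise ValueError("normalisation requires at least 2 individuals")
    counts = raw_counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no transcript has positive counts in every sample; "
            "median-of-ratios is undefined (filter the matrix or add samples)"
        )
    log_counts = np.log(counts[all_positive])
    log_geomean = log_counts.mean(axis=1)
    ratios = np.exp(log_counts - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    size_factors = pd.Series(factors, index=raw_counts.columns, name="size_factor")
    return size_factors, raw_counts / factors


def expressed_transcripts(matrix: pd.DataFrame, min_individuals: int = 3) -> pd.Index:
    """Transcripts with a positive value in at least ``min_individuals``."""
    return matrix.index[(matrix > 0).sum(axis=1) >= min_individuals]


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD r^2).

    Missing dosages (NaN or negative) are dropped pairwise.  A constant
    vector makes r^2 undefined: NaN is returned, never 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2) | (g1 < 0) | (g2 < 0))
    g1, g2 = g1[ok], g2[ok]
    if len(g1) < 2 or np.ptp(g1) == 0 or np.ptp(g2) == 0:
        return float("nan")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def ld_partners(
    ase_snps: list[str],
    genotypes: pd.DataFrame,
    chrom_of: pd.Series,
    r2_min: float = DEFAULT_R2_MIN,
) -> pd.DataFrame:
    """Intra-chromosomal LD partners of each ASE SNP at r^2 >= r2_min.

    ``genotypes`` is SNPs x individuals dosage (0/1/2, -1 or NaN missing);
    ``chrom_of`` maps SNP id -> chromosome.  Each ASE SNP partners itself.
    Partners with any missing genotype are excluded (they could not enter
    correlation testing).  Returns columns ``ase_snp, partner, r2``.
    """
    G = genotypes.to_numpy(dtype=float)
    complete = ~((np.isnan(G)) | (G < 0)).any(axis=1)
    rows = []
    for snp in ase_snps:
        if snp not in genotypes.index:
            continue
        chrom = chrom_of[snp]
        g1 = genotypes.loc[snp].to_numpy(dtype=float)
        same_chrom = chrom_of.reindex(genotypes.index) == chrom
        for j, partner in enumerate(genotypes.index):
            if not same_chrom.iloc[j] or not complete[j]:
                continue
            if partner == snp:
                rows.append({"ase_snp": snp, "partner": snp, "r2": 1.0})
                continue
            r2 = ld_r2(g1, G[j])
            if not np.isnan(r2) and r2 >= r2_min:
                rows.append({"ase_snp": snp, "partner": partner, "r2": r2})
    return pd.DataFrame(rows, columns=["ase_snp", "partner", "r2"])


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n.

    Enumerates all n! orderings of one rank vector; p is the fraction of
    permutations with |rho| >= |rho observed| (within fp tolerance).
    """
    n = len(x_ranks)
    perms = np.array(list(itertools.permutations(range(n))))
    y_perm = y_ranks[perms]  # (n!, n)
    xc = x_ranks - x_ranks.mean()
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    rhos = (yc @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_correlation(dosage: np.ndarray, expression: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and a two-sided p-value.

    The p-value is an exact permutation enumeration for n <= 9 and the
    usual t-distribution approximation for larger n.  Constant input makes
    the correlation undefined (NaN, NaN).
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("Spearman correlation requires >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= EXACT_PERM_MAX_N:
        p = _exact_spearman_p(stats.rankdata(x), stats.rankdata(y), rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


@dataclass
class CorrelationResult:
    snp: str
    transcript: str
    rho: float
    p_value: float
    q_value: float = float("nan")
    n_tests_for_transcript: int = 0
    significant: bool = False


def genotype_expression_correlations(
    partner_table: pd.DataFrame,
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    transcript_of_ase_snp: pd.Series,
) -> pd.DataFrame:
    """Correlate every (partner SNP, transcript) pair implied by LD partners.

    ``transcript_of_ase_snp`` maps each ASE SNP id to the transcript whose
    imbalance it marks.  Returns one row per tested (snp, transcript) pair
    with rho and raw p (use :func:`bonferroni_per_transcript` to finish).
    """
    rows = []
    seen = set()
    for _, rec in partner_table.iterrows():
        transcript = transcript_of_ase_snp.get(rec["ase_snp"])
        if transcript is None or transcript not in expression.index:
            continue
        key = (rec["partner"], transcript)
        if key in seen:
            continue
        seen.add(key)
        dosage = genotypes.loc[rec["partner"]].to_numpy(dtype=float)
        expr = expression.loc[transcript].to_numpy(dtype=float)
        rho, p = spearman_correlation(dosage, expr)
        rows.append({"snp": rec["partner"], "transcript": transcript, "rho": rho, "p_value": p})
    return pd.DataFrame(rows, columns=["snp", "transcript", "rho", "p_value"])


def bonferroni_per_transcript(
    results: pd.DataFrame,
    rho_min: float = DEFAULT_RHO_MIN,
    q_max: float = DEFAULT_Q_MAX,
) -> pd.DataFrame:
    """Per-transcript Bonferroni adjustment and the |rho|/q significance call.

    m = number of SNPs tested against the transcript; q = min(1, m * p);
    significant iff |rho| > rho_min and q < q_max.  (The adjusted p is
    called "q-value" for continuity with the study's terminology; it is a
    family-wise bound, not an FDR.)
    """
    df = results.copy()
    if df.empty:
        df["q_value"] = []
        df["n_tests_for_transcript"] = []
        df["significant"] = []
        return df
    m = df.groupby("transcript")["snp"].transform("count")
    df["q_value"] = np.minimum(1.0, m * df["p_value"])
    df["n_tests_for_transcript"] = m
    df["significant"] = (df["rho"].abs() > rho_min) & (df["q_value"] < q_max)
    return df


def correlate(
    ase_snps: list[str],
    genotypes: pd.DataFrame,
    chrom_of: pd.Series,
    raw_counts: pd.DataFrame,
    transcript_of_ase_snp: pd.Series,
    r2_min: float = DEFAULT_R2_MIN,
    rho_min: float = DEFAULT_RHO_MIN,
    q_max: float = DEFAULT_Q_MAX,
    min_expressed_individuals: int = 3,
) -> pd.DataFrame:
    """Full correlation stage: normalise, filter, find LD partners, test."""
    _, normalized = median_of_ratios_normalize(raw_counts)
    keep = expressed_transcripts(normalized, min_expressed_individuals)
    normalized = normalized.loc[keep]
    partners = ld_partners(ase_snps, genotypes, chrom_of, r2_min)
    results = genotype_expression_correlations(
        partners, genotypes, normalized, transcript_of_ase_snp
    )
    return bonferroni_per_transcript(results, rho_min, q_max)
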