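"""ASE calling from per-allele RNA read counts at heterozygous-concordant SNPs.

The detection rule: a site/individual passes the depth filter when at least
one allele has ``min_reads`` (default 10) supporting reads, and is flagged
ASE when the exact two-sided binomial test of the alt count against an
allelic ratio of 0.5 gives p < alpha (default 0.05).  The exact two-sided
p-value follows the minimum-likelihood convention: the sum of P(X=i) over
every outcome i whose probability does not exceed that of the observed
count.  No multiple-testing correction is applied in this step (the plain
5% threshold is the study rule); an optional Benjamini-Hochberg flag is
available for sensitivity analyses.

Calls inside known CNV regions are excluded (copy-number change mimics
allelic imbalance), and surviving SNPs can be annotated with QTL region
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

DEFAULT_MIN_READS = 10
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open, as in BED."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"malformed region {self.chrom}:{self.start}-{self.end}: start >= end")

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass
class AlleleCount:
    """Per-site, per-individual reference/alternate RNA read counts."""

    chrom: str
    pos: int
    individual: str
    ref_count: int
    alt_count: int

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class ASECall:
    chrom: str
    pos: int
    individual: str
    ref_count: int
    alt_count: int
    p_value: float
    alt_fraction: float
    is_ase: bool
    excluded_reason: str | None = None


def depth_filter(ref_count: int, alt_count: int, min_reads: int = DEFAULT_MIN_READS) -> bool:
    """True iff at least one allele has >= min_reads supporting reads."""
    return max(ref_count, alt_count) >= min_reads


def binomial_pvalues(k: np.ndarray, n: np.ndarray, null_ratio: float = 0.5) -> np.ndarray:
    """Vectorised exact two-sided binomial p-values (minimum-likelihood sum).

    For each observation, p = sum of P(X=i | n, null_ratio) over all i with
    P(X=i) <= P(X=k) (to within a small relative tolerance guarding against
    floating-point asymmetry).  Observations are grouped by n so each depth's
    pmf is computed once.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(n <= 0):
        raise ValueError("binomial test requires total depth > 0")
    if np.any((k < 0) | (k > n)):
        raise ValueError("count k must satisfy 0 <= k <= n")
    p = np.empty(k.shape, dtype=float)
    for nn in np.unique(n):
        sel = n == nn
        pmf = stats.binom.pmf(np.arange(nn + 1), nn, null_ratio)
        order = np.argsort(pmf, kind="stable")
        sorted_pmf = pmf[order]
        cum = np.cumsum(sorted_pmf)
        # count outcomes with pmf <= pmf[k], with relative slack for fp ties
        idx = np.searchsorted(sorted_pmf, pmf[k[sel]] * (1 + 1e-7), side="right")
        p[sel] = cum[idx - 1]
    return np.minimum(p, 1.0)


def binomial_ase_test(
    ref_count: int,
    alt_count: int,
    null_ratio: float = 0.5,
    alpha: float = DEFAULT_ALPHA,
    min_reads: int = DEFAULT_MIN_READS,
    chrom: str = "",
    pos: int = 0,
    individual: str = "",
) -> ASECall:
    """Exact binomial allelic-imbalance test at one site/individual."""
    total = ref_count + alt_count
    if total <= 0:
        raise ValueError("binomial ASE test requires at least one read")
    p = float(binomial_pvalues(np.array([alt_count]), np.array([total]), null_ratio)[0])
    passes_depth = depth_filter(ref_count, alt_count, min_reads)
    return ASECall(
        chrom=chrom,
        pos=pos,
        individual=individual,
        ref_count=ref_count,
        alt_count=alt_count,
        p_value=p,
        alt_fraction=alt_count / total,
        is_ase=bool(p < alpha and passes_depth),
        excluded_reason=None if passes_depth else "low_depth",
    )


def call_ase(
    counts: pd.DataFrame,
    candidates: pd.DataFrame | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    null_ratio: float = 0.5,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run the detection rule over an allele-count table.

    ``counts`` has columns ``chrom, pos, individual, ref_count, alt_count``.
    ``candidates`` (optional) restricts testing to the heterozygous-concordant
    set from the concordance stage; rows outside it are kept with
    ``excluded_reason = not_het_concordant``.  With ``fdr=True`` the ASE flag
    additionally requires a Benjamini-Hochberg q < alpha (off by default:
    the study rule is the plain threshold).
    """
    df = counts.copy()
    key = ["chrom", "pos", "individual"]
    if candidates is not None:
        cand = candidates[key].drop_duplicates()
        df = df.merge(cand.assign(_cand=True), on=key, how="left")
        df["_cand"] = df["_cand"].eq(True)
    else:
        df["_cand"] = True
    total = df["ref_count"] + df["alt_count"]
    if (total <= 0).any():
        df = df[total > 0].copy()
        total = df["ref_count"] + df["alt_count"]
    df["p_value"] = binomial_pvalues(df["alt_count"].to_numpy(), total.to_numpy(), null_ratio)
    df["alt_fraction"] = df["alt_count"] / total
    passes_depth = np.maximum(df["ref_count"], df["alt_count"]) >= min_reads
    df["excluded_reason"] = None
    df.loc[~passes_depth, "excluded_reason"] = "low_depth"
    df.loc[~df["_cand"], "excluded_reason"] = "not_het_concordant"
    significant = df["p_value"] < alpha
    if fdr:
        q = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
        df["q_value"] = q
        significant &= q < alpha
    df["is_ase"] = significant & passes_depth & df["_cand"]
    return df.drop(columns="_cand")


def _region_trees(regions: list[Region]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.label)
    return trees


def exclude_regions(calls: pd.DataFrame, regions: list[Region], reason: str = "cnv_region") -> pd.DataFrame:
    """Mark calls inside any region as excluded (is_ase forced False).

    Containment compares the variant's 0-based coordinate (pos - 1) to the
    half-open [start, end) interval.
    """
    df = calls.copy()
    trees = _region_trees(regions)
    if trees:
        inside = np.fromiter(
            (
                bool(trees[c][p - 1]) if c in trees else False
                for c, p in zip(df["chrom"], df["pos"])
            ),
            dtype=bool,
            count=len(df),
        )
        df.loc[inside, "excluded_reason"] = reason
        df.loc[inside, "is_ase"] = False
    return df


def annotate_regions(snps: pd.DataFrame, regions: list[Region]) -> tuple[pd.DataFrame, dict]:
    """Attach all containing region labels to each SNP.

    Returns the annotated table (new ``labels`` column, list-valued) and a
    summary dict with the number of SNPs carrying at least one label and
    per-label SNP counts.
    """
    df = snps.copy()
    trees = _region_trees(regions)
    labels = []
    for c, p in zip(df["chrom"], df["pos"]):
        hits = sorted(iv.data for iv in trees[c][p - 1]) if c in trees else []
        labels.append(hits)
    df["labels"] = labels
    per_label: dict[str, int] = {}
    for ls in labels:
        for l in set(ls):
            per_label[l] = per_label.get(l, 0) + 1
    summary = {"n_annotated": int(sum(1 for ls in labels if ls)), "per_label": per_label}
    return df, summary


def chromosome_distribution(
    ase_counts: pd.Series,
    chrom_sizes: pd.Series,
    n_genes: pd.Series,
    n_expressed_genes: pd.Series,
) -> pd.DataFrame:
    """Spearman correlation of per-chromosome ASE-SNP counts with covariates.

    Mirrors the descriptive check that ASE SNPs track gene content rather
    than raw chromosome length.  Requires >= 3 chromosomes; a constant
    vector yields NaN (flagged, not silently zero).
    """
    if len(ase_counts) < 3:
        raise ValueError("chromosome_distribution requires >= 3 chromosomes")
    rows = []
    for name, cov in (
        ("chrom_size", chrom_sizes),
        ("n_genes", n_genes),
        ("n_expressed_genes", n_expressed_genes),
    ):
        cov = cov.reindex(ase_counts.index)
        if cov.nunique() <= 1 or ase_counts.nunique() <= 1:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(ase_counts, cov)
        rows.append({"covariate": name, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)
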