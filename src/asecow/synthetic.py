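"""Synthetic cohorts with the statistical structure the ASE analysis assumes.

The generator emulates a small beef-cattle cohort (19 animals by default):

* diploid genotypes organised in intra-chromosomal LD blocks (individuals
  draw whole-block haplotypes from a small founder pool, so adjacent SNPs
  within a block are in strong LD while blocks are independent),
* DNA/RNA genotype discordance from three processes — imprinting-like
  (DNA-het individuals express one allele, so RNA calls homozygous),
  editing-like (DNA-hom sites acquire a heterozygous RNA call) and plain
  genotyping error,
* heterozygous-site allele read counts that are binomial around a true
  allele fraction (0.5 at balanced sites, a configurable fraction at
  true-ASE sites), optionally beta-binomially overdispersed,
* transcript counts with a multiplicative cis-genotype effect per alternate
  allele of the transcript's causal SNP, and
* 3'UTR-like sequences with planted miRNA seed sites broken by one allele.

It also contains a deliberately minimal read-mapping simulation showing the
reference-mapping bias that N-masking removes: with an unmasked reference
and a strict mismatch threshold, reads carrying the alternate allele fail
alignment and the site's alternate fraction collapses toward zero; with the
site masked to N both alleles align equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from asecow.ase import AlleleCount
from asecow.binding import AlleleFlanks, ScanParams, differential_sites, normalize_seq, revcomp, scan_mirna_panel

BASES = np.array(list("ACGT"))
COMPLEMENT_OF = {"A": "T", "T": "A", "C": "G", "G": "C"}
# deterministic non-complementary substitution used to break a planted seed
BREAK_SUBSTITUTION = {"A": "C", "C": "A", "G": "T", "T": "G"}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Cohort simulation parameters.

    Probabilities are per site (``p_imprinting``, ``p_editing``,
    ``p_ase_site``) or per site-individual (``p_genotype_error``).
    ``depth_mean``/``depth_dispersion`` parameterise a negative-binomial
    per-site read depth (variance = mu + dispersion * mu^2).
    ``ase_fraction`` is the expected fraction of reads carrying the
    alternate allele at a true-ASE heterozygous site; ``overdispersion`` is
    the beta-binomial intra-class correlation rho (0 = pure binomial).
    ``cis_effect_size`` multiplies a transcript's expected expression once
    per alternate-allele copy of its causal SNP.
    """

    n_individuals: int = 19
    n_snps: int = 200
    chrom_lengths: dict = field(default_factory=lambda: {"1": 2_000_000, "2": 1_500_000})
    ld_block_size: int = 10
    alt_allele_freq_range: tuple = (0.15, 0.85)
    depth_mean: float = 60.0
    depth_dispersion: float = 0.3
    ase_fraction: float = 0.7
    p_ase_site: float = 0.1
    overdispersion: float = 0.0
    p_imprinting: float = 0.01
    p_editing: float = 0.02
    p_genotype_error: float = 0.002
    cis_effect_size: float = 2.0
    n_transcripts: int = 30
    expression_mean: float = 500.0
    expression_dispersion: float = 0.05
    base_error: float = 0.001
    n_founder_haplotypes: int = 4
    read_length: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be >= 0")
        if self.overdispersion < 0 or self.overdispersion >= 1:
            raise ConfigError("overdispersion (beta-binomial rho) must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if self.n_founder_haplotypes < 2:
            raise ConfigError("n_founder_haplotypes must be >= 2")
        lo, hi = self.alt_allele_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("alt_allele_freq_range must be an ordered pair in [0,1]")
        for name in ("ase_fraction", "p_ase_site", "p_imprinting", "p_editing", "p_genotype_error", "base_error"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.cis_effect_size <= 0:
            raise ConfigError("cis_effect_size must be > 0")
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must name at least one chromosome")


@dataclass
class SyntheticCohort:
    """One simulated cohort with full ground truth."""

    config: SimConfig
    individuals: list
    snps: pd.DataFrame              # snp_id, chrom, pos, ref, alt, block
    dna_dosage: pd.DataFrame        # snp x individual, 0/1/2
    rna_dosage: pd.DataFrame
    allele_counts: pd.DataFrame     # chrom, pos, individual, ref_count, alt_count
    truth: pd.DataFrame             # per site: true_ase, true_alt_fraction, imprinted, edited
    transcript_map: pd.DataFrame    # transcript, snp_id, cis_effect
    expression: pd.DataFrame        # transcript x individual raw counts
    sequences: dict                 # region name -> (ref_seq, alt_seq, snp_offset)
    mirnas: dict                    # mirna id -> sequence

    def genotypes_long(self, assay: str) -> pd.DataFrame:
        """Long genotype table (chrom, pos, individual, gt) for one assay."""
        dosage = self.dna_dosage if assay == "DNA" else self.rna_dosage
        gt_name = {0: "hom_ref", 1: "het", 2: "hom_alt", -1: "missing"}
        long = dosage.reset_index(names="snp_id").melt(
            id_vars="snp_id", var_name="individual", value_name="dosage"
        )
        long = long.merge(self.snps[["snp_id", "chrom", "pos"]], on="snp_id")
        long["gt"] = long["dosage"].map(gt_name)
        return long[["chrom", "pos", "individual", "gt"]]


def _distribute_snps(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Allocate SNPs to chromosomes proportionally to length, sorted positions."""
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    shares = lengths / lengths.sum() * config.n_snps
    counts = np.floor(shares).astype(int)
    for i in np.argsort(-(shares - counts))[: config.n_snps - counts.sum()]:
        counts[i] += 1
    rows = []
    k = 0
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        if n > config.chrom_lengths[chrom]:
            raise ConfigError(f"chrom_lengths[{chrom}] too short for its SNP share")
        pos = np.sort(rng.choice(config.chrom_lengths[chrom], size=n, replace=False) + 1)
        for j, p in enumerate(pos):
            ref = rng.choice(BASES)
            alt = rng.choice([b for b in BASES if b != ref])
            rows.append(
                {
                    "snp_id": f"snp{k:05d}",
                    "chrom": chrom,
                    "pos": int(p),
                    "ref": str(ref),
                    "alt": str(alt),
                    "block": f"{chrom}:{j // config.ld_block_size}",
                }
            )
            k += 1
    return pd.DataFrame(rows)


def _simulate_genotypes(snps: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Block-haplotype genotypes: founder haplotypes copied whole per block."""
    n_ind = config.n_individuals
    dosage = np.zeros((len(snps), n_ind), dtype=np.int64)
    lo, hi = config.alt_allele_freq_range
    for _, idx in snps.groupby("block", sort=False).indices.items():
        idx = np.asarray(idx)
        freqs = rng.uniform(lo, hi, size=len(idx))
        founders = (rng.random((config.n_founder_haplotypes, len(idx))) < freqs).astype(np.int64)
        # called variants are polymorphic by ascertainment: keep both alleles
        # represented in the founder pool at every SNP
        for s in np.flatnonzero(founders.min(axis=0) == founders.max(axis=0)):
            founders[rng.integers(config.n_founder_haplotypes), s] ^= 1
        picks = rng.integers(0, config.n_founder_haplotypes, size=(n_ind, 2))
        dosage[idx[:, None], np.arange(n_ind)] = (founders[picks[:, 0]] + founders[picks[:, 1]]).T
    return dosage


def simulate_allele_counts(
    gt_dosage: int,
    depth: int,
    ase_fraction: float,
    overdispersion: float = 0.0,
    rng: np.random.Generator | None = None,
    base_error: float = 0.0,
) -> AlleleCount:
    """Simulate one site/individual's per-allele RNA read counts.

    Heterozygotes draw the alternate count from a (beta-)binomial with mean
    ``ase_fraction`` and intra-class correlation ``overdispersion``;
    homozygotes place all reads on their single allele apart from a base
    error rate.  Counts always conserve: ref + alt = depth.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if overdispersion < 0:
        raise ValueError("overdispersion (rho) must be >= 0")
    rng = rng or np.random.default_rng()
    if gt_dosage == 1:
        f = ase_fraction
    elif gt_dosage == 0:
        f = base_error
    elif gt_dosage == 2:
        f = 1.0 - base_error
    else:
        raise ValueError(f"cannot simulate counts for dosage {gt_dosage}")
    if overdispersion > 1e-12 and 0 < f < 1:
        scale = 1.0 / overdispersion - 1.0
        a, b = f * scale, (1.0 - f) * scale
        if a > 0 and b > 0:  # underflow guard for extreme fractions
            f = rng.beta(a, b)
    alt = int(rng.binomial(depth, f)) if depth > 0 else 0
    return AlleleCount(chrom="", pos=0, individual="", ref_count=depth - alt, alt_count=alt)


def _negative_binomial(mean: float, dispersion: float, size, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean / shape, size=size))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full cohort; reproducible for a fixed config and seed."""
    rng = np.random.default_rng(config.seed)
    individuals = [f"IND{i + 1:02d}" for i in range(config.n_individuals)]
    snps = _distribute_snps(config, rng)
    n_snps = len(snps)
    dna = _simulate_genotypes(snps, config, rng)

    truth = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "true_ase": rng.random(n_snps) < config.p_ase_site,
            "imprinted": rng.random(n_snps) < config.p_imprinting,
            "edited": rng.random(n_snps) < config.p_editing,
        }
    )
    # a site is one process at most; imprinting wins over editing
    truth.loc[truth["imprinted"], "edited"] = False
    truth["true_alt_fraction"] = np.where(truth["true_ase"], config.ase_fraction, 0.5)

    # RNA genotypes: start concordant, then apply discordance processes
    rna = dna.copy()
    imprint_allele = rng.integers(0, 2, size=n_snps)  # 0 -> ref expressed, 1 -> alt
    for i in np.flatnonzero(truth["imprinted"].to_numpy()):
        het = dna[i] == 1
        rna[i, het] = 2 * imprint_allele[i]
    for i in np.flatnonzero(truth["edited"].to_numpy()):
        hom = dna[i] != 1
        rna[i, hom] = 1
    if config.p_genotype_error > 0:
        err = rng.random(dna.shape) < config.p_genotype_error
        shifted = (rna + rng.integers(1, 3, size=dna.shape)) % 3
        rna = np.where(err, shifted, rna)

    # per-allele read counts at every site/individual with positive depth
    depth = _negative_binomial(config.depth_mean, config.depth_dispersion, dna.shape, rng)
    count_rows = []
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    imprinted_arr = truth["imprinted"].to_numpy()
    frac_arr = truth["true_alt_fraction"].to_numpy()
    for i in range(n_snps):
        for j in range(config.n_individuals):
            d = int(depth[i, j])
            if d == 0:
                continue
            if dna[i, j] == 1 and imprinted_arr[i]:
                f = 1.0 - config.base_error if imprint_allele[i] else config.base_error
                alt = int(rng.binomial(d, f))
                ref = d - alt
            else:
                ac = simulate_allele_counts(
                    int(dna[i, j]), d, frac_arr[i], config.overdispersion, rng, config.base_error
                )
                ref, alt = ac.ref_count, ac.alt_count
            count_rows.append((chrom_arr[i], int(pos_arr[i]), individuals[j], ref, alt))
    allele_counts = pd.DataFrame(
        count_rows, columns=["chrom", "pos", "individual", "ref_count", "alt_count"]
    )

    # transcript counts with a cis effect of the causal SNP's dosage
    transcripts = [f"T{t + 1:04d}" for t in range(config.n_transcripts)]
    causal = snps["snp_id"].to_numpy()[np.arange(config.n_transcripts) % n_snps]
    transcript_map = pd.DataFrame(
        {"transcript": transcripts, "snp_id": causal, "cis_effect": config.cis_effect_size}
    )
    base_means = np.exp(rng.normal(np.log(config.expression_mean), 0.5, size=config.n_transcripts))
    causal_idx = snps.set_index("snp_id").index.get_indexer(causal)
    expected = base_means[:, None] * config.cis_effect_size ** dna[causal_idx, :]
    expr = _negative_binomial(expected, config.expression_dispersion, expected.shape, rng)
    expression = pd.DataFrame(expr, index=transcripts, columns=individuals)

    # 3'UTR-like regions with planted seed sites
    sequences, mirnas = {}, {}
    for u in range(3):
        utr = "".join(rng.choice(BASES, size=201))
        mirna = "".join(rng.choice(BASES, size=21))
        position = 40 + 50 * u
        ref_seq, alt_seq, offset = plant_seed_site(utr, mirna, position, broken_by="alt")
        sequences[f"utr{u + 1}"] = (ref_seq, alt_seq, offset)
        mirnas[f"mir-{u + 1:03d}"] = mirna

    return SyntheticCohort(
        config=config,
        individuals=individuals,
        snps=snps,
        dna_dosage=pd.DataFrame(dna, index=snps["snp_id"], columns=individuals),
        rna_dosage=pd.DataFrame(rna, index=snps["snp_id"], columns=individuals),
        allele_counts=allele_counts,
        truth=truth,
        transcript_map=transcript_map,
        expression=expression,
        sequences=sequences,
        mirnas=mirnas,
    )


# ---------------------------------------------------------------------------
# Read-mapping simulation (reference bias and N-masking)


@dataclass
class SimulatedRead:
    sequence: str
    start: int  # 0-based offset of the read on the reference context


def simulate_read_mapping(
    reference: str,
    site_index: int,
    reads: list[SimulatedRead],
    ref_allele: str,
    alt_allele: str,
    masked: bool,
    max_mismatches: int = 0,
) -> AlleleCount:
    """Align fixed-length reads to a (possibly N-masked) reference and tally.

    A read is retained iff its ungapped mismatch count against the selected
    reference is <= ``max_mismatches``; an N reference position matches any
    base.  Retained reads are tallied by the base they carry at the site.
    Against the unmasked reference, alt-carrying reads always pay the site
    mismatch — the reference bias that masking removes.
    """
    reference = normalize_seq(reference)
    if masked:
        reference = reference[:site_index] + "N" + reference[site_index + 1:]
    ref_n = alt_n = 0
    for read in reads:
        end = read.start + len(read.sequence)
        if not (read.start <= site_index < end):
            raise ValueError(f"read at {read.start} (length {len(read.sequence)}) does not overlap site {site_index}")
        segment = reference[read.start:end]
        mismatches = sum(1 for a, b in zip(read.sequence, segment) if b != "N" and a != b)
        if mismatches > max_mismatches:
            continue
        base = read.sequence[site_index - read.start]
        if base == ref_allele:
            ref_n += 1
        elif base == alt_allele:
            alt_n += 1
    return AlleleCount(chrom="", pos=site_index + 1, individual="", ref_count=ref_n, alt_count=alt_n)


def simulate_het_site_reads(
    depth: int,
    rng: np.random.Generator,
    read_length: int = 20,
    extra_mismatch: bool = False,
) -> tuple[str, int, list[SimulatedRead], str, str]:
    """Reads from a heterozygous site: half carry ref, half alt (in expectation).

    Returns (reference context, site index, reads, ref_allele, alt_allele).
    With ``extra_mismatch`` every read additionally carries one non-site
    mismatch, for probing mismatch-threshold behaviour.
    """
    context_len = 3 * read_length
    site = context_len // 2
    reference = "".join(rng.choice(BASES, size=context_len))
    ref_allele = reference[site]
    alt_allele = str(rng.choice([b for b in BASES if b != ref_allele]))
    reads = []
    for _ in range(depth):
        start = int(rng.integers(site - read_length + 1, site + 1))
        seq = list(reference[start:start + read_length])
        if rng.random() < 0.5:
            seq[site - start] = alt_allele
        if extra_mismatch:
            off_site = [k for k in range(read_length) if start + k != site]
            k = int(rng.choice(off_site))
            seq[k] = str(rng.choice([b for b in BASES if b != seq[k]]))
        reads.append(SimulatedRead("".join(seq), start))
    return reference, site, reads, ref_allele, alt_allele


# ---------------------------------------------------------------------------
# Seed-site planting and the differential-binding fixture panel


def plant_seed_site(
    utr_sequence: str,
    mirna_sequence: str,
    position: int,
    broken_by: str = "alt",
) -> tuple[str, str, int]:
    """Embed a perfect miRNA target site at ``position``, broken by one allele.

    The intact-allele sequence carries the full Watson-Crick reverse
    complement of the miRNA starting at ``position``; the other allele
    differs by a single non-complementary substitution inside the seed
    pairing region, destroying the seed match.  Returns
    (ref_sequence, alt_sequence, snp_offset).
    """
    utr = normalize_seq(utr_sequence)
    mirna = normalize_seq(mirna_sequence)
    L = len(mirna)
    if position < 0 or position + L > len(utr):
        raise ValueError(f"position {position} + site length {L} outside sequence of length {len(utr)}")
    target = revcomp(mirna)
    intact = utr[:position] + target + utr[position + L:]
    snp_offset = position + L - 5  # inside the seed pairing region (miRNA position 5)
    broken_base = BREAK_SUBSTITUTION[intact[snp_offset]]
    broken = intact[:snp_offset] + broken_base + intact[snp_offset + 1:]
    if broken_by == "alt":
        return intact, broken, snp_offset
    if broken_by == "ref":
        return broken, intact, snp_offset
    raise ValueError(f"broken_by must be 'ref' or 'alt', got {broken_by!r}")


def make_differential_panel(
    n_ref_only: int = 9,
    n_alt_only: int = 5,
    radius: int = 100,
    seed: int = 0,
    params: ScanParams | None = None,
    mirna_length: int = 21,
) -> tuple[AlleleFlanks, dict[str, str]]:
    """A SNP flank pair plus a miRNA panel with a known differential split.

    ``n_ref_only`` miRNAs have seed sites spanning the SNP that require the
    reference base, ``n_alt_only`` require the alternate base; extension
    regions are lightly mutated so panel members are distinct sequences.
    The construction is verified by scanning; the builder redraws on the
    rare accidental off-site seed match.
    """
    params = params or ScanParams()
    ext_len = mirna_length - 8
    for attempt in range(100):
        rng = np.random.default_rng((seed, attempt))
        background = "".join(rng.choice(BASES, size=2 * radius + 1))
        offset = radius
        ref_base = background[offset]
        alt_base = BREAK_SUBSTITUTION[ref_base]
        ref_seq = background
        alt_seq = background[:offset] + alt_base + background[offset + 1:]
        mirnas: dict[str, str] = {}

        def build(source: str, label: str, count: int):
            for k in range(count):
                i = int(rng.integers(offset - 6, offset + 1))  # seed window covers the SNP
                region = source[i - ext_len: i + 8]
                mirna = list(revcomp(region))
                for _ in range(int(rng.integers(0, 3))):  # diversify the 3' extension
                    j = int(rng.integers(8, mirna_length))
                    mirna[j] = str(rng.choice([b for b in BASES if b != mirna[j]]))
                mirnas[f"mir-{label}-{k + 1:02d}"] = "".join(mirna)

        build(ref_seq, "ref", n_ref_only)
        build(alt_seq, "alt", n_alt_only)
        flanks = AlleleFlanks(
            chrom="synthetic", pos=offset + 1, ref_sequence=ref_seq, alt_sequence=alt_seq,
            snp_offset=offset, radius=radius,
        )
        diff = differential_sites(*scan_mirna_panel(flanks, mirnas, params))
        expected_ref = sorted(m for m in mirnas if "-ref-" in m)
        expected_alt = sorted(m for m in mirnas if "-alt-" in m)
        if diff.mirnas_ref_only == expected_ref and diff.mirnas_alt_only == expected_alt and not diff.mirnas_both:
            return flanks, mirnas
    raise RuntimeError("could not construct a clean differential panel (unexpected)")


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
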