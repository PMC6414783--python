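# Methods

This note documents the models, parameter choices and numerical conventions
behind `asecow`, and what the synthetic-data tests do and do not establish
about real data.

## Concordance classification

Sites called in both the DNA and RNA assay for an individual are classified
by genotype pair: BH (both homozygous — either homozygous class), Bh (both
heterozygous), Hh (DNA-hom/RNA-het) and hH (DNA-het/RNA-hom).  The classes
partition the overlap; sites called in one assay only are tallied but never
classified, and multi-allelic records are excluded at VCF reading (the
analysis is SNV-only) with the skipped count reported.

Two cohort-level concordance figures are deliberately distinct: the
unweighted mean of per-individual rates, and the pooled rate that weights
individuals by their overlap (ratio of mean concordant count to mean
overlap).  They differ when individuals with small overlaps have atypical
rates, so both are computed and reported.  Reported rates are rounded
half-up to one decimal; full precision is kept internally.

Only Bh sites continue to ASE testing.  This removes imprinting-like (hH)
and editing-like (Hh) discordance by construction; the package does not
attempt to separate those mechanisms from genotyping error beyond the class
labels.

## ASE detection

The test is an exact two-sided binomial test of the alternate count against
a null allelic ratio of 0.5, using the minimum-likelihood convention: the
p-value sums `P(X=i)` over every outcome whose probability does not exceed
that of the observed count (with a 1e-7 relative slack against
floating-point asymmetry of the pmf).  This matches the common exact
two-sided convention (`scipy.stats.binomtest` is used as an independent
cross-check in the tests, never as the implementation).  P-values are
computed vectorised, grouping observations by total depth so each depth's
pmf is evaluated once.

Defaults follow the study design: `min_reads = 10` on at least one allele,
`alpha = 0.05`, `null_ratio = 0.5`.  **No multiple-testing correction is
applied across SNPs in the detection step** — the plain 5 % threshold is
the study rule.  An optional Benjamini–Hochberg flag (`fdr=True`) is
provided for sensitivity analyses and is off by default.  A cohort-level
ASE SNP is any site flagged in at least one individual, deduplicated by
site.

Because the exact test is conservative under discreteness, the realised
type-I error on balanced sites is at or below the nominal 5 % (verified on
20,000 simulated sites across depths 20–200).

CNV exclusion and QTL annotation use 0-based half-open intervals (BED
convention) against the variant's 0-based coordinate `pos − 1`; containment
queries go through an interval tree.  Internal coordinates are 1-based
(VCF-native) throughout; BED is converted at the boundary.

## Correlation stage

*Normalisation.* Median-of-ratios size factors are implemented from their
definition: for each transcript positive in every sample, the ratio of each
sample's count to the transcript's geometric mean is formed, and a sample's
factor is the median of its ratios.  Factors are rescaled to geometric
mean 1 — the absolute scale of normalised counts is arbitrary, and this
makes normalisation exactly idempotent.  The method assumes most
transcripts are not differentially driven between samples; with very few
transcripts (or when every transcript responds to the same genotype) the
factors absorb the biological signal itself, which is why the
parameter-recovery test simulates 20 transcripts with causal SNPs spread
across LD blocks.

*Expressed-transcript filter.* A transcript is kept when it has a positive
count in at least 3 individuals (configurable).

*LD.* r² is the squared Pearson correlation of unphased genotype dosage
vectors (composite LD), computed pairwise-complete; it approximates
haplotype r² under Hardy–Weinberg equilibrium and requires no phasing.
A constant dosage vector makes r² undefined and is reported as missing,
never 0.  Partners of an ASE SNP are restricted to the same chromosome at
r² ≥ 0.75 (inclusive), each SNP partners itself at r² = 1, and SNPs with
any missing genotype are excluded from correlation testing (the design
requires complete genotypes across the cohort).

*Spearman correlation.* ρ uses average ranks for ties.  The two-sided
p-value is an exact permutation enumeration of all n! orderings for n ≤ 9
and the t-distribution approximation for larger n (at the study's n = 19
the approximation agrees with a 20,000-draw permutation oracle within
Monte-Carlo error; this is tested).

*Multiplicity.* Within each transcript, with m SNPs tested, the adjusted
p is `q = min(1, m·p)` (Bonferroni).  The term "q-value" is kept for
continuity with the study's usage; it is a family-wise bound, not an FDR.
Significance requires |ρ| > 0.6 **and** q < 0.05.

## Binding-site differencing

External heuristic scanners are replaced by a fully specified scheme, so
results are transparent and reproducible but are **not** expected to match
any particular third-party tool site-for-site.

*miRNA scan.* A candidate site requires perfect Watson–Crick pairing of
miRNA positions 2–8 (the seed; the duplex is antiparallel, so the target
read 5′→3′ must contain the reverse complement of the seed).  The target
base facing miRNA position 1 upgrades the class from 7mer-m8 to 8mer when
it is an A; position 1 itself is not scored.  The remaining miRNA positions
9..L are scored ungapped against the upstream target bases: +5 per WC pair,
+1 per G:U wobble (permitted outside the seed only), −3 per mismatch;
positions running off the target edge count as mismatches.  The seed
contributes +5 per pair (35 total), and a site passes at score ≥ 60
(default `min_score`; a 21-nt miRNA tops out at 100).  N never pairs:
it blocks a seed and scores as a mismatch in the extension.  DNA and RNA
alphabets are accepted and normalised to DNA (U→T).

*PWM scan.* A 4×width log-odds matrix is slid over both strands; a window
matches at score ≥ 0.85 × (maximum attainable score).  N scores −∞.

*Differencing.* Presence is binary per allele flank (≥ 1 passing hit
anywhere), and miRNAs/motifs are partitioned into ref-only / alt-only /
both.  Swapping the alleles swaps the ref-only and alt-only lists exactly;
any site whose footprint does not overlap the SNP necessarily lands in
"both".  Flank radii default to 100 nt for miRNA scans and 10 nt for TFBS
scans.

## Pyrosequencing arithmetic

The ASE ratio is `(allele1%/allele2%)_cDNA / (allele1%/allele2%)_gDNA`;
dividing by the gDNA ratio cancels allele-specific assay bias.  The ratio
is exactly reciprocal under allele swap and invariant to common rescaling
of a template's percentages.  Reporting can follow the formula as written
or be oriented in favour of the RNA-enriched allele (always ≥ 1).

The validated/not-validated decision is an explicit operationalisation of
the wet-lab criteria: heterozygosity confirmed when the gDNA allele-1
percentage lies in a 30–70 % band, and validation additionally requires a
cDNA-vs-gDNA shift larger than 4 percentage points (the detectability limit
implied by replicate standard deviations of 0–4 %).  Both knobs are
configurable; percentages must sum to 100 within 0.5 (instrument rounding).
Complementary-strand read-outs are marked with an explicit flag on the
measurement, never silently base-flipped.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, with
defaults mirroring the study conditions where stated:

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 19 | cohort size |
| `n_snps` | 200 | SNVs across `chrom_lengths` (proportional to length) |
| `ld_block_size` | 10 | SNPs per LD block |
| `n_founder_haplotypes` | 4 | founder pool per block |
| `alt_allele_freq_range` | (0.15, 0.85) | per-SNP founder allele frequency |
| `depth_mean`, `depth_dispersion` | 60, 0.3 | negative-binomial site depth |
| `ase_fraction` | 0.7 | alt-read fraction at true-ASE het sites |
| `p_ase_site` | 0.1 | fraction of sites that are true-ASE |
| `overdispersion` | 0 | beta-binomial ρ (0 = binomial, as the test assumes) |
| `p_imprinting`, `p_editing`, `p_genotype_error` | 0.01, 0.02, 0.002 | discordance processes |
| `cis_effect_size` | 2.0 | expression multiplier per alternate allele |
| `expression_mean`, `expression_dispersion` | 500, 0.05 | transcript counts |
| `base_error` | 0.001 | stray-allele rate at homozygous sites |

LD is produced by copying whole-block founder haplotypes (no recombination
within a block, independence across blocks): adjacent-SNP r² is high within
blocks and near zero across them, which is all the LD-partner stage needs —
this is deliberately simpler than a coalescent.  Because called variants
are polymorphic by ascertainment, the founder pool is forced to carry both
alleles at every SNP.  Imprinting converts DNA-het individuals to RNA-hom
at imprinted sites (one expressed allele drawn per site); editing converts
DNA-hom individuals to RNA-het; genotype errors replace the RNA call at
random.  A site undergoes at most one process (imprinting takes
precedence).  At edited homozygous sites read counts still follow the DNA
genotype (the RNA *call* is what editing perturbs); modelling edited read
fractions is out of scope.

The depth distribution is a free choice (the study does not state one):
negative binomial with mean 60, moderate dispersion, as a realistic shape
for RNA-Seq site coverage.

The read-mapping simulation is a minimal model that still exhibits the
masking effect: fixed-length error-free reads (default 20 nt) over a random
context, half carrying each allele at a heterozygous site, aligned ungapped
with a mismatch threshold (default 0).  Unmasked, every alt-carrying read
pays the site mismatch and is discarded — the alternate fraction collapses
to 0; with the site masked to N (N matches any base at zero cost) both
alleles align and the fraction is 0.5 in expectation.

`plant_seed_site` embeds the full reverse complement of a miRNA into a UTR
sequence and breaks the seed on one allele with a single
non-complementary substitution; `make_differential_panel` builds a flank
pair plus a panel of miRNAs with a known ref-only/alt-only split (seed
windows all spanning the SNP, extensions lightly mutated so panel members
are distinct), verifying the split by scanning and redrawing on the rare
accidental off-site match.

**What the synthetic tests do not show.** The generator has no read-level
error profiles, alignment artefacts, splicing, allelic mapping bias beyond
the single-site model, population structure, or realistic LD decay; passing
tests demonstrate the correctness and statistical calibration of the
procedures under their stated assumptions, not performance on real
sequencing data.

## Problem sizes and numerical choices

The test suite simulates 20,000 balanced sites for the type-I check, a
4×4 fraction-by-depth grid (3,000 sites per cell) for power monotonicity,
200 replicate 19-individual cohorts (40 SNPs, 20 transcripts,
dispersion 0.01 — the stated low-noise planted-effect condition) for
parameter recovery, and depth 10⁴ for the masking property; the whole
suite runs in well under a minute.  Exact Spearman enumeration is limited
to n ≤ 9 (9! ≈ 3.6×10⁵ permutations, vectorised).  Ties in the binomial
pmf are compared with 1e-7 relative slack; LD and correlation of constant
vectors are NaN-flagged rather than zeroed; rates over empty overlaps are
flagged undefined rather than reported as 0.

## Known limitations

- The detection step's plain 5 % threshold inflates cohort-level false
  positives by design fidelity; use the optional FDR flag for calibrated
  discovery.
- Composite (dosage) r² understates haplotype r² away from HWE.
- The binding scan is a transparent stand-in for heuristic duplex aligners;
  thresholds (`min_score` 60, PWM fraction 0.85) are conventions, not
  fitted values.
- The pyrosequencing validation rule formalises criteria a human analyst
  applied; borderline calls near the 4-point limit depend on that choice.
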