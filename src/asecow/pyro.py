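"""Pyrosequencing validation arithmetic for candidate ASE SNPs.

Pyrosequencing quantifies the two alleles of a SNP as percentages, on
genomic DNA (where a heterozygote should read near 50/50) and on cDNA
(where allelic imbalance shifts the ratio).  The ASE ratio is

    ASE ratio = (allele1% / allele2%)_cDNA / (allele1% / allele2%)_gDNA

so 1.0 means balanced expression and values above 1 mean allele 1 is
enriched in RNA.  Dividing by the gDNA ratio cancels allele-specific assay
bias (unequal amplification or signal per allele).

Validation operationalises two checks the wet-lab procedure supports:
the gDNA percentages must confirm heterozygosity (allele 1 within a
30-70% band by default), and the cDNA-vs-gDNA allele-percentage shift must
exceed the replicate-derived detectability limit (4 percentage points by
default, from replicate standard deviations of 0-4%).
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass


@dataclass
class PyroMeasurement:
    """One pyrosequencing read-out of a SNP on one template.

    ``complemented`` marks assays read on the complementary strand (the
    instrument may report C/T where the variant is catalogued G/A); it is an
    explicit flag, never applied silently.
    """

    snp: str
    individual: str
    template: str  # "gDNA" or "cDNA"
    allele1_pct: float
    allele2_pct: float
    replicate: int = 1
    complemented: bool = False

    def __post_init__(self):
        if self.template not in ("gDNA", "cDNA"):
            raise ValueError(f"template must be gDNA or cDNA, got {self.template!r}")
        if abs(self.allele1_pct + self.allele2_pct - 100.0) > 0.5:
            raise ValueError(
                f"allele percentages must sum to 100 (+/-0.5 instrument rounding), "
                f"got {self.allele1_pct} + {self.allele2_pct}"
            )


@dataclass
class PyroResult:
    snp: str
    ase_ratio: float
    gdna_allele1_pct: float
    cdna_allele1_pct: float
    replicate_sd: dict | None = None
    heterozygous_confirmed: bool = False
    validated: bool = False


def ase_ratio(gdna: PyroMeasurement, cdna: PyroMeasurement, favor: str = "allele1") -> float:
    """(allele1%/allele2%) in cDNA divided by the same ratio in gDNA.

    ``favor`` selects the reporting orientation: ``"allele1"`` reports the
    formula as written; ``"rna_enriched"`` reports in favour of whichever
    allele is enriched in cDNA, so the value is always >= its reciprocal
    (the printed convention: >1 means the RNA-enriched allele).
    """
    for m in (gdna, cdna):
        if m.allele1_pct <= 0 or m.allele2_pct <= 0:
            raise ValueError(
                f"zero allele percentage for {m.snp} on {m.template}: "
                "ratio undefined (suggests homozygosity)"
            )
    ratio = (cdna.allele1_pct / cdna.allele2_pct) / (gdna.allele1_pct / gdna.allele2_pct)
    if favor == "rna_enriched":
        return max(ratio, 1.0 / ratio)
    if favor != "allele1":
        raise ValueError(f"favor must be 'allele1' or 'rna_enriched', got {favor!r}")
    return ratio


def replicate_variation(measurements: list[PyroMeasurement]) -> tuple[float, float]:
    """Replicate agreement for one SNP/template: (mean |pairwise diff|, sample sd).

    Both statistics are on allele1 percentages.  At least two replicates are
    required.
    """
    if len(measurements) < 2:
        raise ValueError("replicate_variation requires >= 2 replicates")
    keys = {(m.snp, m.template) for m in measurements}
    if len(keys) > 1:
        raise ValueError(f"replicates mix SNP/template combinations: {sorted(keys)}")
    vals = [m.allele1_pct for m in measurements]
    diffs = [abs(a - b) for a, b in itertools.combinations(vals, 2)]
    return sum(diffs) / len(diffs), statistics.stdev(vals)


def validate_snp(
    gdna: PyroMeasurement,
    cdna: PyroMeasurement,
    detect_threshold_pct: float = 4.0,
    gdna_het_band: tuple[float, float] = (30.0, 70.0),
    favor: str = "allele1",
) -> PyroResult:
    """Decide validated / not validated for one SNP.

    Heterozygosity is confirmed when the gDNA allele-1 percentage lies in
    ``gdna_het_band``; the SNP is validated when, additionally, the
    cDNA-vs-gDNA allele-1 shift exceeds ``detect_threshold_pct`` (the
    replicate-derived detectability limit).
    """
    lo, hi = gdna_het_band
    het = lo <= gdna.allele1_pct <= hi
    shift = abs(cdna.allele1_pct - gdna.allele1_pct)
    return PyroResult(
        snp=gdna.snp,
        ase_ratio=ase_ratio(gdna, cdna, favor=favor),
        gdna_allele1_pct=gdna.allele1_pct,
        cdna_allele1_pct=cdna.allele1_pct,
        heterozygous_confirmed=het,
        validated=bool(het and shift > detect_threshold_pct),
    )
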