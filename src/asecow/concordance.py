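"""DNA/RNA genotype concordance classification and summaries.

Sites called in both assays for an individual are classified into four
classes by their genotype pair:

* ``BH`` — both homozygous (concordant),
* ``Bh`` — both heterozygous (concordant; the ASE candidate class),
* ``Hh`` — homozygous in DNA, heterozygous in RNA (discordant; the pattern
  RNA editing produces),
* ``hH`` — heterozygous in DNA, homozygous in RNA (discordant; the pattern
  genomic imprinting / mono-allelic expression produces).

Only heterozygous-concordant (``Bh``) sites are carried forward to allelic
imbalance testing, which removes imprinting- and editing-driven discordance
from the candidate set.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_hom(self) -> bool:
        return self in (Genotype.HOM_REF, Genotype.HOM_ALT)


class PairClass(str, enum.Enum):
    BH = "BH"  # both homozygous
    Bh = "Bh"  # both heterozygous
    Hh = "Hh"  # DNA hom / RNA het
    hH = "hH"  # DNA het / RNA hom


#: dosage encoding used throughout the package: alt-allele copies, -1 = missing
DOSAGE_TO_GT = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT, -1: Genotype.MISSING}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention for rates)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def classify_pair(dna_gt: Genotype | str, rna_gt: Genotype | str) -> PairClass:
    """Classify one overlapping DNA/RNA genotype pair.

    Raises ``ValueError`` for missing genotypes: the caller is expected to
    route single-assay sites to the dna_only / rna_only tallies instead.
    """
    dna_gt, rna_gt = Genotype(dna_gt), Genotype(rna_gt)
    if dna_gt is Genotype.MISSING or rna_gt is Genotype.MISSING:
        raise ValueError("cannot classify a pair with a missing genotype")
    if dna_gt.is_hom and rna_gt.is_hom:
        return PairClass.BH
    if dna_gt is Genotype.HET and rna_gt is Genotype.HET:
        return PairClass.Bh
    if dna_gt.is_hom:  # RNA het
        return PairClass.Hh
    return PairClass.hH  # DNA het, RNA hom


@dataclass
class ConcordanceSummary:
    """Per-individual (or averaged) concordance tallies and rates.

    Rates are percentages of the overlap; ``rates_defined`` is False when the
    overlap is zero, in which case rates are NaN (never silently 0).
    """

    individual: str
    dna_only: float = 0
    rna_only: float = 0
    BH: float = 0
    Bh: float = 0
    Hh: float = 0
    hH: float = 0
    concordant_rate: float = field(default=float("nan"))
    discordant_rate: float = field(default=float("nan"))
    hh_fraction_of_discordant: float = field(default=float("nan"))
    rates_defined: bool = False

    @property
    def overlap(self) -> float:
        return self.BH + self.Bh + self.Hh + self.hH


def summarize_concordance(
    pairs=None,
    individual: str = "",
    *,
    counts: dict | None = None,
    dna_only: float = 0,
    rna_only: float = 0,
) -> ConcordanceSummary:
    """Tally pair classes and compute concordance rates for one individual.

    ``pairs`` is an iterable of :class:`PairClass` (or a DataFrame with a
    ``pair_class`` column); alternatively pass ``counts`` with keys
    BH/Bh/Hh/hH directly.  Rates are kept at full precision; use
    :func:`round_half_up` when printing.
    """
    s = ConcordanceSummary(individual=individual, dna_only=dna_only, rna_only=rna_only)
    if counts is not None:
        for k in ("BH", "Bh", "Hh", "hH"):
            setattr(s, k, counts.get(k, 0))
    else:
        if isinstance(pairs, pd.DataFrame):
            pairs = pairs["pair_class"].tolist()
        for c in pairs:
            c = PairClass(c)
            setattr(s, c.value, getattr(s, c.value) + 1)
    ov = s.overlap
    if ov > 0:
        s.concordant_rate = 100.0 * (s.BH + s.Bh) / ov
        s.discordant_rate = 100.0 * (s.Hh + s.hH) / ov
        s.rates_defined = True
    disc = s.Hh + s.hH
    if disc > 0:
        s.hh_fraction_of_discordant = 100.0 * s.Hh / disc
    return s


@dataclass
class CohortConcordance:
    """Cohort-level averages over per-individual summaries.

    Two cohort concordance figures are deliberately distinct and both
    reported: ``mean_concordant_rate`` is the unweighted mean of the
    per-individual rates; ``pooled_concordant_rate`` weights individuals by
    their overlap (ratio of mean concordant count to mean overlap).
    """

    n_individuals: int
    mean_counts: dict
    mean_concordant_rate: float
    mean_discordant_rate: float
    pooled_concordant_rate: float
    bh_share_of_concordant: float
    hh_fraction_of_discordant: float


def cohort_concordance(summaries: list[ConcordanceSummary]) -> CohortConcordance:
    """Average per-individual summaries into cohort-level figures."""
    if not summaries:
        raise ValueError("cohort_concordance requires at least one individual summary")
    defined = [s for s in summaries if s.rates_defined]
    if not defined:
        raise ValueError("no individual has a non-empty DNA/RNA overlap")
    mean = lambda vals: sum(vals) / len(vals)
    mc = {k: mean([getattr(s, k) for s in summaries]) for k in ("dna_only", "rna_only", "BH", "Bh", "Hh", "hH")}
    m_ov = mc["BH"] + mc["Bh"] + mc["Hh"] + mc["hH"]
    m_conc = mc["BH"] + mc["Bh"]
    m_disc = mc["Hh"] + mc["hH"]
    return CohortConcordance(
        n_individuals=len(summaries),
        mean_counts=mc,
        mean_concordant_rate=mean([s.concordant_rate for s in defined]),
        mean_discordant_rate=mean([s.discordant_rate for s in defined]),
        pooled_concordant_rate=100.0 * m_conc / m_ov,
        bh_share_of_concordant=100.0 * mc["BH"] / m_conc if m_conc else float("nan"),
        hh_fraction_of_discordant=100.0 * mc["Hh"] / m_disc if m_disc else float("nan"),
    )


def pair_genotype_tables(dna: pd.DataFrame, rna: pd.DataFrame) -> pd.DataFrame:
    """Join per-site genotype tables from the two assays.

    Both inputs are long tables with columns
    ``chrom, pos, individual, gt`` (``gt`` values from :class:`Genotype`).
    Returns the merged table with columns ``dna_gt, rna_gt, pair_class``;
    ``pair_class`` is NaN where either assay is missing or uncalled, with a
    ``status`` column of overlap / dna_only / rna_only.
    """
    key = ["chrom", "pos", "individual"]
    merged = dna.rename(columns={"gt": "dna_gt"}).merge(
        rna.rename(columns={"gt": "rna_gt"}), on=key, how="outer"
    )
    missing = Genotype.MISSING.value
    dna_called = merged["dna_gt"].notna() & (merged["dna_gt"] != missing)
    rna_called = merged["rna_gt"].notna() & (merged["rna_gt"] != missing)
    merged["status"] = "overlap"
    merged.loc[dna_called & ~rna_called, "status"] = "dna_only"
    merged.loc[~dna_called & rna_called, "status"] = "rna_only"
    merged = merged[dna_called | rna_called].copy()
    both = merged["status"] == "overlap"
    merged["pair_class"] = pd.NA
    merged.loc[both, "pair_class"] = [
        classify_pair(d, r).value
        for d, r in zip(merged.loc[both, "dna_gt"], merged.loc[both, "rna_gt"])
    ]
    return merged


def select_ase_candidates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep only heterozygous-concordant (Bh) sites, per individual.

    Imprinted-looking (hH) and edited-looking (Hh) sites are excluded by
    construction, as are both-homozygous sites where no allelic comparison
    is possible.
    """
    return pairs[pairs["pair_class"] == PairClass.Bh.value][
        ["chrom", "pos", "individual"]
    ].reset_index(drop=True)


def summarize_by_individual(pairs: pd.DataFrame) -> list[ConcordanceSummary]:
    """Per-individual summaries from a paired table (see pair_genotype_tables)."""
    out = []
    for ind, grp in pairs.groupby("individual", sort=True):
        ov = grp[grp["status"] == "overlap"]
        out.append(
            summarize_concordance(
                ov["pair_class"].tolist(),
                individual=str(ind),
                dna_only=int((grp["status"] == "dna_only").sum()),
                rna_only=int((grp["status"] == "rna_only").sum()),
            )
        )
    return out


def concordance_table(summaries: list[ConcordanceSummary]) -> pd.DataFrame:
    """Cohort concordance as a table, one row per individual plus Average."""
    rows = []
    for s in summaries + [None]:
        if s is None:
            c = cohort_concordance(summaries)
            rows.append(
                {
                    "individual": "Average",
                    **{k: c.mean_counts[k] for k in ("dna_only", "rna_only")},
                    "overlap": sum(c.mean_counts[k] for k in ("BH", "Bh", "Hh", "hH")),
                    **{k: c.mean_counts[k] for k in ("BH", "Bh", "Hh", "hH")},
                    "concordant_pct": round_half_up(c.mean_concordant_rate),
                    "discordant_pct": round_half_up(c.mean_discordant_rate),
                }
            )
        else:
            rows.append(
                {
                    "individual": s.individual,
                    "dna_only": s.dna_only,
                    "rna_only": s.rna_only,
                    "overlap": s.overlap,
                    "BH": s.BH,
                    "Bh": s.Bh,
                    "Hh": s.Hh,
                    "hH": s.hH,
                    "concordant_pct": round_half_up(s.concordant_rate) if s.rates_defined else float("nan"),
                    "discordant_pct": round_half_up(s.discordant_rate) if s.rates_defined else float("nan"),
                }
            )
    return pd.DataFrame(rows)
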