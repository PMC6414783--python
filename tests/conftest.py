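"""Shared fixtures: published per-individual concordance tallies and the
pyrosequencing validation panel, plus small synthetic cohorts."""

import pandas as pd
import pytest

from asecow.synthetic import SimConfig, generate_cohort

# Published per-individual DNA/RNA genotype-pair tallies for the 19-animal
# cohort: (BH, Bh, Hh, hH, printed concordant %).
COHORT_TABLE = {
    "LIM01": (27410, 11354, 4979, 1118, 86.4),
    "LIM02": (29535, 12671, 3974, 444, 90.5),
    "LIM03": (31024, 16413, 1633, 651, 95.4),
    "LIM04": (23198, 12968, 1149, 1264, 93.7),
    "LIM05": (22687, 11637, 1513, 509, 94.4),
    "LIM06": (27925, 12860, 3295, 808, 90.9),
    "LIM07": (9088, 3439, 1947, 601, 83.1),
    "LIM08": (35061, 17430, 2306, 916, 94.2),
    "LIM09": (21119, 9012, 2897, 445, 90.0),
    "LIM13": (18020, 3671, 6707, 253, 75.7),
    "LIM14": (22388, 9932, 1796, 570, 93.2),
    "LIM15": (25775, 10135, 3931, 557, 88.9),
    "LIM16": (22612, 11854, 890, 562, 96.0),
    "LIM17": (17675, 3677, 6863, 200, 75.1),
    "LIM18": (15029, 8585, 902, 377, 94.9),
    "LIM19": (25083, 11315, 3573, 557, 89.8),
    "LIM20": (12190, 4423, 2753, 389, 84.1),
    "LIM21": (19059, 6466, 4147, 359, 85.0),
    "LIM22": (45999, 24815, 5907, 839, 91.3),
}

# Published pyrosequencing panel: (ref allele, alt allele, ref reads, alt reads)
PYRO_PANEL = {
    "rs382378456": ("C", "A", 407, 336),  # ATP5F1 3'UTR, validated
    "rs208775256": ("G", "C", 26, 12),    # PGLS missense, not validated
    "rs41255587": ("G", "A", 146, 208),   # CAST 3'UTR, validated
    "rs209641420": ("A", "C", 303, 221),  # CAST 3'UTR, validated
    "rs110694123": ("G", "A", 48, 73),    # PALLD synonymous, validated
    "rs109919583": ("C", "T", 47, 121),   # CBR4 3'UTR, validated
}


@pytest.fixture(scope="session")
def cohort_table() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        COHORT_TABLE, orient="index", columns=["BH", "Bh", "Hh", "hH", "printed_rate"]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort exercising every discordance process."""
    return generate_cohort(
        SimConfig(
            n_snps=120,
            p_imprinting=0.05,
            p_editing=0.05,
            p_genotype_error=0.01,
            p_ase_site=0.2,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with every discordance process switched off."""
    return generate_cohort(
        SimConfig(
            n_snps=80,
            p_imprinting=0.0,
            p_editing=0.0,
            p_genotype_error=0.0,
            seed=11,
        )
    )
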