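"""Standard-format adapters: VCF, BED, TSV tables, FASTA, PWM text, JSON.

Coordinate conventions at the boundaries: VCF positions are 1-based and are
kept 1-based internally (the pipeline is variant-centric); BED intervals
are 0-based half-open and converted to :class:`~asecow.ase.Region` at read
time.  Genotypes travel as alt-allele dosage matrices (0/1/2, -1 missing).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from asecow.ase import Region

_GT_FIELD = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
# cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_CYVCF2_TO_DOSAGE = {0: 0, 1: 1, 2: -1, 3: 2}


def write_vcf(
    path,
    snps: pd.DataFrame,
    dosage: pd.DataFrame,
    contig_lengths: dict | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT genotypes.

    ``snps`` needs columns snp_id, chrom, pos, ref, alt; ``dosage`` is
    snp x individual indexed by snp_id.
    """
    samples = list(dosage.columns)
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for c in sorted(contig_lengths):
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ordered = snps.sort_values(["chrom", "pos"])
    for _, s in ordered.iterrows():
        gts = "\t".join(_GT_FIELD[int(d)] for d in dosage.loc[s["snp_id"]])
        lines.append(
            f"{s['chrom']}\t{s['pos']}\t{s['snp_id']}\t{s['ref']}\t{s['alt']}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_genotypes(path) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Read biallelic SNP genotypes from a VCF.

    Returns (variant table, dosage matrix, n_skipped_multiallelic).
    Multi-allelic records are excluded from pairing (SNV-only analysis).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        snp_id = v.ID or f"{v.CHROM}:{v.POS}"
        rows.append({"snp_id": snp_id, "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]})
        dosages.append([_CYVCF2_TO_DOSAGE[int(t)] for t in v.gt_types])
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosage = pd.DataFrame(
        np.array(dosages, dtype=np.int64).reshape(len(rows), len(samples)),
        index=snps["snp_id"],
        columns=samples,
    )
    return snps, dosage, skipped


def dosage_to_long(snps: pd.DataFrame, dosage: pd.DataFrame) -> pd.DataFrame:
    """Genotype-class long table (chrom, pos, individual, gt) from a dosage matrix."""
    gt_name = {0: "hom_ref", 1: "het", 2: "hom_alt", -1: "missing"}
    long = dosage.reset_index(names="snp_id").melt(
        id_vars="snp_id", var_name="individual", value_name="d"
    )
    long = long.merge(snps[["snp_id", "chrom", "pos"]], on="snp_id")
    long["gt"] = long["d"].map(gt_name)
    return long[["chrom", "pos", "individual", "gt"]]


def read_bed(path) -> list[Region]:
    """BED (0-based half-open) to Region list; 4th column is the label."""
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from e
        label = parts[3] if len(parts) > 3 else f"region{lineno}"
        try:
            regions.append(Region(chrom=parts[0], start=start, end=end, label=label))
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from e
    return regions


def write_bed(path, regions: list[Region]) -> None:
    lines = [f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}" for r in regions]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_allele_counts(path, counts: pd.DataFrame) -> None:
    counts[["chrom", "pos", "individual", "ref_count", "alt_count"]].to_csv(
        path, sep="\t", index=False
    )


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "individual", "ref_count", "alt_count"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: allele-count table missing columns {sorted(missing)}")
    return df


def write_matrix(path, matrix: pd.DataFrame, index_name: str = "transcript") -> None:
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA to a plain {name: sequence} dict (random access via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def read_pwms(path) -> dict[str, np.ndarray]:
    """Simple PWM text: '>id' then 4 whitespace-separated rows (A, C, G, T)."""
    pwms: dict[str, np.ndarray] = {}
    name, rows = None, []
    def flush():
        if name is not None:
            if len(rows) != 4:
                raise ValueError(f"PWM {name}: expected 4 rows (A,C,G,T), got {len(rows)}")
            pwms[name] = np.array(rows, dtype=float)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name, rows = line[1:].strip(), []
        else:
            rows.append([float(x) for x in line.split()])
    flush()
    return pwms


def write_pwms(path, pwms: dict[str, np.ndarray]) -> None:
    chunks = []
    for name, m in pwms.items():
        chunks.append(f">{name}")
        chunks.extend("\t".join(f"{x:g}" for x in row) for row in np.asarray(m))
    Path(path).write_text("\n".join(chunks) + "\n")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_pyro_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"snp", "individual", "template", "replicate", "allele1_pct", "allele2_pct"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: pyro table missing columns {sorted(missing)}")
    return df
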