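"""Allele-specific regulatory-site differencing: miRNA seeds and PWM TFBS.

For a candidate regulatory SNP two flanking sequences are built, one per
allele, and both are scanned for (a) miRNA target sites and (b) PWM
transcription-factor binding sites.  Sites present for exactly one allele
are the candidates for an allele-specific regulatory mechanism (e.g. a
miRNA that represses only the transcript carrying one allele).

The miRNA scan is a seed-plus-extension scheme: a candidate site requires
perfect Watson-Crick complementarity between miRNA positions 2-8 (the seed,
7mer-m8 core) and the target read 5'->3', with the duplex antiparallel.
Sites are classed 8mer when the target base opposite miRNA position 1 is an
A (the canonical A1 anchor), else 7mer-m8.  The remainder of the miRNA
(positions 9..L) is scored ungapped against the upstream target bases:
+5 per Watson-Crick pair, +1 per G:U wobble, -3 per mismatch, with the seed
contributing +5 per pair; a site passes at score >= min_score (default 60).
This is a deliberately transparent stand-in for heuristic duplex aligners:
same biology (seed match plus 3' pairing support), fully specified scoring.

Sequences may be DNA or RNA alphabet; everything is normalised to DNA
internally (U -> T).  N never pairs: it blocks a seed and scores as a
mismatch in the extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PAIR_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
# G:U wobble in DNA alphabet: miRNA G pairs target T, miRNA T (=U) pairs target G
PAIR_WOBBLE = {("G", "T"), ("T", "G")}

SEED_START = 1  # 0-based miRNA index of seed start (position 2)
SEED_END = 8    # exclusive; seed = positions 2..8


def normalize_seq(seq: str) -> str:
    """Uppercase, RNA->DNA (U->T); reject non-nucleotide characters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class ScanParams:
    """Scoring knobs for the seed-plus-extension miRNA scan."""

    min_score: int = 60
    wc_score: int = 5
    wobble_score: int = 1
    mismatch_score: int = -3
    allow_wobble: bool = True  # G:U permitted outside the seed


@dataclass
class MiRNASiteHit:
    mirna_id: str
    position: int  # 0-based start of the seed match on the target
    seed_class: str  # 8mer | 7mer-m8
    score: int
    passes_threshold: bool


@dataclass
class AlleleFlanks:
    """Per-allele flanking sequences centred on a SNP."""

    chrom: str
    pos: int  # 1-based SNP position
    ref_sequence: str
    alt_sequence: str
    snp_offset: int  # index of the variant base within each sequence
    radius: int
    truncated: bool = False

    def __post_init__(self):
        r, a = self.ref_sequence, self.alt_sequence
        if len(r) != len(a):
            raise ValueError("allele flank sequences must have equal length")
        diffs = [i for i, (x, y) in enumerate(zip(r, a)) if x != y]
        if diffs != [self.snp_offset]:
            raise ValueError(
                f"flank sequences must differ exactly at snp_offset {self.snp_offset}; differ at {diffs}"
            )

    def swapped(self) -> "AlleleFlanks":
        """The same locus with reference and alternate alleles exchanged."""
        return AlleleFlanks(
            chrom=self.chrom,
            pos=self.pos,
            ref_sequence=self.alt_sequence,
            alt_sequence=self.ref_sequence,
            snp_offset=self.snp_offset,
            radius=self.radius,
            truncated=self.truncated,
        )


@dataclass
class AlleleSiteDiff:
    """Regulatory sites present for exactly one allele of a SNP."""

    mirnas_ref_only: list = field(default_factory=list)
    mirnas_alt_only: list = field(default_factory=list)
    mirnas_both: list = field(default_factory=list)
    tfbs_ref_only: list = field(default_factory=list)
    tfbs_alt_only: list = field(default_factory=list)


def extract_flanks(genome, chrom: str, pos: int, ref_allele: str, alt_allele: str, radius: int) -> AlleleFlanks:
    """Build the two allele flank sequences around a SNP.

    ``genome`` is a mapping chrom -> sequence (a ``pyfaidx.Fasta`` works:
    values are sliced and stringified).  ``pos`` is 1-based.  The genome
    base at the SNP must equal ``ref_allele``; flanks are truncated (and
    flagged) at contig ends.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    seq = str(genome[chrom][:])
    if not (1 <= pos <= len(seq)):
        raise ValueError(f"SNP position {chrom}:{pos} outside contig of length {len(seq)}")
    genome_base = seq[pos - 1].upper()
    ref_allele, alt_allele = normalize_seq(ref_allele), normalize_seq(alt_allele)
    if genome_base != ref_allele:
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: genome has {genome_base}, variant claims {ref_allele}"
        )
    start = max(0, pos - 1 - radius)
    end = min(len(seq), pos + radius)
    window = normalize_seq(seq[start:end])
    offset = pos - 1 - start
    ref_seq = window
    alt_seq = window[:offset] + alt_allele + window[offset + 1:]
    return AlleleFlanks(
        chrom=chrom,
        pos=pos,
        ref_sequence=ref_seq,
        alt_sequence=alt_seq,
        snp_offset=offset,
        radius=radius,
        truncated=(end - start) < 2 * radius + 1,
    )


def _pair_score(mirna_base: str, target_base: str, params: ScanParams) -> int:
    if "N" in (mirna_base, target_base):
        return params.mismatch_score
    if (mirna_base, target_base) in PAIR_WC:
        return params.wc_score
    if params.allow_wobble and (mirna_base, target_base) in PAIR_WOBBLE:
        return params.wobble_score
    return params.mismatch_score


def mirna_scan(
    target_sequence: str,
    mirna_sequence: str,
    params: ScanParams | None = None,
    mirna_id: str = "",
) -> list[MiRNASiteHit]:
    """Scan a target (5'->3') for seed-anchored miRNA sites.

    The duplex is antiparallel: a seed match at target positions
    [i, i+6] pairs miRNA positions 8..2, the base at i+7 faces miRNA
    position 1 (A there upgrades the class to 8mer), and positions 9..L
    extend over target indices i-1, i-2, ...  Bases beyond the target edge
    count as mismatches.
    """
    params = params or ScanParams()
    target = normalize_seq(target_sequence)
    mirna = normalize_seq(mirna_sequence)
    if not (18 <= len(mirna) <= 26):
        raise ValueError(f"miRNA length {len(mirna)} outside the mature-miRNA range 18-26 nt")
    seed = mirna[SEED_START:SEED_END]  # positions 2..8
    seed_target = revcomp(seed)  # what the target must read 5'->3'
    if "N" in seed_target:
        return []
    hits = []
    w = len(seed_target)
    for i in range(len(target) - w + 1):
        if target[i:i + w] != seed_target:
            continue
        a1 = target[i + w] if i + w < len(target) else ""
        seed_class = "8mer" if a1 == "A" else "7mer-m8"
        score = params.wc_score * w
        for k in range(SEED_END, len(mirna)):  # miRNA positions 9..L
            j = i - (k - SEED_END + 1)
            if j < 0:
                score += params.mismatch_score
            else:
                score += _pair_score(mirna[k], target[j], params)
        hits.append(
            MiRNASiteHit(
                mirna_id=mirna_id,
                position=i,
                seed_class=seed_class,
                score=score,
                passes_threshold=score >= params.min_score,
            )
        )
    return hits


def scan_mirna_panel(
    flanks: AlleleFlanks,
    mirnas: dict[str, str],
    params: ScanParams | None = None,
) -> tuple[dict[str, list[MiRNASiteHit]], dict[str, list[MiRNASiteHit]]]:
    """Scan both allele flanks against a panel of miRNAs."""
    ref_hits: dict[str, list[MiRNASiteHit]] = {}
    alt_hits: dict[str, list[MiRNASiteHit]] = {}
    for mid, seq in mirnas.items():
        ref_hits[mid] = mirna_scan(flanks.ref_sequence, seq, params, mirna_id=mid)
        alt_hits[mid] = mirna_scan(flanks.alt_sequence, seq, params, mirna_id=mid)
    return ref_hits, alt_hits


def differential_sites(
    ref_hits: dict[str, list[MiRNASiteHit]],
    alt_hits: dict[str, list[MiRNASiteHit]],
) -> AlleleSiteDiff:
    """Partition miRNAs into ref-only / alt-only / both by passing hits.

    Presence is binary per flank: at least one passing hit anywhere in the
    sequence.  A site away from the SNP appears for both alleles and is
    therefore excluded from the differential lists.
    """
    def binds(hits: dict[str, list[MiRNASiteHit]]) -> set:
        return {mid for mid, hs in hits.items() if any(h.passes_threshold for h in hs)}

    ref_set, alt_set = binds(ref_hits), binds(alt_hits)
    return AlleleSiteDiff(
        mirnas_ref_only=sorted(ref_set - alt_set),
        mirnas_alt_only=sorted(alt_set - ref_set),
        mirnas_both=sorted(ref_set & alt_set),
    )


# ---------------------------------------------------------------------------
# PWM transcription-factor binding-site scan

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWMMatch:
    pwm_id: str
    position: int
    strand: str  # + / -
    score: float
    score_fraction: float


def pwm_match(
    sequence: str,
    pwm: np.ndarray,
    score_fraction_threshold: float = 0.85,
    pwm_id: str = "",
) -> list[PWMMatch]:
    """Windows on either strand scoring >= threshold x (max attainable score).

    ``pwm`` is a 4 x width array of log-odds scores, rows ordered A,C,G,T.
    N scores -inf, so any window containing N cannot match.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError("PWM must be a 4 x width matrix (rows A,C,G,T)")
    seq = normalize_seq(sequence)
    width = pwm.shape[1]
    if width > len(seq):
        return []
    max_score = float(pwm.max(axis=0).sum())
    matches = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for i in range(len(s) - width + 1):
            window = s[i:i + width]
            score = 0.0
            for j, b in enumerate(window):
                if b == "N":
                    score = float("-inf")
                    break
                score += pwm[BASE_INDEX[b], j]
            if score == float("-inf"):
                continue
            frac = score / max_score if max_score > 0 else float("-inf")
            if frac >= score_fraction_threshold:
                pos = i if strand == "+" else len(seq) - width - i
                matches.append(PWMMatch(pwm_id=pwm_id, position=pos, strand=strand, score=score, score_fraction=frac))
    return matches


def differential_tfbs(
    flanks: AlleleFlanks,
    pwms: dict[str, np.ndarray],
    score_fraction_threshold: float = 0.85,
) -> AlleleSiteDiff:
    """PWMs matching exactly one allele flank."""
    ref_set = {
        pid for pid, m in pwms.items()
        if pwm_match(flanks.ref_sequence, m, score_fraction_threshold, pid)
    }
    alt_set = {
        pid for pid, m in pwms.items()
        if pwm_match(flanks.alt_sequence, m, score_fraction_threshold, pid)
    }
    return AlleleSiteDiff(
        tfbs_ref_only=sorted(ref_set - alt_set),
        tfbs_alt_only=sorted(alt_set - ref_set),
    )
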