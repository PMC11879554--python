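"""Allele-pair sequence divergence: codon alignment, NG86 Ka/Ks, 4DTv.

The substitution-rate estimator is the Nei–Gojobori (1986) counting method:
each codon position contributes the fraction of its three possible point
mutations that are synonymous to the synonymous site count S (mutations to
stop codons count as nonsynonymous); codons differing at several positions
are resolved by averaging synonymous/nonsynonymous difference counts over
all shortest mutational pathways that avoid stop codons. Proportions are
corrected for multiple hits with the Jukes–Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``.

4DTv is the fraction of fourfold-degenerate third-codon positions (both
codons in a fourfold family with identical first two bases) that differ by a
transversion — a saturation-robust divergence clock used for WGD dating.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Data import CodonTable

from .core import InputError

BASES = "ACGT"
PURINES = {"A", "G"}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_standard.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: codon families whose third position is fourfold degenerate
FOURFOLD_PREFIXES = {
    p2
    for p2 in ("".join(t) for t in itertools.product(BASES, repeat=2))
    if len({CODON_TO_AA[p2 + b] for b in BASES}) == 1
    and all(p2 + b not in STOP_CODONS for b in BASES)
}


def is_transversion(b1: str, b2: str) -> bool:
    return b1 != b2 and ((b1 in PURINES) != (b2 in PURINES))


@dataclass
class CodonAlignment:
    """Paired codon columns; ``None`` marks a gap in one sequence."""

    columns: list[tuple[str | None, str | None]]

    @property
    def n_codons(self) -> int:
        return len(self.columns)

    def ungapped(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in self.columns
            if a is not None and b is not None and "N" not in a and "N" not in b
        ]


@dataclass
class DivergenceStats:
    identity: float
    ka: float
    ks: float
    ka_ks: float
    four_dtv: float
    S: float
    N: float
    Sd: float
    Nd: float
    flags: list[str] = field(default_factory=list)


def _prepare(seq: str, label: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) < 3:
        raise InputError(f"{label}: sequence shorter than one codon")
    if len(seq) % 3:
        warnings.warn(
            f"{label}: length {len(seq)} not a multiple of 3; trailing bases trimmed",
            stacklevel=3,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _translate(codons: list[str]) -> str:
    return "".join(CODON_TO_AA.get(c, "X") for c in codons)


def align_codon_pair(
    cds_a: str,
    cds_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> CodonAlignment:
    """Globally align two CDS at the protein level and back-thread to codons.

    Internal stop codons in *both* sequences are rejected; a trailing stop
    codon (or none) is fine.
    """
    codons_a = _prepare(cds_a, "cds_a")
    codons_b = _prepare(cds_b, "cds_b")
    prot_a = _translate(codons_a)
    prot_b = _translate(codons_b)
    if "*" in prot_a[:-1] and "*" in prot_b[:-1]:
        raise InputError("both sequences contain internal stop codons")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(prot_a, prot_b)[0]

    columns: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    for col_a, col_b in zip(aln[0], aln[1]):
        ca = codons_a[ia] if col_a != "-" else None
        cb = codons_b[ib] if col_b != "-" else None
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
        columns.append((ca, cb))
    return CodonAlignment(columns=columns)


# ---------------------------------------------------------------------------
# NG86 site and difference counting


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon."""
    syn = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            # mutations to stops count as nonsynonymous (standard NG86)
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


_SITE_CACHE = {
    c: _codon_site_counts(c)
    for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
    if c not in STOP_CODONS
}


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over shortest pathways.

    Pathways through stop codons are excluded; if every pathway passes
    through a stop, all pathways are used instead (degenerate but defined).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = non = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if not through_stop and CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1.0
            elif not through_stop:
                non += 1.0
            cur = nxt
        if through_stop:
            # recompute counting every step, for the fallback average
            cur = codon_a
            syn = non = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    syn += 1.0
                else:
                    non += 1.0
                cur = nxt
            fallback.append((syn, non))
        else:
            pathways.append((syn, non))
    chosen = pathways or fallback
    syn = sum(p[0] for p in chosen) / len(chosen)
    non = sum(p[1] for p in chosen) / len(chosen)
    return syn, non


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance; requires ``p < 3/4``."""
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_ka_ks(aln: CodonAlignment) -> DivergenceStats:
    """NG86 Ka/Ks and 4DTv over the ungapped codon columns of an alignment."""
    pairs = [
        (a, b)
        for a, b in aln.ungapped()
        if a not in STOP_CODONS and b not in STOP_CODONS
    ]
    if not pairs:
        raise InputError("no ungapped, stop-free codon columns to analyse")

    S = N = 0.0
    Sd = Nd = 0.0
    for a, b in pairs:
        sa, na = _SITE_CACHE[a]
        sb, nb = _SITE_CACHE[b]
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_differences(a, b)
        Sd += sd
        Nd += nd

    flags: list[str] = []
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    if pS >= 0.75 or pN >= 0.75:
        flags.append("jc_correction_undefined")
        ks = math.nan if pS >= 0.75 else jukes_cantor(pS)
        ka = math.nan if pN >= 0.75 else jukes_cantor(pN)
    else:
        ks = jukes_cantor(pS)
        ka = jukes_cantor(pN)

    if ks and ks > 0 and not math.isnan(ks) and not math.isnan(ka):
        ka_ks = ka / ks
    else:
        ka_ks = math.nan
        flags.append("ka_ks_undefined")

    return DivergenceStats(
        identity=pair_identity(aln),
        ka=ka,
        ks=ks,
        ka_ks=ka_ks,
        four_dtv=four_dtv(aln, strict=False),
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        flags=flags,
    )


def four_dtv(aln: CodonAlignment, strict: bool = True) -> float:
    """Transversion fraction at shared fourfold-degenerate third positions."""
    n_sites = 0
    n_tv = 0
    for a, b in aln.ungapped():
        if a[:2] != b[:2]:
            continue
        if a[:2] not in FOURFOLD_PREFIXES:
            continue
        n_sites += 1
        if is_transversion(a[2], b[2]):
            n_tv += 1
    if n_sites == 0:
        if strict:
            raise InputError("no fourfold-degenerate sites in alignment")
        return math.nan
    return n_tv / n_sites


def pair_identity(aln: CodonAlignment) -> float:
    """Matching nucleotides / total nucleotides over ungapped codon columns."""
    total = matches = 0
    for a, b in aln.ungapped():
        for x, y in zip(a, b):
            total += 1
            matches += x == y
    if total == 0:
        raise InputError("alignment has no ungapped columns")
    return matches / total


def divergence_table(
    pairs,
    cds_a: dict[str, str],
    cds_b: dict[str, str],
):
    """Per-locus divergence statistics for a list of :class:`AllelePair`."""
    import pandas as pd

    rows = []
    for pair in pairs:
        aln = align_codon_pair(cds_a[pair.gene_a], cds_b[pair.gene_b])
        st = ng86_ka_ks(aln)
        rows.append(
            {
                "locus_id": pair.locus_id,
                "gene_a": pair.gene_a,
                "gene_b": pair.gene_b,
                "identity": st.identity,
                "ka": st.ka,
                "ks": st.ks,
                "ka_ks": st.ka_ks,
                "four_dtv": st.four_dtv,
                "S": st.S,
                "N": st.N,
                "Sd": st.Sd,
                "Nd": st.Nd,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
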