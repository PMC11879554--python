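"""Haplotype asymmetry of histone-mark occupancy and DNA methylation.

Occupancy is RPKM-style: reads over the gene body plus a configurable
flank, per kb of region per million mapped reads, with partial bins
weighted by overlap. Asymmetry is summarized per dominance class and mark
as the median dominant-minus-recessive occupancy difference, a Wilcoxon
rank-sum comparison against the balanced (HA = HB) class, and the
coefficient of variation of the differences within the class.

The weighted methylation level of a region is the summed methylated read
count over the summed coverage of its covered cytosines, per sequence
context (CG, CHG, CHH); zero-coverage sites are excluded.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinnedTrack, DominanceCall, GeneModel, InputError

DEFAULT_FLANK_BP = 1000

CONTEXTS = ("CG", "CHG", "CHH")


def _region_signal(track: BinnedTrack, chrom: str, start: int, end: int) -> float:
    """Read count over [start, end), partial bins weighted by overlap."""
    if chrom not in track.counts:
        raise InputError(f"chromosome {chrom} not in track")
    w = track.bin_width
    counts = track.counts[chrom]
    clen = len(counts) * w
    start, end = max(0, start), min(end, clen)
    if start >= end:
        raise InputError("region outside track bounds")
    first, last = start // w, (end - 1) // w
    total = 0.0
    for b in range(first, last + 1):
        ov = min(end, (b + 1) * w) - max(start, b * w)
        total += counts[b] * ov / w
    return total


def gene_mark_occupancy(
    track: BinnedTrack, gene: GeneModel, flank_bp: int = DEFAULT_FLANK_BP
) -> float:
    """Reads per kb per million mapped over the gene body +/- flank."""
    chrom_len = track.chrom_length(gene.chrom) if gene.chrom in track.counts else 0
    start = max(0, gene.start - flank_bp)
    end = min(gene.end + flank_bp, chrom_len) if chrom_len else gene.end + flank_bp
    reads = _region_signal(track, gene.chrom, start, end)
    region_len = end - start
    return reads * 1e9 / (track.library_size * region_len)


def occupancy_table(
    tracks: dict[str, BinnedTrack],
    genes: list[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Per-gene, per-mark occupancy for one haplotype's tracks."""
    rows = []
    for mark, track in sorted(tracks.items()):
        for g in genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "haplotype": g.haplotype,
                    "mark": mark,
                    "occupancy": gene_mark_occupancy(track, g, flank_bp),
                }
            )
    return pd.DataFrame(rows)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) == 0 or len(y) == 0:
        return math.nan
    if np.ptp(np.concatenate([x, y])) == 0:  # all-tie degenerate case
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def asymmetry_summary(
    occ_a: pd.DataFrame,
    occ_b: pd.DataFrame,
    pairs,
    dominance: list[DominanceCall],
) -> pd.DataFrame:
    """Per dominance class and mark: median dominant-recessive difference,
    rank-sum P against the HA_eq_HB class, and coefficient of variation.

    ``occ_a``/``occ_b`` are :func:`occupancy_table` outputs for HA and HB.
    Classes with fewer than two loci are flagged ``insufficient``.
    """
    pair_by_locus = {p.locus_id: p for p in pairs}
    klass = {d.locus_id: d.dominance for d in dominance}
    a = occ_a.set_index(["gene_id", "mark"])["occupancy"]
    b = occ_b.set_index(["gene_id", "mark"])["occupancy"]

    marks = sorted(occ_a["mark"].unique())
    diffs: dict[tuple[str, str], list[float]] = {}
    occs: dict[tuple[str, str], list[float]] = {}
    for locus_id, dom in klass.items():
        pair = pair_by_locus.get(locus_id)
        if pair is None:
            continue
        for mark in marks:
            va = a.get((pair.gene_a, mark))
            vb = b.get((pair.gene_b, mark))
            if va is None or vb is None:
                continue
            # dominant minus recessive; HA - HB for the balanced class
            d = vb - va if dom == "HA_lt_HB" else va - vb
            diffs.setdefault((dom, mark), []).append(d)
            occs.setdefault((dom, mark), []).extend([va, vb])

    rows = []
    for dom in DominanceCall.CLASSES:
        for mark in marks:
            dvals = np.asarray(diffs.get((dom, mark), []), dtype=float)
            ovals = np.asarray(occs.get((dom, mark), []), dtype=float)
            eq = np.asarray(diffs.get(("HA_eq_HB", mark), []), dtype=float)
            insufficient = len(dvals) < 2
            cv = (
                float(ovals.std() / ovals.mean())
                if len(ovals) and ovals.mean() > 0
                else math.nan
            )
            rows.append(
                {
                    "dominance": dom,
                    "mark": mark,
                    "n_loci": len(dvals),
                    "median_diff": float(np.median(dvals)) if len(dvals) else math.nan,
                    "p_vs_balanced": math.nan if insufficient else _rank_sum_p(dvals, eq),
                    "cv_occupancy": cv,
                    "insufficient": insufficient,
                }
            )
    return pd.DataFrame(rows)


def weighted_methylation_level(
    records: pd.DataFrame,
    region: tuple[str, int, int] | None = None,
    context: str | None = None,
) -> float:
    """Sum(methylated) / Sum(coverage) over covered sites; NaN if none.

    ``region`` is (chrom, start, end) with 0-based half-open coordinates
    applied to the report's 1-based positions; ``context`` restricts to
    CG/CHG/CHH, or all contexts when None.
    """
    sub = records
    if context is not None:
        if context not in CONTEXTS:
            raise InputError(f"unknown context {context!r}")
        sub = sub[sub["context"] == context]
    if region is not None:
        chrom, start, end = region
        pos0 = sub["pos"] - 1
        sub = sub[(sub["chrom"] == chrom) & (pos0 >= start) & (pos0 < end)]
    cov = sub["count_methylated"] + sub["count_unmethylated"]
    covered = cov > 0
    if not covered.any():
        return math.nan
    return float(sub.loc[covered, "count_methylated"].sum() / cov[covered].sum())
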