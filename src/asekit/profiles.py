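"""Metagene and exon-position signal profiles of a ChIP mark.

The metagene profile rescales every gene body to 20 equal bins and adds
1 kb flanks in fixed 50-bp bins, oriented 5'->3'; per-bin values are
per-kb per-million normalized and averaged across the genes of a stratum
(an FPKM expression bin or an ASEG dominance class). The exon-position
view reports per-kb per-million signal over the first three exons, the
5' UTR plus first CDS segment, and TSS +/- 1 kb.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .core import BinnedTrack, GeneModel, InputError

N_BODY_BINS = 20
FLANK_BP = 1000
FLANK_BIN_BP = 50

EXPRESSION_BIN_LABELS = ("0", "0-1", "1-10", "10-20", ">20")


def expression_bins(fpkm: pd.Series) -> pd.Series:
    """FPKM strata: {0}, (0,1], (1,10], (10,20], (20, inf)."""
    if (fpkm < 0).any():
        raise InputError("negative FPKM values")
    bins = pd.cut(
        fpkm,
        bins=[-np.inf, 0, 1, 10, 20, np.inf],
        labels=EXPRESSION_BIN_LABELS,
        right=True,
    )
    return bins.astype(str)


class _Density:
    """Per-bp read density with O(1) interval sums via cumulative sums."""

    def __init__(self, track: BinnedTrack):
        self.track = track
        self.cum = {
            c: np.concatenate([[0.0], np.cumsum(np.repeat(a / track.bin_width,
                                                          track.bin_width))])
            for c, a in track.counts.items()
        }

    def mean_per_kb_per_million(self, chrom: str, start: int, end: int) -> float:
        """Per-kb per-million signal over [start, end), clipped to the chrom."""
        cum = self.cum[chrom]
        clen = len(cum) - 1
        s, e = max(0, start), min(end, clen)
        if s >= e:
            return math.nan
        reads = cum[e] - cum[s]
        return reads / ((e - s) / 1000.0) / (self.track.library_size / 1e6)


def metagene_profile(
    track: BinnedTrack,
    genes: list[GeneModel],
    strata: dict[str, str] | pd.Series,
    n_body_bins: int = N_BODY_BINS,
    flank_bp: int = FLANK_BP,
    flank_bin_bp: int = FLANK_BIN_BP,
) -> pd.DataFrame:
    """Mean per-bin normalized signal per stratum.

    Rows are strata; columns run upstream flank, scaled gene body, then
    downstream flank in transcript orientation. Genes shorter than
    ``n_body_bins`` bp are skipped with a warning; flank bins truncated by
    a chromosome end average over the covered width only (NaN if fully
    outside), and stratum means ignore NaNs.
    """
    strata = pd.Series(dict(strata)) if not isinstance(strata, pd.Series) else strata
    n_flank_bins = flank_bp // flank_bin_bp
    width = 2 * n_flank_bins + n_body_bins
    dens = _Density(track)

    per_stratum: dict[str, list[np.ndarray]] = {}
    for g in genes:
        if g.gene_id not in strata.index:
            continue
        if g.length < n_body_bins:
            warnings.warn(f"gene {g.gene_id} shorter than {n_body_bins} bp; skipped")
            continue
        if g.chrom not in track.counts:
            raise InputError(f"gene {g.gene_id}: chromosome not in track")
        prof = np.empty(width)
        # upstream flank (genomic left for +, right for -)
        edges = np.linspace(g.start, g.end, n_body_bins + 1)
        for i in range(n_body_bins):
            prof[n_flank_bins + i] = dens.mean_per_kb_per_million(
                g.chrom, int(round(edges[i])), int(round(edges[i + 1]))
            )
        for i in range(n_flank_bins):
            left = dens.mean_per_kb_per_million(
                g.chrom,
                g.start - flank_bp + i * flank_bin_bp,
                g.start - flank_bp + (i + 1) * flank_bin_bp,
            )
            right = dens.mean_per_kb_per_million(
                g.chrom,
                g.end + i * flank_bin_bp,
                g.end + (i + 1) * flank_bin_bp,
            )
            prof[i] = left
            prof[n_flank_bins + n_body_bins + i] = right
        if g.strand == "-":
            prof = prof[::-1]
        per_stratum.setdefault(str(strata[g.gene_id]), []).append(prof)

    rows = {}
    for label, profs in per_stratum.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[label] = np.nanmean(np.vstack(profs), axis=0)
    cols = (
        [f"up{i + 1}" for i in range(n_flank_bins)]
        + [f"body{i + 1}" for i in range(n_body_bins)]
        + [f"down{i + 1}" for i in range(n_flank_bins)]
    )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def exon_position_signal(
    track: BinnedTrack, genes: list[GeneModel], tss_flank: int = 1000
) -> pd.DataFrame:
    """Per-gene per-kb per-million signal in positional regions.

    Columns: ``exon1``/``exon2``/``exon3`` (transcript order; NaN when the
    gene has fewer than three exons), ``utr5_cds1`` (union of annotated
    5' UTR and the first CDS segment; NaN without CDS annotation) and
    ``tss_1kb`` (TSS +/- 1 kb, strand-oriented).
    """
    dens = _Density(track)
    rows = []
    for g in genes:
        exons = g.exons_5to3()
        row: dict[str, float] = {"gene_id": g.gene_id}
        for i in range(3):
            if i < len(exons):
                s, e = exons[i]
                row[f"exon{i + 1}"] = dens.mean_per_kb_per_million(g.chrom, s, e)
            else:
                row[f"exon{i + 1}"] = math.nan
        if g.cds:
            regions = g.utr5() + [g.cds_5to3()[0]]
            reads = 0.0
            bp = 0
            for s, e in regions:
                v = dens.mean_per_kb_per_million(g.chrom, s, e)
                if not math.isnan(v):
                    reads += v * (e - s)
                    bp += e - s
            row["utr5_cds1"] = reads / bp if bp else math.nan
        else:
            row["utr5_cds1"] = math.nan
        tss = g.tss
        row["tss_1kb"] = dens.mean_per_kb_per_million(
            g.chrom, tss - tss_flank, tss + tss_flank
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
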