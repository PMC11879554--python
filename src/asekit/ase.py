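"""Expression normalization and allelic-bias classification.

Per tissue, each allelic locus is classified into one of four bias
categories from the haplotype fold change FC = mean(HA)/mean(HB) on TPM
values: no significant difference (P >= 0.05), smaller (FC <= |2|,
P < 0.05), larger (|2| < FC < |8|, P < 0.05) and largest (FC >= |8|,
P < 0.05). Significance is a two-sided Welch t-test on log2(TPM + 1)
across replicates; no multiple-testing correction is applied. Loci whose
combined mean TPM is below 1 are not tested (``not_expressed``).

Across tissues, a locus is an allele-specifically expressed gene (ASEG)
when at least one tissue shows FC > 2 at P < 0.05 and all such tissues
agree on the dominant haplotype; direction conflicts demote the locus to
``HA_eq_HB``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import AllelePair, BiasCall, DominanceCall, InputError

PSEUDOCOUNT_TPM = 0.1
MIN_COMBINED_TPM = 1.0
ALPHA = 0.05
SMALLER_MAX_L2FC = 1.0  # FC 2
LARGEST_MIN_L2FC = 3.0  # FC 8


def normalize(
    counts: pd.DataFrame, gene_lengths: pd.Series, method: str = "TPM"
) -> pd.DataFrame:
    """TPM or FPKM normalization of a genes x samples raw count matrix."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise InputError("gene_lengths missing for some genes")
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise InputError(f"zero library size for samples {bad}")
    if method == "TPM":
        rate = counts.div(lengths, axis=0)
        return rate.div(rate.sum(axis=0), axis=1) * 1e6
    if method == "FPKM":
        return counts.mul(1e9).div(lib, axis=1).div(lengths, axis=0)
    raise InputError(f"unknown normalization method {method!r}")


def classify_allelic_bias(
    pairs: list[AllelePair],
    tpm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    tissue: str,
    alpha: float = ALPHA,
) -> list[BiasCall]:
    """Per-locus bias category in one tissue (see module docstring)."""
    if not {"tissue", "replicate"} <= set(sample_meta.columns):
        raise InputError("sample_meta needs 'tissue' and 'replicate' columns")
    samples = sample_meta.index[sample_meta["tissue"] == tissue]
    if len(samples) < 2:
        raise InputError(f"tissue {tissue!r} has fewer than 2 replicates")

    calls = []
    sub = tpm[samples]
    for pair in pairs:
        va = sub.loc[pair.gene_a].to_numpy(dtype=float)
        vb = sub.loc[pair.gene_b].to_numpy(dtype=float)
        mean_a, mean_b = va.mean(), vb.mean()
        if mean_a + mean_b < MIN_COMBINED_TPM:
            calls.append(
                BiasCall(pair.locus_id, tissue, math.nan, math.nan,
                         "not_expressed", "none")
            )
            continue
        l2fc = math.log2((mean_a + PSEUDOCOUNT_TPM) / (mean_b + PSEUDOCOUNT_TPM))
        with np.errstate(all="ignore"):
            _, p = stats.ttest_ind(
                np.log2(va + 1.0), np.log2(vb + 1.0), equal_var=False
            )
        if math.isnan(p):  # zero variance in both groups
            p = 1.0 if np.allclose(va.mean(), vb.mean()) else 0.0
        if p >= alpha or l2fc == 0.0:
            calls.append(BiasCall(pair.locus_id, tissue, l2fc, p, "no_bias", "none"))
            continue
        a = abs(l2fc)
        if a <= SMALLER_MAX_L2FC:
            category = "smaller"
        elif a < LARGEST_MIN_L2FC:
            category = "larger"
        else:
            category = "largest"
        direction = "HA" if l2fc > 0 else "HB"
        calls.append(BiasCall(pair.locus_id, tissue, l2fc, p, category, direction))
    return calls


ASEG_CATEGORIES = ("larger", "largest")  # FC > 2, P < 0.05


def aggregate_asegs(
    calls: list[BiasCall],
) -> tuple[list[DominanceCall], float]:
    """Aggregate per-tissue bias calls into haplotype-dominance classes.

    Returns the dominance calls and the consistency fraction: the share of
    loci whose every testable tissue agrees on one biased category and
    direction.
    """
    by_locus: dict[str, list[BiasCall]] = {}
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.locus_id, c.tissue)
        if key in seen:
            raise InputError(f"duplicate call for locus {c.locus_id} in {c.tissue}")
        seen.add(key)
        by_locus.setdefault(c.locus_id, []).append(c)

    dominance = []
    n_consistent = 0
    for locus_id, lcalls in by_locus.items():
        qualifying = [c for c in lcalls if c.category in ASEG_CATEGORIES]
        directions = {c.direction for c in qualifying}
        if len(directions) == 1:
            d = directions.pop()
            dominance.append(
                DominanceCall(
                    locus_id,
                    "HA_gt_HB" if d == "HA" else "HA_lt_HB",
                    supporting_tissues=sorted(c.tissue for c in qualifying),
                )
            )
        else:  # no qualifying tissue, or direction conflict
            dominance.append(DominanceCall(locus_id, "HA_eq_HB"))
        testable = [c for c in lcalls if c.category != "not_expressed"]
        biased = {(c.category, c.direction) for c in testable}
        if testable and len(biased) == 1 and "no_bias" not in next(iter(biased)):
            n_consistent += 1
    consistency = n_consistent / len(by_locus) if by_locus else math.nan
    return dominance, consistency


def dominance_summary(class_counts: dict[str, int]) -> dict[str, float]:
    """Class proportions (percent) and totals from dominance-class counts.

    Accepts counts keyed by the three dominance classes; also derives the
    ASEG count and the total number of allelic genes (two per locus).
    """
    unknown = set(class_counts) - set(DominanceCall.CLASSES)
    if unknown:
        raise InputError(f"unknown dominance classes: {sorted(unknown)}")
    total = sum(class_counts.values())
    if total == 0:
        raise InputError("no loci in summary")
    out = {
        f"pct_{k.lower()}": 100.0 * class_counts.get(k, 0) / total
        for k in DominanceCall.CLASSES
    }
    out["n_loci"] = float(total)
    out["n_aseg"] = float(
        class_counts.get("HA_gt_HB", 0) + class_counts.get("HA_lt_HB", 0)
    )
    out["n_allelic_genes"] = 2.0 * total
    return out


def dominance_class_counts(dominance: list[DominanceCall]) -> dict[str, int]:
    counts = {k: 0 for k in DominanceCall.CLASSES}
    for d in dominance:
        counts[d.dominance] += 1
    return counts
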