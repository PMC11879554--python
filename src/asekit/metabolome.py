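"""Differential metabolite calling via fold change, Welch test and PLS-DA VIP.

Variable importance in projection (VIP) scores come from a two-class
PLS-DA on autoscaled log-free intensities (NIPALS PLS, as implemented in
scikit-learn), with

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

so that the mean squared VIP equals 1. A metabolite is a differentially
accumulated metabolite (DAM) when VIP >= 1, |log2FC| >= 1 and the Welch
P value on log2 intensities is < 0.05.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .core import InputError

VIP_THRESHOLD = 1.0
L2FC_THRESHOLD = 1.0
ALPHA = 0.05


def _validate_groups(intensities: pd.DataFrame, groups: pd.Series) -> list[str]:
    groups = groups.reindex(intensities.columns)
    if groups.isna().any():
        raise InputError("every sample needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise InputError("exactly two groups are required")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise InputError(f"group {lv!r} has fewer than 2 replicates")
    return levels


def impute_zeros(intensities: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Replace zero intensities with half the metabolite's minimum positive value."""
    out = intensities.copy().astype(float)
    flagged = []
    for m in out.index:
        row = out.loc[m]
        if (row <= 0).any():
            positive = row[row > 0]
            if positive.empty:
                raise InputError(f"metabolite {m} has no positive intensities")
            out.loc[m, row <= 0] = positive.min() / 2.0
            flagged.append(m)
    return out, flagged


def plsda_vip(
    intensities: pd.DataFrame, groups: pd.Series, n_components: int = 2
) -> pd.Series:
    """VIP score per metabolite from a two-class PLS-DA.

    Zero-variance metabolites are excluded (VIP = NaN). Raises on a fully
    degenerate contrast (identical group means for every metabolite).
    """
    levels = _validate_groups(intensities, groups)
    n_samples = intensities.shape[1]
    if not 1 <= n_components < min(n_samples, len(intensities)):
        raise InputError("n_components must be >= 1 and < min(samples, metabolites)")

    X_full = intensities.T.to_numpy(dtype=float)  # samples x metabolites
    sd = X_full.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise InputError("all metabolites have zero variance")
    X = X_full[:, keep]
    X = (X - X.mean(axis=0)) / X[:, :].std(axis=0, ddof=1)
    y = (groups.reindex(intensities.columns) == levels[1]).to_numpy(dtype=float)
    y = (y - y.mean()) / y.std(ddof=1)

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    W = pls.x_weights_  # p x A
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # 1 x A
    ssy = (T ** 2).sum(axis=0) * Q[0] ** 2
    if ssy.sum() <= 0:
        raise InputError("degenerate contrast: groups have identical means")
    wnorm2 = (W ** 2).sum(axis=0)
    vip_kept = np.sqrt(
        X.shape[1] * ((W ** 2 / wnorm2) @ ssy) / ssy.sum()
    )
    vip = np.full(len(intensities), np.nan)
    vip[keep] = vip_kept
    return pd.Series(vip, index=intensities.index, name="vip")


def call_dams(
    intensities: pd.DataFrame,
    groups: pd.Series,
    vip: pd.Series,
    alpha: float = ALPHA,
    l2fc_threshold: float = L2FC_THRESHOLD,
    vip_threshold: float = VIP_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """DAM status per metabolite plus (n_up, n_down, n_total) summary.

    log2FC is group1 over group2 with groups in sorted label order;
    significance is a two-sided Welch t-test on log2 intensities.
    """
    levels = _validate_groups(intensities, groups)
    missing = set(intensities.index) - set(vip.index)
    if missing:
        raise InputError(f"VIP missing for metabolites: {sorted(missing)[:5]}")
    groups = groups.reindex(intensities.columns)
    cols1 = intensities.columns[groups == levels[0]]
    cols2 = intensities.columns[groups == levels[1]]

    m1 = intensities[cols1].mean(axis=1)
    m2 = intensities[cols2].mean(axis=1)
    l2fc = np.log2(m1 / m2)
    logi = np.log2(intensities)
    with np.errstate(all="ignore"):
        p = stats.ttest_ind(
            logi[cols1], logi[cols2], axis=1, equal_var=False
        ).pvalue
    p = pd.Series(p, index=intensities.index).fillna(1.0)

    status = pd.Series("not_dam", index=intensities.index)
    sig = (p < alpha) & (vip.reindex(intensities.index) >= vip_threshold)
    status[sig & (l2fc >= l2fc_threshold)] = "up"
    status[sig & (l2fc <= -l2fc_threshold)] = "down"

    table = pd.DataFrame(
        {
            "log2fc": l2fc,
            "p_value": p,
            "vip": vip.reindex(intensities.index),
            "status": status,
        }
    )
    summary = {
        "n_up": int((status == "up").sum()),
        "n_down": int((status == "down").sum()),
        "n_total": int(len(status)),
    }
    return table, summary
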