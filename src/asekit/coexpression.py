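"""Co-expression modules: soft-threshold adjacency, TOM, clustering, merging.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta, with beta
the smallest candidate power whose scale-free topology fit exceeds 0.85
(fit index: signed R^2 of the log10 p(k) ~ log10 k regression). Modules
are average-linkage clusters of the topological-overlap dissimilarity
1 - TOM cut at a static height, with clusters below the minimum size sent
to "grey" and modules merged while their eigengenes' correlation distance
is below the merge cut height (0.15 by default). Eigengenes are the first
principal component of the standardized module expression, signed to
correlate positively with the module's mean expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import InputError

SCALE_FREE_TARGET = 0.85
MIN_MODULE_SIZE = 40
MERGE_CUT_HEIGHT = 0.15
GREY = "grey"


def adjacency_matrix(expr: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned adjacency |Pearson r|^power between gene expression rows."""
    corr = np.corrcoef(expr.to_numpy(dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return np.abs(corr) ** power


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 mean(k) over connectivity bins.

    Follows the WGCNA convention: the fit is -sign(slope) * R^2, so only
    decreasing degree distributions can reach a high index.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return math.nan
    # equal-width bins: equal-frequency bins would flatten p(k) by design
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    means, freqs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (k >= lo) & (k < hi)
        if mask.sum() == 0:
            continue
        means.append(k[mask].mean())
        freqs.append(mask.mean())
    if len(means) < 3:
        return math.nan
    res = stats.linregress(np.log10(means), np.log10(freqs))
    return float(-np.sign(res.slope) * res.rvalue ** 2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 13)),
    target: float = SCALE_FREE_TARGET,
) -> tuple[int, dict[int, float]]:
    """Smallest power whose scale-free fit exceeds ``target``.

    Falls back to the largest candidate (with a warning) when no power
    reaches the target. Requires at least four samples for stable
    correlations.
    """
    if expr.shape[1] < 4:
        raise InputError("need at least 4 samples for correlation networks")
    if len(candidate_powers) < 2:
        raise InputError("need at least 2 candidate powers")
    fits: dict[int, float] = {}
    for power in sorted(candidate_powers):
        adj = adjacency_matrix(expr, power)
        np.fill_diagonal(adj, 0.0)
        fits[power] = scale_free_fit(adj.sum(axis=1))
        if fits[power] > target:
            return power, fits
    warnings.warn(
        f"no candidate power reached scale-free fit {target}; "
        f"using the maximum candidate"
    )
    return max(candidate_powers), fits


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, with k the connectivity excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise InputError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise InputError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module label ("grey" = unassigned)
    eigengenes: pd.DataFrame  # samples x modules


def _eigengene(expr_module: pd.DataFrame) -> np.ndarray:
    """First PC scores over samples, signed toward the module mean profile."""
    X = expr_module.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    norm = np.linalg.norm(pc)
    return pc / norm if norm > 0 else pc


def detect_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    min_size: int = MIN_MODULE_SIZE,
    merge_cut: float = MERGE_CUT_HEIGHT,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Static-cut hierarchical modules on 1 - TOM with eigengene merging.

    ``cut_height`` defaults to the 0.8 quantile of the dendrogram merge
    heights, which separates tight clusters from the diffuse top of the
    tree. Clusters smaller than ``min_size`` become "grey"; modules are
    then merged while any two eigengenes are closer than ``merge_cut`` in
    correlation distance. Final labels are M1, M2, ... by decreasing size.
    """
    genes = list(expr.index)
    if tom.shape != (len(genes), len(genes)):
        raise InputError("TOM shape does not match expression gene count")
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    if cut_height is None:
        cut_height = float(np.quantile(Z[:, 2], 0.8))
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for gene, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(gene)
    modules = [g for g in clusters.values() if len(g) >= min_size]
    if not modules:
        warnings.warn("all genes unassigned (grey): no cluster reached min_size")
        labels = pd.Series(GREY, index=expr.index, name="module")
        return ModuleAssignment(labels=labels,
                                eigengenes=pd.DataFrame(index=expr.columns))

    # iterative eigengene merging
    while True:
        eigs = np.vstack([_eigengene(expr.loc[m]) for m in modules])
        if len(modules) < 2:
            break
        cor = np.corrcoef(eigs)
        dist = 1.0 - cor
        np.fill_diagonal(dist, np.inf)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= merge_cut:
            break
        modules[i] = modules[i] + modules[j]
        del modules[j]

    modules.sort(key=len, reverse=True)
    labels = pd.Series(GREY, index=expr.index, name="module")
    eig_cols = {}
    for rank, members in enumerate(modules, start=1):
        name = f"M{rank}"
        labels.loc[members] = name
        eig_cols[name] = _eigengene(expr.loc[members])
    eigengenes = pd.DataFrame(eig_cols, index=expr.columns)
    return ModuleAssignment(labels=labels, eigengenes=eigengenes)


def module_trait_correlation(
    assignment: ModuleAssignment, trait: pd.Series
) -> pd.DataFrame:
    """Pearson r and t-distribution P of each eigengene against a trait."""
    trait = trait.reindex(assignment.eigengenes.index)
    if trait.isna().any():
        raise InputError("trait value missing for some samples")
    rows = []
    degenerate = trait.std(ddof=0) == 0
    for module in assignment.eigengenes.columns:
        if degenerate:
            rows.append({"module": module, "r": math.nan, "p": math.nan,
                         "flag": "constant_trait"})
            continue
        r, p = stats.pearsonr(assignment.eigengenes[module], trait)
        rows.append({"module": module, "r": float(r), "p": float(p), "flag": ""})
    return pd.DataFrame(rows).set_index("module")
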