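"""Chromatin-state segmentation with a multivariate-Bernoulli HMM.

Binned read counts (200-bp bins by default) are first binarized per mark by
an upper-tail Poisson test against a control-scaled (or global-mean)
expectation, as done by the standard segmentation tools. A K-state hidden
Markov model with independent Bernoulli emissions per mark is then fitted
by Baum-Welch EM and applied genome-wide by per-bin maximum-posterior
decoding. Chromosomes are treated as independent observation sequences
sharing one parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BinnedTrack, InputError

EMISSION_FLOOR = 1e-4  # keeps Bernoulli log-likelihoods finite


@dataclass
class BinaryChromatinMatrix:
    """Per-chromosome bins x marks presence/absence matrices."""

    arrays: dict[str, np.ndarray]
    mark_names: list[str]
    bin_width: int = 200

    def __post_init__(self) -> None:
        m = len(self.mark_names)
        for chrom, arr in self.arrays.items():
            arr = np.asarray(arr, dtype=np.int8)
            if arr.ndim != 2 or arr.shape[1] != m:
                raise InputError(f"{chrom}: matrix must be bins x {m} marks")
            if not np.isin(arr, (0, 1)).all():
                raise InputError(f"{chrom}: entries must be 0/1")
            self.arrays[chrom] = arr

    @property
    def n_bins(self) -> int:
        return sum(a.shape[0] for a in self.arrays.values())

    def stacked(self) -> np.ndarray:
        return np.vstack([self.arrays[c] for c in sorted(self.arrays)])


@dataclass
class ChromatinStateModel:
    """Emission/transition/initial parameters of a fitted K-state model."""

    K: int
    mark_names: list[str]
    emission: np.ndarray  # K x M, P(mark present | state)
    transition: np.ndarray  # K x K, row-stochastic
    initial: np.ndarray  # K
    log_likelihood_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.emission.shape != (self.K, len(self.mark_names)):
            raise InputError("emission matrix has wrong shape")
        if np.any(self.emission < 0) or np.any(self.emission > 1):
            raise InputError("emission probabilities must lie in [0, 1]")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise InputError("initial distribution must sum to 1")


@dataclass
class Segmentation:
    """Per-bin state labels (0-based) and per-state genome coverage."""

    labels: dict[str, np.ndarray]
    coverage: np.ndarray
    bin_width: int = 200


# ---------------------------------------------------------------------------
# Binarization


def binarize_bins(
    mark: BinnedTrack,
    control: BinnedTrack | None = None,
    p_threshold: float = 1e-4,
) -> dict[str, np.ndarray]:
    """Poisson upper-tail presence calls per bin.

    A bin is set to 1 iff P(X >= count; lambda) < ``p_threshold``. With a
    control track, lambda is the control count (floored at one read)
    scaled by the library-size ratio; without one, lambda is the mark's
    global mean count.
    """
    out = {}
    if control is not None:
        if not mark.same_grid(control):
            raise InputError("mark and control tracks are on different bin grids")
        scale = mark.library_size / max(control.library_size, 1)
    total = sum(int(a.sum()) for a in mark.counts.values())
    nbins = sum(len(a) for a in mark.counts.values())
    global_mean = total / max(nbins, 1)
    for chrom, counts in mark.counts.items():
        if control is not None:
            lam = np.maximum(control.counts[chrom], 1) * scale
        else:
            lam = np.full(len(counts), global_mean)
        tail = stats.poisson.sf(counts - 1, lam)  # P(X >= count)
        out[chrom] = (tail < p_threshold).astype(np.int8)
    return out


def binarize_tracks(
    tracks: dict[str, BinnedTrack],
    control: BinnedTrack | None = None,
    p_threshold: float = 1e-4,
) -> BinaryChromatinMatrix:
    """Binarize several marks sharing one grid into a chromatin matrix."""
    mark_names = sorted(tracks)
    columns = {m: binarize_bins(tracks[m], control, p_threshold) for m in mark_names}
    chroms = list(next(iter(columns.values())).keys())
    arrays = {
        c: np.column_stack([columns[m][c] for m in mark_names]) for c in chroms
    }
    return BinaryChromatinMatrix(
        arrays=arrays,
        mark_names=mark_names,
        bin_width=next(iter(tracks.values())).bin_width,
    )


# ---------------------------------------------------------------------------
# Baum-Welch EM


def _emission_likelihood(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """P(x_t | state k) for binary rows; returns T x K."""
    e = np.clip(emission, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
    logb = X @ np.log(e).T + (1 - X) @ np.log(1.0 - e).T
    shift = logb.max(axis=1)
    return np.exp(logb - shift[:, None]), shift


def _forward_backward(B: np.ndarray, logB_shift: np.ndarray,
                      transition: np.ndarray, initial: np.ndarray):
    """Scaled forward-backward; returns gamma, xi-sum, log-likelihood."""
    T, K = B.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = initial * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * B[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (transition @ bb) / scale[t + 1]
        xi_sum += np.outer(alpha[t], bb) * transition / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # undo the per-row shift applied for numerical stability
    loglik = float(np.log(scale).sum() + logB_shift.sum())
    return gamma, xi_sum, loglik


def _init_emissions(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=3, random_state=seed)
    labels = km.fit_predict(X)
    emission = np.empty((K, X.shape[1]))
    for k in range(K):
        members = X[labels == k]
        emission[k] = members.mean(axis=0) if len(members) else X.mean(axis=0)
    return np.clip(emission, 0.05, 0.95)


def fit_chromatin_hmm(
    matrix: BinaryChromatinMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-3,
    n_restarts: int = 3,
) -> ChromatinStateModel:
    """Baum-Welch EM for the independent-Bernoulli-emission HMM.

    Emissions are initialized from K-means cluster means of the mark
    vectors; transitions start near-uniform with 0.9 self-transition. EM is
    restarted ``n_restarts`` times from differently seeded initializations
    and the model with the best final log-likelihood is returned, guarding
    against poor local optima. Each trace is non-decreasing (EM guarantee)
    and fitting stops when the gain drops below ``tol`` or at ``max_iter``.
    """
    best = None
    for r in range(max(n_restarts, 1)):
        model = _fit_once(matrix, K, seed + r, max_iter, tol)
        if best is None or (
            model.log_likelihood_trace[-1] > best.log_likelihood_trace[-1]
        ):
            best = model
    return best


def _fit_once(
    matrix: BinaryChromatinMatrix, K: int, seed: int, max_iter: int, tol: float
) -> ChromatinStateModel:
    if K < 1:
        raise InputError("K must be >= 1")
    if matrix.n_bins == 0:
        raise InputError("empty chromatin matrix")
    if K > matrix.n_bins:
        raise InputError("more states than bins")
    seqs = [matrix.arrays[c].astype(float) for c in sorted(matrix.arrays)]
    X_all = np.vstack(seqs)

    emission = _init_emissions(X_all, K, seed)
    transition = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(transition, 0.9 if K > 1 else 1.0)
    initial = np.full(K, 1.0 / K)

    trace: list[float] = []
    for _ in range(max_iter):
        gamma_sum = np.zeros(K)
        gamma_first = np.zeros(K)
        xi_total = np.zeros((K, K))
        weighted_x = np.zeros((K, X_all.shape[1]))
        loglik = 0.0
        for X in seqs:
            B, shift = _emission_likelihood(X, emission)
            gamma, xi_sum, ll = _forward_backward(B, shift, transition, initial)
            loglik += ll
            gamma_sum += gamma.sum(axis=0)
            gamma_first += gamma[0]
            xi_total += xi_sum
            weighted_x += gamma.T @ X
        trace.append(loglik)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        emission = weighted_x / gamma_sum[:, None]
        emission = np.clip(emission, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
        if K > 1:
            denom = xi_total.sum(axis=1, keepdims=True)
            transition = np.where(denom > 0, xi_total / denom, 1.0 / K)
            transition /= transition.sum(axis=1, keepdims=True)
        initial = gamma_first / gamma_first.sum()

    return ChromatinStateModel(
        K=K,
        mark_names=list(matrix.mark_names),
        emission=emission,
        transition=transition,
        initial=initial,
        log_likelihood_trace=trace,
    )


def state_posteriors(
    model: ChromatinStateModel, X: np.ndarray
) -> np.ndarray:
    """Forward-backward posterior state probabilities for one sequence."""
    B, shift = _emission_likelihood(X.astype(float), model.emission)
    gamma, _, _ = _forward_backward(B, shift, model.transition, model.initial)
    return gamma


def decode_states(
    model: ChromatinStateModel, matrix: BinaryChromatinMatrix
) -> Segmentation:
    """Per-bin maximum-posterior state labels; ties go to the lowest index."""
    if list(model.mark_names) != list(matrix.mark_names):
        raise InputError("model and matrix mark sets differ")
    labels = {}
    counts = np.zeros(model.K)
    for chrom, X in matrix.arrays.items():
        gamma = state_posteriors(model, X)
        lab = np.argmax(gamma, axis=1)  # argmax takes the lowest index on ties
        labels[chrom] = lab
        counts += np.bincount(lab, minlength=model.K)
    return Segmentation(
        labels=labels, coverage=counts / counts.sum(), bin_width=matrix.bin_width
    )


def sample_hmm(
    model: ChromatinStateModel, n_bins: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state path and binary emissions from a model (generator use)."""
    K, M = model.emission.shape
    path = np.empty(n_bins, dtype=np.int64)
    path[0] = rng.choice(K, p=model.initial)
    for t in range(1, n_bins):
        path[t] = rng.choice(K, p=model.transition[path[t - 1]])
    X = (rng.random((n_bins, M)) < model.emission[path]).astype(np.int8)
    return X, path


# ---------------------------------------------------------------------------
# Feature enrichment and model selection


def state_feature_enrichment(
    seg: Segmentation,
    features: list[tuple[str, int, int]],
    genome_size: int,
) -> np.ndarray:
    """Fold enrichment of each state for a feature interval set.

    FE(state) = (overlap/state_bp) / (feature_bp/genome_bp). Empty states
    yield NaN.
    """
    w = seg.bin_width
    K = len(seg.coverage)
    overlap = np.zeros(K)
    feature_bp = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in features:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        # merge overlapping intervals so shared bp are not double-counted
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if chrom not in seg.labels:
            feature_bp += sum(e - s for s, e in merged)
            continue
        labels = seg.labels[chrom]
        clen = len(labels) * w
        for s, e in merged:
            feature_bp += e - s
            s, e = max(0, s), min(e, clen)
            for b in range(s // w, (e + w - 1) // w):
                ov = min(e, (b + 1) * w) - max(s, b * w)
                if ov > 0:
                    overlap[labels[b]] += ov
    state_bp = seg.coverage * sum(len(l) * w for l in seg.labels.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        fe = (overlap / state_bp) / (feature_bp / genome_size)
    fe[state_bp == 0] = np.nan
    return fe


def model_selection_sweep(
    matrix: BinaryChromatinMatrix,
    k_values=range(10, 21),
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-2,
):
    """Log-likelihood and BIC per candidate state count K.

    BIC is reported for guidance only; the choice of K is left to the user.
    """
    import pandas as pd

    n = matrix.n_bins
    M = len(matrix.mark_names)
    rows = []
    for K in k_values:
        model = fit_chromatin_hmm(matrix, K, seed=seed, max_iter=max_iter, tol=tol)
        ll = model.log_likelihood_trace[-1]
        n_params = K * M + K * (K - 1) + (K - 1)
        rows.append(
            {"K": K, "log_likelihood": ll, "n_params": n_params,
             "bic": -2 * ll + n_params * np.log(n)}
        )
    return pd.DataFrame(rows)
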