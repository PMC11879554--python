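"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive results from first principles (explicit loops,
exhaustive enumeration, direct pmf summation) and share no code with the
package paths they check.
"""

from __future__ import annotations

import functools
import itertools
import math

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


@functools.lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_oracle(codons_a: list[str], codons_b: list[str]):
    """NG86 S, N, Sd, Nd, Ka, Ks by exhaustive enumeration."""
    S = N = Sd = Nd = 0.0
    for a, b in zip(codons_a, codons_b):
        if a in STOPS or b in STOPS:
            continue
        for codon in (a, b):
            for i in range(3):
                for base in "ACGT":
                    if base == codon[i]:
                        continue
                    mut = codon[:i] + base + codon[i + 1 :]
                    if mut not in STOPS and _aa(mut) == _aa(codon):
                        S += 1.0 / 6.0  # averaged over the two codons
                    else:
                        N += 1.0 / 6.0
        diff = [i for i in range(3) if a[i] != b[i]]
        if not diff:
            continue
        clean, dirty = [], []
        for perm in itertools.permutations(diff):
            cur, steps = a, []
            for p in perm:
                nxt = cur[:p] + b[p] + cur[p + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            intermediates = [t for _, t in steps[:-1]]
            syn = sum(_aa(x) == _aa(y) for x, y in steps)
            record = (syn, len(steps) - syn)
            if any(c in STOPS for c in intermediates):
                dirty.append(record)
            else:
                clean.append(record)
        use = clean or dirty
        Sd += sum(r[0] for r in use) / len(use)
        Nd += sum(r[1] for r in use) / len(use)
    pS, pN = Sd / S, Nd / N
    ks = -0.75 * math.log(1 - 4 * pS / 3) if pS < 0.75 else math.nan
    ka = -0.75 * math.log(1 - 4 * pN / 3) if pN < 0.75 else math.nan
    return S, N, Sd, Nd, ka, ks


def tom_oracle(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap by the definitional triple loop."""
    a = adjacency.copy().astype(float)
    n = a.shape[0]
    for i in range(n):
        a[i, i] = 0.0
    tom = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            ki = sum(a[i, u] for u in range(n))
            kj = sum(a[j, u] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return tom


def synteny_rules_oracle(block, homolog_map: dict[str, str]) -> bool:
    """Literal evaluation of the three synteny retention rules."""
    on_homologs = homolog_map.get(block.chrom_a) == block.chrom_b
    la = block.end_a - block.start_a
    lb = block.end_b - block.start_b
    ratio_ok = (la <= 3 * lb) and (lb <= 3 * la)
    coverage_ok = block.coverage_a >= 0.5 and block.coverage_b >= 0.5
    return on_homologs and ratio_ok and coverage_ok


def poisson_upper_tail(count: int, lam: float, terms: int = 4000) -> float:
    """P(X >= count) by direct pmf summation from zero."""
    below = 0.0
    pmf = math.exp(-lam)
    for k in range(count):
        below += pmf
        pmf *= lam / (k + 1)
    return 1.0 - below


def scale_free_r2_oracle(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log p(k) vs log k via an explicit least-squares fit."""
    k = connectivity[connectivity > 0]
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = k[(k >= lo) & (k < hi)]
        if len(sel):
            xs.append(math.log10(sel.mean()))
            ys.append(math.log10(len(sel) / len(k)))
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    return float(-np.sign(slope) * r2)
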