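"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the defining formulas with plain
loops / library one-liners, deliberately sharing no code with the package, so
that agreement between the two routes is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_oracle(x: np.ndarray, e: np.ndarray) -> float:
    """Pearson correlation via scipy on raw sequences."""
    return float(stats.pearsonr(x, e).statistic)


def moments_oracle(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, population skewness, non-excess population kurtosis) via scipy."""
    mean = float(np.mean(values))
    sk = float(stats.skew(values, bias=True))
    ku = float(stats.kurtosis(values, fisher=False, bias=True))
    return mean, sk, ku


def minimum_norm_lsq_oracle(m: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares via an explicit SVD pseudoinverse."""
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    tol = max(m.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    s_inv = np.array([1.0 / si if si > tol else 0.0 for si in s])
    return vt.T @ (s_inv * (u.T @ v))


def fds_oracle(d0: np.ndarray, d1: np.ndarray, k: int) -> float:
    """Fisher discriminant score for one feature, by direct summation."""
    a = [float(x) for x in d0[:, k]]
    b = [float(x) for x in d1[:, k]]
    gm = sum(a + b) / len(a + b)
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    sb = (ma - gm) ** 2 + (mb - gm) ** 2
    sw = sum((x - ma) ** 2 for x in a) / len(a) + sum((x - mb) ** 2 for x in b) / len(b)
    if sw == 0.0:
        return math.inf if sb > 0 else 0.0
    return sb / sw


def mahalanobis_ratio_oracle(s: float, c0: np.ndarray, c1: np.ndarray) -> float:
    """Nearer-class-anchored squared-distance ratio, scalar per feature."""

    def dist(vals: np.ndarray) -> float:
        mean = sum(vals) / len(vals)
        var = sum((x - mean) ** 2 for x in vals) / (len(vals) - 1)
        if var == 0.0:
            return 0.0 if s == mean else math.inf
        return (s - mean) ** 2 / var

    m0, m1 = dist(c0), dist(c1)
    near, far = min(m0, m1), max(m0, m1)
    if near == 0.0:
        return 0.0
    if math.isinf(near):
        return math.inf
    if math.isinf(far):
        return 0.0
    return near * near / far


def max_probability_oracle(s: float, c0: np.ndarray, c1: np.ndarray) -> float:
    """Max Gaussian class density at s, via scipy.stats.norm."""

    def dens(vals: np.ndarray) -> float:
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            return math.inf if s == mean else 0.0
        return float(stats.norm.pdf(s, loc=mean, scale=sd))

    return max(dens(c0), dens(c1))


def dfs_cascade_oracle(
    d: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    th_fds: float,
    th_mr: float,
    th_p: float,
) -> np.ndarray:
    """Full cascade by per-feature loops; absolute-density C3 threshold."""
    d0 = d[y == 0]
    d1 = d[y == 1]
    n = d.shape[1]
    mask = np.zeros(n, dtype=bool)
    for k in range(n):
        fds = fds_oracle(d0, d1, k)
        if not fds > th_fds:
            continue
        if not mahalanobis_ratio_oracle(float(s[k]), d0[:, k], d1[:, k]) < th_mr:
            continue
        if not max_probability_oracle(float(s[k]), d0[:, k], d1[:, k]) > th_p:
            continue
        mask[k] = True
    return mask


def auc_oracle(scores: np.ndarray, truths: np.ndarray) -> float:
    """AUC by enumerating all positive/negative pairs; ties count one half."""
    pos = scores[truths == 1]
    neg = scores[truths == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def welch_t_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute Welch t statistic by the textbook formula."""
    ma, mb = float(np.mean(a)), float(np.mean(b))
    va = float(np.var(a, ddof=1)) if len(a) > 1 else 0.0
    vb = float(np.var(b, ddof=1)) if len(b) > 1 else 0.0
    se2 = va / len(a) + vb / len(b)
    diff = abs(ma - mb)
    if se2 == 0.0:
        return 0.0 if diff == 0.0 else math.inf
    return diff / math.sqrt(se2)
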