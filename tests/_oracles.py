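"""Independent reference implementations used only to cross-check the package.

Each oracle solves the same mathematical problem as a library routine by a
deliberately different algorithm (proximal gradient instead of quasi-Newton,
exhaustive enumeration instead of greedy search, trapezoidal ROC integration
instead of rank sums), so agreement is evidence of correctness rather than
of shared code.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp


def prox_gradient_maxent(X_pres: np.ndarray, X_bg: np.ndarray, betas: np.ndarray,
                         max_iter: int = 200_000, tol: float = 1e-10) -> np.ndarray:
    """L1-penalized Gibbs-likelihood maximizer by ISTA with backtracking.

    Maximizes mean_pres(λ·f) − logsumexp_bg(λ·f) − Σβ|λ| by proximal
    gradient steps with soft-thresholding.
    """
    X_pres = np.asarray(X_pres, float)
    X_bg = np.asarray(X_bg, float)
    betas = np.asarray(betas, float)
    fbar = X_pres.mean(axis=0)
    lam = np.zeros(X_pres.shape[1])

    def smooth(l):
        return float(fbar @ l - logsumexp(X_bg @ l))

    def grad(l):
        eta = X_bg @ l
        w = np.exp(eta - logsumexp(eta))
        return fbar - X_bg.T @ w

    step = 1.0
    f_cur = smooth(lam)
    for _ in range(max_iter):
        g = grad(lam)
        while True:
            cand = np.sign(lam + step * g) * np.maximum(
                np.abs(lam + step * g) - step * betas, 0.0)
            d = cand - lam
            # sufficient increase of the smooth part (majorization check)
            if smooth(cand) >= f_cur + g @ d - (d @ d) / (2 * step) - 1e-15:
                break
            step /= 2.0
        lam_new = cand
        f_new = smooth(lam_new)
        if np.max(np.abs(lam_new - lam)) < tol * max(1.0, np.max(np.abs(lam))):
            return lam_new
        lam, f_cur = lam_new, f_new
        step = min(step * 1.5, 1e6)
    return lam


def trapezoid_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """AUC by explicit trapezoidal integration of the empirical ROC curve."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    thresholds = np.unique(np.concatenate([p, b]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append((p >= t).mean())
        fpr.append((b >= t).mean())
    tpr.append(1.0)
    fpr.append(1.0)
    return float(np.trapezoid(tpr, fpr))


def brute_force_thin_optimum(dist: np.ndarray, min_dist_km: float) -> int:
    """Size of the largest subset with all pairwise distances > min_dist_km.

    Exhaustive over all 2^n subsets; n must be small.
    """
    n = dist.shape[0]
    ok = dist > min_dist_km
    best = 0
    for bits in range(1 << n):
        idx = [i for i in range(n) if bits >> i & 1]
        if len(idx) <= best:
            continue
        if all(ok[i, j] for i, j in itertools.combinations(idx, 2)):
            best = len(idx)
    return best


def exhaustive_mtsps(presence: np.ndarray, background: np.ndarray) -> float:
    """MTSPS by exhaustive scan over every midpoint candidate."""
    pooled = np.unique(np.concatenate([presence, background]))
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    vals = [((presence >= t).mean() + (background < t).mean(), -t) for t in candidates]
    best = max(vals)
    return -best[1]


def lexicographic_rank(rows: list[tuple[float, float, float]]) -> list[int]:
    """Order indices by (or10 asc, or0 asc, auc desc) via explicit tuple sort."""
    keyed = [(r[0], r[1], -r[2], i) for i, r in enumerate(rows)]
    return [i for *_, i in sorted(keyed)]
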