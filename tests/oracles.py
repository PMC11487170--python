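"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the ANLS factorizer
below alternates exact scipy NNLS solves from random starts, the
enrichment oracle walks the ranked list literally, and the t oracle is
the closed-form pooled-variance formula.
"""

from itertools import permutations

import numpy as np
from scipy.optimize import nnls
from scipy.special import stdtr


def anls_nmf(X, k, seed, n_restarts=10, max_iter=500, tol=1e-10):
    """Alternating NNLS factorization run to convergence; returns (W, H, err)."""
    X = np.asarray(X, dtype=float)
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + 1000 * r)
        W = rng.random((X.shape[0], k))
        H = np.zeros((k, X.shape[1]))
        prev = np.inf
        for _ in range(max_iter):
            for j in range(X.shape[1]):
                H[:, j], _ = nnls(W, X[:, j])
            for i in range(X.shape[0]):
                W[i, :], _ = nnls(H.T, X[i, :])
            err = np.linalg.norm(X - W @ H)
            if prev - err < tol * max(prev, 1e-30):
                break
            prev = err
        err = np.linalg.norm(X - W @ H)
        if best is None or err < best[2]:
            best = (W, H, err)
    return best


def best_match_correlation(P_hat, P_true):
    """Mean Pearson correlation under the best pattern permutation."""
    k = P_true.shape[0]
    assert P_hat.shape[0] == k
    C = np.corrcoef(np.vstack([P_hat, P_true]))[:k, k:]
    C = np.nan_to_num(C)
    best = -np.inf
    for perm in permutations(range(k)):
        best = max(best, np.mean([C[i, perm[i]] for i in range(k)]))
    return best


def running_sum_es(ranked, members, exponent=1.0):
    """Literal weighted running-sum enrichment score (positive regime)."""
    symbols = [s for s, _ in ranked]
    weights = [w for _, w in ranked]
    members = set(members)
    n = len(symbols)
    n_hits = sum(1 for s in symbols if s in members)
    assert 0 < n_hits < n
    denom = sum(abs(w) ** exponent for s, w in ranked if s in members)
    running = 0.0
    peak = 0.0
    for s, w in ranked:
        if s in members:
            running += (abs(w) ** exponent / denom) if denom > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        peak = max(peak, running)
    return peak


def pooled_t(a, b):
    """Closed-form two-sided pooled-variance two-sample t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * (1 - stdtr(df, abs(t)))
    return t, df, p
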