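"""Independent brute-force reference implementations used only by tests.

These are deliberately naive and share no code with the package: direct
evaluation of the log-likelihood-ratio expression, an O(n^2) textbook
Local Outlier Factor, and a threshold-sweep average precision.
"""

import math

import numpy as np


def g_loglik(c1, c2):
    """Direct evaluation of G = 2*[sum c ln(c/n) terms], 0 ln 0 := 0."""

    def term(c, n):
        return sum(ci * math.log(ci / n) for ci in c if ci > 0)

    n1, n2 = sum(c1), sum(c2)
    tot = [a + b for a, b in zip(c1, c2)]
    return 2.0 * (term(c1, n1) + term(c2, n2) - term(tot, n1 + n2))


def naive_lof(X, k):
    """Textbook LOF: k-distance, reachability distance, lrd, density ratio.

    Exactly k nearest neighbours per point (ties broken by index order);
    coincident points (zero mean reachability) are assigned LOF = 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(D, np.inf)
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k]
    kdist = D[np.arange(n), nbrs[:, -1]]
    lrd = np.empty(n)
    for p in range(n):
        reach = [max(kdist[o], D[p, o]) for o in nbrs[p]]
        m = sum(reach) / k
        lrd[p] = np.inf if m == 0 else 1.0 / m
    lof = np.empty(n)
    for p in range(n):
        num = lrd[nbrs[p]].mean()
        lof[p] = 1.0 if np.isinf(lrd[p]) else num / lrd[p]
    return lof


def sweep_average_precision(y_true, y_score):
    """AP = sum_i (R_i - R_{i-1}) * P_i over descending unique thresholds."""
    y_true = np.asarray(y_true, dtype=bool)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = y_true.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(y_score), reverse=True):
        pred = y_score >= t
        tp = (pred & y_true).sum()
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
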