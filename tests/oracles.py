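"""Independent brute-force oracles used to cross-check the implementation.

Each oracle evaluates its quantity by the most literal route available
(explicit loops, sorting, dense inverses, proximal gradient), sharing no
code with the library paths it checks.
"""

import math

import numpy as np


def mmd_squared_bruteforce(X, Y, sigma):
    """Literal triple-sum evaluation of the expanded squared-MMD kernel form."""
    n, m = len(X), len(Y)

    def k(a, b):
        return math.exp(-float(np.sum((a - b) ** 2)) / (2 * sigma**2))

    s_xx = sum(k(X[i], X[j]) for i in range(n) for j in range(n))
    s_xy = sum(k(X[i], Y[j]) for i in range(n) for j in range(m))
    s_yy = sum(k(Y[i], Y[j]) for i in range(m) for j in range(m))
    return s_xx / n**2 - 2.0 * s_xy / (n * m) + s_yy / m**2


def wasserstein_1d_sorted(a, b):
    """Equal-size 1-D optimal transport: mean |sorted(a) - sorted(b)|."""
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    assert a.shape == b.shape
    return float(np.mean(np.abs(a - b)))


def auc_pairwise(y, scores, positive=1):
    """Mann-Whitney U statistic, normalized: P(s_pos > s_neg) + 0.5 P(tie)."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == positive]
    neg = s[y != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ridge_closed_form_literal(G, Y, beta):
    """Dense literal evaluation of the regularized closed form."""
    L = G.shape[1]
    return np.linalg.inv(G.T @ G + (1.0 / beta) * np.eye(L)) @ G.T @ Y


def lasso_ista(G, y, beta, n_iter=200_000, tol=1e-12):
    """Proximal-gradient (ISTA) solver for 1/2||G w - y||^2 + beta ||w||_1."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    lip = np.linalg.norm(G, 2) ** 2
    step = 1.0 / lip
    w = np.zeros(G.shape[1])
    for _ in range(n_iter):
        grad = G.T @ (G @ w - y)
        w_new = w - step * grad
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * beta, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


def mrmr_greedy_bruteforce(binned, y, n_select, variant="MID"):
    """Greedy mRMR recomputing every mutual-information term at every step.

    ``binned`` is a list of discretized feature columns (ints).
    """
    from sklearn.metrics import mutual_info_score

    p = len(binned)
    relevance = [mutual_info_score(y, b) for b in binned]
    selected = []
    for step in range(n_select):
        best, best_crit = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            if step == 0:
                crit = relevance[j]
            else:
                red = np.mean([mutual_info_score(binned[j], binned[s])
                               for s in selected])
                if variant == "MID":
                    crit = relevance[j] - red
                else:
                    crit = relevance[j] / max(red, 1e-12)
            if crit > best_crit:  # strict: ties keep the lowest index
                best, best_crit = j, crit
        selected.append(best)
    return selected
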