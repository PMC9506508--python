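"""Independent reference implementations used only to check the package.

Deliberately naive: closed forms, exhaustive enumeration and direct
linear algebra, kept free of any admixmet internals so agreement is
meaningful.
"""

import itertools

import numpy as np
from scipy import stats


def grid_admixture(g, p_a, p_e, resolution=1e-6):
    """Maximizer of the binomial admixture log-likelihood on a q-grid.

    Two-stage grid search at the requested resolution: the log-likelihood
    is concave in q (log of an affine function summed over markers), so a
    coarse pass followed by a fine pass around the coarse argmax visits
    the global grid maximizer.
    """
    g = np.asarray(g, dtype=float)

    def ll(qs):
        pi = qs[:, None] * p_a[None, :] + (1 - qs[:, None]) * p_e[None, :]
        pi = np.clip(pi, 1e-300, 1 - 1e-16)
        terms = g[None, :] * np.log(pi) + (2 - g[None, :]) * np.log1p(-pi)
        return np.nansum(terms, axis=1)

    coarse = np.linspace(0.0, 1.0, 1001)
    q0 = coarse[np.argmax(ll(coarse))]
    lo, hi = max(0.0, q0 - 2e-3), min(1.0, q0 + 2e-3)
    fine = np.arange(lo, hi + resolution / 2, resolution)
    return float(fine[np.argmax(ll(fine))])


def bh_stepup(pvals, alpha):
    """Maximal BH rejection set by exhaustive check of all rejection counts."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            best_k = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:best_k]] = True
    return rejected


def ols_normal_equations(y, x):
    """beta, se, t, p for every coefficient via (X'X)^-1 X'y directly."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), n - p)
    return beta, se, t, pvals


def set_partitions(items):
    """All set partitions, generated recursively (independent of any
    restricted-growth-string machinery)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_direct(w, blocks):
    """Q from its definition, summed pair by pair."""
    n = w.shape[0]
    m2 = w.sum()
    k = w.sum(axis=1)
    label = {}
    for ci, block in enumerate(blocks):
        for node in block:
            label[node] = ci
    q = 0.0
    for i in range(n):
        for j in range(n):
            if label[i] == label[j]:
                q += w[i, j] / m2 - k[i] * k[j] / m2 ** 2
    return q


def best_partition_exhaustive(w):
    """Global modularity optimum by brute force over all partitions."""
    n = w.shape[0]
    best_q, best = -np.inf, None
    for blocks in set_partitions(range(n)):
        q = modularity_direct(w, blocks)
        if q > best_q:
            best_q, best = q, blocks
    return best, best_q


def mannwhitney_exact(x, y):
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(a, b):
        return sum(1.0 if ai > bi else 0.5 if ai == bi else 0.0
                   for ai in a for bi in b)

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(a, b)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total
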