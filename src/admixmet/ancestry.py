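"""Supervised two-population admixture estimation from AIM genotypes.

Each individual's global West African ancestry proportion q is the
maximizer of the binomial admixture log-likelihood

    l(q) = sum_m [ g_m * log(pi_m(q)) + (2 - g_m) * log(1 - pi_m(q)) ],
    pi_m(q) = q * p_AFR,m + (1 - q) * p_EUR,m,

where g_m is the counted-allele dosage at marker m and p_AFR/p_EUR are the
ancestral reference allele frequencies (plugged in as known, the standard
supervised convention). l is concave in q (log of an affine function), so
the maximizer is unique whenever any marker is informative. The default
estimator is the EM point estimate; a numerically integrated flat-prior
posterior mean is available for comparison.

Markers are treated as unlinked; missing genotypes are dropped from the
individual's likelihood (missing at random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import POP_AFR, POP_EUR

__all__ = [
    "estimate_panel_frequencies",
    "select_aims",
    "estimate_admixture",
    "assign_ancestry_group",
    "admixture_loglik",
]

DEFAULT_CUTOFF = 0.45


def estimate_panel_frequencies(
    panels: dict[str, pd.DataFrame], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Counted-allele frequencies per population per marker.

    p = (allele count + pseudocount) / (2 * n_observed + 2 * pseudocount).
    The default half-count pseudocount keeps frequencies off 0 and 1 so
    genotypes incompatible with one ancestral origin stay finite in the
    likelihood.

    ``panels`` maps population name to a samples x markers dosage frame
    (0/1/2, NaN missing). All panels must share the marker set.

    Raises ``ValueError`` if any marker is entirely missing in a
    population, listing the offending markers.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    pops = sorted(panels)
    cols = panels[pops[0]].columns
    out = {}
    for pop in pops:
        g = panels[pop]
        if not g.columns.equals(cols):
            raise ValueError("panels must share an identical marker set")
        vals = g.to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        n_obs = observed.sum(axis=0)
        if (n_obs == 0).any():
            bad = cols[n_obs == 0].tolist()
            raise ValueError(f"markers with no observed genotypes in {pop}: {bad}")
        counts = np.nansum(vals, axis=0)
        out[f"p_{pop}"] = (counts + pseudocount) / (2 * n_obs + 2 * pseudocount)
        out[f"n_obs_{pop}"] = n_obs
    freqs = pd.DataFrame(out, index=cols)
    freqs.attrs["pseudocount"] = pseudocount
    return freqs


def select_aims(
    freqs: pd.DataFrame,
    min_diff: float = 0.30,
    pop_a: str = POP_AFR,
    pop_b: str = POP_EUR,
) -> pd.DataFrame:
    """Retain markers with |p_A - p_B| >= min_diff (boundary inclusive).

    Returns the retained rows with an added ``freq_diff`` column;
    ``attrs['n_dropped']`` records the number removed. Raises if nothing
    survives.
    """
    diff = (freqs[f"p_{pop_a}"] - freqs[f"p_{pop_b}"]).abs()
    keep = diff >= min_diff
    if not keep.any():
        raise ValueError(f"no marker reaches |freq diff| >= {min_diff}")
    out = freqs.loc[keep].copy()
    out["freq_diff"] = diff[keep]
    out.attrs["n_retained"] = int(keep.sum())
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def admixture_loglik(
    g: np.ndarray, q: np.ndarray, p_a: np.ndarray, p_e: np.ndarray
) -> np.ndarray:
    """l(q) per individual; ``g`` is (n, m) with NaN for missing."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    pi = q[:, None] * p_a[None, :] + (1 - q[:, None]) * p_e[None, :]
    pi = np.clip(pi, 1e-300, 1 - 1e-16)
    with np.errstate(invalid="ignore"):
        terms = g * np.log(pi) + (2 - g) * np.log1p(-pi)
    return np.nansum(terms, axis=1)


def _newton_polish(
    q: np.ndarray,
    g0: np.ndarray,
    observed: np.ndarray,
    p_a: np.ndarray,
    p_e: np.ndarray,
    valid: np.ndarray,
    n_steps: int = 40,
    eps: float = 1e-12,
) -> np.ndarray:
    """Sharpen EM estimates with damped Newton steps on the concave l(q).

    The score and curvature are
    l'(q)  = sum_m d_m [ g_m / pi_m - (2 - g_m) / (1 - pi_m) ],
    l''(q) = -sum_m d_m^2 [ g_m / pi_m^2 + (2 - g_m) / (1 - pi_m)^2 ],
    with d_m = p_A,m - p_E,m. Steps are clipped into [eps, 1 - eps];
    boundary maxima land on the clip bounds.
    """
    q = q.copy()
    d = p_a - p_e
    for _ in range(n_steps):
        qa = np.clip(q[:, None], eps, 1 - eps)
        pi = qa * p_a + (1 - qa) * p_e
        score_terms = d * (g0 / pi - (2 - g0) / (1 - pi))
        curv_terms = d ** 2 * (g0 / pi ** 2 + (2 - g0) / (1 - pi) ** 2)
        score = np.where(observed, score_terms, 0.0).sum(axis=1)
        curv = np.where(observed, curv_terms, 0.0).sum(axis=1)
        step = np.where(curv > 0, score / np.maximum(curv, 1e-300), 0.0)
        q_new = np.clip(q + step, eps, 1 - eps)
        move = np.where(valid, q_new - q, 0.0)
        q = np.where(valid, q_new, q)
        if np.max(np.abs(move)) < 1e-14:
            break
    return q


def estimate_admixture(
    genotypes: pd.DataFrame,
    freqs: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "mle",
    tol: float = 1e-8,
    max_iter: int = 500,
    pop_a: str = POP_AFR,
    pop_b: str = POP_EUR,
) -> pd.DataFrame:
    """Estimate q for every individual.

    mode="mle" runs EM with allele-level responsibility updates: given q,
    each counted allele copy is African with probability
    q*p_A / (q*p_A + (1-q)*p_E) (and analogously for the other allele);
    the update sets q to the mean responsibility over the individual's
    2 * m_observed allele copies. Convergence when |dq| < ``tol`` or after
    ``max_iter`` sweeps; the EM objective is nondecreasing.

    mode="posterior_mean" integrates q * L(q) / integral(L) on [0, 1]
    under a flat prior (Simpson's rule, log-sum-exp stabilised).

    Returns a DataFrame indexed by individual with columns
    q, group, loglik, n_markers, iterations, converged, identifiable.
    Individuals with zero non-missing markers get q = NaN and
    converged = False.
    """
    if mode not in ("mle", "posterior_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    common = [m for m in genotypes.columns if m in freqs.index]
    if len(common) < len(genotypes.columns):
        missing = set(genotypes.columns) - set(common)
        raise ValueError(f"markers without reference frequencies: {sorted(missing)}")
    g = genotypes.to_numpy(dtype=float)
    p_a = freqs.loc[genotypes.columns, f"p_{pop_a}"].to_numpy()
    p_e = freqs.loc[genotypes.columns, f"p_{pop_b}"].to_numpy()
    if np.any((p_a <= 0) | (p_a >= 1) | (p_e <= 0) | (p_e >= 1)):
        raise ValueError("reference frequencies must lie strictly in (0, 1)")

    n, m = g.shape
    observed = ~np.isnan(g)
    n_markers = observed.sum(axis=1)
    valid = n_markers > 0
    identifiable = np.full(n, bool(np.any(p_a != p_e)))

    q = np.full(n, 0.5)
    iterations = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    g0 = np.where(observed, g, 0.0)

    if mode == "mle":
        active = valid & ~converged
        for it in range(1, max_iter + 1):
            qa = q[:, None]
            pi = qa * p_a + (1 - qa) * p_e
            # responsibility of African origin for counted / other allele copies
            r1 = qa * p_a / pi
            r0 = qa * (1 - p_a) / (1 - pi)
            num = np.where(observed, g0 * r1 + (2 - g0) * r0, 0.0).sum(axis=1)
            q_new = np.where(valid, num / np.maximum(2 * n_markers, 1), q)
            delta = np.abs(q_new - q)
            newly = valid & ~converged & (delta < tol)
            iterations[newly] = it
            converged |= newly
            q = q_new
            if not (valid & ~converged).any():
                break
        iterations[valid & ~converged] = max_iter
        # EM contracts slowly near weakly informative optima; since l(q) is
        # concave a few safeguarded Newton steps finish the job
        if identifiable[0]:
            q = _newton_polish(q, g0, observed, p_a, p_e, valid)
            converged[valid] = True
        else:
            # a flat likelihood never moves q; flag rather than pretend
            converged[:] = False
    else:
        grid = np.linspace(0.0, 1.0, 4097)
        ll = np.empty((n, grid.size))
        for k, qk in enumerate(grid):
            ll[:, k] = admixture_loglik(g, np.full(n, qk), p_a, p_e)
        w = np.exp(ll - ll.max(axis=1, keepdims=True))
        from scipy.integrate import simpson

        num = simpson(w * grid[None, :], x=grid, axis=1)
        den = simpson(w, x=grid, axis=1)
        q = num / den
        converged = valid.copy()
        iterations[:] = 0

    q = np.where(valid, np.clip(q, 0.0, 1.0), np.nan)
    loglik = np.full(n, np.nan)
    loglik[valid] = admixture_loglik(g[valid], q[valid], p_a, p_e)
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} individual(s) had no non-missing markers",
            stacklevel=2,
        )

    group = np.array(
        [assign_ancestry_group(x, cutoff) if np.isfinite(x) else "" for x in q],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "q": q,
            "group": group,
            "loglik": loglik,
            "n_markers": n_markers,
            "iterations": iterations,
            "converged": converged,
            "identifiable": identifiable,
        },
        index=genotypes.index,
    )


def assign_ancestry_group(q: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """"low" if q < cutoff, "high" if q >= cutoff (boundary inclusive)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return "high" if q >= cutoff else "low"
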