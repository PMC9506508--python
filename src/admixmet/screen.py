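"""Screening phase: per-metabolite ancestry-group association.

Each metabolite's non-imputed log abundance is regressed on the
dichotomized ancestry group (high = GWAA >= cutoff) adjusting for age,
sex, recruitment site, log baseline PRA and batch, with casewise deletion
of samples missing that metabolite — so each metabolite has its own n.
Two-sided t-tests on the group coefficient feed Benjamini-Hochberg FDR
control (screening threshold q < 0.2 by default, deliberately lenient:
at this stage type II error is the bigger concern). PLS-DA is a purely
descriptive separation check and gates nothing.

The per-metabolite fit uses a least-squares solve (QR under the hood via
``numpy.linalg.lstsq``) with classical OLS standard errors; equivalence
with statsmodels OLS is enforced in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "ScreenResult",
    "build_design",
    "fit_metabolite_model",
    "screen_metabolites",
    "bh_fdr",
    "plsda_scores",
    "sensitivity_rescreen",
]

GROUP_COL = "group_high"


@dataclass
class RegressionResult:
    metabolite: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    direction: int  # +1 higher in high-GWAA, -1 lower, 0 if beta == 0

    def __post_init__(self) -> None:
        if self.direction != int(np.sign(self.beta)):
            raise ValueError("direction inconsistent with coefficient sign")


@dataclass
class ScreenResult:
    """Per-metabolite regressions with BH q-values and the significant set."""

    table: pd.DataFrame                      # beta, se, t, p, q, n, direction, significant
    fdr_threshold: float
    skipped: dict[str, str] = field(default_factory=dict)  # id -> reason

    @property
    def significant(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()

    @property
    def n_higher_in_high(self) -> int:
        t = self.table
        return int(((t["direction"] > 0) & t["significant"]).sum())

    @property
    def n_higher_in_low(self) -> int:
        t = self.table
        return int(((t["direction"] < 0) & t["significant"]).sum())

    def directions(self) -> pd.Series:
        return self.table["direction"]


def build_design(
    covariates: pd.DataFrame, groups: pd.Series, group_col: str = GROUP_COL
) -> pd.DataFrame:
    """Intercept + group indicator + age + sex/site/batch indicators + log PRA.

    Categorical covariates are coded as reference-level indicators with the
    lexicographically first level as reference (deterministic). ``groups``
    holds "low"/"high" labels aligned to ``covariates``.
    """
    required = {"age", "sex", "site", "batch", "pra"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariates missing columns: {sorted(missing)}")
    if covariates[sorted(required)].isna().any().any():
        raise ValueError("covariates must be complete (no missing values)")
    x = pd.DataFrame(index=covariates.index)
    x["intercept"] = 1.0
    x[group_col] = (groups.loc[covariates.index] == "high").astype(float)
    x["age"] = covariates["age"].astype(float)
    for col in ("sex", "site", "batch"):
        levels = sorted(covariates[col].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            x[f"{col}_{lev}"] = (covariates[col].astype(str) == lev).astype(float)
    x["log_pra"] = np.log(covariates["pra"].astype(float))
    return x


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns a pivoted QR deems redundant."""
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return [names[piv[i]] for i in range(rank, len(names))]


def _ols_t_test(y: np.ndarray, x: np.ndarray, coef_idx: int) -> tuple[float, float, float, float]:
    """OLS beta, SE, t and two-sided p for one coefficient."""
    n, p = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - x @ beta
    dof = n - p
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = float(np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx]))
    b = float(beta[coef_idx])
    if se == 0.0:
        return b, se, 0.0, 1.0
    t = b / se
    pval = 2.0 * stats.t.sf(abs(t), dof)
    return b, se, float(t), float(pval)


def fit_metabolite_model(
    y: pd.Series, design: pd.DataFrame, metabolite: str | None = None
) -> RegressionResult:
    """Covariate-adjusted OLS of one metabolite with casewise deletion.

    Samples missing the metabolite are dropped; the design must then still
    be full rank (a rank-deficient design raises, naming the collinear
    columns) and leave positive residual degrees of freedom. A metabolite
    constant over the retained samples returns beta exactly 0 with p = 1.
    """
    metabolite = metabolite if metabolite is not None else str(y.name)
    keep = y.notna()
    yv = y[keep].to_numpy(dtype=float)
    xv = design.loc[keep.index[keep]].to_numpy(dtype=float)
    n, p = xv.shape
    if n <= p:
        raise ValueError(
            f"{metabolite}: {n} samples after casewise deletion for {p} parameters"
        )
    if np.ptp(yv) == 0.0:
        return RegressionResult(metabolite, 0.0, 0.0, 0.0, 1.0, n, 0)
    coef_idx = design.columns.get_loc(GROUP_COL)
    try:
        b, se, t, pval = _ols_t_test(yv, xv, coef_idx)
    except np.linalg.LinAlgError:
        cols = _collinear_columns(xv, list(design.columns))
        raise ValueError(f"{metabolite}: rank-deficient design; collinear columns {cols}") from None
    return RegressionResult(metabolite, b, se, t, pval, n, int(np.sign(b)))


def bh_fdr(pvalues: pd.Series | np.ndarray, q_threshold: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the q < threshold set.

    Returns (qvalues, significant boolean mask) aligned to the input.
    Metabolites skipped upstream must already be excluded from the family.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < q_threshold


def screen_metabolites(
    log_df: pd.DataFrame,
    covariates: pd.DataFrame,
    groups: pd.Series,
    fdr_threshold: float = 0.2,
) -> ScreenResult:
    """Run the per-metabolite screen and BH control over the fitted family.

    Metabolites with too few complete cases (or degenerate designs after
    deletion) are skipped with a reason and excluded from the BH family —
    no p-value exists for them.
    """
    design = build_design(covariates, groups)
    x_all = design.to_numpy(dtype=float)
    y_all = log_df.to_numpy(dtype=float)
    coef_idx = design.columns.get_loc(GROUP_COL)
    n_params = x_all.shape[1]
    rows = []
    skipped: dict[str, str] = {}
    for j, met in enumerate(log_df.columns):
        met = str(met)
        yj = y_all[:, j]
        mask = ~np.isnan(yj)
        yv = yj[mask]
        n = yv.size
        if n <= n_params:
            skipped[met] = (
                f"{met}: {n} samples after casewise deletion for {n_params} parameters"
            )
            continue
        if np.ptp(yv) == 0.0:
            rows.append(RegressionResult(met, 0.0, 0.0, 0.0, 1.0, n, 0))
            continue
        try:
            b, se, t, pval = _ols_t_test(yv, x_all[mask], coef_idx)
        except np.linalg.LinAlgError:
            cols = _collinear_columns(x_all[mask], list(design.columns))
            skipped[met] = f"{met}: rank-deficient design; collinear columns {cols}"
            continue
        rows.append(RegressionResult(met, b, se, t, pval, n, int(np.sign(b))))
    if not rows:
        table = pd.DataFrame(
            columns=["beta", "se", "t", "p", "q", "n", "direction", "significant"]
        )
        return ScreenResult(table=table, fdr_threshold=fdr_threshold, skipped=skipped)
    table = pd.DataFrame(
        {
            "beta": [r.beta for r in rows],
            "se": [r.se for r in rows],
            "t": [r.t for r in rows],
            "p": [r.p for r in rows],
            "n": [r.n for r in rows],
            "direction": [r.direction for r in rows],
        },
        index=pd.Index([r.metabolite for r in rows], name="metabolite_id"),
    )
    q, sig = bh_fdr(table["p"], fdr_threshold)
    table["q"] = q
    table["significant"] = sig
    table = table[["beta", "se", "t", "p", "q", "n", "direction", "significant"]]
    return ScreenResult(table=table, fdr_threshold=fdr_threshold, skipped=skipped)


@dataclass
class PLSDAResult:
    scores: pd.DataFrame           # samples x components
    explained_variance: np.ndarray  # fraction of X variance per component
    separation: float               # centroid distance / pooled within-group SD, comp 1


def plsda_scores(
    imputed: pd.DataFrame, groups: pd.Series, n_comp: int = 2
) -> PLSDAResult:
    """Partial least squares discriminant analysis (NIPALS, via sklearn).

    X is the centered imputed log matrix, y the centered group indicator.
    The separation summary is the distance between group centroids on
    component 1 in units of the pooled within-group SD. Descriptive only.
    """
    from sklearn.cross_decomposition import PLSRegression

    g = groups.loc[imputed.index]
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("PLS-DA needs two groups")
    y = (g == labels[-1]).astype(float).to_numpy()
    x = imputed.to_numpy(dtype=float)
    n_comp = min(n_comp, min(x.shape) - 1)
    pls = PLSRegression(n_components=n_comp, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(x, y)
    scores = pls.x_scores_
    xc = x - x.mean(axis=0)
    total_ss = (xc ** 2).sum()
    expl = np.array(
        [
            (scores[:, c] ** 2).sum() * (pls.x_loadings_[:, c] ** 2).sum() / total_ss
            for c in range(n_comp)
        ]
    )
    t1 = scores[:, 0]
    hi = t1[y == 1]
    lo = t1[y == 0]
    pooled = np.sqrt(
        ((hi.size - 1) * hi.var(ddof=1) + (lo.size - 1) * lo.var(ddof=1))
        / max(hi.size + lo.size - 2, 1)
    )
    separation = abs(hi.mean() - lo.mean()) / pooled if pooled > 0 else np.inf
    score_df = pd.DataFrame(
        scores, index=imputed.index, columns=[f"comp{c + 1}" for c in range(n_comp)]
    )
    return PLSDAResult(scores=score_df, explained_variance=expl, separation=float(separation))


@dataclass
class SensitivityResult:
    full: ScreenResult
    reduced: ScreenResult
    jaccard: float
    sign_agreement: float
    n_excluded_samples: int
    dropped_levels: list[str] = field(default_factory=list)


def sensitivity_rescreen(
    log_df: pd.DataFrame,
    covariates: pd.DataFrame,
    groups: pd.Series,
    flagged_samples: list[str],
    fdr_threshold: float = 0.2,
    full_result: ScreenResult | None = None,
) -> SensitivityResult:
    """Re-run the screen without PCA/SED-flagged samples and compare.

    Reports the Jaccard overlap of the two significant sets and the
    fraction of metabolites (fitted in both runs) whose group-coefficient
    signs agree. Covariate levels emptied by the exclusion drop out of the
    design automatically and are recorded.
    """
    if full_result is None:
        full_result = screen_metabolites(log_df, covariates, groups, fdr_threshold)
    keep = [s for s in log_df.index if str(s) not in set(map(str, flagged_samples))]
    sub_cov = covariates.loc[keep]
    dropped_levels = []
    for col in ("sex", "site", "batch"):
        gone = set(covariates[col].astype(str)) - set(sub_cov[col].astype(str))
        dropped_levels.extend(f"{col}_{lev}" for lev in sorted(gone))
    reduced = screen_metabolites(
        log_df.loc[keep], sub_cov, groups.loc[keep], fdr_threshold
    )
    a = set(full_result.significant)
    b = set(reduced.significant)
    union = a | b
    jaccard = len(a & b) / len(union) if union else 1.0
    common = full_result.table.index.intersection(reduced.table.index)
    if len(common):
        s1 = np.sign(full_result.table.loc[common, "beta"])
        s2 = np.sign(reduced.table.loc[common, "beta"])
        agreement = float((s1.to_numpy() == s2.to_numpy()).mean())
    else:
        agreement = 1.0
    return SensitivityResult(
        full=full_result,
        reduced=reduced,
        jaccard=jaccard,
        sign_agreement=agreement,
        n_excluded_samples=len(log_df) - len(keep),
        dropped_levels=dropped_levels,
    )
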