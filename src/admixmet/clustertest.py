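"""Cluster-level discovery testing, replication and dose-response.

Each metabolic cluster is summarized by the first principal component
(the "eigen-metabolite") of its standardized, KNN-imputed log abundances.
PC1 is regressed on the dichotomized ancestry group with the standard
covariate adjustment, with Bonferroni control at alpha / K over the K
clusters tested in the family. PC1 distributions are screened for heavy
skew (|G1| > 1) or bimodality (Sarle's coefficient > 0.555) — linear
models tolerate mild non-normality, so flagged clusters are not dropped
but marked for a Mann-Whitney sensitivity check.

Replication recomputes PC1 within the second cohort (its own loadings,
not projected from discovery), tests at alpha / K2 over the clusters
carried forward, and additionally requires >= 90% of the cluster's
metabolites (those assayed in both cohorts) to have the same estimated
effect direction in the two cohorts' screens; the boundary is evaluated
with exact rational arithmetic so 9/10 passes. The dose-response path
regresses each replicated-cluster metabolite on the continuous ancestry
proportion within the high-ancestry subset, where that proportion is
approximately normally distributed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .screen import GROUP_COL, build_design, fit_metabolite_model

__all__ = [
    "ClusterTestResult",
    "ReplicationResult",
    "cluster_pc1",
    "test_cluster",
    "test_clusters",
    "bonferroni",
    "distribution_flags",
    "mannwhitney",
    "replicate_clusters",
    "dose_response",
]

BIMODALITY_THRESHOLD = 0.555
SKEW_THRESHOLD = 1.0


# ---------------------------------------------------------------------------
# PC1 extraction

def cluster_pc1(
    imputed: pd.DataFrame, members: list[str]
) -> tuple[pd.Series, float, pd.Series]:
    """PC1 scores, % variance explained, and loadings for one cluster.

    Member metabolites are z-scored and decomposed by SVD; the component
    sign is fixed so the loadings sum positive (first loading positive on
    an exact zero sum), making scores invariant to member order and to
    sign flips of any input metabolite. A single-metabolite cluster
    returns its z-scores with 100% variance.
    """
    present = [m for m in members if m in imputed.columns]
    if not present:
        raise ValueError("no cluster members present in the matrix")
    x = imputed[present].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        dropped = [present[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(f"dropping zero-variance members {dropped}", stacklevel=2)
        keep = sd > 0
        present = [p for p, k in zip(present, keep) if k]
        if not present:
            raise ValueError("all cluster members have zero variance")
        x = x[:, keep]
        sd = sd[keep]
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[0]
    lsum = loadings.sum()
    flip = -1.0 if (lsum < 0 or (lsum == 0 and loadings[0] < 0)) else 1.0
    scores = pd.Series(u[:, 0] * s[0] * flip, index=imputed.index, name="pc1")
    pct_var = float(s[0] ** 2 / (s ** 2).sum() * 100.0)
    return scores, pct_var, pd.Series(loadings * flip, index=present, name="loading")


# ---------------------------------------------------------------------------
# regression and multiplicity

def test_cluster(
    pc1: pd.Series, covariates: pd.DataFrame, groups: pd.Series
):
    """Covariate-adjusted OLS of PC1 on the ancestry group indicator."""
    design = build_design(covariates, groups)
    return fit_metabolite_model(pc1, design, metabolite=str(pc1.name or "pc1"))


@dataclass
class BonferroniResult:
    alpha: float
    k: int
    threshold: float
    display_threshold: float
    significant: list

    def is_significant(self, p: float) -> bool:
        return p < self.threshold


def _floor_two_significant(x: float) -> float:
    if x <= 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(x))
    scale = 10.0 ** (exp - 1)
    return math.floor(x / scale + 1e-12) * scale


def bonferroni(pvalues: dict | pd.Series, alpha: float = 0.05) -> BonferroniResult:
    """Family-wise threshold alpha / K with the significant sub-family.

    ``display_threshold`` rounds the threshold down to two significant
    digits, the convention used when quoting e.g. 0.05/24 as 0.002 and
    0.05/13 as 0.0038.
    """
    p = pd.Series(pvalues)
    k = len(p)
    if k < 1:
        raise ValueError("family size must be >= 1")
    thr = alpha / k
    return BonferroniResult(
        alpha=alpha,
        k=k,
        threshold=thr,
        display_threshold=_floor_two_significant(thr),
        significant=p.index[p < thr].tolist(),
    )


# ---------------------------------------------------------------------------
# distribution diagnostics

@dataclass
class DistributionFlags:
    skewness: float
    bimodality: float
    shapiro_p: float
    skewed: bool
    bimodal: bool

    @property
    def flag(self) -> str:
        if not np.isfinite(self.skewness):
            return "undefined"
        if self.skewed:
            return "skewed"
        if self.bimodal:
            return "bimodal"
        return "none"

    @property
    def flagged(self) -> bool:
        return self.skewed or self.bimodal


def distribution_flags(
    scores: pd.Series | np.ndarray,
    skew_threshold: float = SKEW_THRESHOLD,
    bimodality_threshold: float = BIMODALITY_THRESHOLD,
) -> DistributionFlags:
    """Skewness and bimodality diagnostics for a PC1 score vector.

    Skewness is the adjusted Fisher-Pearson G1; bimodality is Sarle's
    coefficient b = (G1^2 + 1) / (kurt + 3 (n-1)^2 / ((n-2)(n-3))) with
    ``kurt`` the bias-corrected excess kurtosis (a uniform distribution
    sits at ~0.555, the default flag boundary). The Shapiro-Wilk p-value
    is reported as a diagnostic only and never gates anything. Constant
    scores yield undefined (NaN) diagnostics.
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("distribution diagnostics need n >= 8")
    if np.ptp(x) == 0.0:
        return DistributionFlags(np.nan, np.nan, np.nan, False, False)
    g1 = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    b = (g1 ** 2 + 1.0) / (kurt + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(stats.shapiro(x if n <= 5000 else x[:5000]).pvalue)
    return DistributionFlags(
        skewness=g1,
        bimodality=float(b),
        shapiro_p=shapiro_p,
        skewed=abs(g1) > skew_threshold,
        bimodal=float(b) > bimodality_threshold,
    )


def mannwhitney(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray):
    """Two-sided Mann-Whitney U between the two ancestry groups.

    Exact enumeration when the smaller group has <= 8 observations and
    there are no ties; otherwise the normal approximation with tie
    correction and continuity correction. All-tied data returns p = 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("Mann-Whitney needs exactly two non-empty groups")
    x = v[g == labels[0]]
    y = v[g == labels[1]]
    if np.ptp(v) == 0.0:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(v).size < v.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# discovery-phase driver

@dataclass
class ClusterTestResult:
    label: str
    n_metabolites: int
    pc1: pd.Series
    pct_variance: float
    beta: float
    p: float
    n: int
    flags: DistributionFlags
    bonferroni_threshold: float = np.nan
    significant: bool = False


def test_clusters(
    imputed: pd.DataFrame,
    clusters: dict[str, list[str]],
    covariates: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> tuple[list[ClusterTestResult], BonferroniResult | None]:
    """PC1 + regression + Bonferroni over all clusters in the family."""
    results = []
    for label in sorted(clusters):
        members = clusters[label]
        scores, pct, _ = cluster_pc1(imputed, members)
        scores.name = label
        reg = test_cluster(scores, covariates.loc[scores.index], groups)
        flags = distribution_flags(scores)
        results.append(
            ClusterTestResult(
                label=label,
                n_metabolites=len(members),
                pc1=scores,
                pct_variance=pct,
                beta=reg.beta,
                p=reg.p,
                n=reg.n,
                flags=flags,
            )
        )
    if not results:
        return [], None
    bonf = bonferroni({r.label: r.p for r in results}, alpha=alpha)
    for r in results:
        r.bonferroni_threshold = bonf.threshold
        r.significant = r.p < bonf.threshold
    return results, bonf


# ---------------------------------------------------------------------------
# replication

@dataclass
class ReplicationResult:
    label: str
    n_available: int
    n_lost: int
    beta: float
    p: float
    pct_variance: float
    bonferroni_threshold: float
    concordance: Fraction | None
    concordant: int
    compared: int
    p_significant: bool
    direction_ok: bool
    replicated: bool
    flags: DistributionFlags | None = None
    mannwhitney_p: float | None = None
    pc1: pd.Series | None = None
    testable: bool = True


def _screen_directions(table: pd.DataFrame, members: list[str]) -> pd.Series:
    present = [m for m in members if m in table.index]
    return np.sign(table.loc[present, "beta"])


def replicate_clusters(
    clusters: dict[str, list[str]],
    rep_imputed: pd.DataFrame,
    rep_covariates: pd.DataFrame,
    rep_groups: pd.Series,
    screen_disc: pd.DataFrame,
    screen_rep: pd.DataFrame,
    alpha: float = 0.05,
    concordance_min: Fraction = Fraction(9, 10),
    loss_warn_frac: float = 0.5,
) -> list[ReplicationResult]:
    """Test the discovery-significant clusters in the second cohort.

    ``clusters`` maps each carried-forward label to its discovery member
    list; ``screen_disc`` / ``screen_rep`` are the per-metabolite screen
    tables of the two cohorts (same covariate-adjusted model) whose
    coefficient signs define the per-metabolite directions. A cluster is
    replicated iff its cohort-2 PC1 regression p is below alpha / K2 AND
    the direction-concordance fraction (over metabolites assayed and
    fitted in both cohorts) is at least ``concordance_min``, compared as
    exact rationals. Clusters losing more than ``loss_warn_frac`` of
    their members in cohort 2 trigger a warning; clusters with no
    available member are reported untestable and leave the family.
    """
    testable: dict[str, list[str]] = {}
    untestable: list[str] = []
    for label in sorted(clusters):
        avail = [m for m in clusters[label] if m in rep_imputed.columns]
        if not avail:
            untestable.append(label)
            continue
        lost = len(clusters[label]) - len(avail)
        if lost > loss_warn_frac * len(clusters[label]):
            warnings.warn(
                f"cluster {label!r} lost {lost}/{len(clusters[label])} members "
                f"in the replication cohort", stacklevel=2
            )
        testable[label] = avail

    results: list[ReplicationResult] = []
    k2 = len(testable)
    for label in untestable:
        results.append(
            ReplicationResult(
                label=label, n_available=0, n_lost=len(clusters[label]),
                beta=np.nan, p=np.nan, pct_variance=np.nan,
                bonferroni_threshold=np.nan, concordance=None, concordant=0,
                compared=0, p_significant=False, direction_ok=False,
                replicated=False, testable=False,
            )
        )
    if k2 == 0:
        return results
    threshold = alpha / k2
    for label, avail in testable.items():
        scores, pct, _ = cluster_pc1(rep_imputed, avail)
        scores.name = label
        reg = test_cluster(scores, rep_covariates.loc[scores.index], rep_groups)
        d1 = _screen_directions(screen_disc, avail)
        d2 = _screen_directions(screen_rep, avail)
        common = d1.index.intersection(d2.index)
        concordant = int((d1.loc[common].to_numpy() == d2.loc[common].to_numpy()).sum())
        compared = len(common)
        conc = Fraction(concordant, compared) if compared else None
        p_sig = reg.p < threshold
        dir_ok = conc is not None and conc >= concordance_min
        flags = distribution_flags(scores) if len(scores) >= 8 else None
        mw_p = None
        if flags is not None and flags.flagged:
            _, mw_p = mannwhitney(scores, rep_groups.loc[scores.index])
        results.append(
            ReplicationResult(
                label=label,
                n_available=len(avail),
                n_lost=len(clusters[label]) - len(avail),
                beta=reg.beta,
                p=reg.p,
                pct_variance=pct,
                bonferroni_threshold=threshold,
                concordance=conc,
                concordant=concordant,
                compared=compared,
                p_significant=p_sig,
                direction_ok=dir_ok,
                replicated=p_sig and dir_ok,
                flags=flags,
                mannwhitney_p=mw_p,
                pc1=scores,
            )
        )
    return results


# ---------------------------------------------------------------------------
# dose-response within the high-ancestry subset

def dose_response(
    log_df: pd.DataFrame,
    q: pd.Series,
    covariates: pd.DataFrame,
    clusters: dict[str, list[str]],
    cutoff: float = 0.45,
) -> pd.DataFrame:
    """Per-metabolite association with continuous ancestry, high-GWAA subset.

    For each metabolite of each (replicated) cluster, OLS of log abundance
    on the continuous ancestry proportion q plus the standard covariates,
    restricted to samples with q >= cutoff. Returns a table with cluster,
    beta, p and n; the per-cluster count of positive slopes is the sign
    tally reported downstream.
    """
    subset = q.index[q >= cutoff]
    if len(subset) == 0:
        raise ValueError("high-ancestry subset is empty")
    qs = q.loc[subset]
    if np.ptp(qs.to_numpy()) == 0.0:
        raise ValueError("ancestry proportion does not vary within the subset")
    cov = covariates.loc[subset]
    # the "group" slot of the standard design carries continuous q here
    design = build_design(cov, pd.Series("low", index=subset))
    design[GROUP_COL] = qs.astype(float)
    rows = []
    for label in sorted(clusters):
        for met in clusters[label]:
            if met not in log_df.columns:
                continue
            y = log_df.loc[subset, met]
            try:
                res = fit_metabolite_model(y, design, str(met))
            except ValueError:
                continue
            rows.append((str(met), label, res.beta, res.se, res.p, res.n))
    return pd.DataFrame(
        rows, columns=["metabolite_id", "cluster", "beta", "se", "p", "n"]
    ).set_index("metabolite_id")
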