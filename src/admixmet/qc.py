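"""Metabolomics data processing and quality control.

The battery mirrors a standard untargeted-LC-MS workflow: exclusion of
xenobiotics and heavily missing metabolites, natural-log transform,
K-nearest-neighbour imputation (used *only* for PCA-based diagnostics and
cluster PC1 extraction — association models run on non-imputed data with
casewise deletion), sample-outlier detection by PCA scores and by
standardized Euclidean distance (SED), and metabolite flagging by the
Bland-Altman concordance method and by coefficient of variation (CV).

Matrices are pandas DataFrames, samples in rows, metabolites in columns,
``NaN`` marking missing values. Flags are advisory: flagged metabolites
stay in every analysis; flagged samples are only removed in the screening
module's sensitivity re-run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "filter_metabolites",
    "log_transform",
    "knn_impute",
    "pca_sample_outliers",
    "sed_sample_outliers",
    "bland_altman_flags",
    "cv_flags",
    "run_qc",
]

EXCLUDE_XENOBIOTIC = "xenobiotic"
EXCLUDE_MISSINGNESS = "missingness"


@dataclass
class QCReport:
    """Everything the QC battery decided, with the thresholds it used."""

    n_input_metabolites: int = 0
    n_input_samples: int = 0
    excluded_metabolites: dict[str, str] = field(default_factory=dict)   # id -> reason
    flagged_samples: dict[str, list[str]] = field(default_factory=dict)  # id -> methods
    flagged_metabolites: dict[str, list[str]] = field(default_factory=dict)
    unflaggable_metabolites: list[str] = field(default_factory=list)     # too few BA pairs
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input_metabolites - len(self.excluded_metabolites)

    def add_sample_flag(self, sample: str, method: str) -> None:
        self.flagged_samples.setdefault(sample, [])
        if method not in self.flagged_samples[sample]:
            self.flagged_samples[sample].append(method)

    def add_metabolite_flag(self, met: str, method: str) -> None:
        self.flagged_metabolites.setdefault(met, [])
        if method not in self.flagged_metabolites[met]:
            self.flagged_metabolites[met].append(method)

    def to_dict(self) -> dict:
        return {
            "n_input_metabolites": self.n_input_metabolites,
            "n_input_samples": self.n_input_samples,
            "n_retained": self.n_retained,
            "excluded_metabolites": dict(self.excluded_metabolites),
            "flagged_samples": {k: list(v) for k, v in self.flagged_samples.items()},
            "flagged_metabolites": {k: list(v) for k, v in self.flagged_metabolites.items()},
            "unflaggable_metabolites": list(self.unflaggable_metabolites),
            "thresholds": dict(self.thresholds),
        }

    def summary(self) -> str:
        lines = [
            f"metabolites: {self.n_input_metabolites} in, {self.n_retained} retained",
            f"excluded: {sum(1 for r in self.excluded_metabolites.values() if r == EXCLUDE_XENOBIOTIC)} xenobiotic, "
            f"{sum(1 for r in self.excluded_metabolites.values() if r == EXCLUDE_MISSINGNESS)} heavy missingness",
            f"flagged samples: {len(self.flagged_samples)}",
            f"flagged metabolites: {len(self.flagged_metabolites)}",
        ]
        return "\n".join(lines)


def filter_metabolites(
    raw: pd.DataFrame,
    annotations: pd.DataFrame,
    max_missing: float = 0.60,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Exclude xenobiotics and metabolites with missingness > ``max_missing``.

    The missingness cut is strictly greater-than: a metabolite missing in
    exactly 60.0% of samples is retained at the default threshold. Input
    column order is preserved. Every metabolite must carry a ``xenobiotic``
    annotation.
    """
    if report is None:
        report = QCReport()
    report.n_input_metabolites = raw.shape[1]
    report.n_input_samples = raw.shape[0]
    report.thresholds["max_missing"] = max_missing

    unannotated = [m for m in raw.columns if m not in annotations.index]
    if unannotated:
        raise ValueError(f"metabolites without annotation: {unannotated[:10]}"
                         f"{'...' if len(unannotated) > 10 else ''}")
    if raw.shape[1] == 0:
        return raw, report

    xeno = annotations.loc[raw.columns, "xenobiotic"].to_numpy(dtype=bool)
    frac_missing = raw.isna().mean(axis=0).to_numpy() if len(raw) else np.zeros(raw.shape[1])
    keep = np.ones(raw.shape[1], dtype=bool)
    for j, met in enumerate(raw.columns):
        if xeno[j]:
            report.excluded_metabolites[met] = EXCLUDE_XENOBIOTIC
            keep[j] = False
        elif frac_missing[j] > max_missing:
            report.excluded_metabolites[met] = EXCLUDE_MISSINGNESS
            keep[j] = False
    return raw.loc[:, keep], report


def log_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """Natural log of observed entries; missingness mask unchanged."""
    vals = raw.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        rows, cols = np.nonzero(bad)
        coords = [(raw.index[r], raw.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"non-positive observed values at {coords}")
    with np.errstate(invalid="ignore"):
        return pd.DataFrame(np.log(vals), index=raw.index, columns=raw.columns)


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    """Column z-scores over observed entries; zero-variance columns -> 0."""
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / safe
    z[:, sd == 0] = 0.0
    return z


def knn_impute(log_df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries from the k most similar samples.

    A missing entry (sample s, metabolite j) becomes the mean of metabolite
    j over the k samples nearest to s — Euclidean distance on z-scored
    shared-observed metabolites, candidates restricted to samples observed
    at j. If no eligible neighbour exists the metabolite's observed median
    is used. Observed entries are returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = log_df.to_numpy(dtype=float)
    n, m = x.shape
    obs = ~np.isnan(x)
    if m and not obs.any(axis=0).all():
        empty = log_df.columns[~obs.any(axis=0)].tolist()
        raise ValueError(f"metabolites with no observed value: {empty}")
    if k > n - 1:
        warnings.warn(f"k={k} exceeds n_samples-1; truncated to {n - 1}", stacklevel=2)
        k = max(n - 1, 1)
    if obs.all():
        return log_df.copy()

    z = _zscore_columns(x)
    z0 = np.where(obs, z, 0.0)
    sq = z0 ** 2
    mask = obs.astype(float)
    # squared distance restricted to coordinates observed in both samples:
    # d2(s,t) = sum_shared (z_s - z_t)^2 = sq_s.mask_t + mask_s.sq_t - 2 z_s.z_t
    d2 = sq @ mask.T + mask @ sq.T - 2.0 * (z0 @ z0.T)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)
    order = np.argsort(d2, axis=1, kind="stable")

    out = x.copy()
    medians = np.nanmedian(x, axis=0)
    miss_rows, miss_cols = np.nonzero(~obs)
    obs_by_col = obs  # alias for readability
    for s, j in zip(miss_rows, miss_cols):
        acc = 0.0
        cnt = 0
        for t in order[s]:
            if not np.isfinite(d2[s, t]):
                break
            if obs_by_col[t, j]:
                acc += x[t, j]
                cnt += 1
                if cnt == k:
                    break
        out[s, j] = acc / cnt if cnt else medians[j]
    return pd.DataFrame(out, index=log_df.index, columns=log_df.columns)


def _drop_zero_variance(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.to_numpy().std(axis=0, ddof=1) if len(df) > 1 else np.zeros(df.shape[1])
    if (sd == 0).any():
        dropped = df.columns[sd == 0].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance metabolite(s) "
                      f"from outlier detection", stacklevel=3)
        df = df.loc[:, sd > 0]
    return df


def pca_sample_outliers(
    imputed: pd.DataFrame,
    n_pcs: int = 2,
    z_thresh: float = 3.0,
    report: QCReport | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Flag samples with |score| > z_thresh * SD(score) on any leading PC.

    PCA runs on column-z-scored imputed data via SVD. Returns the flagged
    sample ids and the score matrix for the first ``n_pcs`` components.
    """
    if len(imputed) < 3:
        raise ValueError("PCA outlier detection needs >= 3 samples")
    df = _drop_zero_variance(imputed)
    z = _zscore_columns(df.to_numpy(dtype=float))
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = u[:, :n_pcs] * s[:n_pcs]
    sd = scores.std(axis=0, ddof=1)
    flagged_mask = (np.abs(scores) > z_thresh * sd).any(axis=1)
    flagged = [str(i) for i in imputed.index[flagged_mask]]
    score_df = pd.DataFrame(
        scores, index=imputed.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    if report is not None:
        report.thresholds["pca_z_thresh"] = z_thresh
        for sample in flagged:
            report.add_sample_flag(sample, "PCA")
    return flagged, score_df


def sed_sample_outliers(
    imputed: pd.DataFrame,
    thresh_sd: float = 3.0,
    report: QCReport | None = None,
) -> tuple[list[str], pd.Series]:
    """Standardized Euclidean distance of each sample from the centroid.

    SED_s = sqrt(sum_j ((x_sj - mean_j) / SD_j)^2); a sample is flagged if
    its SED exceeds mean(SED) + thresh_sd * SD(SED).
    """
    if len(imputed) < 3:
        raise ValueError("SED outlier detection needs >= 3 samples")
    df = _drop_zero_variance(imputed)
    z = _zscore_columns(df.to_numpy(dtype=float))
    sed = np.sqrt((z ** 2).sum(axis=1))
    cut = sed.mean() + thresh_sd * sed.std(ddof=1)
    flagged = [str(i) for i in imputed.index[sed > cut]]
    if report is not None:
        report.thresholds["sed_thresh_sd"] = thresh_sd
        for sample in flagged:
            report.add_sample_flag(sample, "SED")
    return flagged, pd.Series(sed, index=imputed.index, name="sed")


def _make_pairs(samples: list, groups: pd.Series | None,
                rng: np.random.Generator | None) -> list[tuple]:
    """Deterministic consecutive pairing of sorted ids within each subgroup
    (or seeded random pairing when an rng is supplied)."""
    pairs = []
    if groups is None:
        groups = pd.Series("all", index=samples)
    for _, members in sorted(groups.groupby(groups).groups.items()):
        ids = sorted(members)
        if rng is not None:
            ids = [ids[i] for i in rng.permutation(len(ids))]
        for i in range(0, len(ids) - 1, 2):
            pairs.append((ids[i], ids[i + 1]))
    return pairs


def bland_altman_flags(
    log_df: pd.DataFrame,
    groups: pd.Series | None = None,
    outlier_frac: float = 0.05,
    loa_mult: float = 1.96,
    min_pairs: int = 3,
    rng: np.random.Generator | None = None,
    report: QCReport | None = None,
) -> list[str]:
    """Flag metabolites with poor within-pair concordance.

    Samples are paired within each subgroup (consecutive pairs after
    sorting by id; pass ``rng`` for seeded random pairing). For each
    metabolite the pair differences d over complete pairs are compared to
    their limits of agreement: a pair is an outlier when
    |d - mean(d)| > loa_mult * SD(d). A metabolite is flagged when its
    pooled outlier fraction exceeds ``outlier_frac``. Metabolites with
    fewer than ``min_pairs`` complete pairs are recorded as unflaggable.
    """
    if groups is not None:
        counts = groups.value_counts()
        if (counts < 4).any():
            raise ValueError("every subgroup needs >= 4 samples for pairing")
    pairs = _make_pairs(list(log_df.index), groups, rng)
    if not pairs:
        raise ValueError("no pairs could be formed")
    left = log_df.loc[[a for a, _ in pairs]].to_numpy(dtype=float)
    right = log_df.loc[[b for _, b in pairs]].to_numpy(dtype=float)
    d = left - right
    complete = ~np.isnan(d)

    flagged = []
    for j, met in enumerate(log_df.columns):
        dj = d[complete[:, j], j]
        if dj.size < min_pairs:
            if report is not None:
                report.unflaggable_metabolites.append(str(met))
            continue
        sd = dj.std(ddof=1)
        if sd == 0:
            continue
        outliers = np.abs(dj - dj.mean()) > loa_mult * sd
        if outliers.mean() > outlier_frac:
            flagged.append(str(met))
    if report is not None:
        report.thresholds["ba_outlier_frac"] = outlier_frac
        report.thresholds["ba_loa_mult"] = loa_mult
        for met in flagged:
            report.add_metabolite_flag(met, "BA")
    return flagged


def cv_flags(
    raw: pd.DataFrame,
    top_frac: float = 0.10,
    report: QCReport | None = None,
) -> tuple[list[str], pd.Series]:
    """Flag the ceil(top_frac * M) metabolites with the largest CV.

    CV_j = SD_j / mean_j over observed raw values (sample SD). Ties at the
    cutoff break by metabolite id order.
    """
    vals = raw.to_numpy(dtype=float)
    n_obs = (~np.isnan(vals)).sum(axis=0)
    if (n_obs < 2).any():
        bad = raw.columns[n_obs < 2].tolist()
        raise ValueError(f"metabolites with < 2 observed values: {bad}")
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    cv = pd.Series(sd / mean, index=raw.columns, name="cv")
    n_flag = math.ceil(top_frac * raw.shape[1]) if raw.shape[1] else 0
    ranked = cv.to_frame().assign(_id=cv.index.astype(str))
    ranked = ranked.sort_values(["cv", "_id"], ascending=[False, True])
    flagged = [str(i) for i in ranked.index[:n_flag]]
    if report is not None:
        report.thresholds["cv_top_frac"] = top_frac
        for met in flagged:
            report.add_metabolite_flag(met, "CV")
    return flagged, cv


def run_qc(
    raw: pd.DataFrame,
    annotations: pd.DataFrame,
    groups: pd.Series | None = None,
    max_missing: float = 0.60,
    knn_k: int = 10,
    pca_z_thresh: float = 3.0,
    sed_thresh_sd: float = 3.0,
    ba_outlier_frac: float = 0.05,
    cv_top_frac: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, QCReport]:
    """Run the full battery.

    Returns (filtered raw, log layer, KNN-imputed log layer, QCReport).
    """
    report = QCReport()
    filtered, report = filter_metabolites(raw, annotations, max_missing, report)
    log_df = log_transform(filtered)
    imputed = knn_impute(log_df, k=knn_k)
    pca_sample_outliers(imputed, z_thresh=pca_z_thresh, report=report)
    sed_sample_outliers(imputed, thresh_sd=sed_thresh_sd, report=report)
    bland_altman_flags(log_df, groups, outlier_frac=ba_outlier_frac, report=report)
    cv_flags(filtered, top_frac=cv_top_frac, report=report)
    return filtered, log_df, imputed, report
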