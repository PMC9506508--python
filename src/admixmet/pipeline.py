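"""Three-phase orchestration: screen -> discover -> replicate.

`analyze_study` runs the whole analysis in memory on a `Study` bundle
(simulated or assembled from files): ancestry estimation from the AIM
panel, the QC battery, per-metabolite screening with FDR control and the
flagged-sample sensitivity re-run, metabolic clustering of the
significant set, PC1 cluster tests with Bonferroni control, replication
with the direction-concordance rule, and the continuous-ancestry
dose-response within the high-ancestry subset.

`run_pipeline` wraps it with file I/O: inputs are loaded (or simulated
from a seed), every stage artifact is written to a run directory as
TSV/JSON together with a manifest (input checksums, config echo, package
versions, seed), and `report` renders a human-readable summary whose
descriptive block mirrors a baseline-characteristics table (mean +/- SD
with t-tests for normal variables, median/IQR with Mann-Whitney for PRA
and ancestry, counts with chi-square for sex).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import ancestry as anc
from . import cluster as clu
from . import clustertest as ct
from . import io as aio
from . import qc as qcm
from . import screen as scr
from . import simulate as sim

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "CohortAnalysis",
    "StudyResult",
    "analyze_study",
    "run_pipeline",
    "report",
    "descriptive_table",
]


@dataclass(frozen=True)
class PipelineParams:
    """All analysis thresholds in one place (study-convention defaults)."""

    pseudocount: float = 0.5
    min_freq_diff: float = 0.30
    ancestry_cutoff: float = 0.45
    max_missing: float = 0.60
    knn_k: int = 10
    pca_z_thresh: float = 3.0
    sed_thresh_sd: float = 3.0
    ba_outlier_frac: float = 0.05
    cv_top_frac: float = 0.10
    fdr_threshold: float = 0.2
    alpha: float = 0.05
    min_cluster_size: int = 2
    sharpness_grid: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    concordance_min: Fraction = Fraction(9, 10)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr_threshold and alpha must lie in (0, 1)")
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must lie in [0, 1]")
        if not 0 <= self.ancestry_cutoff <= 1:
            raise ValueError("ancestry_cutoff must lie in [0, 1]")


@dataclass
class PipelineConfig:
    """File-level run configuration; ``simulate_seed`` replaces input paths."""

    output_dir: str = "admixmet_run"
    seed: int | None = None
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    discovery_only: bool = False
    genotype_paths: dict[str, str] = field(default_factory=dict)
    metabolome_paths: dict[str, str] = field(default_factory=dict)
    covariate_paths: dict[str, str] = field(default_factory=dict)
    panel_paths: dict[str, str] = field(default_factory=dict)
    annotation_path: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pr = raw.pop("params", {})
        if "concordance_min" in pr:
            pr["concordance_min"] = Fraction(str(pr["concordance_min"]))
        if "sharpness_grid" in pr:
            pr["sharpness_grid"] = tuple(pr["sharpness_grid"])
        return cls(params=PipelineParams(**pr), **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["params"]["concordance_min"] = str(self.params.concordance_min)
        d["params"]["sharpness_grid"] = list(self.params.sharpness_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class CohortAnalysis:
    name: str
    ancestry: pd.DataFrame
    groups: pd.Series
    raw: pd.DataFrame
    log: pd.DataFrame
    imputed: pd.DataFrame
    qc: qcm.QCReport
    screen: scr.ScreenResult


@dataclass
class StudyResult:
    params: PipelineParams
    freqs: pd.DataFrame
    aims: pd.DataFrame
    discovery: CohortAnalysis
    replication: CohortAnalysis | None
    plsda: scr.PLSDAResult | None
    sensitivity: scr.SensitivityResult | None
    cluster_set: clu.ClusterSet
    mmc: clu.MMCResult | None
    cluster_tests: list[ct.ClusterTestResult]
    cluster_bonferroni: ct.BonferroniResult | None
    replication_results: list[ct.ReplicationResult]
    dose_response: dict[str, pd.DataFrame]

    @property
    def significant_clusters(self) -> list[str]:
        return [r.label for r in self.cluster_tests if r.significant]

    @property
    def replicated_clusters(self) -> list[str]:
        return [r.label for r in self.replication_results if r.replicated]

    def stage_counts(self) -> dict[str, int]:
        return {
            "aims_retained": len(self.aims),
            "metabolites_retained": self.discovery.qc.n_retained,
            "metabolites_significant": len(self.discovery.screen.significant),
            "metabolites_clustered": len(self.cluster_set.members),
            "metabolites_excluded_nonclustering": len(self.cluster_set.excluded),
            "clusters": len(self.cluster_set.clusters),
            "clusters_significant": len(self.significant_clusters),
            "clusters_replicated": len(self.replicated_clusters),
        }


def _analyze_cohort(
    name: str,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    metabolome: pd.DataFrame,
    annotations: pd.DataFrame,
    aims: pd.DataFrame,
    params: PipelineParams,
) -> CohortAnalysis:
    est = anc.estimate_admixture(
        genotypes[aims.index], aims, cutoff=params.ancestry_cutoff
    )
    groups = est["group"].astype(str)
    filtered, log_df, imputed, qc_report = qcm.run_qc(
        metabolome,
        annotations,
        groups=groups,
        max_missing=params.max_missing,
        knn_k=params.knn_k,
        pca_z_thresh=params.pca_z_thresh,
        sed_thresh_sd=params.sed_thresh_sd,
        ba_outlier_frac=params.ba_outlier_frac,
        cv_top_frac=params.cv_top_frac,
    )
    screen_res = scr.screen_metabolites(
        log_df, covariates, groups, fdr_threshold=params.fdr_threshold
    )
    return CohortAnalysis(
        name=name, ancestry=est, groups=groups, raw=filtered, log=log_df,
        imputed=imputed, qc=qc_report, screen=screen_res,
    )


def analyze_study(study: sim.Study, params: PipelineParams | None = None) -> StudyResult:
    """Run the full three-phase analysis on an in-memory study bundle."""
    if params is None:
        params = PipelineParams()
    freqs = anc.estimate_panel_frequencies(study.panels, params.pseudocount)
    aims = anc.select_aims(freqs, params.min_freq_diff)

    disc = _analyze_cohort(
        "discovery", study.discovery.genotypes, study.discovery.covariates,
        study.discovery.metabolome, study.annotations, aims, params,
    )
    plsda = scr.plsda_scores(disc.imputed, disc.groups)
    pca_sed_flagged = [
        s for s, methods in disc.qc.flagged_samples.items()
        if {"PCA", "SED"} & set(methods)
    ]
    sensitivity = scr.sensitivity_rescreen(
        disc.log, study.discovery.covariates, disc.groups, pca_sed_flagged,
        fdr_threshold=params.fdr_threshold, full_result=disc.screen,
    )

    significant = disc.screen.significant
    mmc_res = None
    if len(significant) >= 2:
        r = clu.correlation_matrix(disc.imputed[significant])
        mmc_res = clu.mmc_cluster(r, sharpness_grid=params.sharpness_grid)
        cluster_set = clu.biology_refine(
            mmc_res.partition, study.annotations,
            min_size=params.min_cluster_size, corr=r,
        )
    elif len(significant) == 1:
        cluster_set = clu.ClusterSet(
            clusters={}, excluded={significant[0]: clu.REASON_ORPHAN}
        )
    else:
        cluster_set = clu.ClusterSet(clusters={}, excluded={})

    cluster_tests, cluster_bonf = ct.test_clusters(
        disc.imputed, cluster_set.clusters, study.discovery.covariates,
        disc.groups, alpha=params.alpha,
    )
    significant_clusters = {
        r.label: cluster_set.clusters[r.label]
        for r in cluster_tests if r.significant
    }

    rep = None
    rep_results: list[ct.ReplicationResult] = []
    dose: dict[str, pd.DataFrame] = {}
    if study.replication is not None:
        rep = _analyze_cohort(
            "replication", study.replication.genotypes,
            study.replication.covariates, study.replication.metabolome,
            study.annotations, aims, params,
        )
        if significant_clusters:
            rep_results = ct.replicate_clusters(
                significant_clusters, rep.imputed,
                study.replication.covariates, rep.groups,
                disc.screen.table, rep.screen.table,
                alpha=params.alpha, concordance_min=params.concordance_min,
            )
        replicated = {
            r.label: significant_clusters[r.label]
            for r in rep_results if r.replicated
        }
        if replicated:
            for cohort_name, cohort_an, cov in (
                ("discovery", disc, study.discovery.covariates),
                ("replication", rep, study.replication.covariates),
            ):
                q = cohort_an.ancestry["q"]
                dose[cohort_name] = ct.dose_response(
                    cohort_an.log, q, cov, replicated,
                    cutoff=params.ancestry_cutoff,
                )

    return StudyResult(
        params=params, freqs=freqs, aims=aims, discovery=disc, replication=rep,
        plsda=plsda, sensitivity=sensitivity, cluster_set=cluster_set,
        mmc=mmc_res, cluster_tests=cluster_tests,
        cluster_bonferroni=cluster_bonf, replication_results=rep_results,
        dose_response=dose,
    )


# ---------------------------------------------------------------------------
# file-level driver

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_study(config: PipelineConfig) -> sim.Study:
    if config.simulate:
        sim_cfg = sim.SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.simulation.items()
        })
        return sim.simulate_study(sim_cfg, seed=config.seed)
    panels = {
        pop: aio.read_dosage_tsv(p) for pop, p in sorted(config.panel_paths.items())
    }
    annotations = aio.read_table_tsv(config.annotation_path)
    annotations["known"] = annotations["known"].astype(bool)
    annotations["xenobiotic"] = annotations["xenobiotic"].astype(bool)

    def load_cohort(name: str) -> sim.Cohort:
        dosages, _ = aio.load_genotypes(config.genotype_paths[name])
        cov = aio.read_table_tsv(config.covariate_paths[name])
        met = aio.read_matrix_tsv(config.metabolome_paths[name])
        return sim.Cohort(name=name, genotypes=dosages, covariates=cov,
                          metabolome=met, q_true=pd.Series(dtype=float))

    discovery = load_cohort("discovery")
    replication = None if config.discovery_only else load_cohort("replication")
    markers = pd.DataFrame(index=discovery.genotypes.columns)
    return sim.Study(
        config=sim.SimulationConfig(), markers=markers, panels=panels,
        annotations=annotations, truth=None, discovery=discovery,
        replication=replication,
    )


def _replication_table(results: list[ct.ReplicationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": [r.label for r in results],
            "n_available": [r.n_available for r in results],
            "n_lost": [r.n_lost for r in results],
            "pct_variance_pc1": [r.pct_variance for r in results],
            "beta": [r.beta for r in results],
            "p": [r.p for r in results],
            "bonferroni_threshold": [r.bonferroni_threshold for r in results],
            "concordance": [
                float(r.concordance) if r.concordance is not None else np.nan
                for r in results
            ],
            "concordant": [r.concordant for r in results],
            "compared": [r.compared for r in results],
            "replicated": [r.replicated for r in results],
            "mannwhitney_p": [
                r.mannwhitney_p if r.mannwhitney_p is not None else np.nan
                for r in results
            ],
        }
    ).set_index("cluster")


def _cluster_table(tests: list[ct.ClusterTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": [t.label for t in tests],
            "n_metabolites": [t.n_metabolites for t in tests],
            "pct_variance_pc1": [t.pct_variance for t in tests],
            "beta": [t.beta for t in tests],
            "p": [t.p for t in tests],
            "n": [t.n for t in tests],
            "significant": [t.significant for t in tests],
            "skewness": [t.flags.skewness for t in tests],
            "bimodality": [t.flags.bimodality for t in tests],
            "flag": [t.flags.flag for t in tests],
        }
    ).set_index("cluster")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and write the run directory; returns its path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    try:
        study = _load_study(config)
        result = analyze_study(study, config.params)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if failed_marker.exists():
        failed_marker.unlink()

    for cohort in filter(None, (result.discovery, result.replication)):
        aio.write_table_tsv(out / f"ancestry_{cohort.name}.tsv", cohort.ancestry)
        aio.write_json(out / f"qc_{cohort.name}.json", cohort.qc.to_dict())
        aio.write_table_tsv(out / f"screen_{cohort.name}.tsv", cohort.screen.table)
    aio.write_table_tsv(out / "covariates_discovery.tsv", study.discovery.covariates)
    if study.replication is not None:
        aio.write_table_tsv(out / "covariates_replication.tsv",
                            study.replication.covariates)
    aio.write_table_tsv(out / "aims.tsv", result.aims)
    if result.plsda is not None:
        aio.write_table_tsv(out / "plsda_scores.tsv", result.plsda.scores)
    aio.write_json(out / "clusters.json", result.cluster_set.to_dict())
    aio.write_table_tsv(out / "cluster_tests.tsv", _cluster_table(result.cluster_tests))
    aio.write_table_tsv(
        out / "replication.tsv", _replication_table(result.replication_results)
    )
    for name, table in result.dose_response.items():
        aio.write_table_tsv(out / f"dose_response_{name}.tsv", table)
    for t in result.cluster_tests:
        safe = "".join(c if c.isalnum() else "_" for c in t.label)[:60]
        export = pd.DataFrame(
            {"pc1": t.pc1, "group": result.discovery.groups.loc[t.pc1.index]}
        )
        aio.write_table_tsv(out / f"pc1_discovery_{safe}.tsv", export)

    import sklearn
    import statsmodels

    manifest = {
        "seed": config.seed,
        "mode": "discovery-only" if config.discovery_only else "two-cohort",
        "simulated": config.simulate,
        "config": json.loads(json.dumps(
            dataclasses.asdict(config),
            default=lambda o: str(o))),
        "stage_counts": result.stage_counts(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": __import__("scipy").__version__,
            "statsmodels": statsmodels.__version__,
            "sklearn": sklearn.__version__,
        },
        "input_checksums": {
            str(p): _sha256(Path(p))
            for paths in (config.genotype_paths, config.metabolome_paths,
                          config.covariate_paths, config.panel_paths)
            for p in paths.values()
            if not config.simulate and Path(p).exists()
        },
    }
    aio.write_json(out / "manifest.json", manifest)
    return out


# ---------------------------------------------------------------------------
# descriptive reporting

def descriptive_table(covariates: pd.DataFrame, groups: pd.Series,
                      q: pd.Series | None = None) -> pd.DataFrame:
    """Baseline-characteristics block with group comparisons.

    Age: mean +/- SD and t-test. PRA (and ancestry proportion when given):
    median (IQR) and Mann-Whitney. Sex: N (%) female and chi-square.
    """
    lo = groups == "low"
    hi = groups == "high"
    rows = []

    def mean_sd(x):
        return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"

    def med_iqr(x):
        return f"{x.median():.2f} ({x.quantile(0.25):.2f}–{x.quantile(0.75):.2f})"

    age = covariates["age"]
    t_p = stats.ttest_ind(age[lo], age[hi], equal_var=True).pvalue
    rows.append(("Age, years", mean_sd(age[lo]), mean_sd(age[hi]), t_p, "t-test"))

    sex = covariates["sex"]
    table = pd.crosstab(sex, groups)
    chi_p = stats.chi2_contingency(table.to_numpy(), correction=False).pvalue
    f_lo = int((sex[lo] == "F").sum())
    f_hi = int((sex[hi] == "F").sum())
    rows.append((
        "Female, N (%)",
        f"{f_lo} ({100 * f_lo / max(lo.sum(), 1):.1f}%)",
        f"{f_hi} ({100 * f_hi / max(hi.sum(), 1):.1f}%)",
        chi_p, "chi-square",
    ))

    pra = covariates["pra"]
    mw_p = stats.mannwhitneyu(pra[lo], pra[hi], alternative="two-sided").pvalue
    rows.append(("Baseline PRA, ng/mL/h", med_iqr(pra[lo]), med_iqr(pra[hi]),
                 mw_p, "Mann-Whitney"))

    if q is not None:
        mw_q = stats.mannwhitneyu(q[lo], q[hi], alternative="two-sided").pvalue
        rows.append(("GWAA (%)",
                     med_iqr(100 * q[lo]), med_iqr(100 * q[hi]),
                     mw_q, "Mann-Whitney"))

    return pd.DataFrame(
        rows, columns=["variable", "low_gwaa", "high_gwaa", "p", "test"]
    ).set_index("variable")


def report(run_dir: str | Path) -> str:
    """Render a plain-text summary of a completed run directory.

    Purely a formatting layer over the stage outputs; regenerating the
    report from the same directory is byte-identical.
    """
    run_dir = Path(run_dir)
    lines = ["admixmet run summary", "=" * 40]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"mode: {manifest['mode']}, seed: {manifest['seed']}")
        lines.append("stage counts:")
        for k, v in sorted(manifest["stage_counts"].items()):
            lines.append(f"  {k}: {v}")
    else:
        lines.append("manifest.json missing -- partial report")

    for name in ("discovery", "replication"):
        path = run_dir / f"ancestry_{name}.tsv"
        if not path.exists():
            continue
        est = aio.read_table_tsv(path)
        cov_path = run_dir / f"covariates_{name}.tsv"
        lines.append(f"\n{name} cohort: n={len(est)}, "
                     f"low={int((est['group'] == 'low').sum())}, "
                     f"high={int((est['group'] == 'high').sum())}")
        if cov_path.exists():
            cov = aio.read_table_tsv(cov_path)
            desc = descriptive_table(cov, est["group"], est["q"])
            lines.append(desc.to_string(float_format=lambda v: f"{v:.3g}"))

    ct_path = run_dir / "cluster_tests.tsv"
    if ct_path.exists():
        tbl = aio.read_table_tsv(ct_path)
        lines.append("\ndiscovery cluster tests:")
        lines.append(
            tbl[["n_metabolites", "pct_variance_pc1", "p", "significant", "flag"]]
            .to_string(float_format=lambda v: f"{v:.3g}")
        )
    else:
        lines.append("\ncluster tests missing -- gap")
    rep_path = run_dir / "replication.tsv"
    if rep_path.exists():
        tbl = aio.read_table_tsv(rep_path)
        if len(tbl):
            lines.append("\nreplication verdicts:")
            lines.append(
                tbl[["n_available", "pct_variance_pc1", "p", "concordance",
                     "replicated"]].to_string(float_format=lambda v: f"{v:.3g}")
            )
    return "\n".join(lines) + "\n"
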