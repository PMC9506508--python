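"""Synthetic two-cohort generator for ancestry-stratified metabolomics.

Generates everything the downstream pipeline consumes, with known ground
truth: two ancestral reference panels genotyped at ancestry-informative
markers (AIMs), two admixed hypertensive cohorts ("discovery" and
"replication") with a bimodal West African ancestry (GWAA) distribution,
ancestry-dependent plasma renin activity (PRA), and log-normal metabolite
abundance matrices with planted correlation clusters, ancestry effects,
batch effects and left-censored missingness.

Defaults emulate the study conditions of a two-trial hypertension
pharmacogenomics setting: 84 AIMs with >=30% allele-frequency differential,
90 reference individuals per ancestral population, cohorts of 633 and 411
participants (roughly 60% in the low-GWAA component, medians ~1.6% and
~85%), and 1223 detected metabolites of which ~15.6% are xenobiotics,
~20.6% are chemically unidentified and ~11.9% have heavy missingness.

Every stochastic operation takes an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "Cohort",
    "Study",
    "make_reference_panels",
    "draw_admixture_proportions",
    "draw_genotypes",
    "draw_covariates",
    "draw_metabolome",
    "make_truth",
    "simulate_study",
]

POP_AFR = "AFR"
POP_EUR = "EUR"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with study-condition defaults.

    Ancestry side
    -------------
    n_markers, n_ref_per_pop, min_freq_diff : AIM panel geometry — 84
        unlinked biallelic markers, 90 individuals per ancestral reference
        panel, and a minimum |p_AFR - p_EUR| of 0.30 for the true
        frequencies.
    mix_weight_low : fraction of each cohort drawn from the low-GWAA
        mixture component (default 383/633 ~ 0.605).
    beta_low, beta_high : (a, b) of the two Beta components of the GWAA
        mixture. Beta(1.3, 60) has median 0.016; Beta(18, 3.4) has median
        0.852, matching the reported group medians.

    Covariates
    ----------
    age_mean/age_sd, female_frac, n_sites, n_batches : demographic and
        design covariates, assigned independently of ancestry.
    log_pra_mean_low/high, log_pra_sd : log-normal PRA location per
        ancestry group (medians 0.9 and 0.4 ng/mL/h) and common scale.

    Metabolome
    ----------
    n_metabolites : detected features before any filtering.
    cluster_sizes : sizes of the planted correlation clusters; the first
        ``n_differential`` are differential between ancestry groups.
    n_pos / n_discordant : per differential cluster, how many members have
        a positive (higher-in-high-GWAA) true direction in the discovery
        cohort, and how many flip sign in the replication cohort.
    effect_size : |group mean shift| on the natural-log scale.
    latent_loading, noise_sd : within-cluster latent factor loading and
        residual SD; loading 1.0 over SD 0.6 gives within-cluster
        |r| ~ 0.74.
    baseline_mean/sd : per-metabolite log-abundance baselines.
    batch_sd : SD of per-(batch, metabolite) additive log shifts.
    missing_rate, censor_share : total missingness for ordinary
        metabolites and the share of it realised as left-censoring below a
        per-metabolite detection quantile (the rest is uniform dropout).
    xenobiotic_frac, unknown_frac, unclassified_frac, high_missing_frac :
        annotation mix; high-missingness metabolites get a missing rate
        drawn from ``high_missing_range``.
    replication_absent_frac : fraction of non-differential metabolites
        absent from the replication cohort's assay.
    n_unknown_per_cluster : chemically unidentified members planted inside
        each cluster (they must be rescued by correlation clustering).
    """

    # ancestry
    n_markers: int = 84
    n_ref_per_pop: int = 90
    min_freq_diff: float = 0.30
    n_discovery: int = 633
    n_replication: int = 411
    mix_weight_low: float = 0.605
    beta_low: tuple[float, float] = (1.3, 60.0)
    beta_high: tuple[float, float] = (18.0, 3.4)
    # covariates
    age_mean: float = 50.0
    age_sd: float = 9.5
    female_frac: float = 0.5
    n_sites: int = 3
    n_batches: int = 4
    log_pra_mean_low: float = math.log(0.9)
    log_pra_mean_high: float = math.log(0.4)
    log_pra_sd: float = 0.81
    ancestry_cutoff: float = 0.45
    # metabolome
    n_metabolites: int = 1223
    cluster_sizes: tuple[int, ...] = (15, 14, 22, 12, 12, 12, 12, 12, 12, 12, 12, 12)
    n_differential: int = 4
    n_pos: tuple[int, ...] = (15, 7, 16, 12)
    n_discordant: tuple[int, ...] = (1, 1, 2, 0)
    effect_size: float = 0.8
    latent_loading: float = 1.0
    noise_sd: float = 0.6
    baseline_mean: float = 15.0
    baseline_sd: float = 2.0
    batch_sd: float = 0.1
    missing_rate: float = 0.15
    censor_share: float = 0.7
    xenobiotic_frac: float = 0.156
    unknown_frac: float = 0.206
    unclassified_frac: float = 0.03
    high_missing_frac: float = 0.119
    high_missing_range: tuple[float, float] = (0.65, 0.95)
    replication_absent_frac: float = 0.15
    n_unknown_per_cluster: int = 2

    def __post_init__(self) -> None:
        for name in ("min_freq_diff",):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in (
            "mix_weight_low", "female_frac", "missing_rate", "censor_share",
            "xenobiotic_frac", "unknown_frac", "unclassified_frac",
            "high_missing_frac", "replication_absent_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_markers", "n_ref_per_pop", "n_discovery",
                     "n_replication", "n_metabolites", "n_sites", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(a <= 0 or b <= 0 for a, b in (self.beta_low, self.beta_high)):
            raise ValueError("Beta component parameters must be positive")
        if sum(self.cluster_sizes) > self.n_metabolites:
            raise ValueError("cluster sizes exceed n_metabolites")
        if self.n_differential > len(self.cluster_sizes):
            raise ValueError("n_differential exceeds number of clusters")
        if len(self.n_pos) != self.n_differential or len(self.n_discordant) != self.n_differential:
            raise ValueError("n_pos / n_discordant must have length n_differential")
        for i in range(self.n_differential):
            if self.n_pos[i] > self.cluster_sizes[i]:
                raise ValueError("n_pos exceeds cluster size")
            if self.n_discordant[i] > self.cluster_sizes[i]:
                raise ValueError("n_discordant exceeds cluster size")


@dataclass
class TruthRecord:
    """Ground truth shared by the two cohorts.

    ``metabolites`` has one row per metabolite: ``cluster`` (planted
    cluster label or empty), ``differential`` flag, ``direction_discovery``
    and ``direction_replication`` in {+1, -1, 0}, the per-metabolite
    ``baseline``, ``loading`` and ``missing_rate``, and ``in_replication``
    availability. ``q`` ancestry proportions live on each cohort.
    """

    metabolites: pd.DataFrame
    cluster_labels: list[str] = field(default_factory=list)
    differential_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = self.metabolites["direction_discovery"]
        if not d.isin([-1, 0, 1]).all():
            raise ValueError("directions must be in {-1, 0, +1}")


@dataclass
class Cohort:
    name: str
    genotypes: pd.DataFrame          # samples x markers, dosages 0/1/2
    covariates: pd.DataFrame         # age, sex, site, batch, pra
    metabolome: pd.DataFrame         # samples x metabolites, raw area counts, NaN missing
    q_true: pd.Series


@dataclass
class Study:
    config: SimulationConfig
    markers: pd.DataFrame            # marker_id, chrom, pos, ref, alt, p_AFR, p_EUR
    panels: dict[str, pd.DataFrame]  # population -> samples x markers dosages
    annotations: pd.DataFrame        # metabolite_id, super_pathway, sub_pathway, known, xenobiotic
    truth: TruthRecord
    discovery: Cohort
    replication: Cohort


# ---------------------------------------------------------------------------
# reference panels and genotypes

def make_reference_panels(
    config: SimulationConfig, rng: np.random.Generator, max_attempts: int = 10_000
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw true ancestral allele frequencies and reference-panel genotypes.

    True frequencies are sampled uniformly on [0.01, 0.99] subject to
    |p_AFR - p_EUR| >= ``config.min_freq_diff`` (rejection sampling, bounded
    by ``max_attempts`` batches). Panel genotypes are Binomial(2, p) per
    individual.

    Returns a marker table (id, chrom, pos, ref, alt, p_AFR, p_EUR) and a
    dict of per-population genotype DataFrames.
    """
    m = config.n_markers
    p_afr = np.empty(m)
    p_eur = np.empty(m)
    filled = 0
    for _ in range(max_attempts):
        need = m - filled
        if need == 0:
            break
        a = rng.uniform(0.01, 0.99, size=need)
        e = rng.uniform(0.01, 0.99, size=need)
        ok = np.abs(a - e) >= config.min_freq_diff
        k = int(ok.sum())
        p_afr[filled:filled + k] = a[ok]
        p_eur[filled:filled + k] = e[ok]
        filled += k
    else:
        raise ValueError(
            f"could not find {m} marker frequency pairs with "
            f"|p_AFR - p_EUR| >= {config.min_freq_diff} after {max_attempts} attempts"
        )

    ids = [f"AIM_{i + 1:03d}" for i in range(m)]
    markers = pd.DataFrame(
        {
            "marker_id": ids,
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "p_AFR": p_afr,
            "p_EUR": p_eur,
        }
    ).set_index("marker_id")

    panels = {}
    for pop, p in ((POP_AFR, p_afr), (POP_EUR, p_eur)):
        g = rng.binomial(2, p, size=(config.n_ref_per_pop, m))
        idx = [f"{pop}_{i + 1:03d}" for i in range(config.n_ref_per_pop)]
        panels[pop] = pd.DataFrame(g, index=idx, columns=ids)
    return markers, panels


def draw_admixture_proportions(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw GWAA proportions from the two-component Beta mixture."""
    low = rng.random(n) < config.mix_weight_low
    q = np.empty(n)
    a, b = config.beta_low
    q[low] = rng.beta(a, b, size=int(low.sum()))
    a, b = config.beta_high
    q[~low] = rng.beta(a, b, size=int((~low).sum()))
    return q


def draw_genotypes(
    markers: pd.DataFrame, q: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw counted-allele dosages g ~ Binomial(2, q*p_AFR + (1-q)*p_EUR).

    Each of an individual's two allele copies descends from the African
    ancestral population with probability q (independent markers, no
    linkage).
    """
    q = np.asarray(q, dtype=float)
    p_a = markers["p_AFR"].to_numpy()
    p_e = markers["p_EUR"].to_numpy()
    if p_a.shape != p_e.shape:
        raise ValueError("frequency vectors must have equal length")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    pi = q[:, None] * p_a[None, :] + (1 - q[:, None]) * p_e[None, :]
    return rng.binomial(2, pi)


# ---------------------------------------------------------------------------
# covariates

def draw_covariates(
    config: SimulationConfig,
    q: np.ndarray,
    rng: np.random.Generator,
    sample_ids: list[str],
) -> pd.DataFrame:
    """Draw age, sex, site, batch and baseline PRA.

    PRA is log-normal with an ancestry-group-dependent location (medians
    0.9 vs 0.4 ng/mL/h under defaults); sites and batches are assigned
    independently of ancestry.
    """
    n = len(sample_ids)
    high = np.asarray(q) >= config.ancestry_cutoff
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = np.where(rng.random(n) < config.female_frac, "F", "M")
    site = rng.integers(1, config.n_sites + 1, size=n)
    batch = rng.integers(1, config.n_batches + 1, size=n)
    mu = np.where(high, config.log_pra_mean_high, config.log_pra_mean_low)
    pra = np.exp(rng.normal(mu, config.log_pra_sd))
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "site": [f"site{s}" for s in site],
            "batch": [f"batch{b}" for b in batch],
            "pra": pra,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# metabolome

_SUBPATHWAY_PAIRS: list[tuple[str, ...]] = [
    ("Plasmalogen", "Lysoplasmalogen"),
    ("Sphingolipid Metabolism", "Ceramides"),
    ("Cofactors and Vitamins",),
    ("Urea cycle; Arginine and Proline Metabolism",),
]

_BACKGROUND_SUBPATHWAYS = [
    "Fatty Acid", "Fatty Acid Metabolism (Acyl Carnitine)", "Histidine Metabolism",
    "Lysine Metabolism", "Tyrosine Metabolism", "Glutathione Metabolism",
    "Leucine, Isoleucine and Valine Metabolism", "Primary Bile Acid Metabolism",
    "Secondary Bile Acid Metabolism", "Pyrimidine Metabolism", "Purine Metabolism",
    "Gamma-glutamyl Amino Acid", "Phospholipid Metabolism", "Lysophospholipid",
    "Steroid", "Glycine, Serine and Threonine Metabolism", "Glutamate Metabolism",
    "Methionine, Cysteine, SAM and Taurine Metabolism", "Carbohydrate",
    "Creatine Metabolism", "Tryptophan Metabolism", "Alanine and Aspartate Metabolism",
    "Diacylglycerol", "Monoacylglycerol", "Polyamine Metabolism",
    "Guanidino and Acetamido Metabolism", "Energy", "Benzoate Metabolism",
]


def make_truth(config: SimulationConfig, rng: np.random.Generator) -> tuple[TruthRecord, pd.DataFrame]:
    """Lay out metabolite ground truth shared by both cohorts.

    Assigns cluster membership, true effect directions per cohort,
    per-metabolite baselines and missing rates, and annotation labels
    (xenobiotic / unknown / known-unclassified). Returns the TruthRecord
    and the annotation table.
    """
    n = config.n_metabolites
    ids = [f"M{i + 1:05d}" for i in range(n)]
    cluster = np.array([""] * n, dtype=object)
    sub_pathway = np.array([""] * n, dtype=object)
    known = np.ones(n, dtype=bool)
    xeno = np.zeros(n, dtype=bool)
    dir_disc = np.zeros(n, dtype=int)
    dir_rep = np.zeros(n, dtype=int)
    differential = np.zeros(n, dtype=bool)
    loading = np.zeros(n)
    in_rep = np.ones(n, dtype=bool)

    labels = []
    pos = 0
    for ci, size in enumerate(config.cluster_sizes):
        if ci < len(_SUBPATHWAY_PAIRS):
            pathways = _SUBPATHWAY_PAIRS[ci]
            label = " and ".join(p.lower() for p in pathways) if len(pathways) > 1 else pathways[0]
        else:
            pw = _BACKGROUND_SUBPATHWAYS[ci - len(_SUBPATHWAY_PAIRS)]
            pathways, label = (pw,), pw
        labels.append(label)
        members = np.arange(pos, pos + size)
        cluster[members] = label
        loading[members] = config.latent_loading
        # planted unknowns must be rescued by correlation clustering
        n_unk = min(config.n_unknown_per_cluster, size - 1)
        known[members[size - n_unk:]] = False
        for j, mi in enumerate(members):
            sub_pathway[mi] = pathways[j % len(pathways)] if known[mi] else ""
        if ci < config.n_differential:
            differential[members] = True
            signs = np.where(np.arange(size) < config.n_pos[ci], 1, -1)
            dir_disc[members] = signs
            rep_signs = signs.copy()
            if config.n_discordant[ci]:
                flip = rng.choice(size, size=config.n_discordant[ci], replace=False)
                rep_signs[flip] = -rep_signs[flip]
            dir_rep[members] = rep_signs
        pos += size

    background = np.arange(pos, n)
    n_bg = len(background)
    # annotation mix applied to the background only, so planted clusters are
    # never filtered out as xenobiotic or heavy-missingness
    shuffled = rng.permutation(background)
    n_xeno = int(round(config.xenobiotic_frac * n))
    n_unknown_total = int(round(config.unknown_frac * n))
    n_unknown_bg = max(0, n_unknown_total - int((~known).sum()))
    n_unclassified = int(round(config.unclassified_frac * n))
    take = 0
    xeno[shuffled[take:take + n_xeno]] = True
    take += n_xeno
    known[shuffled[take:take + n_unknown_bg]] = False
    take += n_unknown_bg
    uncl = shuffled[take:take + n_unclassified]  # known but no pathway
    take += n_unclassified
    uncl_set = set(uncl.tolist())
    for mi in background:
        if known[mi] and mi not in uncl_set:
            sub_pathway[mi] = _BACKGROUND_SUBPATHWAYS[int(rng.integers(len(_BACKGROUND_SUBPATHWAYS)))]
    sub_pathway[uncl] = ""

    miss = np.full(n, config.missing_rate)
    n_high = int(round(config.high_missing_frac * n))
    eligible = shuffled[take:]  # background, not already consumed
    if n_high > len(eligible):
        n_high = len(eligible)
    high_idx = eligible[:n_high]
    lo, hi = config.high_missing_range
    miss[high_idx] = rng.uniform(lo, hi, size=n_high)

    # replication availability: drop a fraction of non-differential metabolites
    droppable = np.flatnonzero(~differential)
    n_drop = int(round(config.replication_absent_frac * len(droppable)))
    if n_drop:
        in_rep[rng.choice(droppable, size=n_drop, replace=False)] = False

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    truth = TruthRecord(
        metabolites=pd.DataFrame(
            {
                "cluster": cluster,
                "differential": differential,
                "direction_discovery": dir_disc,
                "direction_replication": dir_rep,
                "baseline": baseline,
                "loading": loading,
                "missing_rate": miss,
                "in_replication": in_rep,
            },
            index=pd.Index(ids, name="metabolite_id"),
        ),
        cluster_labels=labels,
        differential_labels=labels[: config.n_differential],
    )
    annotations = pd.DataFrame(
        {
            "super_pathway": np.where(xeno, "Xenobiotics", np.where(known, "Endogenous", "")),
            "sub_pathway": sub_pathway,
            "known": known,
            "xenobiotic": xeno,
        },
        index=pd.Index(ids, name="metabolite_id"),
    )
    return truth, annotations


def draw_metabolome(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    q: np.ndarray,
    rng: np.random.Generator,
    truth: TruthRecord,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Draw a raw abundance matrix (samples x metabolites) for one cohort.

    Each planted cluster is driven by a latent factor; members load on it
    with signed loadings (the member's true effect direction), and for
    differential clusters the factor itself is shifted by ``effect_size``
    in the high-GWAA group. A member's log-abundance group difference is
    therefore loading_j * effect_size, and anti-correlated members carry
    the opposing directions — so the cluster PC1 aggregates the effect
    rather than cancelling it. Log-abundance = baseline + signed loading
    * factor + batch shift + noise; raw = exp(log). Missingness is
    left-censoring below the per-metabolite detection quantile (share
    ``censor_share`` of the total rate) plus uniform dropout for the
    remainder. Metabolites absent from the replication assay are dropped
    entirely for that cohort.
    """
    meta = truth.metabolites
    n_s = len(covariates)
    n_m = len(meta)
    high = (np.asarray(q) >= config.ancestry_cutoff).astype(float)
    dir_col = "direction_replication" if cohort == "replication" else "direction_discovery"
    direction = meta[dir_col].to_numpy(dtype=float)
    differential = meta["differential"].to_numpy(dtype=bool)
    signed_loading = meta["loading"].to_numpy() * np.where(differential, direction, 1.0)

    log_x = np.tile(meta["baseline"].to_numpy(), (n_s, 1))
    # latent cluster factors induce within-cluster correlation; the
    # ancestry effect enters through the factor of differential clusters
    for label in truth.cluster_labels:
        members = np.flatnonzero((meta["cluster"] == label).to_numpy())
        factor = rng.normal(size=n_s)
        if differential[members].any():
            factor = factor + config.effect_size * high
        log_x[:, members] += factor[:, None] * signed_loading[members][None, :]
    # batch shifts
    batches = covariates["batch"].to_numpy()
    for b in np.unique(batches):
        shift = rng.normal(0.0, config.batch_sd, size=n_m)
        log_x[batches == b] += shift[None, :]
    log_x += rng.normal(0.0, config.noise_sd, size=(n_s, n_m))

    raw = np.exp(log_x)
    # left-censoring below the detection quantile, then uniform dropout
    rates = meta["missing_rate"].to_numpy()
    c = rates * config.censor_share
    for j in range(n_m):
        if rates[j] <= 0:
            continue
        thr = np.quantile(raw[:, j], c[j])
        censored = raw[:, j] < thr
        remaining = (rates[j] - c[j]) / max(1.0 - c[j], 1e-12)
        drop = (~censored) & (rng.random(n_s) < remaining)
        raw[censored | drop, j] = np.nan

    df = pd.DataFrame(raw, index=covariates.index, columns=meta.index)
    if cohort == "replication":
        df = df.loc[:, meta["in_replication"].to_numpy()]
    return df


# ---------------------------------------------------------------------------
# whole-study driver

def _simulate_cohort(
    config: SimulationConfig,
    markers: pd.DataFrame,
    truth: TruthRecord,
    rng: np.random.Generator,
    name: str,
    n: int,
    prefix: str,
) -> Cohort:
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    q = draw_admixture_proportions(config, rng, n)
    genotypes = pd.DataFrame(
        draw_genotypes(markers, q, rng), index=ids, columns=markers.index
    )
    covariates = draw_covariates(config, q, rng, ids)
    metabolome = draw_metabolome(config, covariates, q, rng, truth, cohort=name)
    return Cohort(
        name=name,
        genotypes=genotypes,
        covariates=covariates,
        metabolome=metabolome,
        q_true=pd.Series(q, index=ids, name="q_true"),
    )


def simulate_study(config: SimulationConfig | None = None, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> Study:
    """Simulate the full two-cohort study with shared ground truth."""
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    markers, panels = make_reference_panels(config, rng)
    truth, annotations = make_truth(config, rng)
    discovery = _simulate_cohort(
        config, markers, truth, rng, "discovery", config.n_discovery, "D"
    )
    replication = _simulate_cohort(
        config, markers, truth, rng, "replication", config.n_replication, "R"
    )
    return Study(
        config=config,
        markers=markers,
        panels=panels,
        annotations=annotations,
        truth=truth,
        discovery=discovery,
        replication=replication,
    )


def null_config(**overrides) -> SimulationConfig:
    """A configuration with no planted ancestry effects (null calibration)."""
    base = SimulationConfig(
        n_differential=0, n_pos=(), n_discordant=(), **overrides
    )
    return base


def scaled_config(**overrides) -> SimulationConfig:
    """A smaller study for fast end-to-end tests; same structure, fewer
    background metabolites and participants."""
    defaults = dict(
        n_discovery=240,
        n_replication=160,
        n_metabolites=360,
        high_missing_frac=0.08,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
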