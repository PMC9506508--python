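import numpy as np
import pandas as pd
import pytest

from admixmet.simulate import SimulationConfig, scaled_config, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_study():
    """A scaled two-cohort study shared by read-only tests."""
    return simulate_study(scaled_config(), seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    """A very small configuration for fast generator checks."""
    return SimulationConfig(
        n_markers=20,
        n_ref_per_pop=40,
        n_discovery=80,
        n_replication=60,
        n_metabolites=60,
        cluster_sizes=(8, 6),
        n_differential=2,
        n_pos=(8, 3),
        n_discordant=(1, 0),
        high_missing_frac=0.05,
    )


def make_covariates(n, rng, n_sites=2, n_batches=2):
    """Covariate table helper for regression tests."""
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(
        {
            "age": rng.normal(50, 8, n),
            "sex": rng.choice(["F", "M"], n),
            "site": rng.choice([f"site{i}" for i in range(1, n_sites + 1)], n),
            "batch": rng.choice([f"batch{i}" for i in range(1, n_batches + 1)], n),
            "pra": np.exp(rng.normal(0, 0.5, n)),
        },
        index=idx,
    )


def make_groups(covariates, rng, p_high=0.4):
    return pd.Series(
        np.where(rng.random(len(covariates)) < p_high, "high", "low"),
        index=covariates.index,
    )
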