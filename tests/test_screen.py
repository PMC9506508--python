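import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from admixmet.screen import (
    bh_fdr,
    build_design,
    fit_metabolite_model,
    plsda_scores,
    screen_metabolites,
    sensitivity_rescreen,
)
from conftest import make_covariates, make_groups
from oracles import bh_stepup, ols_normal_equations


@pytest.fixture
def design_setup(rng):
    cov = make_covariates(40, rng)
    groups = make_groups(cov, rng)
    design = build_design(cov, groups)
    return cov, groups, design


class TestDesign:
    def test_reference_levels_are_lexicographic(self, design_setup):
        _, _, design = design_setup
        assert "sex_F" not in design.columns  # F is the reference level
        assert "sex_M" in design.columns
        assert "site_site1" not in design.columns

    def test_missing_covariate_rejected(self, rng):
        cov = make_covariates(10, rng)
        cov.loc[cov.index[0], "age"] = np.nan
        with pytest.raises(ValueError, match="complete"):
            build_design(cov, make_groups(cov, rng))


class TestMetaboliteModel:
    def test_constant_outcome_gives_zero_coefficient(self, design_setup):
        _, _, design = design_setup
        y = pd.Series(3.0, index=design.index, name="m")
        res = fit_metabolite_model(y, design)
        assert res.beta == 0.0
        assert res.p == 1.0
        assert res.direction == 0

    def test_matches_normal_equations_and_statsmodels(self, design_setup, rng):
        _, _, design = design_setup
        y = pd.Series(rng.normal(size=len(design)), index=design.index, name="m")
        res = fit_metabolite_model(y, design)
        x = design.to_numpy()
        idx = design.columns.get_loc("group_high")
        beta, se, t, p = ols_normal_equations(y.to_numpy(), x)
        assert res.beta == pytest.approx(beta[idx], abs=1e-8)
        assert res.se == pytest.approx(se[idx], abs=1e-8)
        assert res.p == pytest.approx(p[idx], abs=1e-8)
        smres = sm.OLS(y.to_numpy(), x).fit()
        assert res.beta == pytest.approx(smres.params[idx], abs=1e-10)
        assert res.p == pytest.approx(smres.pvalues[idx], abs=1e-10)

    def test_casewise_deletion_shrinks_n(self, design_setup, rng):
        _, _, design = design_setup
        y = pd.Series(rng.normal(size=len(design)), index=design.index, name="m")
        y.iloc[:5] = np.nan
        res = fit_metabolite_model(y, design)
        assert res.n == len(design) - 5

    def test_duplicating_samples_keeps_beta_shrinks_p(self, design_setup, rng):
        cov, groups, design = design_setup
        y = pd.Series(rng.normal(size=len(design)) + 0.4 * design["group_high"],
                      index=design.index, name="m")
        res1 = fit_metabolite_model(y, design)
        cov2 = pd.concat([cov, cov.set_axis([f"{i}b" for i in cov.index])])
        groups2 = pd.concat([groups, groups.set_axis([f"{i}b" for i in groups.index])])
        y2 = pd.concat([y, y.set_axis([f"{i}b" for i in y.index])])
        res2 = fit_metabolite_model(y2, build_design(cov2, groups2))
        assert res2.beta == pytest.approx(res1.beta, abs=1e-10)
        assert res2.p < res1.p

    def test_group_beta_invariant_to_covariate_rescaling(self, design_setup, rng):
        cov, groups, _ = design_setup
        y = pd.Series(rng.normal(size=len(cov)), index=cov.index, name="m")
        res1 = fit_metabolite_model(y, build_design(cov, groups))
        cov2 = cov.copy()
        cov2["age"] = cov2["age"] * 12.0 - 100.0
        res2 = fit_metabolite_model(y, build_design(cov2, groups))
        assert res1.beta == pytest.approx(res2.beta, abs=1e-10)
        assert res1.p == pytest.approx(res2.p, abs=1e-10)

    def test_insufficient_samples_rejected(self, design_setup, rng):
        _, _, design = design_setup
        y = pd.Series(rng.normal(size=len(design)), index=design.index, name="m")
        y.iloc[: len(design) - 3] = np.nan
        with pytest.raises(ValueError, match="casewise deletion"):
            fit_metabolite_model(y, design)


class TestFdr:
    def test_stepup_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            p = rng.random(rng.integers(3, 25))
            q, sig = bh_fdr(p, q_threshold=0.2)
            assert np.array_equal(sig, bh_stepup(p, 0.2))

    def test_worked_example(self):
        q, sig = bh_fdr(np.array([0.01, 0.03, 0.04, 0.5]), q_threshold=0.2)
        assert np.array_equal(sig, bh_stepup([0.01, 0.03, 0.04, 0.5], 0.2))
        assert sig[:3].all() and not sig[3]

    def test_null_family(self):
        _, sig = bh_fdr(np.ones(10))
        assert not sig.any()

    def test_single_p_identity(self):
        q, _ = bh_fdr(np.array([0.05]))
        assert q[0] == pytest.approx(0.05)

    def test_qvalues_monotone_in_p(self, rng):
        p = np.sort(rng.random(50))
        q, _ = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_significant_set_order_invariant(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        _, sig1 = bh_fdr(p)
        _, sig2 = bh_fdr(p[perm])
        assert np.array_equal(sig1[perm], sig2)


class TestScreen:
    def test_counts_partition_significant_set(self, rng):
        cov = make_covariates(60, rng)
        groups = make_groups(cov, rng)
        vals = rng.normal(size=(60, 12))
        vals[:, 0] += 2.0 * (groups == "high").to_numpy()
        vals[:, 1] -= 2.0 * (groups == "high").to_numpy()
        log_df = pd.DataFrame(vals, index=cov.index,
                              columns=[f"M{j}" for j in range(12)])
        res = screen_metabolites(log_df, cov, groups)
        assert res.n_higher_in_high + res.n_higher_in_low == len(res.significant)
        assert "M0" in res.significant and "M1" in res.significant
        assert res.table.loc["M0", "direction"] == 1
        assert res.table.loc["M1", "direction"] == -1

    def test_skipped_metabolites_leave_family(self, rng):
        cov = make_covariates(30, rng)
        groups = make_groups(cov, rng)
        vals = rng.normal(size=(30, 3))
        log_df = pd.DataFrame(vals, index=cov.index, columns=["A", "B", "C"])
        log_df.loc[log_df.index[3:], "B"] = np.nan
        res = screen_metabolites(log_df, cov, groups)
        assert "B" in res.skipped
        assert list(res.table.index) == ["A", "C"]


class TestPlsda:
    def test_constructed_separation(self, rng):
        n = 60
        groups = pd.Series(["low"] * 30 + ["high"] * 30,
                           index=[f"S{i}" for i in range(n)])
        x = rng.normal(size=(n, 10))
        x[30:, 0] += 10.0
        df = pd.DataFrame(x, index=groups.index,
                          columns=[f"M{j}" for j in range(10)])
        res = plsda_scores(df, groups)
        assert res.separation > 5
        # direct projection check: component 1 aligns with the shifted axis
        assert abs(np.corrcoef(res.scores["comp1"], x[:, 0])[0, 1]) > 0.95

    def test_permuted_labels_show_no_separation(self):
        """With labels carrying no signal the component-1 separation stays
        small (n large enough that supervised overfitting is negligible)."""
        seps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 500
            x = r.normal(size=(n, 8))
            groups = pd.Series(
                r.permutation(["low"] * (n // 2) + ["high"] * (n // 2)),
                index=[f"S{i}" for i in range(n)],
            )
            df = pd.DataFrame(x, index=groups.index,
                              columns=[f"M{j}" for j in range(8)])
            seps.append(plsda_scores(df, groups).separation)
        assert max(seps) < 0.5

    def test_scores_are_centered(self, rng):
        groups = pd.Series(["low"] * 20 + ["high"] * 20,
                           index=[f"S{i}" for i in range(40)])
        df = pd.DataFrame(rng.normal(size=(40, 6)), index=groups.index,
                          columns=[f"M{j}" for j in range(6)])
        res = plsda_scores(df, groups)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_single_group_rejected(self, rng):
        groups = pd.Series(["low"] * 10, index=[f"S{i}" for i in range(10)])
        df = pd.DataFrame(rng.normal(size=(10, 4)), index=groups.index)
        with pytest.raises(ValueError, match="two groups"):
            plsda_scores(df, groups)


class TestSensitivity:
    def test_no_flagged_samples_is_identity(self, rng):
        cov = make_covariates(50, rng)
        groups = make_groups(cov, rng)
        log_df = pd.DataFrame(rng.normal(size=(50, 8)), index=cov.index,
                              columns=[f"M{j}" for j in range(8)])
        res = sensitivity_rescreen(log_df, cov, groups, [])
        assert res.jaccard == 1.0
        assert res.sign_agreement == 1.0
        assert res.n_excluded_samples == 0

    def test_exclusion_reduces_every_n(self, rng):
        cov = make_covariates(50, rng)
        groups = make_groups(cov, rng)
        log_df = pd.DataFrame(rng.normal(size=(50, 5)), index=cov.index,
                              columns=[f"M{j}" for j in range(5)])
        res = sensitivity_rescreen(log_df, cov, groups, list(cov.index[:4]))
        assert (res.reduced.table["n"] < res.full.table["n"]).all()

    def test_outliers_leave_signs_stable(self):
        """Planted group effects keep their signs when a few extreme
        samples are excluded."""
        agreements = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            cov = make_covariates(200, r)
            groups = make_groups(cov, r)
            vals = r.normal(size=(200, 20))
            vals[:, :10] += 1.5 * (groups == "high").to_numpy()[:, None]
            vals[:3, 17:] += 10.0  # three samples wild on a few metabolites
            log_df = pd.DataFrame(vals, index=cov.index,
                                  columns=[f"M{j}" for j in range(20)])
            res = sensitivity_rescreen(log_df, cov, groups, list(cov.index[:3]))
            agreements.append(res.sign_agreement)
        assert np.mean(agreements) >= 0.95
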