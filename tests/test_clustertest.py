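from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from admixmet.clustertest import (
    bonferroni,
    cluster_pc1,
    distribution_flags,
    dose_response,
    mannwhitney,
    replicate_clusters,
)
from admixmet.clustertest import test_cluster as fit_cluster
from admixmet.clustertest import test_clusters as fit_cluster_family
from conftest import make_covariates, make_groups
from oracles import mannwhitney_exact, ols_normal_equations


def _imputed(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"M{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"S{i:03d}" for i in range(values.shape[0])],
                        columns=ids)


class TestPc1:
    def test_single_metabolite_is_identity(self, rng):
        df = _imputed(rng.normal(size=(20, 1)))
        scores, pct, _ = cluster_pc1(df, ["M0"])
        z = (df["M0"] - df["M0"].mean()) / df["M0"].std(ddof=1)
        assert pct == pytest.approx(100.0)
        assert np.allclose(np.abs(scores), np.abs(z))

    def test_perfect_correlation_explains_everything(self, rng):
        x = rng.normal(size=20)
        df = _imputed(np.column_stack([x, 2 * x + 5]))
        _, pct, _ = cluster_pc1(df, ["M0", "M1"])
        assert pct == pytest.approx(100.0)

    def test_uncorrelated_pair_splits_variance(self, rng):
        df = _imputed(rng.normal(size=(5000, 2)))
        _, pct, _ = cluster_pc1(df, ["M0", "M1"])
        assert pct == pytest.approx(50.0, abs=3.0)

    def test_matches_eigendecomposition(self, rng):
        df = _imputed(rng.normal(size=(30, 6)))
        scores, pct, loadings = cluster_pc1(df, list(df.columns))
        z = (df - df.mean()) / df.std(ddof=1)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        eigvals = np.linalg.eigvalsh(corr)
        assert pct == pytest.approx(eigvals[-1] / eigvals.sum() * 100, abs=1e-10)
        # scores reproduce the projection on the top eigenvector
        proj = z.to_numpy() @ np.linalg.eigh(corr)[1][:, -1]
        assert np.allclose(np.abs(scores), np.abs(proj), atol=1e-8)

    def test_sign_convention_absorbs_flips_and_order(self, rng):
        df = _imputed(rng.normal(size=(25, 4)))
        df["M0"] += df["M1"]  # give PC1 some structure
        s1, _, _ = cluster_pc1(df, ["M0", "M1", "M2", "M3"])
        s2, _, _ = cluster_pc1(df, ["M3", "M1", "M0", "M2"])
        assert np.allclose(s1, s2)
        flipped = df.copy()
        flipped["M2"] = -flipped["M2"]
        s3, _, load3 = cluster_pc1(flipped, ["M0", "M1", "M2", "M3"])
        assert np.allclose(s1, s3)
        assert load3["M2"] == pytest.approx(
            -cluster_pc1(df, ["M0", "M1", "M2", "M3"])[2]["M2"]
        )

    def test_zero_variance_member_dropped(self, rng):
        df = _imputed(rng.normal(size=(15, 2)))
        df["M1"] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, pct, _ = cluster_pc1(df, ["M0", "M1"])
        assert pct == pytest.approx(100.0)


class TestClusterRegression:
    def test_constant_pc1_gives_zero(self, rng):
        cov = make_covariates(30, rng)
        groups = make_groups(cov, rng)
        pc1 = pd.Series(1.0, index=cov.index, name="c")
        res = fit_cluster(pc1, cov, groups)
        assert res.beta == 0.0

    def test_matches_normal_equations(self, rng):
        cov = make_covariates(45, rng)
        groups = make_groups(cov, rng)
        pc1 = pd.Series(rng.normal(size=45), index=cov.index, name="c")
        res = fit_cluster(pc1, cov, groups)
        from admixmet.screen import build_design

        design = build_design(cov, groups)
        beta, se, t, p = ols_normal_equations(pc1.to_numpy(), design.to_numpy())
        idx = design.columns.get_loc("group_high")
        assert res.beta == pytest.approx(beta[idx], abs=1e-8)
        assert res.p == pytest.approx(p[idx], abs=1e-8)

    def test_planted_cluster_effect_detected(self):
        """A strong planted shift on a correlated cluster yields a
        Bonferroni-sized p-value in nearly all seeds."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            cov = make_covariates(300, r)
            groups = make_groups(cov, r)
            factor = r.normal(size=300) + 0.8 * (groups == "high").to_numpy()
            vals = factor[:, None] + 0.6 * r.normal(size=(300, 8))
            df = pd.DataFrame(vals, index=cov.index,
                              columns=[f"M{j}" for j in range(8)])
            scores, _, _ = cluster_pc1(df, list(df.columns))
            scores.name = "c"
            res = fit_cluster(scores, cov, groups)
            hits += res.p < 0.002
        assert hits >= 9


class TestBonferroni:
    @pytest.mark.parametrize(
        "k,display", [(24, 0.002), (13, 0.0038), (1, 0.05)]
    )
    def test_display_thresholds(self, k, display):
        res = bonferroni({f"c{i}": 0.5 for i in range(k)}, alpha=0.05)
        assert res.display_threshold == pytest.approx(display)
        assert res.threshold == pytest.approx(0.05 / k)

    def test_significant_set_shrinks_with_family_size(self):
        p = {f"c{i}": 0.004 for i in range(5)}
        small = bonferroni(p, alpha=0.05)
        p2 = dict(p, **{f"d{i}": 0.9 for i in range(20)})
        large = bonferroni(p2, alpha=0.05)
        assert set(large.significant) <= set(small.significant)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni({})


class TestDistributionFlags:
    def test_symmetric_sample_not_skewed(self, rng):
        x = rng.normal(size=250)
        x = np.concatenate([x, -x])
        flags = distribution_flags(x)
        assert flags.skewness == pytest.approx(0.0, abs=1e-12)
        assert not flags.skewed

    def test_exponential_sample_flagged_skewed(self):
        x = np.random.default_rng(3).exponential(size=500)
        flags = distribution_flags(x)
        assert abs(flags.skewness) > 1
        assert flags.flag == "skewed"

    def test_two_point_mass_flagged_bimodal(self):
        x = np.array([-1.0, 1.0] * 50)
        flags = distribution_flags(x)
        assert flags.bimodality > 0.555
        assert flags.flag == "bimodal"

    def test_constant_scores_undefined(self):
        flags = distribution_flags(np.ones(20))
        assert flags.flag == "undefined"
        assert not flags.flagged

    def test_gaussian_unflagged(self, rng):
        flags = distribution_flags(rng.normal(size=400))
        assert flags.flag == "none"


class TestMannWhitney:
    def test_fully_separated_tiny_groups(self):
        u, p = mannwhitney(np.array([1, 2, 3, 4, 5, 6.0]),
                          np.array(["a", "a", "a", "b", "b", "b"]))
        assert p == pytest.approx(0.1)

    def test_matches_exact_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=4) + 0.5
        vals = np.concatenate([x, y])
        labels = np.array(["a"] * 5 + ["b"] * 4)
        _, p = mannwhitney(vals, labels)
        assert p == pytest.approx(mannwhitney_exact(x, y), abs=1e-10)

    def test_identical_multisets_not_significant(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        _, p = mannwhitney(vals, labels)
        assert p > 0.99

    def test_all_tied_returns_one(self):
        _, p = mannwhitney(np.ones(10), np.array(["a"] * 5 + ["b"] * 5))
        assert p == 1.0

    def test_large_shift_is_extreme(self, rng):
        vals = np.concatenate([rng.normal(size=100), rng.normal(5, 1, 100)])
        labels = np.array(["a"] * 100 + ["b"] * 100)
        _, p = mannwhitney(vals, labels)
        assert p < 1e-6


class TestReplication:
    def _setup(self, rng, n=200, size=10, shift=0.8):
        cov = make_covariates(n, rng)
        groups = make_groups(cov, rng)
        factor = rng.normal(size=n) + shift * (groups == "high").to_numpy()
        vals = factor[:, None] + 0.6 * rng.normal(size=(n, size))
        df = pd.DataFrame(vals, index=cov.index,
                          columns=[f"M{j}" for j in range(size)])
        return cov, groups, df

    def _screen_table(self, betas):
        return pd.DataFrame({"beta": betas})

    def test_concordance_rule_boundaries(self, rng):
        cov, groups, df = self._setup(rng)
        members = list(df.columns)
        d1 = self._screen_table(pd.Series(1.0, index=members))
        # 9 of 10 concordant passes the 90% rule exactly
        betas2 = pd.Series(1.0, index=members)
        betas2.iloc[0] = -1.0
        results = replicate_clusters({"c": members}, df, cov, groups, d1,
                                     self._screen_table(betas2))
        r = results[0]
        assert r.concordance == Fraction(9, 10)
        assert r.direction_ok
        # 8 of 10 fails regardless of p
        betas3 = betas2.copy()
        betas3.iloc[1] = -1.0
        r2 = replicate_clusters({"c": members}, df, cov, groups, d1,
                                self._screen_table(betas3))[0]
        assert not r2.direction_ok
        assert not r2.replicated

    def test_half_concordance_never_replicates(self, rng):
        cov, groups, df = self._setup(rng)
        members = list(df.columns)
        d1 = self._screen_table(pd.Series(1.0, index=members))
        betas2 = pd.Series([1.0, -1] * 5, index=members)
        r = replicate_clusters({"c": members}, df, cov, groups, d1,
                               self._screen_table(betas2))[0]
        assert r.p < 0.05 / 1  # effect is there
        assert not r.replicated

    def test_adding_concordant_member_cannot_unreplicate(self, rng):
        cov, groups, df = self._setup(rng, size=12)
        members = list(df.columns)[:11]
        d1 = self._screen_table(pd.Series(1.0, index=df.columns))
        betas2 = pd.Series(1.0, index=df.columns)
        betas2.iloc[0] = -1.0
        base = replicate_clusters({"c": members}, df, cov, groups, d1,
                                  self._screen_table(betas2))[0]
        grown = replicate_clusters({"c": list(df.columns)}, df, cov, groups,
                                   d1, self._screen_table(betas2))[0]
        assert grown.concordance >= base.concordance
        if base.replicated:
            assert grown.replicated

    def test_unavailable_cluster_reported_untestable(self, rng):
        cov, groups, df = self._setup(rng)
        d1 = self._screen_table(pd.Series(1.0, index=["X1", "X2"]))
        results = replicate_clusters({"gone": ["X1", "X2"]}, df, cov, groups,
                                     d1, d1)
        assert not results[0].testable
        assert not results[0].replicated

    def test_member_loss_warns(self, rng):
        cov, groups, df = self._setup(rng, size=4)
        members = list(df.columns) + [f"Z{i}" for i in range(6)]
        d1 = self._screen_table(pd.Series(1.0, index=members))
        with pytest.warns(UserWarning, match="lost"):
            replicate_clusters({"c": members}, df, cov, groups, d1, d1)

    def test_flagged_cluster_gets_mannwhitney(self, rng):
        cov, groups, df = self._setup(rng, shift=2.5)
        # strong shift makes the PC1 distribution bimodal
        members = list(df.columns)
        d1 = self._screen_table(pd.Series(1.0, index=members))
        r = replicate_clusters({"c": members}, df, cov, groups, d1, d1)[0]
        if r.flags is not None and r.flags.flagged:
            assert r.mannwhitney_p is not None
            assert r.mannwhitney_p < 0.01


class TestDoseResponse:
    def test_recovers_planted_slope_sign(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 250
            cov = make_covariates(n, r)
            q = pd.Series(r.uniform(0.5, 0.99, n), index=cov.index)
            y = 1.0 * q.to_numpy() + r.normal(0, 0.5, n)
            log_df = pd.DataFrame({"M0": y}, index=cov.index)
            out = dose_response(log_df, q, cov, {"c": ["M0"]})
            hits += out.loc["M0", "beta"] > 0
        assert hits >= 9

    def test_null_slope_sign_is_symmetric(self):
        signs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            cov = make_covariates(120, r)
            q = pd.Series(r.uniform(0.5, 0.99, 120), index=cov.index)
            log_df = pd.DataFrame({"M0": r.normal(size=120)}, index=cov.index)
            out = dose_response(log_df, q, cov, {"c": ["M0"]})
            signs.append(out.loc["M0", "beta"] > 0)
        assert 0.2 < np.mean(signs) < 0.8

    def test_subset_restricted_to_high_ancestry(self, rng):
        cov = make_covariates(100, rng)
        q = pd.Series(np.concatenate([np.full(50, 0.02), rng.uniform(0.5, 0.9, 50)]),
                      index=cov.index)
        log_df = pd.DataFrame({"M0": rng.normal(size=100)}, index=cov.index)
        out = dose_response(log_df, q, cov, {"c": ["M0"]})
        assert out.loc["M0", "n"] == 50

    def test_constant_q_rejected(self, rng):
        cov = make_covariates(40, rng)
        q = pd.Series(0.8, index=cov.index)
        log_df = pd.DataFrame({"M0": rng.normal(size=40)}, index=cov.index)
        with pytest.raises(ValueError, match="vary"):
            dose_response(log_df, q, cov, {"c": ["M0"]})


class TestFamilyDriver:
    def test_family_threshold_and_flags(self, rng):
        cov = make_covariates(150, rng)
        groups = make_groups(cov, rng)
        factor = rng.normal(size=150) + 1.0 * (groups == "high").to_numpy()
        vals = np.column_stack([
            factor[:, None] + 0.5 * rng.normal(size=(150, 4)),
            rng.normal(size=(150, 4)),
        ])
        df = pd.DataFrame(vals, index=cov.index,
                          columns=[f"M{j}" for j in range(8)])
        clusters = {"signal": [f"M{j}" for j in range(4)],
                    "noise": [f"M{j}" for j in range(4, 8)]}
        results, bonf = fit_cluster_family(df, clusters, cov, groups)
        assert bonf.k == 2
        by_label = {r.label: r for r in results}
        assert by_label["signal"].significant
        assert not by_label["noise"].significant
        assert by_label["signal"].bonferroni_threshold == pytest.approx(0.025)
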