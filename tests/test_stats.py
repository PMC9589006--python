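"""The statistics layer: transforms, EV, LMM, ANCOVA, BH, Tukey, Spearman, loess."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from biliflux.stats import (
    FeatureTable,
    ancova_differential,
    autoscale,
    bh_fdr,
    explained_variance,
    lmm_association,
    loess_fit,
    log2_transform,
    spearman_fdr,
    tukey_hsd,
)


def table_from(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{j}" for j in range(arr.shape[1])]
    idx = [f"s{i}" for i in range(arr.shape[0])]
    return FeatureTable(pd.DataFrame(arr, index=idx, columns=cols), "raw")


class TestTransforms:
    def test_half_min_positive_pseudocount(self):
        """Column (4, 0): delta = 2, so values map to (log2 6, 1)."""
        out = log2_transform(table_from([[4.0], [0.0]]))
        assert out.data.iloc[0, 0] == pytest.approx(math.log2(6.0))
        assert out.data.iloc[1, 0] == pytest.approx(1.0)
        assert out.transform_state == "log2"

    def test_monotone_rank_preservation(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 3.0, size=(30, 1))
        out = log2_transform(table_from(x))
        assert (np.argsort(out.data.iloc[:, 0].values) == np.argsort(x[:, 0])).all()

    def test_double_transform_is_state_error(self):
        out = log2_transform(table_from([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="raw state"):
            log2_transform(out)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log2_transform(table_from([[-1.0], [2.0]]))

    def test_autoscale_zero_mean_unit_variance(self):
        rng = np.random.default_rng(1)
        out = autoscale(log2_transform(table_from(rng.gamma(2, 2, (40, 5)))))
        vals = out.data.to_numpy()
        assert np.abs(vals.mean(axis=0)).max() < 1e-9
        assert np.abs(vals.std(axis=0, ddof=1) - 1.0).max() < 1e-9


class TestExplainedVariance:
    def _autoscaled(self, arr):
        t = table_from(np.asarray(arr))
        t.transform_state = "log2"
        return autoscale(t)

    def test_feature_equal_to_factor_gives_r2_one(self):
        x = np.arange(20.0)
        table = self._autoscaled(x[:, None])
        meta = pd.DataFrame({"age": x}, index=table.data.index)
        (ev,) = explained_variance(table, meta, ["age"])
        assert ev.median_marginal_r2 == pytest.approx(1.0, abs=1e-12)
        assert ev.is_confounder

    def test_independent_factor_gives_near_zero_median(self):
        rng = np.random.default_rng(2)
        table = self._autoscaled(rng.normal(size=(400, 50)))
        meta = pd.DataFrame({"age": rng.normal(size=400)}, index=table.data.index)
        (ev,) = explained_variance(table, meta, ["age"])
        assert ev.median_marginal_r2 < 0.02
        assert not ev.is_confounder

    def test_constructed_thirty_percent_variance(self):
        """Features built as sqrt(.3) z_age + sqrt(.7) noise -> median EV ~ 0.30."""
        rng = np.random.default_rng(3)
        n, p = 500, 60
        age = rng.normal(size=n)
        z = (age - age.mean()) / age.std()
        Y = math.sqrt(0.3) * z[:, None] + math.sqrt(0.7) * rng.normal(size=(n, p))
        table = self._autoscaled(Y)
        meta = pd.DataFrame({"age": age}, index=table.data.index)
        (ev,) = explained_variance(table, meta, ["age"])
        assert ev.median_marginal_r2 == pytest.approx(0.30, abs=0.05)

    def test_constant_factor_reports_zero(self):
        table = self._autoscaled(np.random.default_rng(4).normal(size=(10, 3)))
        meta = pd.DataFrame({"batch": ["a"] * 10}, index=table.data.index)
        (ev,) = explained_variance(table, meta, ["batch"])
        assert ev.median_marginal_r2 == 0.0


class TestLMM:
    @staticmethod
    def _simulate(rng, n_subj=40, n_visit=5, beta_age=0.5, sd_b=1.0, sd_e=1.0):
        rows = []
        for s in range(n_subj):
            b = rng.normal(0, sd_b)
            for v in range(n_visit):
                age = 3.0 * (v + 1)
                y = 1.0 + beta_age * age + b + rng.normal(0, sd_e)
                rows.append((f"subj{s}", age, y))
        df = pd.DataFrame(rows, columns=["subject", "age", "y"])
        return df

    def test_zero_between_subject_variance_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        df = self._simulate(rng, sd_b=0.0)
        res = lmm_association(df["y"], df[["age"]], df["subject"])
        X = np.column_stack([np.ones(len(df)), df["age"]])
        beta_ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert res.params["age"] == pytest.approx(beta_ols[1], abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        df = self._simulate(rng, sd_b=1.0)
        res = lmm_association(df["y"], df[["age"]], df["subject"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM.from_formula("y ~ age", groups="subject", data=df).fit(reml=True)
        assert res.params["age"] == pytest.approx(ref.params["age"], abs=1e-4)
        assert res.se["age"] == pytest.approx(ref.bse["age"], rel=1e-3)
        assert res.sigma_subject**2 == pytest.approx(ref.cov_re.iloc[0, 0], rel=0.01)

    def test_variance_ratio_recovery(self):
        rng = np.random.default_rng(7)
        df = self._simulate(rng, n_subj=100, n_visit=6, sd_b=1.0, sd_e=1.0)
        res = lmm_association(df["y"], df[["age"]], df["subject"])
        assert res.variance_ratio == pytest.approx(1.0, rel=0.2)

    def test_one_observation_per_subject_warns_and_uses_ols(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(3, 36, size=30)
        df = pd.DataFrame(
            {
                "subject": [f"subj{i}" for i in range(30)],
                "age": ages,
                "y": 1.0 + 0.5 * ages + rng.normal(size=30),
            }
        )
        with pytest.warns(UserWarning, match="single observation"):
            res = lmm_association(df["y"], df[["age"]], df["subject"])
        assert res.method == "ols"

    def test_singular_design_names_collinear_columns(self):
        rng = np.random.default_rng(9)
        df = self._simulate(rng)
        df["age2"] = df["age"] * 2.0
        with pytest.raises(ValueError, match="age2"):
            lmm_association(df["y"], df[["age", "age2"]], df["subject"])


class TestBH:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False), min_size=1, max_size=30))
    def test_matches_bruteforce_definition(self, pvals):
        """q_(i) = min_{j >= i} m p_(j) / j, capped at 1."""
        q = bh_fdr(pvals)
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
            brute[idx] = min(1.0, min(candidates))
        assert np.allclose(q, brute, atol=1e-12)


class TestANCOVA:
    @staticmethod
    def _cohort(rng, shift=0.0, n_per=20, p=10, confounded=False):
        groups = ["CTR"] * n_per + ["P1Ab"] * n_per + ["P2Ab"] * n_per
        n = len(groups)
        diet = rng.normal(9, 3, size=n)
        Y = rng.normal(size=(n, p))
        if confounded:
            Y[:, 0] = 0.5 * diet + rng.normal(scale=0.1, size=n)
        Y[np.array(groups) == "P2Ab", 0] += shift
        idx = [f"s{i}" for i in range(n)]
        table = FeatureTable(pd.DataFrame(Y, index=idx, columns=[f"f{j}" for j in range(p)]), "log2")
        meta = pd.DataFrame(
            {"group": groups, "age_months": 6, "diet": diet}, index=idx
        )
        return table, meta

    def test_injected_shift_is_detected(self):
        rng = np.random.default_rng(10)
        table, meta = self._cohort(rng, shift=2.0)
        res = ancova_differential(table, meta, 6, covariates=("diet",))
        by_feat = {r.feature: r for r in res if r.contrast == ("P2Ab", "P1Ab")}
        assert by_feat["f0"].q < 0.05
        assert by_feat["f0"].log2_fc == pytest.approx(2.0, abs=0.8)

    def test_covariate_fully_explaining_group_kills_f(self):
        rng = np.random.default_rng(11)
        table, meta = self._cohort(rng, confounded=True)
        res = ancova_differential(table, meta, 6, covariates=("diet",))
        f0 = next(r for r in res if r.feature == "f0")
        assert f0.p > 0.2

    def test_no_covariates_two_groups_equals_oneway_anova(self):
        rng = np.random.default_rng(12)
        table, meta = self._cohort(rng)
        keep = meta["group"] != "P2Ab"
        table2 = FeatureTable(table.data[keep.to_numpy()], "log2")
        meta2 = meta[keep.to_numpy()]
        res = ancova_differential(table2, meta2, 6, covariates=())
        f0 = next(r for r in res if r.feature == "f0")
        a = table2.data["f0"][(meta2["group"] == "CTR").to_numpy()]
        b = table2.data["f0"][(meta2["group"] == "P1Ab").to_numpy()]
        F_ref, p_ref = sps.f_oneway(a, b)
        assert f0.F_stat == pytest.approx(F_ref, rel=1e-9)
        assert f0.p == pytest.approx(p_ref, rel=1e-9)

    def test_log2_fc_antisymmetric_under_contrast_swap(self):
        rng = np.random.default_rng(13)
        table, meta = self._cohort(rng, shift=1.0)
        res = ancova_differential(
            table, meta, 6, covariates=("diet",),
            contrasts=[("P2Ab", "P1Ab"), ("P1Ab", "P2Ab")],
        )
        f0 = [r for r in res if r.feature == "f0"]
        assert f0[0].log2_fc == pytest.approx(-f0[1].log2_fc)

    def test_small_group_dropped_with_warning(self):
        rng = np.random.default_rng(14)
        table, meta = self._cohort(rng, n_per=5)
        meta = meta.copy()
        # shrink P2Ab below the n=3 floor
        drop = meta.index[meta["group"] == "P2Ab"][:3]
        keep = ~meta.index.isin(drop)
        with pytest.warns(UserWarning, match="dropped"):
            res = ancova_differential(
                FeatureTable(table.data[keep], "log2"), meta[keep], 6, covariates=("diet",)
            )
        assert all(r.contrast[0] != "P2Ab" and r.contrast[1] != "P2Ab" for r in res)


class TestTukey:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=30)
        vals = np.concatenate([x, x, x])
        labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        res = tukey_hsd(vals, labels)
        assert all(c.p_adj > 0.99 for c in res.comparisons)

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = tukey_hsd(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.comparisons[0].p_adj == pytest.approx(p_ref, abs=1e-6)

    def test_agrees_with_scipy_tukey(self):
        rng = np.random.default_rng(17)
        groups = [rng.normal(mu, 1, 11) for mu in (0.0, 0.6, 1.4)]
        labels = sum([[g] * 11 for g in "abc"], [])
        res = tukey_hsd(np.concatenate(groups), labels)
        ref = sps.tukey_hsd(*groups)
        mine = {frozenset((c.group_a, c.group_b)): c.p_adj for c in res.comparisons}
        for i, gi in enumerate("abc"):
            for j, gj in enumerate("abc"):
                if i < j:
                    assert mine[frozenset((gi, gj))] == pytest.approx(
                        ref.pvalue[i, j], abs=1e-6
                    )

    def test_zero_variance_everywhere_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            tukey_hsd([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])

    def test_tiny_group_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestSpearman:
    @staticmethod
    def _frames(x, y):
        idx = [f"s{i}" for i in range(len(x))]
        return (
            pd.DataFrame({"x": x}, index=idx),
            pd.DataFrame({"y": y}, index=idx),
        )

    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(1, 10, 12)
        X, Y = self._frames(x, np.exp(x))
        res = spearman_fdr(X, Y)
        assert res.rho.iloc[0, 0] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(10.0)
        X, Y = self._frames(x, x[::-1])
        res = spearman_fdr(X, Y)
        assert res.rho.iloc[0, 0] == pytest.approx(-1.0)

    def test_ties_match_scipy_average_rank(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        X, Y = self._frames(x, y)
        res = spearman_fdr(X, Y)
        rho_ref, p_ref = sps.spearmanr(x, y)
        assert res.rho.iloc[0, 0] == pytest.approx(rho_ref, abs=1e-12)
        assert res.p.iloc[0, 0] == pytest.approx(p_ref, rel=1e-6)

    def test_constant_column_is_missing(self):
        x = np.arange(8.0)
        X, Y = self._frames(x, np.ones(8))
        res = spearman_fdr(X, Y)
        assert np.isnan(res.rho.iloc[0, 0])
        assert np.isnan(res.q.iloc[0, 0])

    def test_too_few_samples_rejected(self):
        X, Y = self._frames(np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValueError, match=">= 5"):
            spearman_fdr(X, Y)


class TestLoess:
    def test_linear_data_reproduced_exactly(self):
        x = np.linspace(0, 10, 30)
        y = 2.0 + 3.0 * x
        for degree in (1, 2):
            fit = loess_fit(x, y, span=0.5, degree=degree)
            assert np.abs(fit.fitted - (2.0 + 3.0 * fit.x)).max() < 1e-8

    def test_constant_y_gives_flat_curve(self):
        x = np.linspace(0, 5, 20)
        fit = loess_fit(x, np.full(20, 3.3), span=0.75)
        assert np.abs(fit.fitted - 3.3).max() < 1e-10

    def test_smaller_span_fits_noisy_sine_tighter(self):
        rng = np.random.default_rng(18)
        x = np.sort(rng.uniform(0, 4 * np.pi, 120))
        y = np.sin(x) + rng.normal(0, 0.3, 120)
        rss = {}
        for span in (0.3, 0.9):
            fit = loess_fit(x, y, span=span, degree=2, eval_x=x)
            rss[span] = float(((y - fit.fitted) ** 2).sum())
        assert rss[0.3] <= rss[0.9]

    def test_span_too_small_is_error(self):
        x = np.linspace(0, 1, 30)
        with pytest.raises(ValueError, match="span"):
            loess_fit(x, x, span=0.05, degree=2)

    def test_no_extrapolation(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="x-range"):
            loess_fit(x, x, eval_x=[2.0])

    def test_interval_contains_truth_for_linear_fit(self):
        rng = np.random.default_rng(19)
        x = np.linspace(0, 10, 200)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.5, 200)
        fit = loess_fit(x, y, span=0.75, degree=1)
        truth = 1.0 + 0.5 * fit.x
        coverage = np.mean((truth >= fit.lower) & (truth <= fit.upper))
        assert coverage > 0.8
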