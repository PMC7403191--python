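"""Elastic-net sex models: nested LOOCV, exact rank-sum inference, projection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import enet_path

import orthoimmune as oi
from orthoimmune.en_model import (
    ENModelResult,
    _fit_at,
    fit_en_loocv,
    model_pvalue,
    project_model,
    sex_separation_by_timepoint,
    univariate_feature_pvalues,
)
from orthoimmune.stats import exact_rank_sum_p

from conftest import EN_SIM_KW, make_feature_table

P_COMPLETE_SEPARATION = 2 / 12870  # C(16, 8) assignments, two-sided


def separable_matrix(seed=0, n_noise=15, flip=False):
    """One perfectly separating feature plus pure-noise features, n = 8+8."""
    rng = np.random.default_rng(seed)
    sex = pd.Series(["M"] * 8 + ["F"] * 8, index=[f"s{i}" for i in range(16)])
    y = np.where(sex == "M", 1.0, -1.0)
    signal = y * (3.0 if not flip else -3.0) + 0.05 * rng.normal(size=16)
    cols = {"sig|m": signal}
    for i in range(n_noise):
        cols[f"noise{i}|m"] = rng.normal(size=16)
    return pd.DataFrame(cols, index=sex.index), sex


class TestExactRankSum:
    def test_complete_separation_eight_vs_eight(self):
        p = exact_rank_sum_p(np.arange(8) + 100.0, np.arange(8))
        assert p == pytest.approx(P_COMPLETE_SEPARATION, rel=1e-12)

    def test_all_tied_gives_one(self):
        assert exact_rank_sum_p(np.zeros(8), np.zeros(8)) == 1.0

    def test_identical_distributions_large_p(self):
        x = np.arange(8.0)
        assert exact_rank_sum_p(x, x) > 0.5

    def test_matches_scipy_exact_without_ties(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        for _ in range(5):
            x, y = rng.normal(size=6), rng.normal(size=7)
            ours = exact_rank_sum_p(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)


class TestUnivariatePvalues:
    def test_constant_feature_p_one(self):
        X, sex = separable_matrix()
        X["flat|m"] = 2.5
        p = univariate_feature_pvalues(X, sex)
        assert p["flat|m"] == 1.0

    def test_separating_feature_exact_p(self):
        X, sex = separable_matrix()
        p = univariate_feature_pvalues(X, sex)
        assert p["sig|m"] == pytest.approx(P_COMPLETE_SEPARATION, rel=1e-12)

    def test_matches_monte_carlo_permutation_oracle(self):
        # oracle: random label permutations of the rank-sum distance |W - mu|
        from scipy import stats

        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(16, 5)),
                         columns=[f"f{i}|m" for i in range(5)])
        sex = pd.Series(["M"] * 8 + ["F"] * 8, index=X.index)
        p = univariate_feature_pvalues(X, sex)
        n_mc = 100_000
        mask = (sex == "M").to_numpy()
        mu = mask.sum() * (len(mask) + 1) / 2.0
        for col in X.columns:
            ranks = stats.rankdata(X[col].to_numpy())
            w_obs = ranks[mask].sum()
            perms = np.array([rng.permutation(len(mask)) for _ in range(n_mc)])
            w = ranks[perms[:, : mask.sum()]].sum(axis=1)
            mc = np.mean(np.abs(w - mu) >= np.abs(w_obs - mu) - 1e-9)
            se = np.sqrt(mc * (1 - mc) / n_mc) + 1e-5
            assert p[col] == pytest.approx(mc, abs=4 * se)


class TestFitENLoocv:
    def test_separable_instance_orders_all_scores(self):
        X, sex = separable_matrix()
        res = fit_en_loocv(X, sex, **EN_SIM_KW)
        male = res.oof_scores[sex == "M"]
        female = res.oof_scores[sex == "F"]
        assert male.min() > female.max()
        assert res.p_raw == pytest.approx(P_COMPLETE_SEPARATION, rel=1e-12)
        assert res.p_bonferroni == pytest.approx(4 * P_COMPLETE_SEPARATION)

    def test_sign_convention_female_elevated_negative(self):
        X, sex = separable_matrix(flip=True)  # signal higher in females
        res = fit_en_loocv(X, sex, **EN_SIM_KW)
        assert res.coef[list(X.columns).index("sig|m")] < 0

    def test_full_shrinkage_zeroes_all_coefficients(self):
        X, sex = separable_matrix()
        y = np.where(sex == "M", 1.0, -1.0)
        coef, intercept, _, _ = _fit_at(X.to_numpy(), y, l1_ratio=0.5,
                                        alpha=1e6)
        assert np.all(coef == 0.0)
        assert intercept == pytest.approx(y.mean())

    def test_single_sex_input_rejected(self):
        X, sex = separable_matrix()
        with pytest.raises(ValueError, match="per sex"):
            fit_en_loocv(X, pd.Series("M", index=X.index), **EN_SIM_KW)

    def test_missing_values_rejected(self):
        X, sex = separable_matrix()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_en_loocv(X, sex, **EN_SIM_KW)

    def test_constant_features_dropped_with_zero_coef(self):
        X, sex = separable_matrix()
        X["flat|m"] = 7.0
        res = fit_en_loocv(X, sex, **EN_SIM_KW)
        assert "flat|m" in res.dropped_features
        assert res.coef[list(X.columns).index("flat|m")] == 0.0

    def test_fold_audit_excludes_held_out_sample(self):
        X, sex = separable_matrix()
        res = fit_en_loocv(X, sex, **EN_SIM_KW)
        assert len(res.fold_log) == 16
        for entry in res.fold_log:
            assert entry["held_out"] not in entry["train"]
            assert len(entry["train"]) == 15

    def test_sparsity_monotone_along_path(self):
        # orthogonal design: soft-thresholding applies coordinate-wise, so
        # the active set can only grow as the penalty relaxes
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(16, 10)))
        y = Q @ np.linspace(2.0, 0.1, 10) + 0.01 * rng.normal(size=16)
        alphas = np.logspace(0, -3, 40) * np.abs(Q.T @ y).max() / len(y) / 0.5
        _, coefs, _ = enet_path(Q, y - y.mean(), l1_ratio=0.5, alphas=alphas)
        nnz = (coefs != 0).sum(axis=0)  # alphas descend: penalty decreasing
        assert (np.diff(nnz) >= 0).all()
        assert nnz[0] <= 1 and nnz[-1] == 10

    def test_json_round_trip(self, tmp_path):
        X, sex = separable_matrix()
        res = fit_en_loocv(X, sex, timepoint="12h", **EN_SIM_KW)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = ENModelResult.from_json(path)
        assert back.timepoint == "12h"
        assert np.allclose(back.coef, res.coef)
        assert back.p_raw == res.p_raw
        assert back.n_nonzero_features == res.n_nonzero_features


class TestModelPvalue:
    def test_bonferroni_cap(self):
        scores = pd.Series(np.r_[np.arange(8) + 10.0, np.arange(8)],
                           index=[f"s{i}" for i in range(16)])
        sex = pd.Series(["M"] * 8 + ["F"] * 8, index=scores.index)
        p_raw, p_bonf = model_pvalue(scores, sex, family_size=4)
        assert p_bonf == min(1.0, 4 * p_raw)
        p_raw2, p_bonf2 = model_pvalue(
            scores.sample(frac=1.0, random_state=0), sex, family_size=4
        )
        assert p_raw2 == p_raw
        # capped case
        assert model_pvalue(
            pd.Series(np.tile([0.0, 1.0], 8), index=scores.index), sex, 4
        )[1] == 1.0

    def test_missing_scores_rejected(self):
        scores = pd.Series([np.nan] + [0.0] * 15,
                           index=[f"s{i}" for i in range(16)])
        sex = pd.Series(["M"] * 8 + ["F"] * 8, index=scores.index)
        with pytest.raises(ValueError):
            model_pvalue(scores, sex)


class TestProjection:
    def test_zero_model_projects_to_intercept(self):
        X, sex = separable_matrix()
        ft = make_feature_table(X, sex)
        model = ENModelResult(
            timepoint="12h", feature_names=list(X.columns),
            coef=np.zeros(X.shape[1]), intercept=0.25,
            l1_ratio=0.5, alpha=1.0,
            standardize_mean=X.mean().to_numpy(),
            standardize_sd=X.std().to_numpy(),
            oof_scores=pd.Series(0.0, index=X.index), sex=sex,
            p_raw=1.0, p_bonferroni=1.0, family_size=4,
            univariate_p=pd.Series(1.0, index=X.columns),
        )
        proj = project_model(model, ft)
        assert np.allclose(proj.per_sample["value"], 0.25)

    def test_projection_reproduces_fitted_scores(self):
        X, sex = separable_matrix()
        res = fit_en_loocv(X, sex, timepoint="12h", **EN_SIM_KW)
        ft = make_feature_table(X, sex)
        proj = project_model(res, ft)
        fitted = res.fitted_scores()
        got = proj.per_sample.set_index("sample_id")["value"]
        assert np.allclose(got.loc[fitted.index], fitted)

    def test_missing_feature_column_rejected(self):
        X, sex = separable_matrix()
        res = fit_en_loocv(X, sex, **EN_SIM_KW)
        ft = make_feature_table(X.drop(columns=["sig|m"]), sex)
        with pytest.raises(ValueError, match="missing"):
            project_model(res, ft)

    def test_summary_recomputable_from_per_sample(self):
        X, sex = separable_matrix()
        res = fit_en_loocv(X, sex, timepoint="12h", **EN_SIM_KW)
        proj = project_model(res, make_feature_table(X, sex))
        manual = (proj.per_sample.groupby(["timepoint", "sex"])["value"]
                  .agg(["median", "min", "max"]))
        pd.testing.assert_frame_equal(proj.summary, manual)
        sep = sex_separation_by_timepoint(proj)
        assert sep.loc["12h"] > 0


def test_univariate_tests_calibrated_on_null_cohorts(sim_setup):
    """Univariate male-vs-female rank-sum tests reject ~5% of features on
    no-effect cohorts (pooled over cohorts; features within a cohort are
    correlated, so only the pooled rate is compared)."""
    from orthoimmune.features import derive_feature_table, impute_missing
    from orthoimmune.gating import apply_gating
    from orthoimmune.synthetic import simulation_cohort_config

    n_sig = n_tot = 0
    for r in range(6):
        config = simulation_cohort_config(null=True, seed=700 + r)
        events, _ = oi.generate_cohort(config)
        labels = apply_gating(events, sim_setup)
        table, _ = impute_missing(derive_feature_table(events, labels, sim_setup))
        tp = table.at_timepoint("12h")
        p = univariate_feature_pvalues(tp.values, tp.sex())
        n_sig += int((p < 0.05).sum())
        n_tot += len(p)
    assert 0.01 <= n_sig / n_tot <= 0.11
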