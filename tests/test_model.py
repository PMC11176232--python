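import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import qluc10d as q
from qluc10d.model import ModelSpec, significance_stars


def _toy_data(toy_spec, n_resp=20, n_sets=8, seed=21):
    """Small simulated dataset on the enumerable toy attribute space."""
    design = q.generate_design(toy_spec, n_sets=n_sets, overlap=1,
                               priors=np.zeros(toy_spec.n_params),
                               n_iter=60, seed=seed)
    plans = q.allocate(design, n_resp, min(n_sets, 4), seed=seed + 1)
    truth = q.TrueModel(alpha=0.5, beta={("mobility", 2): -0.4, ("mood", 2): -0.2})
    return q.simulate_choices(plans, design, truth, seed=seed + 2)


def _neg_loglik(theta, xd, y):
    """Independent paired-logit likelihood: V_chosen - log(e^Va + e^Vb)."""
    eta = xd @ theta
    return -np.sum(y * eta - np.log1p(np.exp(eta)))


def _diff_arrays(data, spec):
    """Differenced covariates recomputed from the raw frame, independently
    of the estimation path."""
    df = data.df.sort_values(["respondent_id", "set_id", "alt"])
    X = q.build_design_matrix(df, spec).to_numpy()
    y = df["chosen"].to_numpy(float)[0::2]
    resp = df["respondent_id"].to_numpy()[0::2]
    return X[0::2] - X[1::2], y, resp


class TestDesignMatrix:
    def test_full_health_has_only_duration(self):
        df = pd.DataFrame(
            [
                {"respondent_id": 0, "set_id": 0, "alt": "A", "chosen": 1,
                 "duration_years": 10, **{d: 1 for d in q.DIMENSIONS}},
                {"respondent_id": 0, "set_id": 0, "alt": "B", "chosen": 0,
                 "duration_years": 1, **{d: 4 for d in q.DIMENSIONS}},
            ]
        )
        X = q.build_design_matrix(q.ChoiceData(df))
        assert X.loc[0, "duration"] == 10
        assert (X.loc[0].drop("duration") == 0).all()
        # worst state at t=1: every level-4 column is 1
        l4 = [c for c in X.columns if c.endswith("_4")]
        assert (X.loc[1, l4] == 1).all()
        assert (X.loc[1].drop(["duration", *l4]) == 0).all()

    def test_merged_levels_share_a_regressor(self):
        spec = ModelSpec(merges={"sleep": ((2, 3), (4,))})
        rows = []
        for i, lv in enumerate([2, 3]):
            state = {d: 1 for d in q.DIMENSIONS}
            state["sleep"] = lv
            rows.append({"respondent_id": 0, "set_id": i, "alt": "A",
                         "chosen": 1, "duration_years": 5, **state})
        X = q.build_design_matrix(pd.DataFrame(rows), spec)
        assert "sleep_23" in X.columns
        assert X.loc[0].equals(X.loc[1])
        assert spec.n_params == 30

    def test_unknown_level_rejected(self):
        row = {"respondent_id": 0, "set_id": 0, "alt": "A", "chosen": 1,
               "duration_years": 5, **{d: 1 for d in q.DIMENSIONS}}
        row["pain"] = 7
        with pytest.raises(ValueError, match="pain"):
            q.build_design_matrix(pd.DataFrame([row]))


class TestFit:
    def test_matches_brute_force_likelihood_optimum(self, toy_spec):
        data = _toy_data(toy_spec)
        spec = ModelSpec(toy_spec)
        ours = q.fit(data, spec)
        xd, y, _ = _diff_arrays(data, spec)
        res = optimize.minimize(
            _neg_loglik, np.zeros(toy_spec.n_params), args=(xd, y),
            method="BFGS", options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(ours.params.to_numpy(), res.x, atol=1e-6)
        assert ours.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_matches_statsmodels_logit(self, toy_spec):
        statsmodels = pytest.importorskip("statsmodels.api")
        data = _toy_data(toy_spec, n_resp=60, seed=31)
        spec = ModelSpec(toy_spec)
        ours = q.fit(data, spec)
        xd, y, _ = _diff_arrays(data, spec)
        sm_fit = statsmodels.Logit(y, xd).fit(disp=0, tol=1e-12)
        np.testing.assert_allclose(ours.params.to_numpy(), sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(
            ours.se("model").to_numpy(), sm_fit.bse, rtol=1e-5
        )

    def test_zero_truth_recovers_null(self, small_design):
        plans = q.allocate(small_design, 400, 12, seed=41)
        null_truth = q.TrueModel(alpha=0.0, beta={})
        data = q.simulate_choices(plans, small_design, null_truth, seed=42)
        f = q.fit(data)
        z = (f.params / f.se("clustered")).abs()
        assert (z < 3).all()
        assert f.pseudo_r2 == pytest.approx(0.0, abs=0.01)

    def test_invariant_to_ab_relabeling_and_row_order(self, toy_spec):
        data = _toy_data(toy_spec, seed=51)
        spec = ModelSpec(toy_spec)
        base = q.fit(data, spec)
        flipped = data.df.copy()
        flipped["alt"] = flipped["alt"].map({"A": "B", "B": "A"})
        shuffled = flipped.sample(frac=1.0, random_state=0).reset_index(drop=True)
        alt = q.fit(q.ChoiceData(shuffled, toy_spec), spec)
        np.testing.assert_allclose(base.params, alt.params, atol=1e-9)
        assert base.loglik == pytest.approx(alt.loglik, abs=1e-9)

    def test_invariant_to_weight_rescaling(self, toy_spec):
        data = _toy_data(toy_spec, n_resp=40, seed=61)
        spec = ModelSpec(toy_spec)
        ids = data.df["respondent_id"].unique()
        rng = np.random.default_rng(62)
        w = pd.Series(rng.uniform(0.5, 2.0, len(ids)), index=ids)
        f1 = q.fit(data, spec, weights=w)
        f2 = q.fit(data, spec, weights=w * 7.3)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-9)
        np.testing.assert_allclose(
            f1.se("clustered"), f2.se("clustered"), rtol=1e-8
        )

    def test_duplicating_respondents_preserves_estimates(self, toy_spec):
        data = _toy_data(toy_spec, seed=71)
        spec = ModelSpec(toy_spec)
        base = q.fit(data, spec)
        dup = data.df.copy()
        dup["respondent_id"] = dup["respondent_id"] + 10_000
        doubled = q.ChoiceData(
            pd.concat([data.df, dup], ignore_index=True), toy_spec
        )
        np.testing.assert_allclose(
            base.params, q.fit(doubled, spec).params, atol=1e-9
        )

    def test_complete_separation_raises(self, toy_spec):
        # enormous true coefficients make choices deterministic
        design = q.generate_design(toy_spec, n_sets=8, overlap=1,
                                   priors=np.zeros(3), n_iter=20, seed=81)
        plans = q.allocate(design, 30, 4, seed=82)
        truth = q.TrueModel(alpha=60.0, beta={("mobility", 2): -80.0,
                                              ("mood", 2): -40.0})
        data = q.simulate_choices(plans, design, truth, seed=83)
        with pytest.raises((q.NonConvergenceError, q.CollinearityError)):
            q.fit(data, ModelSpec(toy_spec))

    def test_collinear_column_named(self, toy_spec):
        data = _toy_data(toy_spec, seed=91)
        # a dimension that never varies leaves its column all-zero
        df = data.df.copy()
        df["mood"] = 1
        with pytest.raises(q.CollinearityError, match="mood"):
            q.fit(q.ChoiceData(df, toy_spec), ModelSpec(toy_spec))


class TestClusteredVcov:
    def test_matches_textbook_sandwich(self, toy_spec):
        data = _toy_data(toy_spec, n_resp=30, seed=22)
        spec = ModelSpec(toy_spec)
        f = q.fit(data, spec)
        xd, y, resp = _diff_arrays(data, spec)
        theta = f.params.to_numpy()
        p = 1 / (1 + np.exp(-(xd @ theta)))
        scores = xd * (y - p)[:, None]
        G = len(np.unique(resp))
        g = np.array([scores[resp == r].sum(axis=0) for r in np.unique(resp)])
        B = g.T @ g * G / (G - 1)
        A = (xd * (p * (1 - p))[:, None]).T @ xd
        oracle = np.linalg.inv(A) @ B @ np.linalg.inv(A)
        np.testing.assert_allclose(
            q.clustered_vcov(f).to_numpy(), oracle, atol=1e-10
        )

    def test_singleton_clusters_equal_hc_robust(self, toy_spec):
        data = _toy_data(toy_spec, n_resp=80, seed=23)
        df = data.df.copy()
        # one set per respondent: relabel each (respondent, set) as its own id
        df["respondent_id"] = df.groupby(
            ["respondent_id", "set_id"], sort=False
        ).ngroup()
        spec = ModelSpec(toy_spec)
        f = q.fit(q.ChoiceData(df, toy_spec), spec)
        xd, y, resp = _diff_arrays(q.ChoiceData(df, toy_spec), spec)
        theta = f.params.to_numpy()
        p = 1 / (1 + np.exp(-(xd @ theta)))
        scores = xd * (y - p)[:, None]
        n = len(y)
        B = scores.T @ scores * n / (n - 1)
        A = (xd * (p * (1 - p))[:, None]).T @ xd
        hc = np.linalg.inv(A) @ B @ np.linalg.inv(A)
        np.testing.assert_allclose(f.vcov_clustered.to_numpy(), hc, atol=1e-12)

    def test_requires_two_clusters(self, toy_spec):
        data = _toy_data(toy_spec, seed=24)
        f = q.fit(data, ModelSpec(toy_spec))
        with pytest.raises(ValueError, match="2 clusters"):
            q.clustered_vcov(f, cluster=np.zeros(f.n_sets))


class TestFitStatistics:
    def test_definitions_on_a_real_fit(self, toy_spec):
        data = _toy_data(toy_spec, seed=25)
        f = q.fit(data, ModelSpec(toy_spec))
        stats_ = q.fit_statistics(f)
        assert stats_["pseudo_r2"] == pytest.approx(
            1 - f.loglik / (f.n_sets * np.log(0.5))
        )
        assert stats_["aic"] == pytest.approx(2 * f.k - 2 * f.loglik)
        assert stats_["bic"] == pytest.approx(
            f.k * np.log(f.n_rows) - 2 * f.loglik
        )
        assert f.n_rows == 2 * f.n_sets

    def test_merged_model_is_nested(self, small_cohort):
        """Pooling levels restricts the model, so its likelihood is lower."""
        full = q.fit(small_cohort)
        merged = q.fit(small_cohort, ModelSpec(merges={"sleep": ((2, 3), (4,))}))
        assert merged.k == full.k - 1
        assert merged.loglik <= full.loglik + 1e-9


class TestCoefficientTable:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.5, ""), (0.04, "*"), (0.009, "**"), (0.0005, "***"), (0.05, "")],
    )
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def test_stars_match_normal_cdf_oracle(self, toy_spec):
        data = _toy_data(toy_spec, n_resp=60, seed=26)
        f = q.fit(data, ModelSpec(toy_spec))
        table = q.coefficient_table(f)
        for name, row in table.iterrows():
            p = 2 * (1 - stats.norm.cdf(abs(row["estimate"] / row["se"])))
            assert row["p"] == pytest.approx(p, abs=1e-12)
            expected = "***" if p < 0.001 else "**" if p < 0.01 else \
                "*" if p < 0.05 else ""
            assert row["stars"] == expected


class TestParameterRecovery:
    def test_full_size_coverage_over_replicates(self, full_design):
        """95% clustered Wald intervals cover each true coefficient in at
        least 17 of 20 study-scale replicates."""
        truth = q.TrueModel.from_reference()
        theta0 = truth.theta(full_design.spec)
        covered = np.zeros(len(theta0), int)
        for rep in range(20):
            plans = q.allocate(full_design, 2435, 16, seed=1000 + rep)
            data = q.simulate_choices(plans, full_design, truth,
                                      seed=2000 + rep)
            f = q.fit(data)
            se = f.se("clustered").to_numpy()
            est = f.params.to_numpy()
            covered += (np.abs(est - theta0) <= 1.96 * se).astype(int)
        assert (covered >= 17).all(), covered
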