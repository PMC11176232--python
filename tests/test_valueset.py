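import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qluc10d as q
from qluc10d import reference as R
from qluc10d.model import FittedChoiceModel, ModelSpec
from qluc10d.valueset import AnchoringError, PreferenceWeight, decrements


def _mock_fit(params: dict, vcov: np.ndarray | None = None,
              mspec: ModelSpec | None = None) -> FittedChoiceModel:
    """Hand-built fitted model for deterministic ratio/monotonicity tests."""
    mspec = mspec or ModelSpec()
    s = pd.Series(params, name="coef").reindex(mspec.column_names())
    if s.isna().any():
        raise AssertionError("params incomplete")
    k = len(s)
    v = vcov if vcov is not None else np.eye(k) * 1e-4
    vdf = pd.DataFrame(v, index=s.index, columns=s.index)
    return FittedChoiceModel(
        params=s, vcov_model=vdf, vcov_clustered=vdf, loglik=-1.0,
        n_respondents=10, n_sets=100, n_rows=200, converged=True,
        n_iter=1, gradient_norm=0.0, model_spec=mspec,
    )


def _reference_params() -> dict:
    out = {"duration": R.UNWEIGHTED_M1_DURATION[0]}
    for (dim, lv), (c, _) in R.UNWEIGHTED_M1.items():
        out[f"{dim}_{lv}"] = c
    return out


class TestDecrements:
    def test_published_ratio_arithmetic(self):
        vs = q.reference_valueset()
        assert vs.decrement("physical", 4) == pytest.approx(-0.26675, abs=1e-5)
        assert vs.decrement("physical", 1) == 0.0

    def test_zero_coefficient_ratio_identity(self):
        params = _reference_params()
        params["pain_2"] = 0.0
        fit = _mock_fit(params)
        ws = {(w.dimension, w.level): w for w in decrements(fit)}
        w = ws[("pain", 2)]
        assert w.decrement == 0.0
        se_beta = 0.01  # sqrt(1e-4)
        assert w.se == pytest.approx(se_beta / params["duration"], rel=1e-12)

    def test_level_one_is_exactly_zero_everywhere(self, full_fit):
        ws = decrements(full_fit)
        level1 = [w for w in ws if w.level == 1]
        assert len(level1) == 10
        assert all(w.decrement == 0.0 for w in level1)
        assert len(ws) == 40

    def test_negative_alpha_raises_anchoring_error(self):
        params = _reference_params()
        params["duration"] = -0.2
        with pytest.raises(AnchoringError):
            decrements(_mock_fit(params))

    def test_delta_se_matches_parametric_bootstrap(self, full_fit):
        """Delta-method ratio SEs agree with a 10,000-draw parametric
        bootstrap from the fitted covariance within 5%."""
        rng = np.random.default_rng(7)
        theta = full_fit.params.to_numpy()
        draws = rng.multivariate_normal(
            theta, full_fit.vcov_clustered.to_numpy(), size=10_000
        )
        names = list(full_fit.params.index)
        ws = {(w.dimension, w.level): w for w in decrements(full_fit)}
        for col in ("physical_4", "pain_3", "sleep_2"):
            dim, lv = col.rsplit("_", 1)
            ratios = draws[:, names.index(col)] / draws[:, 0]
            assert ws[(dim, int(lv))].se == pytest.approx(
                ratios.std(ddof=1), rel=0.05
            )


class TestMonotonicity:
    def test_published_unweighted_coefficients_are_monotone(self):
        coefs = {k: c for k, (c, _) in R.UNWEIGHTED_M1.items()}
        assert q.check_monotonicity(coefs) == []

    def test_published_weighted_sleep_violation(self):
        coefs = {k: c for k, (c, _) in R.WEIGHTED_M1.items()}
        v = q.check_monotonicity(coefs)
        assert [(x.dimension, x.level_low, x.level_high) for x in v] == [
            ("sleep", 2, 3)
        ]

    def test_exact_ties_are_not_violations(self):
        coefs = {k: c for k, (c, _) in R.UNWEIGHTED_M1.items()}
        coefs[("sleep", 3)] = coefs[("sleep", 2)]
        assert q.check_monotonicity(coefs) == []

    def test_positive_level2_coefficient_is_a_violation(self):
        coefs = {k: c for k, (c, _) in R.UNWEIGHTED_M1.items()}
        coefs[("pain", 2)] = 0.01
        v = q.check_monotonicity(coefs)
        assert ("pain", 1, 2) in [(x.dimension, x.level_low, x.level_high) for x in v]


class TestMergeAndRefit:
    def test_monotone_fit_is_a_fixed_point(self, small_cohort):
        fit = _mock_fit(_reference_params())
        mspec, out = q.merge_and_refit(small_cohort, fit=fit)
        assert out is fit
        assert mspec.merges == {}

    def test_tied_truth_merge_study(self, full_design):
        """With exactly tied true sleep levels the estimated ordering
        inverts in roughly half the replicates; whenever it does, pooling
        recovers the common coefficient within 3 SE."""
        truth = q.TrueModel.from_reference()
        beta = dict(truth.beta)
        beta[("sleep", 2)] = beta[("sleep", 3)] = -0.0277
        tied = q.TrueModel(truth.alpha, beta)
        detected = within = 0
        for rep in range(20):
            plans = q.allocate(full_design, 2435, 16, seed=5000 + rep)
            data = q.simulate_choices(plans, full_design, tied, seed=6000 + rep)
            f = q.fit(data)
            if any(v.dimension == "sleep" for v in q.check_monotonicity(f)):
                detected += 1
                mspec, f2 = q.merge_and_refit(data, fit=f)
                assert (2, 3) in mspec.partition("sleep")
                est, se = f2.params["sleep_23"], f2.se()["sleep_23"]
                within += abs(est - (-0.0277)) <= 3 * se
        assert detected >= 8
        assert within == detected

    def test_inverted_truth_merge_detection(self, full_design):
        """The published weighted sleep inversion (L3 less negative than
        L2 by 0.0094) is detected and repaired in most replicates."""
        truth = q.TrueModel.from_reference()
        beta = dict(truth.beta)
        beta[("sleep", 2)], beta[("sleep", 3)] = -0.0317, -0.0223
        inv = q.TrueModel(truth.alpha, beta)
        detected = 0
        for rep in range(20):
            plans = q.allocate(full_design, 2435, 16, seed=7000 + rep)
            data = q.simulate_choices(plans, full_design, inv, seed=8000 + rep)
            f = q.fit(data)
            if any(v.dimension == "sleep" for v in q.check_monotonicity(f)):
                mspec, f2 = q.merge_and_refit(data, fit=f)
                assert f2.k < f.k
                assert f2.loglik <= f.loglik + 1e-9
                detected += 1
        assert detected >= 13

    def test_repair_produces_monotone_fit(self, small_cohort):
        _, f2 = q.merge_and_refit(small_cohort)
        assert q.check_monotonicity(f2) == []


levels10 = st.lists(st.integers(1, 4), min_size=10, max_size=10)


class TestUtility:
    def test_full_health_is_exactly_one(self):
        assert q.reference_valueset().utility("1111111111") == 1.0

    def test_worst_state_value(self):
        u = q.reference_valueset().utility("4444444444")
        assert u == pytest.approx(-0.23145, abs=1e-4)

    def test_mild_state_worked_example(self):
        # a little impairment in physical functioning and pain
        u = q.reference_valueset().utility("2111121111")
        assert u == pytest.approx(0.8686, abs=1e-4)

    @given(levels10)
    def test_no_state_exceeds_full_health(self, lv):
        assert q.reference_valueset().utility(lv) <= 1.0

    @given(levels10, st.integers(0, 9))
    def test_single_step_worsening_never_raises_utility(self, lv, d):
        vs = q.reference_valueset()
        if lv[d] == 4:
            lv[d] = 3
        worse = list(lv)
        worse[d] += 1
        assert vs.utility(worse) <= vs.utility(lv)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            q.reference_valueset().utility("5111111111")


class TestExport:
    def test_round_trip_and_recomputation(self, full_fit, tmp_path):
        vs = q.ValueSet.from_fit(full_fit, seed=0)
        path = tmp_path / "valueset.csv"
        q.export_valueset(vs, path)
        loaded = q.read_valueset(path)
        pd.testing.assert_frame_equal(vs.to_frame(), loaded.to_frame())
        frame = loaded.to_frame()
        assert len(frame) == 40
        assert (frame.loc[frame["level"] == 1, "decrement"] == 0).all()
        # exported decrements are exactly beta/alpha from the stored fit
        alpha = full_fit.alpha
        for name, beta in full_fit.beta.items():
            dim, lv = name.rsplit("_", 1)
            row = frame[(frame["dimension"] == dim) & (frame["level"] == int(lv))]
            assert row["decrement"].iloc[0] == pytest.approx(
                beta / alpha, abs=1e-12
            )


class TestQLQC30Scoring:
    def _records(self, value):
        mapping = q.QLQC30Mapping.default()
        rec = {"record_id": 1, **{i: value for i in mapping.all_items}}
        return pd.DataFrame([rec])

    def test_all_best_scores_one(self):
        out = q.score_qlqc30(self._records(1), q.reference_valueset())
        assert out["utility"].iloc[0] == 1.0
        assert out["state"].iloc[0] == "1111111111"

    def test_all_worst_matches_worst_state(self):
        vs = q.reference_valueset()
        out = q.score_qlqc30(self._records(4), vs)
        assert out["utility"].iloc[0] == pytest.approx(vs.utility("4444444444"))

    def test_worst_item_carries_within_dimension(self):
        vs = q.reference_valueset()
        rec = self._records(1)
        rec.loc[0, "q02"] = 3  # one of the two physical items
        out = q.score_qlqc30(rec, vs)
        assert out["state"].iloc[0] == "3111111111"

    def test_missing_item_yields_missing_utility(self):
        rec = self._records(2)
        rec.loc[0, "q11"] = np.nan
        out = q.score_qlqc30(rec, q.reference_valueset())
        assert np.isnan(out["utility"].iloc[0])
        assert out.attrs["n_missing"] == 1

    def test_out_of_range_response_rejected(self):
        rec = self._records(2)
        rec.loc[0, "q14"] = 6
        with pytest.raises(ValueError, match="q14"):
            q.score_qlqc30(rec, q.reference_valueset())

    def test_mapping_uses_thirteen_distinct_items(self):
        mapping = q.QLQC30Mapping.default()
        assert len(set(mapping.all_items)) == 13
        assert set(mapping.items) == set(q.DIMENSIONS)
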