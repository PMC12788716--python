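"""Base-learner correctness: split, LASSO selection, interaction Cox,
backward elimination, survival prediction and IPCW metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import compact_config
from pa_optim.survival import (
    CoxInteractionModel,
    backward_eliminate,
    brier_score,
    calibration_bins,
    cox_partial_loglik,
    evaluate_model,
    fit_interaction_cox,
    predict_survival,
    select_covariates_lasso,
    split_cohort,
    time_dependent_auc,
)
from pa_optim.synthetic import generate_cohort


class TestSplitCohort:
    def test_sizes_and_disjointness(self):
        df = pd.DataFrame({"x": range(10)})
        train, test = split_cohort(df, 0.8, seed=0)
        assert len(train) == 8 and len(test) == 2
        assert set(train.index).isdisjoint(test.index)

    def test_reproducible_and_exhaustive(self):
        df = pd.DataFrame({"x": range(57)})
        t1, v1 = split_cohort(df, 0.8, seed=5)
        t2, v2 = split_cohort(df, 0.8, seed=5)
        assert list(t1.index) == list(t2.index)
        assert sorted(list(t1.index) + list(v1.index)) == list(range(57))

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(pd.DataFrame({"x": [1]}), 0.8, seed=0)


@pytest.fixture(scope="module")
def fitted(small_cohort_module):
    table, truth = small_cohort_module
    covs = ["age", "sex_male", "stroke", "diabetes"]
    model = fit_interaction_cox(table, covs, interactions=["stroke", "age"])
    return table, truth, model


@pytest.fixture(scope="module")
def small_cohort_module():
    return generate_cohort(compact_config(n=4000, seed=11))


class TestFitInteractionCox:
    def test_duplicating_rows_leaves_estimates_unchanged(self):
        table, _ = generate_cohort(compact_config(n=800, seed=12))
        covs = ["age", "stroke"]
        m1 = fit_interaction_cox(table, covs, interactions=["stroke"])
        m2 = fit_interaction_cox(
            pd.concat([table, table], ignore_index=True), covs, interactions=["stroke"]
        )
        # exact under Breslow ties; Efron's correction treats the duplicated
        # event times as ties, leaving a discrepancy far below one SE
        assert np.allclose(m1.beta.to_numpy(), m2.beta.to_numpy(), atol=5e-3)

    def test_too_many_terms_rejected(self):
        table, _ = generate_cohort(compact_config(n=4000, seed=13))
        few = table.head(60)
        with pytest.raises(ValueError, match="events"):
            fit_interaction_cox(few, ["age", "sex_male", "stroke", "diabetes"])

    def test_baseline_hazard_monotone_from_zero(self, fitted):
        _, _, model = fitted
        assert model.cumulative_hazard(0.0)[0] == 0.0
        H = model.baseline_cumhaz
        assert (np.diff(H) >= 0).all()

    def test_parameter_recovery_single_replicate(self, fitted):
        table, truth, model = fitted
        cfg = truth.config
        checks = {
            "pattern[active_regular]": cfg.beta_main["active_regular"],
            "stroke": cfg.beta_main["stroke"],
            "pattern[active_regular]:stroke": cfg.beta_interaction[
                ("active_regular", "stroke")
            ],
            "pattern[active_ww]:age": cfg.beta_interaction[("active_ww", "age")],
        }
        for term, tv in checks.items():
            z = (model.beta[term] - tv) / model.se[term]
            assert abs(z) < 4.0, f"{term}: z={z:.2f}"

    def test_serialization_round_trip(self, fitted, tmp_path):
        table, _, model = fitted
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = CoxInteractionModel.from_json(path)
        s1 = model.predict_survival(table.head(20), pattern="active_ww", t=10.0)
        s2 = clone.predict_survival(table.head(20), pattern="active_ww", t=10.0)
        assert np.allclose(s1, s2, atol=1e-12)


class TestPredictSurvival:
    def test_t_zero_is_one(self, fitted):
        table, _, model = fitted
        assert np.allclose(model.predict_survival(table.head(5), "baseline", 0.0), 1.0)

    def test_baseline_individual_is_exp_minus_h0(self, fitted):
        table, _, model = fitted
        row = table.head(1).copy()
        # design origin: continuous covariates at training means, binaries 0
        for c, mu in model.centers.items():
            row[c] = mu
        for c in model.covariates:
            if c not in model.centers:
                row[c] = 0
        s = predict_survival(model, row, "baseline", 8.0)
        assert s[0] == pytest.approx(np.exp(-model.cumulative_hazard(8.0)[0]), abs=1e-12)

    def test_monotone_nonincreasing_in_t(self, fitted):
        table, _, model = fitted
        ts = np.linspace(0, 14, 30)
        for p in ("baseline", "active_lpa", "active_regular", "active_ww"):
            s = np.column_stack([model.predict_survival(table.head(10), p, t) for t in ts])
            assert (np.diff(s, axis=1) <= 1e-12).all()

    def test_large_n_truth_alignment(self, fitted):
        table, truth, model = fitted
        pred = model.predict_survival(table, pattern=None, t=10.0)
        ts = truth.true_survival(10.0)
        idx = np.arange(len(table))
        true_obs = ts.to_numpy()[idx, [list(ts.columns).index(p) for p in table["pattern"]]]
        assert np.abs(pred - true_obs).mean() < 0.02

    def test_univariate_hr_recovery(self):
        # univariate Cox on a simulated binary exposure with known HR
        rng = np.random.default_rng(3)
        n = 4000
        x = (rng.random(n) < 0.4).astype(float)
        h = 1.6
        T = 15.0 * (rng.exponential(size=n) / np.exp(np.log(h) * x)) ** (1 / 1.2)
        C = rng.uniform(1, 20, n)
        df = pd.DataFrame({"x": x, "time": np.minimum(T, C), "event": (T <= C).astype(int)})
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(df, "time", "event")
        assert abs(cph.params_["x"] - np.log(h)) < 3 * cph.standard_errors_["x"]


class TestLasso:
    @staticmethod
    def _cohort_with_nulls(n, seed):
        rng = np.random.default_rng(seed)
        active = {f"a{i}": rng.normal(size=n) for i in range(3)}
        null = {f"n{i}": rng.normal(size=n) for i in range(7)}
        lp = 0.5 * active["a0"] + 0.4 * active["a1"] - 0.5 * active["a2"]
        T = 20.0 * (rng.exponential(size=n) / np.exp(lp)) ** (1 / 1.2)
        C = rng.uniform(2, 25, n)
        df = pd.DataFrame({**active, **null})
        df["pattern"] = rng.choice(
            ["baseline", "active_lpa", "active_regular", "active_ww"], n
        )
        df["time"] = np.minimum(T, C)
        df["event"] = (T <= C).astype(int)
        return df

    def test_active_support_selected(self):
        df = self._cohort_with_nulls(5000, 0)
        fit = select_covariates_lasso(df, [c for c in df.columns if c[0] in "an"], seed=0)
        assert {"a0", "a1", "a2"} <= set(fit.selected)
        assert fit.forced == [
            "pattern[active_lpa]", "pattern[active_regular]", "pattern[active_ww]"
        ]

    def test_huge_penalty_keeps_only_forced_terms(self):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        df = self._cohort_with_nulls(1000, 1)
        cand = [c for c in df.columns if c[0] in "an"]
        from pa_optim.survival import pattern_dummies

        dummies = pattern_dummies(df["pattern"].reset_index(drop=True))
        X = np.column_stack([dummies.to_numpy(), df[cand].to_numpy()])
        penalty = np.array([0.0] * 3 + [1.0] * len(cand))
        m = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[1e6], penalty_factor=penalty, alpha_min_ratio=0.01
        )
        m.fit(X, Surv.from_arrays(df["event"].astype(bool), df["time"]))
        beta = m.coef_[:, 0]
        assert np.abs(beta[3:]).max() < 1e-8  # all penalized terms shrunk away

    def test_tiny_penalty_matches_unpenalized_support(self):
        df = self._cohort_with_nulls(2000, 2)
        cand = ["a0", "a1", "a2"]
        fit = select_covariates_lasso(df, cand, seed=2, folds=5)
        assert set(fit.selected) == set(cand)  # strong signals survive CV choice

    def test_constant_candidate_dropped_with_warning(self):
        df = self._cohort_with_nulls(1000, 3)
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fit = select_covariates_lasso(df, ["a0", "const"], seed=3, folds=5)
        assert "const" not in fit.selected

    def test_partial_loglik_matches_lifelines(self):
        df = self._cohort_with_nulls(500, 4)
        from lifelines import CoxPHFitter

        sub = df[["a0", "a1", "time", "event"]]
        cph = CoxPHFitter().fit(sub, "time", "event", fit_options={"step_size": 0.95})
        beta = cph.params_.to_numpy()
        lp = sub[["a0", "a1"]].to_numpy() @ beta
        ours = cox_partial_loglik(lp, sub["time"].to_numpy(), sub["event"].to_numpy())
        # ties are almost surely absent in continuous time: Breslow == Efron
        assert ours == pytest.approx(cph.log_likelihood_, rel=1e-6)


class TestBackwardElimination:
    @pytest.fixture(scope="class")
    def elimination_world(self):
        # one real interaction (stroke) and null interactions elsewhere
        cfg = compact_config(n=6000, seed=21).with_(
            beta_interaction={
                ("active_lpa", "stroke"): 0.50,
                ("active_regular", "stroke"): 1.20,
                ("active_ww", "stroke"): 1.20,
            }
        )
        table, _ = generate_cohort(cfg)
        covs = ["age", "sex_male", "stroke", "diabetes"]
        full = fit_interaction_cox(table, covs)  # interactions on all four
        return table, full

    def test_real_interaction_survives_and_nulls_drop(self, elimination_world):
        table, full = elimination_world
        reduced = backward_eliminate(table, full)
        assert "stroke" in reduced.interactions
        dropped_nulls = {"age", "sex_male", "diabetes"} - set(reduced.interactions)
        assert len(dropped_nulls) >= 2
        assert reduced.aic <= full.aic

    def test_fixed_point(self, elimination_world):
        table, full = elimination_world
        reduced = backward_eliminate(table, full)
        again = backward_eliminate(table, reduced)
        assert again.terms == reduced.terms

    def test_hierarchy_preserved_on_trace(self, elimination_world):
        table, full = elimination_world
        reduced = backward_eliminate(table, full)
        removed = [t["removed"] for t in reduced.metadata["elimination_trace"]]
        seen_main = set()
        for r in removed:
            kind, cov = r.split(":")
            if kind == "main":
                seen_main.add(cov)
            else:
                assert cov not in seen_main  # interaction removed before its main
        # pattern dummies are never eliminated
        assert all(t.startswith("pattern[") for t in reduced.terms[:3])

    def test_homogeneous_truth_drops_interactions_and_predictions_agree(self):
        from pa_optim.synthetic import no_interaction_config

        cfg = no_interaction_config(n=6000, seed=22)
        table, _ = generate_cohort(cfg)
        covs = ["age", "sex_male", "stroke", "diabetes"]
        full = fit_interaction_cox(table, covs)
        reduced = backward_eliminate(table, full)
        assert len(reduced.interactions) <= 1
        s_full = full.predict_survival(table.head(200), "active_regular", 10.0)
        s_red = reduced.predict_survival(table.head(200), "active_regular", 10.0)
        assert np.abs(s_full - s_red).mean() < 0.01


class TestMetrics:
    def test_perfect_predictions_no_censoring_zero_brier(self):
        time = np.array([2.0, 3.0, 12.0, 15.0])
        event = np.ones(4, dtype=int)
        surv = np.array([0.0, 0.0, 1.0, 1.0])  # matches outcome at t=10
        assert brier_score(surv, time, event, 10.0).value == pytest.approx(0.0, abs=1e-12)

    def test_constant_prediction_closed_form(self):
        rng = np.random.default_rng(0)
        time = rng.uniform(1, 20, 200)
        event = np.ones(200, dtype=int)
        t = 10.0
        q = (time <= t).mean()
        for p in (0.2, 0.5, 0.9):  # p = predicted event risk
            bs = brier_score(np.full(200, 1 - p), time, event, t).value
            assert bs == pytest.approx(q * (1 - p) ** 2 + (1 - q) * p**2, abs=1e-10)

    def test_ipcw_brier_matches_brute_force(self, censored_fixture):
        df = censored_fixture
        t = 8.0
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(df["time"], 1 - df["event"])
        total = 0.0
        for _, r in df.iterrows():
            if r.time <= t and r.event == 1:
                g = float(km.survival_function_at_times(r.time - 1e-9).iloc[0])
                total += (0.0 - r.surv_prob) ** 2 / g
            elif r.time > t:
                total += (1.0 - r.surv_prob) ** 2 / float(km.predict(t))
        oracle = total / len(df)
        ours = brier_score(
            df["surv_prob"].to_numpy(), df["time"].to_numpy(), df["event"].to_numpy(), t
        ).value
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_auc_one_for_oracle_score(self):
        time = np.array([1.0, 2.0, 3.0, 12.0, 13.0, 14.0])
        event = np.ones(6, dtype=int)
        risk = (time <= 10.0).astype(float)
        assert time_dependent_auc(risk, time, event, 10.0).value == pytest.approx(1.0)

    def test_random_score_auc_near_half(self):
        rng = np.random.default_rng(1)
        n = 2000
        time = rng.uniform(0.5, 20, n)
        event = np.ones(n, dtype=int)
        risk = rng.normal(size=n)
        auc = time_dependent_auc(risk, time, event, 10.0).value
        assert abs(auc - 0.5) < 0.05

    def test_no_censoring_equals_pairwise_enumeration(self):
        rng = np.random.default_rng(2)
        n = 80
        time = rng.uniform(1, 20, n)
        event = np.ones(n, dtype=int)
        risk = rng.normal(size=n)
        t = 10.0
        cases = np.where(time <= t)[0]
        controls = np.where(time > t)[0]
        num = 0.0
        for i in cases:
            for j in controls:
                num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
        oracle = num / (len(cases) * len(controls))
        ours = time_dependent_auc(risk, time, event, t).value
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_horizons_rejected(self, censored_fixture):
        df = censored_fixture
        with pytest.raises(ValueError):
            time_dependent_auc(
                df["surv_prob"], df["time"], df["event"], df["time"].max() + 1
            )

    def test_bootstrap_ci_brackets_estimate(self, censored_fixture):
        df = censored_fixture
        res = brier_score(
            df["surv_prob"].to_numpy(), df["time"].to_numpy(), df["event"].to_numpy(),
            8.0, n_boot=100, seed=0,
        )
        assert res.ci_lower <= res.value <= res.ci_upper

    def test_calibration_bins_structure(self, small_cohort_module):
        table, _ = small_cohort_module
        covs = ["age", "sex_male", "stroke", "diabetes"]
        model = fit_interaction_cox(table, covs, interactions=["stroke"])
        sp = model.predict_survival(table, pattern=None, t=10.0)
        bins = calibration_bins(sp, table["time"], table["event"], 10.0)
        assert bins["n"].sum() == len(table)
        assert bins["predicted_risk"].is_monotonic_increasing


class TestEvaluateModel:
    def test_metrics_in_range_and_informative(self, small_cohort_module):
        table, _ = small_cohort_module
        train, test = split_cohort(table, 0.8, seed=1)
        model = fit_interaction_cox(
            train, ["age", "sex_male", "stroke", "diabetes"], interactions=["stroke"]
        )
        res = evaluate_model(model, test, horizons=(10.0,), n_boot=0)
        assert 0.0 <= res[0].brier.value <= 0.25
        assert 0.6 <= res[0].auc.value <= 1.0
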