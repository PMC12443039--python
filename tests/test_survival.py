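import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subtypekit import (ExpressionMatrix, build_signature,
                        centroid_distance_features, classify_nearest_centroid,
                        concordance_index, fit_cox, kaplan_meier,
                        likelihood_ratio_test, run_model_registry,
                        truncate_follow_up)

from conftest import make_separable


def brute_force_cindex(risk, time, event):
    """All-pairs Harrell's c: comparable pair = the earlier time is an
    observed event (a death tied with a censoring time precedes it); tied
    risks count one half; tied event times are not comparable."""
    risk, time, event = map(np.asarray, (risk, time, event))
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                pass
            elif time[i] == time[j] and event[i] == 1 and event[j] == 0:
                pass
            else:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return np.nan if den == 0 else num / den


def sim_survival(n, rng, log_hr=0.0, censor=0.2):
    """Binary covariate, exponential times, independent exponential
    censoring with rate solved for the target censored fraction."""
    from scipy.optimize import brentq
    x = rng.integers(0, 2, size=n)
    h = 0.05 * np.exp(log_hr * x)
    t = rng.exponential(1.0 / h)
    if censor > 0:
        rates = 0.05 * np.exp(log_hr * np.array([0, 1]))
        c = brentq(lambda c: np.mean(c / (c + rates)) - censor, 1e-12, 1e6)
        tc = rng.exponential(1.0 / c, size=n)
        event = (t <= tc).astype(int)
        time = np.minimum(t, tc)
    else:
        event, time = np.ones(n, int), t
    return pd.DataFrame({"time": np.maximum(time, 1e-9),
                         "event": event, "x": x})


class TestConcordance:
    def test_hand_enumerated_example(self):
        """times (1,2,3), events (1,1,0), risks (3,2,1): all three
        comparable pairs concordant."""
        assert concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 0]) == 1.0

    def test_perfectly_anti_ordered_risk(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=20)
        assert concordance_index(-t, t, np.ones(20, int)) == 1.0

    def test_constant_risk_is_half(self):
        assert concordance_index([1, 1, 1, 1], [1, 2, 3, 4],
                                 [1, 1, 1, 1]) == 0.5

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(5, 40)
            time = rng.integers(1, 8, size=n).astype(float)   # forced ties
            event = rng.integers(0, 2, size=n)
            risk = rng.integers(0, 4, size=n).astype(float)
            if event.sum() == 0:
                continue
            expected = brute_force_cindex(risk, time, event)
            got = concordance_index(risk, time, event)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert np.isclose(got, expected, atol=1e-12)


class TestFitCox:
    def test_duplicating_data_leaves_estimate_nearly_unchanged(self):
        """Under Breslow ties duplication is exactly neutral (the partial
        likelihood just doubles); Efron's tie correction sees the
        duplicates as ties, so the estimate moves only marginally."""
        rng = np.random.default_rng(2)
        df = sim_survival(120, rng, log_hr=0.6)
        single = fit_cox(df, ["x"])
        double = fit_cox(pd.concat([df, df], ignore_index=True), ["x"])
        assert np.isclose(single.coefficients.loc["x", "coef"],
                          double.coefficients.loc["x", "coef"], atol=0.01)

    def test_recovers_sign_and_rough_magnitude(self):
        rng = np.random.default_rng(3)
        df = sim_survival(800, rng, log_hr=0.7)
        fit = fit_cox(df, ["x"])
        assert 0.4 < fit.coefficients.loc["x", "coef"] < 1.0
        assert fit.train_cindex > 0.5

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0],
                           "x": [0, 1]})
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, ["x"])

    def test_missing_feature_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError, match="y"):
            fit_cox(df, ["y"])

    def test_null_covariate_lrt_p_uniform(self):
        """Likelihood-ratio p-values are uniform when the covariate is
        independent of survival (null calibration)."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(300):
            df = sim_survival(60, rng, log_hr=0.0)
            fit = fit_cox(df, ["x"])
            pvals.append(float(
                fit.fitter.log_likelihood_ratio_test().p_value))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        km = kaplan_meier(df, ["g"] * 3)
        assert np.allclose(km["survival"], 1.0)

    def test_product_limit_hand_values(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        km = kaplan_meier(df, ["g", "g"]).set_index("time")["survival"]
        assert np.isclose(km.loc[1.0], 0.5)
        assert np.isclose(km.loc[2.0], 0.0)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(1, 10, size=8))
        df = pd.DataFrame({"time": t, "event": np.ones(8, int)})
        km = kaplan_meier(df, ["g"] * 8)
        sub = km[km["time"] > 0].set_index("time")["survival"]
        for i, ti in enumerate(t):
            assert np.isclose(sub.loc[ti], 1 - (i + 1) / 8)

    def test_curves_monotone_in_unit_interval(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"time": rng.exponential(5, 40) + 1e-3,
                           "event": rng.integers(0, 2, 40)})
        km = kaplan_meier(df, rng.integers(0, 2, 40))
        for _, grp in km.groupby("group"):
            s = grp.sort_values("time")["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert s.min() >= 0 and s.max() <= 1


class TestCentroidDistances:
    def test_pythagorean_toy_example(self):
        from subtypekit.signature import CentroidSignature
        sig = CentroidSignature(
            classes=["A", "B"], n_per_class=1, genes=["g0", "g1"],
            class_of_gene=pd.Series({"g0": "A", "g1": "B"}),
            centroids=pd.DataFrame([[0.0, 0.0], [3.0, 4.0]],
                                   index=["A", "B"], columns=["g0", "g1"]),
            training_stats=pd.DataFrame({"mean": [1.5, 2.0],
                                         "sd": [1.0, 1.0]},
                                        index=["g0", "g1"]))
        expr = ExpressionMatrix(pd.DataFrame({"p": [3.0, 4.0]},
                                             index=["g0", "g1"]))
        d = centroid_distance_features(sig, expr)
        assert np.isclose(d.loc["p", "dist_A"], 5.0)
        assert np.isclose(d.loc["p", "dist_B"], 0.0)

    def test_consistent_with_classifier_and_gene_order(self):
        expr, labels = make_separable((4, 4, 4), markers_per_class=3)
        sig = build_signature(expr, labels, 2)
        d = centroid_distance_features(sig, expr)
        pred = classify_nearest_centroid(sig, expr)
        argmin = d.to_numpy().argmin(axis=1)
        assert all(pred["label"].iloc[i] == sig.classes[argmin[i]]
                   for i in range(len(pred)))
        # permuting gene rows consistently leaves distances unchanged
        perm = ExpressionMatrix(expr.values.iloc[::-1])
        pd.testing.assert_frame_equal(d, centroid_distance_features(sig, perm))


class TestTruncation:
    def test_horizon_beyond_last_time_changes_nothing(self):
        df = pd.DataFrame({"time": [3.0, 8.0], "event": [1, 0]})
        pd.testing.assert_frame_equal(truncate_follow_up(df, 100.0), df)

    def test_events_after_horizon_become_censored(self):
        df = pd.DataFrame({"time": [3.0, 80.0], "event": [1, 1]})
        out = truncate_follow_up(df, 60.0)
        assert out.loc[1, "time"] == 60.0
        assert out.loc[1, "event"] == 0
        assert out.loc[0, "time"] == 3.0 and out.loc[0, "event"] == 1


class TestModelRegistry:
    @staticmethod
    def _cohort(seed, n_per_class=30):
        rng = np.random.default_rng(seed)
        expr, labels = make_separable((n_per_class,) * 3, markers_per_class=4)
        noisy = ExpressionMatrix(
            expr.values + rng.uniform(0, 0.5, size=expr.shape))
        hazard = np.array([0.01, 0.03, 0.08])[labels.to_numpy() - 1]
        t = rng.exponential(1 / hazard)
        cens = rng.random(len(t)) < 0.2
        surv = pd.DataFrame({
            "time": np.maximum(np.where(cens, rng.random(len(t)) * t, t),
                               1e-6),
            "event": (~cens).astype(int),
            "stage": rng.integers(1, 5, size=len(t)),
            "age": rng.normal(65, 8, len(t)),
            "sex": rng.integers(0, 2, len(t))},
            index=labels.index)
        return noisy, labels, surv

    def test_identity_split_equal_cindexes(self):
        expr, labels, surv = self._cohort(0)
        sig = build_signature(expr, labels, 2)
        table = run_model_registry(surv, surv, sig, expr, expr,
                                   models=["A", "C", "F"])
        for mid in ("A", "C", "F"):
            assert np.isclose(table.loc[mid, "train_cindex"],
                              table.loc[mid, "test_cindex"], atol=1e-12)

    def test_subtype_only_hazard_favors_expression_model(self):
        expr, labels, surv = self._cohort(1)
        expr2, labels2, surv2 = self._cohort(2)
        sig = build_signature(expr, labels, 2)
        table = run_model_registry(surv, surv2, sig, expr, expr2,
                                   models=["A", "C", "F"])
        assert table.loc["C", "test_cindex"] > table.loc["A", "test_cindex"]
        assert np.isfinite(table.loc["F", "lrt_p"])

    def test_models_missing_covariates_are_skipped(self):
        expr, labels, surv = self._cohort(3)
        sig = build_signature(expr, labels, 2)
        table = run_model_registry(surv, surv, sig, expr, expr,
                                   models=["B", "D", "C"])
        assert table.loc["B", "status"].startswith("skipped")
        assert table.loc["D", "status"].startswith("skipped")
        assert table.loc["C", "status"] == "ok"

    def test_grade_model_train_only_when_test_lacks_grade(self):
        expr, labels, surv = self._cohort(4)
        rng = np.random.default_rng(4)
        train = surv.copy()
        train["grade"] = rng.integers(1, 4, size=len(train))
        table = run_model_registry(train, surv,
                                   build_signature(expr, labels, 2),
                                   expr, expr, models=["D", "H"])
        assert table.loc["D", "status"].startswith("train only")
        assert np.isfinite(table.loc["D", "train_cindex"])
        assert np.isnan(table.loc["D", "test_cindex"])


class TestLikelihoodRatio:
    def test_nested_model_statistic_nonnegative_chi2(self):
        rng = np.random.default_rng(7)
        df = sim_survival(200, rng, log_hr=0.8)
        df["noise"] = rng.normal(size=len(df))
        full = fit_cox(df, ["x", "noise"])
        nested = fit_cox(df, ["x"])
        stat, p = likelihood_ratio_test(full, nested)
        assert stat >= 0
        assert 0 <= p <= 1
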