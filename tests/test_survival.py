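import numpy as np
import pandas as pd
import pytest

from respseg import (DataError, ModelingError, aft_fit,
                     classification_metrics, compare_models, cox_fit,
                     km_estimate, logrank_test)


class TestClassificationMetrics:
    def test_hand_confusion_matrix(self):
        m = classification_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert m.accuracy == pytest.approx(0.75)
        assert m.mse == pytest.approx(0.25)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(1.0)

    def test_perfect_prediction(self):
        m = classification_metrics([1, 0, 1], [1, 0, 1])
        assert (m.accuracy, m.mse, m.specificity, m.precision, m.recall) == \
            (1.0, 0.0, 1.0, 1.0, 1.0)

    def test_accuracy_plus_mse_is_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 60))
            pred = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            m = classification_metrics(pred, y)
            assert m.accuracy + m.mse == 1.0

    def test_undefined_ratios_flagged_as_zero(self):
        m = classification_metrics([0, 0], [1, 1])  # no predicted positives
        assert m.precision == 0.0
        assert "precision" in m.undefined

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            classification_metrics([1, 0], [1])


class TestKaplanMeier:
    def test_three_subject_product_limit_by_hand(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1], ["g", "g", "g"])
        c = km.groups["g"]
        # S(1) = 2/3 (3 at risk, 1 event); censoring at 2; S(3) = 0 (1 at risk)
        s = dict(zip(c.times, c.survival))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = km_estimate([5.0, 8.0, 9.0], [0, 0, 0], ["g"] * 3)
        assert np.allclose(km.groups["g"].survival, 1.0)
        assert np.isnan(km.groups["g"].median)

    def test_no_censoring_matches_ecdf_complement(self, rng):
        t = rng.exponential(10.0, 80)
        km = km_estimate(t, np.ones(80, dtype=int), ["g"] * 80)
        c = km.groups["g"]
        for ti, si in zip(c.times, c.survival):
            if ti > 0:
                assert si == pytest.approx(np.mean(t > ti), abs=1e-12)

    def test_survival_non_increasing_starts_at_one(self, rng):
        t = rng.exponential(10.0, 60)
        e = rng.binomial(1, 0.7, 60)
        km = km_estimate(t, e, ["g"] * 60)
        surv = km.groups["g"].survival
        assert surv[0] <= 1.0 + 1e-12
        assert np.all(np.diff(surv) <= 1e-12)


class TestLogRank:
    def test_identical_duplicated_groups_give_null(self, rng):
        t = rng.exponential(5.0, 40)
        e = rng.binomial(1, 0.8, 40)
        times = np.concatenate([t, t])
        events = np.concatenate([e, e])
        groups = np.array(["a"] * 40 + ["b"] * 40)
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_detects_strong_separation(self, rng):
        n = 150
        t = np.concatenate([rng.exponential(5.0, n), rng.exponential(15.0, n)])
        events = np.ones(2 * n, dtype=int)
        groups = np.array(["a"] * n + ["b"] * n)
        _, p = logrank_test(t, events, groups)
        assert p < 1e-6

    def test_requires_two_groups(self, rng):
        with pytest.raises(DataError):
            logrank_test(rng.exponential(5.0, 10), np.ones(10, dtype=int),
                         ["a"] * 10)


def _sim_cox_data(rng, n=800, hr=0.668, p_group=0.5, censor_at=None):
    g = rng.binomial(1, p_group, n)
    t = rng.exponential(1.0, n) / (0.01 * np.exp(np.log(hr) * g))
    e = np.ones(n, dtype=int)
    if censor_at is not None:
        e = (t <= censor_at).astype(int)
        t = np.minimum(t, censor_at)
    return t, e, g


class TestCox:
    def test_duplicating_subjects_preserves_hazard_ratio(self, rng):
        t, e, g = _sim_cox_data(rng, n=300)
        x = rng.normal(size=300)
        cov = pd.DataFrame({"x": x, "group": g})
        fit1 = cox_fit(t, e, cov)
        cov2 = pd.concat([cov, cov], ignore_index=True)
        fit2 = cox_fit(np.concatenate([t, t]), np.concatenate([e, e]), cov2)
        # duplication introduces tied event times; the Efron tie correction
        # perturbs the point estimate only marginally
        assert fit2.group_effect["estimate"] == pytest.approx(
            fit1.group_effect["estimate"], rel=5e-3)

    def test_ci_brackets_estimate_and_events_counted(self, rng):
        t, e, g = _sim_cox_data(rng, n=400, censor_at=150.0)
        fit = cox_fit(t, e, pd.DataFrame({"group": g}))
        assert fit.table.loc["group", "ci_low"] <= fit.table.loc["group", "estimate"] \
            <= fit.table.loc["group", "ci_high"]
        assert fit.n_events == int(e.sum()) and fit.n == 400

    def test_constant_covariate_named(self, rng):
        t, e, g = _sim_cox_data(rng, n=100)
        with pytest.raises(ModelingError, match="const"):
            cox_fit(t, e, pd.DataFrame({"group": g, "c": np.ones(100)}))

    def test_null_covariate_ci_covers_one(self, rng):
        hits = 0
        for _ in range(40):
            t, e, g = _sim_cox_data(rng, n=250, hr=1.0)
            fit = cox_fit(t, e, pd.DataFrame({"group": g}))
            row = fit.table.loc["group"]
            hits += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert hits >= 35  # ≈95% nominal coverage


class TestAFT:
    def test_time_rescaling_leaves_time_ratios_invariant(self, rng):
        t, e, g = _sim_cox_data(rng, n=400, censor_at=120.0)
        cov = pd.DataFrame({"group": g})
        fit1 = aft_fit(t, e, cov)
        fit2 = aft_fit(t * 3.0, e, cov)
        assert fit2.group_effect["estimate"] == pytest.approx(
            fit1.group_effect["estimate"], rel=1e-4)

    def test_lognormal_distribution_selectable(self, rng):
        t, e, g = _sim_cox_data(rng, n=300, censor_at=120.0)
        fit = aft_fit(t, e, pd.DataFrame({"group": g}), distribution="lognormal")
        assert fit.model_kind == "aft"
        assert np.isfinite(fit.aic)

    def test_unknown_distribution_rejected(self, rng):
        t, e, g = _sim_cox_data(rng, n=60)
        with pytest.raises(ModelingError):
            aft_fit(t, e, pd.DataFrame({"group": g}), distribution="gamma")


class TestCompare:
    def _fit(self, rng, hr):
        t, e, g = _sim_cox_data(rng, n=200, hr=hr)
        return cox_fit(t, e, pd.DataFrame({"group": g}))

    def test_lower_aic_wins(self, rng):
        a, b = self._fit(rng, 0.5), self._fit(rng, 0.9)
        cmp = compare_models(a, b)
        expected = "novel" if a.aic < b.aic else "standard"
        assert cmp["winner"] == expected
        assert cmp["delta_aic"] == pytest.approx(a.aic - b.aic)

    def test_equal_aics_tie(self, rng):
        a = self._fit(rng, 0.7)
        cmp = compare_models(a, a)
        assert cmp["winner"] == "tie"

    def test_mismatched_kinds_rejected(self, rng):
        t, e, g = _sim_cox_data(rng, n=200, censor_at=200.0)
        cox = cox_fit(t, e, pd.DataFrame({"group": g}))
        aft = aft_fit(t, e, pd.DataFrame({"group": g}))
        with pytest.raises(ModelingError):
            compare_models(cox, aft)
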