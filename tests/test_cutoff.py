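import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respseg import (DataError, ModelingError, best_cutoff, f1_at_cutoff,
                     fit_logistic, out_of_fold_probabilities, predict_proba,
                     search_cutoff, select_optimal_technique)
from respseg.cv import CVTechniqueSpec, generate_splits

from conftest import logistic_xy


def brute_force_best_f1(probs, y, n_grid=10001):
    """Independent oracle: exhaustive search over an even cutoff grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    gt = probs[None, :] > grid[:, None]
    tp = gt @ (y == 1).astype(float)
    pp = gt.sum(axis=1)
    pos = float((y == 1).sum())
    f1 = np.where(pp + pos > 0, 2.0 * tp / np.maximum(pp + pos, 1.0), 0.0)
    return float(f1.max())


class TestFitLogistic:
    def test_matches_statsmodels_mle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X, y = logistic_xy(rng, n=500)
        ours = fit_logistic(X, y)
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        ref = oracle.params
        got = np.concatenate([[ours.intercept], ours.slopes()])
        assert np.allclose(got, ref, rtol=1e-4, atol=1e-6)

    def test_zero_design_balanced_outcome_gives_half(self):
        X = np.zeros((20, 5))
        y = np.array([0, 1] * 10)
        coefs = fit_logistic(X, y)
        assert abs(coefs.intercept) < 1e-6
        assert np.allclose(predict_proba(coefs, X), 0.5, atol=1e-6)

    def test_null_covariates_give_near_zero_slopes(self, rng):
        X = rng.normal(size=(2000, 5))
        y = rng.binomial(1, 0.4, 2000)  # independent of X
        coefs = fit_logistic(X, y)
        # ~3 SE bound: SE ≈ 1/sqrt(n p (1-p)) per standardized covariate
        assert np.all(np.abs(coefs.slopes()) < 3.0 / np.sqrt(2000 * 0.24))

    def test_recovers_known_coefficients(self, rng):
        slopes = np.array([0.9, -0.8, 0.7, -0.6, 1.0])
        X, y = logistic_xy(rng, n=10000, slopes=slopes, intercept=-0.3)
        coefs = fit_logistic(X, y)
        assert np.all(np.abs(coefs.slopes() - slopes) / np.abs(slopes) < 0.10)

    def test_single_class_outcome_raises(self):
        with pytest.raises(ModelingError):
            fit_logistic(np.random.default_rng(0).normal(size=(10, 5)),
                         np.ones(10))

    def test_separable_data_stays_finite(self, rng):
        X = np.hstack([np.linspace(-2, 2, 40)[:, None], rng.normal(size=(40, 4))])
        y = (X[:, 0] > 0).astype(int)  # perfectly separated on column 0
        coefs = fit_logistic(X, y)
        assert np.all(np.isfinite(coefs.slopes()))


class TestOutOfFold:
    def test_kfold_n_equals_loocv(self, rng):
        X, y = logistic_xy(rng, n=30, slopes=(0.8, -0.5, 0.4))
        loo = generate_splits(CVTechniqueSpec("LOOCV"), y, seed=0)
        kf = generate_splits(CVTechniqueSpec("KFold", k=30), y, seed=5)
        p_loo, c_loo = out_of_fold_probabilities(X, y, loo)
        p_kf, c_kf = out_of_fold_probabilities(X, y, kf)
        assert np.array_equal(p_loo, p_kf)
        assert np.all(c_loo == 1) and np.all(c_kf == 1)

    def test_repeated_coverage_counts(self, rng):
        X, y = logistic_xy(rng, n=40, slopes=(0.8, -0.5, 0.4))
        splits = generate_splits(CVTechniqueSpec("RepeatedKFold", k=5, repeats=2),
                                 y, seed=1)
        _, counts = out_of_fold_probabilities(X, y, splits)
        assert np.all(counts == 2)

    def test_deterministic(self, rng):
        X, y = logistic_xy(rng, n=40, slopes=(0.8, -0.5, 0.4))
        splits = generate_splits(CVTechniqueSpec("KFold", k=5), y, seed=2)
        a, _ = out_of_fold_probabilities(X, y, splits)
        b, _ = out_of_fold_probabilities(X, y, splits)
        assert np.array_equal(a, b)

    def test_single_class_folds_skipped_then_error(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.array([1, 0, 0, 0, 0, 0])
        # leave-one-out: removing the lone positive leaves single-class train
        splits = generate_splits(CVTechniqueSpec("LOOCV"), y, seed=0)
        probs, counts = out_of_fold_probabilities(X, y, splits)
        assert counts[0] == 0 and np.isnan(probs[0])
        with pytest.raises(ModelingError):
            out_of_fold_probabilities(X, np.array([1, 1, 1, 1, 1, 1])[:6],
                                      splits)


class TestF1:
    def test_hand_confusion_example(self):
        probs = np.array([0.9, 0.8, 0.3, 0.2])
        y = np.array([1, 1, 0, 1])
        assert f1_at_cutoff(probs, y, 0.5) == pytest.approx(0.8)  # TP=2 FP=0 FN=1

    def test_perfectly_separated(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert f1_at_cutoff(probs, y, 0.5) == 1.0

    def test_no_predicted_positives_is_zero(self):
        assert f1_at_cutoff(np.array([0.3, 0.4]), np.array([1, 0]), 1.0) == 0.0

    def test_cutoff_domain_checked(self):
        with pytest.raises(DataError):
            f1_at_cutoff(np.array([0.5]), np.array([1]), 1.5)


class TestBestCutoff:
    def test_hand_enumerated_example(self):
        probs = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 0, 1, 1])
        cut, f1, curve = best_cutoff(probs, y)
        assert cut == pytest.approx(0.4)  # strict >: predictions [0,0,1,1]
        assert f1 == 1.0
        assert max(v for _, v in curve) == f1

    def test_all_equal_probs_selects_zero_cutoff(self):
        probs = np.full(6, 0.7)
        y = np.array([1, 0, 1, 0, 1, 1])
        cut, f1, _ = best_cutoff(probs, y)
        assert cut == 0.0
        assert f1 == pytest.approx(f1_at_cutoff(probs, y, 0.0))

    def test_returned_f1_consistent(self, rng):
        probs = rng.random(50)
        y = rng.binomial(1, 0.4, 50)
        cut, f1, _ = best_cutoff(probs, y)
        assert f1 == pytest.approx(f1_at_cutoff(probs, y, cut), abs=1e-15)

    def test_matches_brute_force_grid(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 120))
            probs = np.round(rng.random(n), 2)  # force ties
            y = rng.binomial(1, 0.4, n)
            if y.min() == y.max():
                continue
            _, f1, _ = best_cutoff(probs, y)
            assert abs(f1 - brute_force_best_f1(probs, y)) <= 1e-12

    @given(shift=st.floats(min_value=-0.2, max_value=0.2))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, shift):
        # F1 is unchanged by a strictly monotone transform applied to both
        # probabilities and cutoff
        probs = np.array([0.1, 0.35, 0.5, 0.62, 0.9])
        y = np.array([0, 1, 0, 1, 1])
        cutoff = 0.45
        f = lambda p: 1.0 / (1.0 + np.exp(-(4 * p + shift)))  # noqa: E731
        assert f1_at_cutoff(probs, y, cutoff) == pytest.approx(
            f1_at_cutoff(f(probs), y, float(f(cutoff))))

    def test_single_class_rejected(self):
        with pytest.raises(ModelingError):
            best_cutoff(np.array([0.2, 0.8]), np.array([1, 1]))


class TestSelection:
    def test_single_spec_grid_chosen(self, rng):
        X, y = logistic_xy(rng, n=60, slopes=(0.8, -0.5, 0.4))
        grid = [CVTechniqueSpec("KFold", k=5)]
        sel = select_optimal_technique(X, y, grid, seed=1)
        assert sel.chosen.spec is grid[0]
        assert 0.0 <= sel.chosen.best_cutoff < 1.0

    def test_max_cutoff_vs_max_f1_rules(self, rng):
        X, y = logistic_xy(rng, n=80, slopes=(0.8, -0.5, 0.4))
        grid = [CVTechniqueSpec("KFold", k=k) for k in (3, 5, 8)]
        by_cut = select_optimal_technique(X, y, grid, seed=3, rule="max_cutoff")
        by_f1 = select_optimal_technique(X, y, grid, seed=3, rule="max_f1")
        cuts = [r.best_cutoff for r in by_cut.per_technique]
        f1s = [r.best_f1 for r in by_f1.per_technique]
        assert by_cut.chosen.best_cutoff == max(cuts)
        assert by_f1.chosen.best_f1 == max(f1s)

    def test_tie_break_prefers_enumeration_order(self, rng):
        X, y = logistic_xy(rng, n=40, slopes=(0.8, -0.5, 0.4))
        # LOOCV splits do not depend on the derived per-spec seed, so two
        # copies produce identical OOF probabilities and cutoffs
        spec = CVTechniqueSpec("LOOCV")
        r1 = search_cutoff(X, y, spec, seed=7)
        r2 = search_cutoff(X, y, spec, seed=8)
        assert r1.best_cutoff == r2.best_cutoff
        sel = select_optimal_technique(X, y, [spec, spec], seed=7)
        assert sel.chosen is sel.per_technique[0]

    def test_all_failing_specs_raise_aggregate(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        X = np.random.default_rng(0).normal(size=(8, 2))
        grid = [CVTechniqueSpec("StratifiedKFold", k=5)]
        with pytest.raises(ModelingError, match="Stratified"):
            select_optimal_technique(X, y, grid, seed=0)
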