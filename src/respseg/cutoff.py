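"""Out-of-fold logistic probabilities, F1-optimal cutoffs, and technique
selection.

For each CV technique, a logistic regression is refit on every training
fold and its probabilities are collected out-of-fold; the probability
cutoff maximizing the F1 score of "predicted responder iff probability >
cutoff" (strict) is the technique's best cutoff.  Across the technique
grid, the spec with the maximum best cutoff is selected (the alternative
max-F1 rule is also available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cv import CVTechniqueSpec, generate_splits
from .errors import ConfigError, DataError, ModelingError
from .features import BASE_COVARIATES, DesignMatrix

logger = logging.getLogger(__name__)

_SEPARATION_COEF = 1e3   # |coef| beyond this is treated as (quasi)separation
_RIDGE_C = 1e6           # fallback L2 strength 1/C = 1e-6 on the slopes


@dataclass
class CoefficientVector:
    """Logistic-regression coefficients on the log-odds scale.

    One slope per design column (sex, age, weight, smoke, race,
    pc_1..pc_k) plus the intercept.
    """

    sex: float
    age: float
    weight: float
    smoke: float
    race: float
    pcs: tuple
    intercept: float

    @property
    def n_components(self) -> int:
        return len(self.pcs)

    def slopes(self) -> np.ndarray:
        return np.array([self.sex, self.age, self.weight, self.smoke,
                         self.race, *self.pcs], dtype=float)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in BASE_COVARIATES}
        d.update({f"pc{j + 1}": v for j, v in enumerate(self.pcs)})
        d["intercept"] = self.intercept
        return d

    @classmethod
    def from_arrays(cls, slopes, intercept: float) -> "CoefficientVector":
        slopes = np.asarray(slopes, dtype=float)
        if slopes.shape[0] < len(BASE_COVARIATES):
            raise ModelingError("coefficient vector shorter than the base covariates")
        return cls(sex=float(slopes[0]), age=float(slopes[1]),
                   weight=float(slopes[2]), smoke=float(slopes[3]),
                   race=float(slopes[4]),
                   pcs=tuple(float(v) for v in slopes[5:]),
                   intercept=float(intercept))


@dataclass
class CutoffSearchResult:
    """F1-vs-cutoff search outcome for one CV technique."""

    spec: CVTechniqueSpec
    oof_probs: np.ndarray     # NaN where a patient was never out-of-fold
    coverage: np.ndarray      # number of out-of-fold predictions per patient
    best_cutoff: float
    best_f1: float
    f1_curve: list            # (cutoff, F1) pairs over the candidate set


@dataclass
class CVSelectionResult:
    per_technique: list
    chosen: CutoffSearchResult
    selection_rule: str
    failures: list            # (spec, reason) for specs that could not run


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _fit_raw(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ModelingError("outcome has a single class; logistic fit is degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, solver="lbfgs",
                                       tol=1e-8, max_iter=2000).fit(X, y)
            separated = np.abs(model.coef_).max() > _SEPARATION_COEF
        except ConvergenceWarning:
            separated = True
            model = None
    if separated:
        logger.warning("possible (quasi-)separation; refitting with a small "
                       "ridge penalty (1/C=%.0e) to keep coefficients finite",
                       1.0 / _RIDGE_C)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LogisticRegression(C=_RIDGE_C, solver="lbfgs",
                                       tol=1e-8, max_iter=2000).fit(X, y)
    return model


def fit_logistic(X, y) -> CoefficientVector:
    """Unpenalized maximum-likelihood logistic regression with intercept.

    Perfect or quasi-perfect separation falls back to a vanishingly small
    ridge penalty with a logged warning, so coefficients stay finite.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y)
    if Xm.shape[0] != y.shape[0]:
        raise DataError("design matrix and outcome lengths differ")
    if not np.all(np.isfinite(Xm)):
        raise DataError("design matrix contains non-finite entries")
    model = _fit_raw(Xm, y)
    return CoefficientVector.from_arrays(model.coef_[0], model.intercept_[0])


def predict_proba(coefs: CoefficientVector, X) -> np.ndarray:
    """Inverse-logit of the linear predictor under ``coefs``."""
    Xm = _as_matrix(X)
    lp = Xm @ coefs.slopes() + coefs.intercept
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-lp))


def out_of_fold_probabilities(X, y, splits):
    """Mean out-of-fold probability and coverage count per patient.

    Each split's model is fit on its training indices only; patients
    landing in several test sets (repeated CV, LpOCV) are aggregated by
    arithmetic mean.  Splits whose training fold is single-class are
    skipped with a warning; if every split is skipped this is an error.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y)
    n = y.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    skipped = 0
    for train_idx, test_idx in splits:
        if np.unique(y[train_idx]).shape[0] < 2:
            skipped += 1
            continue
        model = _fit_raw(Xm[train_idx], y[train_idx])
        probs = model.predict_proba(Xm[test_idx])[:, 1]
        sums[test_idx] += probs
        counts[test_idx] += 1
    if skipped:
        logger.warning("skipped %d/%d splits with single-class training folds",
                       skipped, len(splits))
    if counts.sum() == 0:
        raise ModelingError("every CV split had a single-class training fold")
    with np.errstate(invalid="ignore"):
        probs = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return probs, counts


def f1_at_cutoff(probs, y, cutoff: float) -> float:
    """F1 of "responder iff probability > cutoff" (strict inequality).

    With no predicted positives F1 is defined as 0.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise DataError(f"cutoff must lie in [0, 1], got {cutoff}")
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    pred = probs > cutoff
    tp = int(np.sum(pred & (y == 1)))
    pp = int(np.sum(pred))
    pos = int(np.sum(y == 1))
    if pp + pos == 0:
        return 0.0
    return 2.0 * tp / (pp + pos)


def best_cutoff(probs, y):
    """F1-maximizing cutoff over the candidate set {0} ∪ unique(probs).

    Because predictions only change when the cutoff crosses an observed
    probability, this candidate set realizes every achievable confusion
    matrix; ties are broken toward the smallest maximizing cutoff
    (favoring sensitivity).  Returns (cutoff, F1, curve).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    mask = np.isfinite(probs)
    probs, y = probs[mask], y[mask]
    if probs.shape[0] == 0:
        raise DataError("no out-of-fold probabilities available")
    if np.unique(y).shape[0] < 2:
        raise ModelingError("cutoff search requires both classes in the outcome")
    cands = np.unique(np.concatenate(([0.0], probs)))
    pos = float(np.sum(y == 1))
    # F1 = 2*TP/(PP + P) evaluated at every candidate via one matrix compare
    gt = probs[None, :] > cands[:, None]
    tp = gt @ (y == 1).astype(float)
    pp = gt.sum(axis=1)
    denom = pp + pos
    f1 = np.where(denom > 0, 2.0 * tp / np.where(denom > 0, denom, 1.0), 0.0)
    best_idx = int(np.argmax(f1))  # candidates ascending -> first max = smallest
    return float(cands[best_idx]), float(f1[best_idx]), list(zip(cands.tolist(),
                                                                 f1.tolist()))


def search_cutoff(X, y, spec: CVTechniqueSpec, seed: int,
                  lpocv_cap: int | None = None) -> CutoffSearchResult:
    """Run one technique end-to-end: splits -> OOF probabilities -> cutoff."""
    kwargs = {} if lpocv_cap is None else {"lpocv_cap": lpocv_cap}
    splits = generate_splits(spec, y, seed, **kwargs)
    probs, counts = out_of_fold_probabilities(X, y, splits)
    cut, f1, curve = best_cutoff(probs, np.asarray(y))
    return CutoffSearchResult(spec=spec, oof_probs=probs, coverage=counts,
                              best_cutoff=cut, best_f1=f1, f1_curve=curve)


def spec_seed(master_seed: int, index: int) -> int:
    """Deterministic per-technique seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0] % (2 ** 31))


def select_optimal_technique(X, y, grid, seed: int, rule: str = "max_cutoff",
                             lpocv_cap: int | None = None) -> CVSelectionResult:
    """Search the technique grid and select the optimal technique.

    Under ``max_cutoff`` (the default) the spec with the largest best
    cutoff wins, ties broken by larger F1 then enumeration order; under
    ``max_f1`` the two criteria swap.
    """
    if rule not in ("max_cutoff", "max_f1"):
        raise ConfigError(f"unknown selection rule {rule!r}")
    if not grid:
        raise ConfigError("CV technique grid is empty")
    results, failures = [], []
    for i, spec in enumerate(grid):
        try:
            res = search_cutoff(X, y, spec, spec_seed(seed, i), lpocv_cap=lpocv_cap)
        except (DataError, ModelingError) as exc:
            failures.append((spec, str(exc)))
            logger.warning("technique %s failed: %s", spec.label, exc)
            continue
        logger.info("technique %-38s best_cutoff=%.4f F1=%.4f",
                    spec.label, res.best_cutoff, res.best_f1)
        results.append(res)
    if not results:
        raise ModelingError(
            "no CV technique could run: " +
            "; ".join(f"{s.label}: {m}" for s, m in failures))
    if rule == "max_cutoff":
        key = lambda r: (r.best_cutoff, r.best_f1)  # noqa: E731
    else:
        key = lambda r: (r.best_f1, r.best_cutoff)  # noqa: E731
    chosen = results[0]
    for r in results[1:]:
        if key(r) > key(chosen):  # strict: ties keep the earlier spec
            chosen = r
    logger.info("selected technique %s (rule=%s)", chosen.spec.label, rule)
    return CVSelectionResult(per_technique=results, chosen=chosen,
                             selection_rule=rule, failures=failures)
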