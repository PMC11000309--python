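"""Segmentation quality: classification metrics and survival separation.

Classification metrics compare a segmentation against the known binary
response.  Survival separation between the predicted responder and
non-responder groups is quantified with the Kaplan-Meier product-limit
estimator and log-rank test, a covariate-adjusted Cox proportional
hazards model (Efron tie handling; effects reported as hazard ratios),
and a parametric accelerated-failure-time model (Weibull by default,
lognormal selectable; effects reported as time ratios — note that AFT
effects are time ratios even where clinical tables sometimes label them
"HR").  AIC compares fits of the same kind between segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import (CoxPHFitter, KaplanMeierFitter, LogNormalAFTFitter,
                       WeibullAFTFitter)
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .errors import DataError, ModelingError


@dataclass
class ClassificationMetrics:
    """Accuracy, MSE (= misclassification rate for 0/1 predictions),
    specificity, precision, recall.

    ``undefined`` lists metrics whose denominator was zero; those are
    reported as 0.0 with the flag rather than as missing cells.
    """

    accuracy: float
    mse: float
    specificity: float
    precision: float
    recall: float
    undefined: tuple = ()

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "mse": self.mse,
                "specificity": self.specificity, "precision": self.precision,
                "recall": self.recall, "undefined": list(self.undefined)}


@dataclass
class GroupCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float            # NaN when S(t) never reaches 0.5
    median_ci: tuple


@dataclass
class KMCurve:
    groups: dict
    logrank_stat: float | None
    logrank_p: float | None


@dataclass
class SurvivalFitSummary:
    """Per-covariate effects of one survival regression.

    ``table`` rows: estimate (hazard ratio for Cox, time ratio for AFT),
    ci_low, ci_high (95%), p_value.  ``group_effect`` is the Group row.
    """

    model_kind: str          # {"cox", "aft"}
    table: pd.DataFrame
    group_effect: dict
    aic: float
    n: int
    n_events: int


def classification_metrics(pred, y) -> ClassificationMetrics:
    """Confusion-matrix metrics of a binary segmentation vs. true response."""
    pred = np.asarray(pred, dtype=int)
    y = np.asarray(y, dtype=int)
    if pred.shape[0] != y.shape[0]:
        raise DataError("prediction and truth lengths differ")
    if pred.shape[0] == 0:
        raise DataError("empty prediction vector")
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / pred.shape[0]
    return ClassificationMetrics(
        accuracy=acc,
        mse=float(np.mean((pred - y) ** 2)),
        specificity=ratio(tn, tn + fp, "specificity"),
        precision=ratio(tp, tp + fp, "precision"),
        recall=ratio(tp, tp + fn, "recall"),
        undefined=tuple(undefined))


def km_estimate(times, events, groups) -> KMCurve:
    """Product-limit survival per group, medians with 95% CIs (log-log),
    and the two-group log-rank test when exactly two groups are present."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if times.shape[0] == 0:
        raise DataError("no subjects")
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise DataError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        ci = median_survival_times(kmf.confidence_interval_)
        med = kmf.median_survival_time_
        curves[g] = GroupCurve(
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=kmf.event_table["at_risk"].to_numpy(dtype=float),
            median=float(med) if np.isfinite(med) else float("nan"),
            median_ci=tuple(float(v) for v in ci.iloc[0].to_numpy()))
    stat = p = None
    if len(curves) == 2:
        stat, p = logrank_test(times, events, groups)
    return KMCurve(groups=curves, logrank_stat=stat, logrank_p=p)


def logrank_test(times, events, groups):
    """Two-group log-rank chi-square (1 df) and its two-sided p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise DataError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    if events.sum() == 0:
        raise DataError("no events observed; log-rank test undefined")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def _prepare_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    X = covariates.copy()
    for c in X.columns:
        X[c] = pd.to_numeric(X[c])
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ModelingError(f"constant covariate(s): {const}")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ModelingError("covariate matrix is rank-deficient (collinear columns)")
    return X


def cox_fit(times, events, covariates: pd.DataFrame,
            group_col: str = "group") -> SurvivalFitSummary:
    """Cox proportional hazards regression adjusted for the covariates.

    Reports hazard ratios with 95% Wald CIs and p-values, and the
    partial-likelihood AIC (-2 logPL + 2 * n covariates).
    """
    X = _prepare_covariates(covariates)
    if group_col not in X.columns:
        raise ModelingError(f"covariates must include the {group_col!r} column")
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise DataError("need at least 2 observed events for a Cox fit")
    df = X.copy()
    df["_T"] = np.asarray(times, dtype=float)
    df["_E"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_T", event_col="_E")
    s = cph.summary
    table = pd.DataFrame({
        "estimate": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p_value": s["p"],
    })
    group_row = table.loc[group_col].to_dict()
    return SurvivalFitSummary(model_kind="cox", table=table,
                              group_effect=group_row,
                              aic=float(cph.AIC_partial_),
                              n=int(df.shape[0]), n_events=int(events.sum()))


def aft_fit(times, events, covariates: pd.DataFrame,
            distribution: str = "weibull",
            group_col: str = "group") -> SurvivalFitSummary:
    """Parametric AFT regression by maximum likelihood with right censoring.

    Effects are time ratios exp(coef); AIC = -2 logL + 2 * n parameters.
    """
    if distribution not in ("weibull", "lognormal"):
        raise ModelingError(f"distribution must be 'weibull' or 'lognormal', got {distribution!r}")
    X = _prepare_covariates(covariates)
    if group_col not in X.columns:
        raise ModelingError(f"covariates must include the {group_col!r} column")
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise DataError("need at least 2 observed events for an AFT fit")
    df = X.copy()
    df["_T"] = np.asarray(times, dtype=float)
    df["_E"] = events
    if distribution == "weibull":
        fitter, primary = WeibullAFTFitter(), "lambda_"
    else:
        fitter, primary = LogNormalAFTFitter(), "mu_"
    try:
        fitter.fit(df, duration_col="_T", event_col="_E")
    except Exception as exc:  # lifelines raises ConvergenceError/ValueError
        raise ModelingError(f"AFT fit did not converge: {exc}") from exc
    s = fitter.summary.loc[primary]
    s = s.drop(index="Intercept", errors="ignore")
    table = pd.DataFrame({
        "estimate": s["exp(coef)"],
        "ci_low": np.exp(s["coef lower 95%"]),
        "ci_high": np.exp(s["coef upper 95%"]),
        "p_value": s["p"],
    })
    group_row = table.loc[group_col].to_dict()
    return SurvivalFitSummary(model_kind="aft", table=table,
                              group_effect=group_row, aic=float(fitter.AIC_),
                              n=int(df.shape[0]), n_events=int(events.sum()))


def compare_models(fit_a: SurvivalFitSummary,
                   fit_b: SurvivalFitSummary,
                   label_a: str = "novel", label_b: str = "standard") -> dict:
    """AIC comparison of two same-kind fits; lower AIC wins."""
    if fit_a.model_kind != fit_b.model_kind:
        raise ModelingError(
            f"cannot compare {fit_a.model_kind} with {fit_b.model_kind}")
    delta = fit_a.aic - fit_b.aic
    if delta < 0:
        winner = label_a
    elif delta > 0:
        winner = label_b
    else:
        winner = "tie"
    return {
        "model_kind": fit_a.model_kind,
        f"aic_{label_a}": fit_a.aic,
        f"aic_{label_b}": fit_b.aic,
        "delta_aic": delta,
        "winner": winner,
        "group_effects": {label_a: fit_a.group_effect,
                          label_b: fit_b.group_effect},
    }
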