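"""End-to-end orchestration of the novel and standard segmentation methods.

Novel method: per training trial, fit the trajectory PCA, search the CV
technique grid for the F1-optimal cutoff, select the optimal technique,
refit the logistic model on the full trial, then pool the two trials'
coefficients and cutoffs.  Test patients are projected with a PCA fit on
the pooled training trajectories, scored with the pooled model, and
segmented at the pooled cutoff.  The standard method shares the feature
pipeline and pooled full-data logistic fits but thresholds at 0.5 and
never touches the CV engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cv import GridConfig, enumerate_cv_grid
from .cutoff import CVSelectionResult, fit_logistic, spec_seed
from .cutoff import select_optimal_technique
from .errors import ConfigError, DataError
from .features import (DesignMatrix, PCAModel, TrajectoryMatrix,
                       build_design_matrix, fit_pca, trajectory_matrix)
from .scoring import (NON_RESPONDER, RESPONDER, PooledScoringModel,
                      pool_models, score_patients, segment_patients,
                      standard_train)
from .survival import (aft_fit, classification_metrics, compare_models,
                       cox_fit, km_estimate)
from .trial_data import TrialDataset, bor_to_binary, complete_cases

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20240408


@dataclass
class RunConfig:
    """Options of one end-to-end run."""

    n_components: int = 2
    rule: str = "max_cutoff"           # {"max_cutoff", "max_f1"}
    seed: int = DEFAULT_SEED
    grid: GridConfig = field(default_factory=GridConfig)
    method: str = "both"               # {"novel", "standard", "both"}
    aft_distribution: str = "weibull"
    pca_basis: str = "pooled"          # {"pooled", "per-trial"} for the test trial

    def __post_init__(self):
        if self.method not in ("novel", "standard", "both"):
            raise ConfigError(f"method must be novel/standard/both, got {self.method!r}")
        if self.pca_basis not in ("pooled", "per-trial"):
            raise ConfigError(f"pca_basis must be 'pooled' or 'per-trial', got {self.pca_basis!r}")
        if not 1 <= self.n_components <= 4:
            raise ConfigError("n_components must be in 1..4")


@dataclass
class PreparedTrial:
    dataset: TrialDataset
    pca: PCAModel
    X: DesignMatrix
    y: np.ndarray | None


def prepare_trial(ds: TrialDataset, n_components: int,
                  require_bor: bool, pca: PCAModel | None = None) -> PreparedTrial:
    """Complete-case filter, PCA (fit here unless given), design matrix, labels."""
    ds_c = complete_cases(ds, require_bor=require_bor)
    if len(ds_c) == 0:
        raise DataError(f"trial {ds.trial_id}: no complete-case patients")
    traj = trajectory_matrix(ds_c)
    model = pca if pca is not None else fit_pca(traj, n_components)
    X = build_design_matrix(ds_c, model)
    y = None
    if require_bor:
        y = np.array([bor_to_binary(p.bor) for p in ds_c.patients])
    return PreparedTrial(dataset=ds_c, pca=model, X=X, y=y)


def _spec_dict(sel: CVSelectionResult) -> dict:
    c = sel.chosen
    return {"technique": c.spec.label, "family": c.spec.family,
            "k": c.spec.k, "repeats": c.spec.repeats,
            "best_cutoff": c.best_cutoff, "best_f1": c.best_f1,
            "rule": sel.selection_rule}


def train_novel(train_a: TrialDataset, train_b: TrialDataset,
                cfg: RunConfig | None = None):
    """Fit the novel pooled scoring model on two training trials.

    Returns ``(PooledScoringModel, details)`` where details holds the
    per-trial technique selections and full F1 curves.
    """
    cfg = cfg or RunConfig()
    grid = enumerate_cv_grid(cfg.grid)
    trials, selections, coeffs, cutoffs = [], [], [], []
    for i, ds in enumerate((train_a, train_b)):
        prep = prepare_trial(ds, cfg.n_components, require_bor=True)
        sel = select_optimal_technique(prep.X, prep.y, grid,
                                       seed=spec_seed(cfg.seed, 1000 + i),
                                       rule=cfg.rule,
                                       lpocv_cap=cfg.grid.lpocv_cap)
        coeffs.append(fit_logistic(prep.X, prep.y))
        cutoffs.append(sel.chosen.best_cutoff)
        trials.append(prep)
        selections.append(sel)
        logger.info("trial %s: optimal technique %s, best cutoff %.3f",
                    ds.trial_id, sel.chosen.spec.label, sel.chosen.best_cutoff)
    provenance = {
        "training_trials": [train_a.trial_id, train_b.trial_id],
        "chosen": {ds.trial_id: _spec_dict(sel)
                   for ds, sel in zip((train_a, train_b), selections)},
        "seed": cfg.seed, "n_components": cfg.n_components,
        "package_version": __version__,
    }
    model = pool_models(coeffs[0], cutoffs[0], coeffs[1], cutoffs[1],
                        method="novel", provenance=provenance)
    details = {"selections": selections, "prepared": trials,
               "per_trial_coeffs": coeffs, "per_trial_cutoffs": cutoffs}
    return model, details


def train_standard(train_a: TrialDataset, train_b: TrialDataset,
                   cfg: RunConfig | None = None) -> PooledScoringModel:
    """Fit the 0.5-threshold comparator (no CV engine involved)."""
    cfg = cfg or RunConfig()
    pa = prepare_trial(train_a, cfg.n_components, require_bor=True)
    pb = prepare_trial(train_b, cfg.n_components, require_bor=True)
    return standard_train(pa.X, pa.y, pb.X, pb.y, provenance={
        "training_trials": [train_a.trial_id, train_b.trial_id],
        "seed": cfg.seed, "n_components": cfg.n_components,
        "package_version": __version__,
    })


def test_features(train_a: TrialDataset, train_b: TrialDataset,
                  test: TrialDataset, cfg: RunConfig) -> PreparedTrial:
    """Design matrix for the test trial.

    By default the PCA basis is fit on the pooled training trajectories
    (the least-leaky deterministic mapping of test patients); the
    ``per-trial`` option uses the first training trial's basis instead.
    """
    a = complete_cases(train_a)
    b = complete_cases(train_b)
    if cfg.pca_basis == "pooled":
        ta, tb = trajectory_matrix(a), trajectory_matrix(b)
        pooled = TrajectoryMatrix(np.vstack([ta.values, tb.values]),
                                  ta.subject_ids + tb.subject_ids)
        pca = fit_pca(pooled, cfg.n_components)
    else:
        pca = fit_pca(trajectory_matrix(a), cfg.n_components)
    return prepare_trial(test, cfg.n_components, require_bor=False, pca=pca)


def _evaluate_method(model: PooledScoringModel, prep_test: PreparedTrial,
                     cfg: RunConfig) -> dict:
    seg = segment_patients(score_patients(model, prep_test.X), model.bcut)
    group = (seg["group"] == RESPONDER).astype(int).to_numpy()
    ds = prep_test.dataset
    times = np.array([p.os_time for p in ds.patients])
    events = np.array([p.os_event for p in ds.patients])
    out: dict = {
        "bcut": model.bcut,
        "n_test": int(len(ds)),
        "n_predicted_responders": int(group.sum()),
        "segmentation": seg,
    }
    have_bor = [i for i, p in enumerate(ds.patients) if p.bor is not None]
    if have_bor:
        y = np.array([bor_to_binary(ds.patients[i].bor) for i in have_bor])
        out["metrics"] = classification_metrics(group[have_bor], y).as_dict()
    else:
        out["metrics"] = None
    if 0 < group.sum() < group.shape[0]:
        labels = np.where(group == 1, RESPONDER, NON_RESPONDER)
        km = km_estimate(times, events, labels)
        out["logrank"] = {"statistic": km.logrank_stat, "p_value": km.logrank_p}
        out["km_medians"] = {g: {"median": c.median, "ci": list(c.median_ci)}
                             for g, c in km.groups.items()}
        out["km"] = km
        covs = pd.DataFrame(prep_test.X.values, columns=list(prep_test.X.columns))
        covs["group"] = group
        try:
            cox = cox_fit(times, events, covs)
            out["cox"] = cox
            out["cox_summary"] = {"group": cox.group_effect, "aic": cox.aic}
        except Exception as exc:
            out["cox"] = None
            out["cox_summary"] = {"error": str(exc)}
        try:
            aft = aft_fit(times, events, covs, distribution=cfg.aft_distribution)
            out["aft"] = aft
            out["aft_summary"] = {"group": aft.group_effect, "aic": aft.aic}
        except Exception as exc:
            out["aft"] = None
            out["aft_summary"] = {"error": str(exc)}
    else:
        note = "segmentation assigned every test patient to one group"
        out["logrank"] = {"error": note}
        out["km_medians"] = {}
        out["km"] = out["cox"] = out["aft"] = None
        out["cox_summary"] = {"error": note}
        out["aft_summary"] = {"error": note}
    return out


def _report_branch(res: dict, model: PooledScoringModel) -> dict:
    """JSON-ready view of one method's evaluation."""
    return {
        "bcut": res["bcut"],
        "coefficients": model.mean_coeffs.as_dict(),
        "provenance": model.provenance,
        "n_test": res["n_test"],
        "n_predicted_responders": res["n_predicted_responders"],
        "metrics": res["metrics"],
        "logrank": res["logrank"],
        "km_medians": res["km_medians"],
        "cox": res["cox_summary"],
        "aft": res["aft_summary"],
    }


def run_and_compare(train_a: TrialDataset, train_b: TrialDataset,
                    test: TrialDataset, cfg: RunConfig | None = None) -> dict:
    """Train the requested method(s), segment the test trial, evaluate.

    The returned report dict is JSON-serializable except for the
    ``"artifacts"`` entry, which carries the in-memory segmentations and
    fit objects for callers that want them.
    """
    cfg = cfg or RunConfig()
    prep_test = test_features(train_a, train_b, test, cfg)
    report: dict = {"config": {"seed": cfg.seed, "rule": cfg.rule,
                               "n_components": cfg.n_components,
                               "method": cfg.method,
                               "aft_distribution": cfg.aft_distribution,
                               "package_version": __version__},
                    "test_trial": test.trial_id}
    artifacts: dict = {"test_design": prep_test}

    novel_res = standard_res = None
    if cfg.method in ("novel", "both"):
        novel_model, details = train_novel(train_a, train_b, cfg)
        novel_res = _evaluate_method(novel_model, prep_test, cfg)
        report["novel"] = _report_branch(novel_res, novel_model)
        artifacts.update(novel_model=novel_model, novel_details=details,
                         novel=novel_res)
    if cfg.method in ("standard", "both"):
        standard_model = train_standard(train_a, train_b, cfg)
        standard_res = _evaluate_method(standard_model, prep_test, cfg)
        report["standard"] = _report_branch(standard_res, standard_model)
        artifacts.update(standard_model=standard_model, standard=standard_res)

    if novel_res is not None and standard_res is not None:
        comparison = {}
        for kind in ("cox", "aft"):
            fa, fb = novel_res[kind], standard_res[kind]
            if fa is not None and fb is not None:
                comparison[kind] = compare_models(fa, fb)
            else:
                comparison[kind] = {"error": "fit unavailable for at least one method"}
        report["comparison"] = comparison
    report["artifacts"] = artifacts
    return report


def report_to_json(report: dict) -> dict:
    """Strip non-serializable artifacts and coerce numpy scalars."""
    def convert(obj):
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    return convert({k: v for k, v in report.items() if k != "artifacts"})
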