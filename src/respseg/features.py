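"""Tumor-trajectory features and the model design matrix.

The predictive models use each patient's percent change in the sum of
longest tumor diameters at the first four visits, reduced by principal
component analysis, alongside the encoded baseline covariates.  Percent
change at visit i is 100*(size_i - baseline)/baseline, so shrinking
tumors give negative values.

Covariate encodings (fixed, documented):
    sex: female=0 / male=1
    age: ordinal bin 0 (18-<65) / 1 (65-75) / 2 (>75)
    weight: <=75 kg = 0 / >75 kg = 1
    smoking: ordinal never=0 / former=1 / current=2
    race: caucasian=0 / non-caucasian=1
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ModelingError
from .trial_data import (N_VISITS, PatientRecord, SEX_LEVELS, SMOKING_LEVELS,
                         RACE_LEVELS, TrialDataset)

BASE_COVARIATES = ("sex", "age", "weight", "smoke", "race")

_RANK_TOL = 1e-10


@dataclass
class TrajectoryMatrix:
    """Patients x 4 matrix of percent change from baseline (%)."""

    values: np.ndarray
    subject_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_VISITS:
            raise DataError(f"trajectory matrix must have {N_VISITS} columns")
        if not np.all(np.isfinite(self.values)):
            raise DataError("trajectory matrix contains non-finite entries")


@dataclass
class PCAModel:
    """Centering vector plus orthonormal loadings of the trajectory PCA."""

    center: np.ndarray
    loadings: np.ndarray          # 4 x n_components
    explained_variance: np.ndarray
    n_components: int


@dataclass
class DesignMatrix:
    """Covariate matrix in the fixed documented column order.

    The intercept is implicit (added by the fitter).
    """

    values: np.ndarray
    columns: tuple
    subject_ids: list


def percent_change_trajectory(record: PatientRecord) -> np.ndarray:
    """Percent change from baseline at each of the four visits."""
    b = record.baseline_tumor_size
    if not b > 0:
        raise DataError(f"{record.subject_id}: baseline tumor size must be > 0")
    if not record.has_complete_trajectory:
        raise DataError(f"{record.subject_id}: incomplete visit trajectory")
    sizes = np.asarray(record.visit_sizes, dtype=float)
    return 100.0 * (sizes - b) / b


def trajectory_matrix(ds: TrialDataset) -> TrajectoryMatrix:
    """Stack per-patient percent-change vectors (complete cases only)."""
    rows, ids = [], []
    for p in ds.patients:
        rows.append(percent_change_trajectory(p))
        ids.append(p.subject_id)
    if not rows:
        return TrajectoryMatrix(np.empty((0, N_VISITS)), [])
    return TrajectoryMatrix(np.vstack(rows), ids)


def fit_pca(traj: TrajectoryMatrix, n_components: int = 2) -> PCAModel:
    """PCA of the percent-change trajectories.

    Loadings are the top eigenvectors of the sample covariance, ordered
    by decreasing variance, with the deterministic sign convention that
    each component's largest-magnitude element is positive (first index
    on ties), so results are reproducible across linear-algebra backends.
    """
    X = traj.values
    n = X.shape[0]
    if not 1 <= n_components <= N_VISITS:
        raise ModelingError(f"n_components must be in [1, {N_VISITS}]")
    if n < n_components + 1:
        raise ModelingError(
            f"need at least {n_components + 1} patients to fit {n_components} components")
    center = X.mean(axis=0)
    Xc = X - center
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    rank = int(np.sum(evals > _RANK_TOL * max(evals.max(), 1.0)))
    if rank < n_components:
        raise ModelingError(
            f"trajectory covariance has rank {rank} < n_components={n_components} "
            "(constant or collinear visit columns)")
    loadings = evecs[:, :n_components].copy()
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(center=center, loadings=loadings,
                    explained_variance=evals[:n_components],
                    n_components=n_components)


def project_pca(model: PCAModel, traj: TrajectoryMatrix | np.ndarray) -> np.ndarray:
    """Component scores (values - center) @ loadings; never mutates the model."""
    X = traj.values if isinstance(traj, TrajectoryMatrix) else np.asarray(traj, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.center.shape[0]:
        raise DataError(
            f"trajectory has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"PCA expects {model.center.shape[0]}")
    return (X - model.center) @ model.loadings


def encode_covariates(record: PatientRecord) -> np.ndarray:
    return np.array([
        float(SEX_LEVELS.index(record.sex)),
        float(record.age_bin),
        float(record.weight_class),
        float(SMOKING_LEVELS.index(record.smoking)),
        float(RACE_LEVELS.index(record.race)),
    ])


def build_design_matrix(ds: TrialDataset, pca: PCAModel) -> DesignMatrix:
    """Assemble [sex, age, weight, smoke, race, pc_1..pc_k] per patient.

    Column order is fixed and identical for training and test builds.
    All patients must have complete trajectories (filter with
    :func:`respseg.trial_data.complete_cases` first).
    """
    columns = tuple(list(BASE_COVARIATES) + [f"pc{j + 1}" for j in range(pca.n_components)])
    if len(ds) == 0:
        return DesignMatrix(np.empty((0, len(columns))), columns, [])
    traj = trajectory_matrix(ds)
    scores = project_pca(pca, traj)
    base = np.vstack([encode_covariates(p) for p in ds.patients])
    return DesignMatrix(np.hstack([base, scores]), columns, ds.subject_ids())
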