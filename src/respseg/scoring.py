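"""Pooled scoring system and patient segmentation.

Two training trials each contribute a logistic coefficient vector (and,
for the novel method, an F1-optimal cutoff).  The scoring system
averages the two coefficient vectors element-wise; a test patient's
score is that mean linear predictor and their probability its inverse
logit.  Segmentation compares the probability against the pooled cutoff
Bcut = (bcut_1 + bcut_2)/2 — strictly greater means responder.  The
standard comparator uses the same pooled coefficients but a fixed 0.5
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .cutoff import CoefficientVector, fit_logistic, predict_proba
from .errors import DataError, ModelingError
from .features import DesignMatrix

RESPONDER = "responder"
NON_RESPONDER = "non-responder"


@dataclass
class PooledScoringModel:
    """Mean coefficients of two training trials plus the pooled cutoff."""

    method: str                   # {"novel", "standard"}
    mean_coeffs: CoefficientVector
    bcut: float
    provenance: dict

    def __post_init__(self):
        if self.method not in ("novel", "standard"):
            raise ModelingError(f"method must be 'novel' or 'standard', got {self.method!r}")
        if not 0.0 < self.bcut < 1.0:
            raise ModelingError(f"bcut must lie in (0, 1), got {self.bcut}")

    def to_json(self, path=None) -> str:
        doc = {
            "schema": "respseg.pooled_scoring_model/1",
            "package_version": __version__,
            "method": self.method,
            "coefficients": self.mean_coeffs.as_dict(),
            "n_components": self.mean_coeffs.n_components,
            "bcut": self.bcut,
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "PooledScoringModel":
        with open(path) as fh:
            doc = json.load(fh)
        coeffs = doc["coefficients"]
        k = int(doc["n_components"])
        cv = CoefficientVector(
            sex=coeffs["sex"], age=coeffs["age"], weight=coeffs["weight"],
            smoke=coeffs["smoke"], race=coeffs["race"],
            pcs=tuple(coeffs[f"pc{j + 1}"] for j in range(k)),
            intercept=coeffs["intercept"])
        return cls(method=doc["method"], mean_coeffs=cv,
                   bcut=float(doc["bcut"]), provenance=doc.get("provenance", {}))


def pool_models(coeffs1: CoefficientVector, cutoff1: float,
                coeffs2: CoefficientVector, cutoff2: float,
                method: str = "novel",
                provenance: dict | None = None) -> PooledScoringModel:
    """Element-wise mean of two coefficient vectors and their cutoffs.

    For the standard method the pooled cutoff is fixed at 0.5 regardless
    of the per-trial cutoffs.
    """
    if coeffs1.n_components != coeffs2.n_components:
        raise ModelingError(
            f"coefficient layouts differ: {coeffs1.n_components} vs "
            f"{coeffs2.n_components} principal components")
    mean = CoefficientVector.from_arrays(
        (coeffs1.slopes() + coeffs2.slopes()) / 2.0,
        (coeffs1.intercept + coeffs2.intercept) / 2.0)
    bcut = 0.5 if method == "standard" else (float(cutoff1) + float(cutoff2)) / 2.0
    return PooledScoringModel(method=method, mean_coeffs=mean, bcut=bcut,
                              provenance=provenance or {})


def score_patients(model: PooledScoringModel, X: DesignMatrix) -> pd.DataFrame:
    """Score = pooled linear predictor; probability = inverse-logit(score)."""
    expected = 5 + model.mean_coeffs.n_components
    if X.values.shape[1] != expected:
        raise ModelingError(
            f"design matrix has {X.values.shape[1]} columns, model expects {expected}")
    scores = X.values @ model.mean_coeffs.slopes() + model.mean_coeffs.intercept
    probs = predict_proba(model.mean_coeffs, X.values)
    return pd.DataFrame({"subject_id": X.subject_ids,
                         "score": scores, "probability": probs})


def segment_patients(scores: pd.DataFrame, bcut: float) -> pd.DataFrame:
    """Assign responder iff probability > bcut (strict); ties go to
    non-responder."""
    if not 0.0 < bcut < 1.0:
        raise DataError(f"bcut must lie in (0, 1), got {bcut}")
    out = scores.copy()
    out["group"] = np.where(out["probability"].to_numpy() > bcut,
                            RESPONDER, NON_RESPONDER)
    return out


def standard_train(X1: DesignMatrix, y1, X2: DesignMatrix, y2,
                   provenance: dict | None = None) -> PooledScoringModel:
    """The 0.5-threshold comparator: full-data logistic fits, no CV."""
    c1 = fit_logistic(X1, y1)
    c2 = fit_logistic(X2, y2)
    return pool_models(c1, 0.5, c2, 0.5, method="standard",
                       provenance=provenance or {})
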