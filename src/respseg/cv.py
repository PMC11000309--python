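"""The seven cross-validation technique families and their split grids.

Families and default hyperparameter grids:

    LOOCV                    — one fold per patient
    LpOCV (p=2)              — all patient pairs, capped by seeded sampling
    HoldOut                  — single 75/25 train/test split
    KFold                    — k in 3..10
    RepeatedKFold            — k in 3..10, repeats in 2..4
    StratifiedKFold          — k in 3..5
    RepeatedStratifiedKFold  — k in 3..5, repeats in 2..4

giving 1+1+1+8+24+3+9 = 47 technique specifications at the defaults.
Grid enumeration order is deterministic (families in the order above,
then k ascending, then repeats ascending).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.model_selection import (KFold, LeaveOneOut, RepeatedKFold,
                                     RepeatedStratifiedKFold, ShuffleSplit,
                                     StratifiedKFold)

from .errors import ConfigError, DataError

FAMILIES = ("LOOCV", "LpOCV", "HoldOut", "KFold", "RepeatedKFold",
            "StratifiedKFold", "RepeatedStratifiedKFold")

DEFAULT_LPOCV_CAP = 2000


@dataclass(frozen=True)
class CVTechniqueSpec:
    """One concrete CV configuration from the technique grid."""

    family: str
    k: int | None = None
    repeats: int | None = None
    p: int | None = None
    holdout_fraction: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown CV family {self.family!r}")

    @property
    def label(self) -> str:
        if self.family == "LOOCV":
            return "LOOCV"
        if self.family == "LpOCV":
            return f"LpOCV(p={self.p})"
        if self.family == "HoldOut":
            return f"HoldOut({self.holdout_fraction:.0%} test)"
        if self.family == "KFold":
            return f"{self.k}-Fold"
        if self.family == "RepeatedKFold":
            return f"{self.repeats} Repeated-{self.k} Fold"
        if self.family == "StratifiedKFold":
            return f"Stratified {self.k}-Fold"
        return f"{self.repeats} Repeated Stratified {self.k}-Fold"


@dataclass
class GridConfig:
    """Technique grid; defaults reproduce the full 47-spec grid."""

    families: tuple = FAMILIES
    kfold_k: tuple = tuple(range(3, 11))
    repeated_k: tuple = tuple(range(3, 11))
    repeats: tuple = (2, 3, 4)
    stratified_k: tuple = (3, 4, 5)
    stratified_repeats: tuple = (2, 3, 4)
    lpocv_p: int = 2
    lpocv_cap: int = DEFAULT_LPOCV_CAP
    holdout_fraction: float = 0.25

    def __post_init__(self):
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ConfigError(f"unknown CV family(ies) {unknown}")

    @classmethod
    def from_dict(cls, d: dict) -> "GridConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown CV grid option(s): {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("families", "kfold_k", "repeated_k", "repeats",
                    "stratified_k", "stratified_repeats"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"CV grid file {path} must contain a mapping")
        return cls.from_dict(d)


def enumerate_cv_grid(config: GridConfig | None = None) -> list:
    """All technique specs of the configured grid, deterministically ordered."""
    cfg = config or GridConfig()
    if cfg.lpocv_p != 2:
        raise ConfigError("LpOCV is defined with p=2")
    if not 0 < cfg.holdout_fraction < 1:
        raise ConfigError("holdout_fraction must be in (0, 1)")
    for fam in cfg.families:
        if fam not in FAMILIES:
            raise ConfigError(f"unknown CV family {fam!r}")
    specs: list = []
    if "LOOCV" in cfg.families:
        specs.append(CVTechniqueSpec("LOOCV"))
    if "LpOCV" in cfg.families:
        specs.append(CVTechniqueSpec("LpOCV", p=cfg.lpocv_p))
    if "HoldOut" in cfg.families:
        specs.append(CVTechniqueSpec("HoldOut", holdout_fraction=cfg.holdout_fraction))
    if "KFold" in cfg.families:
        specs.extend(CVTechniqueSpec("KFold", k=k) for k in sorted(cfg.kfold_k))
    if "RepeatedKFold" in cfg.families:
        specs.extend(CVTechniqueSpec("RepeatedKFold", k=k, repeats=r)
                     for k, r in itertools.product(sorted(cfg.repeated_k),
                                                   sorted(cfg.repeats)))
    if "StratifiedKFold" in cfg.families:
        specs.extend(CVTechniqueSpec("StratifiedKFold", k=k)
                     for k in sorted(cfg.stratified_k))
    if "RepeatedStratifiedKFold" in cfg.families:
        specs.extend(CVTechniqueSpec("RepeatedStratifiedKFold", k=k, repeats=r)
                     for k, r in itertools.product(sorted(cfg.stratified_k),
                                                   sorted(cfg.stratified_repeats)))
    if not specs:
        raise ConfigError("CV grid is empty")
    return specs


def _lpocv_splits(n: int, seed: int, cap: int) -> list:
    """All C(n,2) leave-pair-out splits, or `cap` seeded random distinct
    pairs when full enumeration is infeasible."""
    total = math.comb(n, 2)
    idx = np.arange(n)
    if total <= cap:
        pairs = itertools.combinations(range(n), 2)
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(total, size=cap, replace=False)
        chosen.sort()
        # decode linear pair index into (i, j), i < j, row-major over i
        pairs = []
        for c in chosen:
            i = int(n - 2 - math.floor(math.sqrt(-8 * c + 4 * n * (n - 1) - 7) / 2 - 0.5))
            j = int(c + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
            pairs.append((i, j))
    splits = []
    for i, j in pairs:
        test = np.array([i, j])
        train = np.setdiff1d(idx, test, assume_unique=True)
        splits.append((train, test))
    return splits


def generate_splits(spec: CVTechniqueSpec, labels, seed: int,
                    lpocv_cap: int = DEFAULT_LPOCV_CAP) -> list:
    """Materialize the (train_idx, test_idx) splits of one technique.

    Stratified families require every class to have at least k members.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if n < 3:
        raise DataError(f"need at least 3 patients for cross-validation, got {n}")
    fam = spec.family
    if fam == "LOOCV":
        return [(tr, te) for tr, te in LeaveOneOut().split(y)]
    if fam == "LpOCV":
        return _lpocv_splits(n, seed, lpocv_cap)
    if fam == "HoldOut":
        ss = ShuffleSplit(n_splits=1, test_size=spec.holdout_fraction, random_state=seed)
        return [(tr, te) for tr, te in ss.split(y)]
    if fam == "KFold":
        if n < spec.k:
            raise DataError(f"{spec.label}: n={n} < k={spec.k}")
        kf = KFold(n_splits=spec.k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in kf.split(y)]
    if fam == "RepeatedKFold":
        if n < spec.k:
            raise DataError(f"{spec.label}: n={n} < k={spec.k}")
        rkf = RepeatedKFold(n_splits=spec.k, n_repeats=spec.repeats, random_state=seed)
        return [(tr, te) for tr, te in rkf.split(y)]
    if fam in ("StratifiedKFold", "RepeatedStratifiedKFold"):
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < spec.k:
            raise DataError(
                f"{spec.label}: smallest class has {counts.min()} members < k={spec.k}")
        if fam == "StratifiedKFold":
            skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=seed)
        else:
            skf = RepeatedStratifiedKFold(n_splits=spec.k, n_repeats=spec.repeats,
                                          random_state=seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(n), y)]
    raise ConfigError(f"unknown CV family {fam!r}")
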