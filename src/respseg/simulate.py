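"""Synthetic small-cell-lung-cancer-like trials with known ground truth.

The generator emulates the schema and statistical structure the
segmentation method assumes, so the whole pipeline can be exercised and
its estimates checked against known truth:

* baseline covariates drawn from categorical prevalences (defaults echo
  the demographic mix of the real registry trials: mostly male, mostly
  caucasian, mostly under 65, many current smokers);
* a latent per-patient tumor shrinkage rate driving correlated percent
  changes at four visits (visit j trend = rate * j plus Gaussian noise);
* best overall response drawn from a logistic model on the encoded
  covariates plus the mean percent change, with the intercept calibrated
  numerically to hit a target responder prevalence;
* overall survival from a Weibull proportional-hazards model whose
  hazard depends on true responder status and the covariates, with
  independent uniform administrative censoring calibrated to a target
  censoring fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigError
from .trial_data import (AGE_LABELS, PatientRecord, RACE_LEVELS, SEX_LEVELS,
                         SMOKING_LEVELS, TrialDataset, WEIGHT_LABELS)


@dataclass
class SimulationConfig:
    """Generating process for one synthetic trial.

    Covariate prevalences default to the approximate demographic mix of
    the registry trials the method targets.  ``bor_*`` are log-odds-scale
    coefficients on the encoded covariates; ``bor_traj`` multiplies the
    mean percent tumor-size change (so negative values make shrinking
    tumors respond).  ``log_hr_*`` act on the survival log-hazard;
    ``log_hr_responder`` defaults to log(0.668) — a clinically material
    survival benefit for responders.
    """

    n_patients: int = 600
    # covariate prevalences
    p_male: float = 0.78
    p_smoking: tuple = (0.07, 0.48, 0.45)       # never / former / current
    p_caucasian: float = 0.95
    p_weight_gt75: float = 0.60
    p_age: tuple = (0.55, 0.36, 0.09)           # 18-<65 / 65-75 / >75
    # baseline tumor size (mm), lognormal
    base_size_log_mean: float = math.log(60.0)
    base_size_log_sd: float = 0.40
    # trajectory model (percent change per visit)
    traj_rate_mean: float = -3.0
    traj_rate_sd: float = 8.0
    traj_noise_sd: float = 4.0
    # BOR logistic model
    bor_sex: float = 0.30
    bor_age: float = -0.20
    bor_weight: float = 0.10
    bor_smoke: float = -0.20
    bor_race: float = 0.30
    bor_traj: float = -0.12
    responder_prevalence: float = 0.35
    # survival model (Weibull PH)
    weibull_shape: float = 1.2
    weibull_scale: float = 400.0                # days
    log_hr_responder: float = math.log(0.668)
    log_hr_sex: float = 0.20
    log_hr_age: float = 0.15
    log_hr_weight: float = 0.00
    log_hr_smoke: float = 0.10
    log_hr_race: float = 0.10
    censoring_fraction: float = 0.25
    # triplet sizes (train, train, test); reduced-scale echo of the real
    # trials' 962/146/670
    triplet_sizes: tuple = (600, 140, 600)
    seed: int = 20240408

    def validate(self) -> None:
        if self.n_patients < 20:
            raise ConfigError("n_patients must be >= 20")
        probs = [self.p_male, self.p_caucasian, self.p_weight_gt75,
                 self.responder_prevalence, *self.p_smoking, *self.p_age]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("prevalences must lie in [0, 1]")
        if not math.isclose(sum(self.p_smoking), 1.0, abs_tol=1e-9):
            raise ConfigError("smoking prevalences must sum to 1")
        if not math.isclose(sum(self.p_age), 1.0, abs_tol=1e-9):
            raise ConfigError("age prevalences must sum to 1")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ConfigError("censoring_fraction must lie in [0, 1)")
        if not 0.0 < self.responder_prevalence < 1.0:
            raise ConfigError("responder_prevalence must lie in (0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ConfigError("Weibull shape and scale must be positive")


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    bor_coefficients: dict
    bor_intercept: float
    responder_probability: np.ndarray
    responder_label: np.ndarray
    log_hr_responder: float
    survival_log_hazard: dict
    config: dict = field(default_factory=dict)


def _calibrate_intercept(lp0: np.ndarray, target: float) -> float:
    """Intercept making mean responder probability equal the target."""
    f = lambda c: float(np.mean(expit(lp0 + c))) - target  # noqa: E731
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _calibrate_censoring(t: np.ndarray, u: np.ndarray, frac: float) -> float:
    """Upper bound tau of Uniform(0, tau) censoring hitting the target
    fraction: censored_i iff u_i * tau < t_i, i.e. tau < t_i/u_i."""
    r = t / np.maximum(u, 1e-12)
    return float(np.quantile(r, 1.0 - frac))


def simulate_trial(cfg: SimulationConfig, trial_id: str,
                   seed: int | None = None,
                   role: str = "training"):
    """Draw one trial; returns ``(TrialDataset, GroundTruth)``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_patients

    sex = rng.binomial(1, cfg.p_male, n)                       # 1 = male
    smoke = rng.choice(3, size=n, p=list(cfg.p_smoking))       # ordinal
    race = rng.binomial(1, 1.0 - cfg.p_caucasian, n)           # 1 = non-caucasian
    weight = rng.binomial(1, cfg.p_weight_gt75, n)             # 1 = >75 kg
    age = rng.choice(3, size=n, p=list(cfg.p_age))             # ordinal bin
    base = np.exp(rng.normal(cfg.base_size_log_mean, cfg.base_size_log_sd, n))

    rate = rng.normal(cfg.traj_rate_mean, cfg.traj_rate_sd, n)
    visits = np.arange(1, 5)
    pct = rate[:, None] * visits[None, :] + rng.normal(
        0.0, cfg.traj_noise_sd, (n, 4))
    pct = np.clip(pct, -95.0, 150.0)
    sizes = base[:, None] * (1.0 + pct / 100.0)

    traj_summary = pct.mean(axis=1)
    lp0 = (cfg.bor_sex * sex + cfg.bor_age * age + cfg.bor_weight * weight
           + cfg.bor_smoke * smoke + cfg.bor_race * race
           + cfg.bor_traj * traj_summary)
    intercept = _calibrate_intercept(lp0, cfg.responder_prevalence)
    p_resp = expit(lp0 + intercept)
    responder = rng.binomial(1, p_resp)

    bor = np.where(responder == 1,
                   np.where(rng.random(n) < 0.15, "CR", "PR"),
                   np.where(rng.random(n) < 0.45, "PD", "SD"))

    surv_lp = (cfg.log_hr_responder * responder + cfg.log_hr_sex * sex
               + cfg.log_hr_age * age + cfg.log_hr_weight * weight
               + cfg.log_hr_smoke * smoke + cfg.log_hr_race * race)
    # Weibull PH: S(t) = exp(-(t/scale)^shape * exp(lp))
    e = rng.exponential(1.0, n)
    t_event = cfg.weibull_scale * (e / np.exp(surv_lp)) ** (1.0 / cfg.weibull_shape)
    if cfg.censoring_fraction > 0:
        u = rng.random(n)
        tau = _calibrate_censoring(t_event, u, cfg.censoring_fraction)
        t_cens = u * tau
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time = t_event
        os_event = np.ones(n, dtype=int)

    patients = []
    for i in range(n):
        patients.append(PatientRecord(
            subject_id=f"{trial_id}-{i:05d}",
            sex=SEX_LEVELS[sex[i]],
            age_bin=int(age[i]),
            weight_class=int(weight[i]),
            smoking=SMOKING_LEVELS[smoke[i]],
            race=RACE_LEVELS[race[i]],
            baseline_tumor_size=float(base[i]),
            visit_sizes=tuple(float(v) for v in sizes[i]),
            bor=str(bor[i]),
            os_time=float(np.round(os_time[i], 3)),
            os_event=int(os_event[i]),
        ))
    ds = TrialDataset(trial_id=trial_id, patients=patients, role=role)
    truth = GroundTruth(
        bor_coefficients={"sex": cfg.bor_sex, "age": cfg.bor_age,
                          "weight": cfg.bor_weight, "smoke": cfg.bor_smoke,
                          "race": cfg.bor_race, "traj": cfg.bor_traj},
        bor_intercept=float(intercept),
        responder_probability=p_resp,
        responder_label=responder,
        log_hr_responder=cfg.log_hr_responder,
        survival_log_hazard={"responder": cfg.log_hr_responder,
                             "sex": cfg.log_hr_sex, "age": cfg.log_hr_age,
                             "weight": cfg.log_hr_weight,
                             "smoke": cfg.log_hr_smoke,
                             "race": cfg.log_hr_race},
        config=asdict(cfg))
    return ds, truth


def make_trial_triplet(cfg: SimulationConfig | None = None,
                       seed: int | None = None):
    """Two training trials and one test trial from one generating process.

    Per-trial seeds are derived independently from the master seed;
    subject IDs are disjoint across trials.  Returns
    ``(train_a, train_b, test, truths)`` with one GroundTruth per trial.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    master = cfg.seed if seed is None else seed
    children = np.random.SeedSequence(int(master)).generate_state(3) % (2 ** 31)
    sizes = cfg.triplet_sizes
    if len(sizes) != 3 or any(s < 20 for s in sizes):
        raise ConfigError("triplet_sizes must be three sizes >= 20")
    out, truths = [], {}
    specs = [("SIM-A", "training", sizes[0]), ("SIM-B", "training", sizes[1]),
             ("SIM-TEST", "test", sizes[2])]
    for (tid, role, size), child in zip(specs, children):
        trial_cfg = SimulationConfig(**{**asdict(cfg), "n_patients": int(size)})
        # tuples survive asdict as lists; normalize back
        trial_cfg.p_smoking = tuple(trial_cfg.p_smoking)
        trial_cfg.p_age = tuple(trial_cfg.p_age)
        trial_cfg.triplet_sizes = tuple(trial_cfg.triplet_sizes)
        ds, truth = simulate_trial(trial_cfg, tid, seed=int(child), role=role)
        out.append(ds)
        truths[tid] = truth
    return out[0], out[1], out[2], truths
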