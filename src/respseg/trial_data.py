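"""Patient-level trial data model and delimited-file I/O.

One row per patient: baseline covariates (sex, age, weight, smoking
status, race), baseline tumor size, sums of longest tumor diameters at
the first four post-baseline visits, best overall response (BOR:
CR/PR/SD/PD), and overall survival (time in days + event indicator).

Canonical CSV columns: subject_id, sex, age, weight, smoking, race,
base_size, size_v1..size_v4, bor, os_days, os_event.  Age and weight may
be given either numerically (they are binned on read) or as the bin
labels used in reports ("18-<65", "65-75", ">75"; "<=75", ">75").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

SEX_LEVELS = ("female", "male")
SMOKING_LEVELS = ("never", "former", "current")
RACE_LEVELS = ("caucasian", "non-caucasian")
AGE_LABELS = ("18-<65", "65-75", ">75")
WEIGHT_LABELS = ("<=75", ">75")
BOR_LEVELS = ("CR", "PR", "SD", "PD")
N_VISITS = 4

CANONICAL_COLUMNS = (
    "subject_id", "sex", "age", "weight", "smoking", "race", "base_size",
    "size_v1", "size_v2", "size_v3", "size_v4", "bor", "os_days", "os_event",
)


@dataclass(frozen=True)
class PatientRecord:
    """A single patient.

    ``age_bin`` and ``weight_class`` are ordinal codes into
    :data:`AGE_LABELS` / :data:`WEIGHT_LABELS`; ``visit_sizes`` holds the
    four per-visit sums of longest diameters (mm), any of which may be
    ``None`` when the visit is missing.
    """

    subject_id: str
    sex: str
    age_bin: int
    weight_class: int
    smoking: str
    race: str
    baseline_tumor_size: float
    visit_sizes: tuple
    bor: str | None
    os_time: float
    os_event: int

    def __post_init__(self):
        if self.sex not in SEX_LEVELS:
            raise SchemaError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.age_bin not in (0, 1, 2):
            raise SchemaError(f"age_bin must be 0/1/2, got {self.age_bin!r}")
        if self.weight_class not in (0, 1):
            raise SchemaError(f"weight_class must be 0/1, got {self.weight_class!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise SchemaError(f"smoking must be one of {SMOKING_LEVELS}, got {self.smoking!r}")
        if self.race not in RACE_LEVELS:
            raise SchemaError(f"race must be one of {RACE_LEVELS}, got {self.race!r}")
        if not self.baseline_tumor_size > 0:
            raise SchemaError(f"baseline_tumor_size must be > 0, got {self.baseline_tumor_size}")
        if len(self.visit_sizes) != N_VISITS:
            raise SchemaError(f"expected {N_VISITS} visit sizes, got {len(self.visit_sizes)}")
        for v in self.visit_sizes:
            if v is not None and not v > 0:
                raise SchemaError(f"visit sizes must be > 0 when present, got {v}")
        if self.bor is not None and self.bor not in BOR_LEVELS:
            raise SchemaError(f"bor must be one of {BOR_LEVELS} or missing, got {self.bor!r}")
        if self.os_time < 0:
            raise SchemaError(f"os_time must be >= 0, got {self.os_time}")
        if self.os_event not in (0, 1):
            raise SchemaError(f"os_event must be 0 or 1, got {self.os_event!r}")

    @property
    def has_complete_trajectory(self) -> bool:
        return all(v is not None for v in self.visit_sizes)


@dataclass
class TrialDataset:
    """All patients of one trial, tagged with its role in the analysis."""

    trial_id: str
    patients: list = field(default_factory=list)
    role: str = "training"  # {"training", "test"}

    def __post_init__(self):
        if self.role not in ("training", "test"):
            raise SchemaError(f"role must be 'training' or 'test', got {self.role!r}")
        ids = [p.subject_id for p in self.patients]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise SchemaError(f"duplicated subject_id in trial {self.trial_id}: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def subject_ids(self) -> list:
        return [p.subject_id for p in self.patients]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {
                "subject_id": p.subject_id,
                "sex": p.sex,
                "age": AGE_LABELS[p.age_bin],
                "weight": WEIGHT_LABELS[p.weight_class],
                "smoking": p.smoking,
                "race": p.race,
                "base_size": p.baseline_tumor_size,
                "bor": "" if p.bor is None else p.bor,
                "os_days": p.os_time,
                "os_event": p.os_event,
            }
            for i, v in enumerate(p.visit_sizes, start=1):
                row[f"size_v{i}"] = "" if v is None else v
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def bor_to_binary(bor: str | None) -> int:
    """Binary response: 1 for responders (CR, PR), 0 for SD/PD.

    A missing BOR raises rather than silently mapping to 0.
    """
    if bor is None or (isinstance(bor, float) and math.isnan(bor)):
        raise DataError("BOR label is missing; cannot derive binary response")
    label = str(bor).strip().upper()
    if label in ("CR", "PR"):
        return 1
    if label in ("SD", "PD"):
        return 0
    raise SchemaError(f"unknown BOR label {bor!r}")


def complete_cases(ds: TrialDataset, require_bor: bool = False) -> TrialDataset:
    """Patients with all four visit sizes (and BOR, when required).

    Excluded counts are logged; the method only ever models patients with
    the full four-visit early trajectory.
    """
    kept, dropped = [], 0
    for p in ds.patients:
        if not p.has_complete_trajectory or (require_bor and p.bor is None):
            dropped += 1
        else:
            kept.append(p)
    if dropped:
        logger.info("trial %s: excluded %d/%d patients with incomplete visits%s",
                    ds.trial_id, dropped, len(ds), " or missing BOR" if require_bor else "")
    return replace(ds, patients=kept)


# ---------------------------------------------------------------------------
# parsing helpers

def _norm(value) -> str:
    return str(value).strip().lower()


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() == ""


def _parse_age(value) -> int:
    s = _norm(value)
    labels = {"18-<65": 0, "18-64": 0, "65-75": 1, ">75": 2}
    if s in labels:
        return labels[s]
    try:
        a = float(s)
    except ValueError:
        raise SchemaError(f"unknown age label {value!r}")
    if a < 18:
        raise SchemaError(f"age below 18: {value!r}")
    if a < 65:
        return 0
    if a <= 75:
        return 1
    return 2


def _parse_weight(value) -> int:
    s = _norm(value)
    if s in ("<=75", "≤75", "le75"):
        return 0
    if s == ">75":
        return 1
    try:
        w = float(s)
    except ValueError:
        raise SchemaError(f"unknown weight label {value!r}")
    if w <= 0:
        raise SchemaError(f"nonpositive weight: {value!r}")
    return 0 if w <= 75 else 1


def _parse_category(value, levels, fieldname) -> str:
    s = _norm(value)
    if s not in levels:
        raise SchemaError(f"unknown {fieldname} label {value!r}")
    return s


def _parse_positive(value, fieldname) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{fieldname} is not numeric: {value!r}")
    if not x > 0:
        raise SchemaError(f"{fieldname} must be > 0, got {value!r}")
    return x


def read_trial_table(path, schema_config: dict | None = None,
                     trial_id: str | None = None,
                     role: str = "training") -> TrialDataset:
    """Read a delimited patient table into a :class:`TrialDataset`.

    ``schema_config`` maps canonical column names to the file's column
    names (absent keys fall back to the canonical name itself), so
    SDTM-style exports can be absorbed without rewriting the file.
    Category labels are normalized case-insensitively.  Any malformed
    mandatory field raises a :class:`SchemaError` carrying row-level
    diagnostics for every offending row.
    """
    mapping = dict(schema_config or {})
    colname = {c: mapping.get(c, c) for c in CANONICAL_COLUMNS}
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty input file: {path}")
    if df.empty and len(df.columns) == 0:
        raise DataError(f"empty input file: {path}")
    missing = [c for c in CANONICAL_COLUMNS if colname[c] not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {[colname[c] for c in missing]} in {path}")

    patients, problems = [], []
    for i, row in df.iterrows():
        label = f"row {i + 1}"
        try:
            sid = row[colname["subject_id"]]
            if _is_missing(sid):
                raise SchemaError("subject_id is missing")
            sid = str(sid).strip()
            visit_sizes = []
            for k in range(1, N_VISITS + 1):
                v = row[colname[f"size_v{k}"]]
                visit_sizes.append(None if _is_missing(v)
                                   else _parse_positive(v, f"size_v{k}"))
            bor_raw = row[colname["bor"]]
            bor = None if _is_missing(bor_raw) else _parse_category(
                bor_raw, [b.lower() for b in BOR_LEVELS], "bor").upper()
            ev_raw = str(row[colname["os_event"]]).strip()
            if ev_raw not in ("0", "1", "0.0", "1.0"):
                raise SchemaError(f"os_event must be 0/1, got {ev_raw!r}")
            os_time = float(row[colname["os_days"]])
            if os_time < 0 or not math.isfinite(os_time):
                raise SchemaError(f"os_days must be >= 0, got {os_time!r}")
            patients.append(PatientRecord(
                subject_id=sid,
                sex=_parse_category(row[colname["sex"]], SEX_LEVELS, "sex"),
                age_bin=_parse_age(row[colname["age"]]),
                weight_class=_parse_weight(row[colname["weight"]]),
                smoking=_parse_category(row[colname["smoking"]], SMOKING_LEVELS, "smoking"),
                race=_parse_category(row[colname["race"]], RACE_LEVELS, "race"),
                baseline_tumor_size=_parse_positive(row[colname["base_size"]], "base_size"),
                visit_sizes=tuple(visit_sizes),
                bor=bor,
                os_time=os_time,
                os_event=int(float(ev_raw)),
            ))
        except (SchemaError, ValueError) as exc:
            problems.append(f"{label}: {exc}")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))

    tid = trial_id if trial_id is not None else str(path)
    return TrialDataset(trial_id=tid, patients=patients, role=role)


def write_trial_table(ds: TrialDataset, path) -> None:
    """Write the canonical CSV form; ``read_trial_table`` round-trips it."""
    ds.to_frame().to_csv(path, index=False)


def write_segmentation(path, assignments: pd.DataFrame) -> None:
    """Persist per-patient scores and group labels.

    ``assignments`` must have columns subject_id, score, probability,
    group (one row per patient).  Floats are written with ``repr``
    precision so a read-back reproduces them exactly.
    """
    required = ["subject_id", "score", "probability", "group"]
    missing = [c for c in required if c not in assignments.columns]
    if missing:
        raise SchemaError(f"segmentation frame missing column(s) {missing}")
    assignments.loc[:, required].to_csv(path, index=False)


def read_segmentation(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty segmentation file: {path}")
    missing = [c for c in ("subject_id", "score", "probability", "group")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"segmentation file missing column(s) {missing}")
    return df
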