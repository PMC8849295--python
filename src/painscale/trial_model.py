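"""Domain types, validation and file I/O for trial tables and scale models.

A *trial* is one mechanical stimulus application to one hind paw.  Trials
live in a flat CSV (one row per trial, fixed column order, see
:data:`TRIAL_COLUMNS`); in memory they are a validated pandas DataFrame.
Dataclasses are provided for single-trial work and for the fitted scale
model, which serializes to a single JSON document.

Conventions
-----------
* Missing optional kinematics are empty CSV cells (NaN in memory), never
  0 — zero is a meaningful value (a retained no-withdrawal trial).
* Trials with ``withdrawal == 0`` are retained and scored; their behavior
  and kinematic features are legitimately all-zero.
* Paw side (left/right) is not modeled: responses do not differ between
  paws, so side is not a column.
* Reals round-trip bit-identically through both CSV and JSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ModelIntegrityError,
    ModelVersionError,
    SchemaError,
    TrialValidationError,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "1.0"

STIMULI = ("CS", "DB", "VFH", "LP", "HP")
#: nominal class of each stimulus: cotton swab and dynamic brush are
#: innocuous, light/heavy pinprick noxious, von Frey hairs ambiguous.
NOMINAL_CLASS = {
    "CS": "innocuous",
    "DB": "innocuous",
    "VFH": "ambiguous",
    "LP": "noxious",
    "HP": "noxious",
}
#: calibrated von Frey filament forces (grams) in use for rats.
VFH_FORCES = (0.008, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 26.0, 60.0, 100.0, 180.0, 300.0)

STRAINS = ("SpragueDawley", "LongEvans")
SEXES = ("F", "M")
SIRES = ("naive", "saline_sired", "morphine_sired")
TIMEPOINTS = ("baseline", "post15min", "post60min")

BEHAVIOR_COLUMNS = ("orbital_tightening", "paw_shake", "jump", "paw_guard")

#: exact, ordered trial CSV columns.
TRIAL_COLUMNS = (
    "trial_id",
    "subject_id",
    "strain",
    "sex",
    "sire",
    "stimulus",
    "force_grams",
    "timepoint",
    "withdrawal",
    "orbital_tightening",
    "paw_shake",
    "jump",
    "paw_guard",
    "paw_height_mm",
    "paw_speed_mm_per_s",
    "lift_onset_s",
    "apex_time_s",
    "lift_before_orient",
)

_STRING_COLUMNS = ("trial_id", "subject_id", "strain", "sex", "sire", "stimulus", "timepoint")
_OPTIONAL_FLOAT_COLUMNS = ("force_grams", "lift_onset_s", "apex_time_s", "lift_before_orient")


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """A stimulus label plus, for von Frey hairs only, the filament force."""

    name: str
    force_grams: float | None = None

    def __post_init__(self):
        if self.name not in STIMULI:
            raise TrialValidationError(f"unknown stimulus {self.name!r}; expected one of {STIMULI}")
        if self.name == "VFH":
            if self.force_grams is None:
                raise TrialValidationError("VFH stimulus requires force_grams")
            if not _is_known_force(self.force_grams):
                raise TrialValidationError(
                    f"force_grams {self.force_grams!r} is not a calibrated VFH force {VFH_FORCES}"
                )
        elif self.force_grams is not None:
            raise TrialValidationError(f"force_grams only valid for VFH, not {self.name}")

    @property
    def nominal_class(self) -> str:
        return NOMINAL_CLASS[self.name]


@dataclass(frozen=True)
class Behaviors:
    """The four binary nocifensive behaviors scored per trial."""

    orbital_tightening: int
    paw_shake: int
    jump: int
    paw_guard: int

    def __post_init__(self):
        for name in BEHAVIOR_COLUMNS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise TrialValidationError(f"behavior {name} must be 0 or 1, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.orbital_tightening, self.paw_shake, self.jump, self.paw_guard)


@dataclass(frozen=True)
class Kinematics:
    """Subsecond paw-withdrawal kinematics for one trial.

    ``paw_height_mm`` is the apex displacement above the mesh floor and
    ``paw_speed_mm_per_s`` the lift-to-apex distance over elapsed time.
    Onset/apex times and the lift-before-orient flag are optional (absent
    when not measured, e.g. manually scored tables).
    """

    paw_height_mm: float
    paw_speed_mm_per_s: float
    lift_onset_s: float | None = None
    apex_time_s: float | None = None
    lift_before_orient: int | None = None

    def __post_init__(self):
        if not (math.isfinite(self.paw_height_mm) and self.paw_height_mm >= 0):
            raise TrialValidationError(f"paw_height_mm must be finite and >= 0, got {self.paw_height_mm!r}")
        if not (math.isfinite(self.paw_speed_mm_per_s) and self.paw_speed_mm_per_s >= 0):
            raise TrialValidationError(
                f"paw_speed_mm_per_s must be finite and >= 0, got {self.paw_speed_mm_per_s!r}"
            )
        if self.lift_onset_s is not None and self.apex_time_s is not None:
            if self.apex_time_s < self.lift_onset_s:
                raise TrialValidationError("apex_time_s must be >= lift_onset_s")
            if self.apex_time_s == self.lift_onset_s:
                raise TrialValidationError("paw speed undefined: apex_time_s == lift_onset_s")
        if self.lift_before_orient is not None and self.lift_before_orient not in (0, 1):
            raise TrialValidationError("lift_before_orient must be 0, 1 or absent")


@dataclass(frozen=True)
class Trial:
    trial_id: str
    subject_id: str
    strain: str
    sex: str
    sire: str
    stimulus: StimulusSpec
    timepoint: str
    withdrawal: int
    behaviors: Behaviors
    kinematics: Kinematics

    def __post_init__(self):
        if self.strain not in STRAINS:
            raise TrialValidationError(f"unknown strain {self.strain!r}")
        if self.sex not in SEXES:
            raise TrialValidationError(f"unknown sex {self.sex!r}")
        if self.sire not in SIRES:
            raise TrialValidationError(f"unknown sire {self.sire!r}")
        if self.timepoint not in TIMEPOINTS:
            raise TrialValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.withdrawal not in (0, 1):
            raise TrialValidationError(f"withdrawal must be 0 or 1, got {self.withdrawal!r}")
        if self.withdrawal == 0:
            if any(self.behaviors.as_tuple()):
                raise TrialValidationError("withdrawal == 0 requires all behaviors == 0")
            if self.kinematics.paw_height_mm != 0 or self.kinematics.paw_speed_mm_per_s != 0:
                raise TrialValidationError("withdrawal == 0 requires zero height and speed")


def _is_known_force(force: float) -> bool:
    return any(math.isclose(force, f, rel_tol=1e-9, abs_tol=1e-12) for f in VFH_FORCES)


# ---------------------------------------------------------------------------
# table validation
# ---------------------------------------------------------------------------


def validate_trials(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Check every trial-table invariant; return ``(row_index, message)`` diagnostics.

    Validation is total: every row either passes or yields a located
    diagnostic.  An empty list means the table is valid.
    """
    problems: list[tuple[int, str]] = []

    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    dup = df["trial_id"].duplicated(keep="first")
    for i in df.index[dup]:
        problems.append((int(i), f"duplicate trial_id {df.at[i, 'trial_id']!r}"))

    enum_checks = [
        ("strain", STRAINS),
        ("sex", SEXES),
        ("sire", SIRES),
        ("stimulus", STIMULI),
        ("timepoint", TIMEPOINTS),
    ]
    for col, allowed in enum_checks:
        bad = ~df[col].isin(allowed)
        for i in df.index[bad]:
            problems.append((int(i), f"{col} value {df.at[i, col]!r} not in {allowed}"))

    for col in ("withdrawal",) + BEHAVIOR_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1]) | vals.isna()
        for i in df.index[bad]:
            problems.append((int(i), f"{col} must be 0 or 1, got {df.at[i, col]!r}"))

    for col in ("paw_height_mm", "paw_speed_mm_per_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals < 0)
        for i in df.index[bad]:
            problems.append((int(i), f"{col} must be finite and >= 0, got {df.at[i, col]!r}"))

    force = pd.to_numeric(df["force_grams"], errors="coerce")
    is_vfh = df["stimulus"] == "VFH"
    for i in df.index[is_vfh & force.isna()]:
        problems.append((int(i), "VFH trial missing force_grams"))
    for i in df.index[is_vfh & force.notna()]:
        if not _is_known_force(float(force[i])):
            problems.append((int(i), f"force_grams {force[i]!r} not a calibrated VFH force"))
    for i in df.index[~is_vfh & force.notna()]:
        problems.append((int(i), f"force_grams set on non-VFH stimulus {df.at[i, 'stimulus']!r}"))

    onset = pd.to_numeric(df["lift_onset_s"], errors="coerce")
    apex = pd.to_numeric(df["apex_time_s"], errors="coerce")
    both = onset.notna() & apex.notna()
    for i in df.index[both & (apex < onset)]:
        problems.append((int(i), "apex_time_s < lift_onset_s"))
    for i in df.index[both & (apex == onset)]:
        problems.append((int(i), "apex_time_s == lift_onset_s (speed undefined)"))

    lbo = pd.to_numeric(df["lift_before_orient"], errors="coerce")
    bad_lbo = df["lift_before_orient"].notna() & ~lbo.isin([0, 1])
    for i in df.index[bad_lbo]:
        problems.append((int(i), f"lift_before_orient must be 0, 1 or empty, got {df.at[i, 'lift_before_orient']!r}"))

    wd = pd.to_numeric(df["withdrawal"], errors="coerce")
    no_wd = wd == 0
    beh_sum = sum(pd.to_numeric(df[c], errors="coerce").fillna(0) for c in BEHAVIOR_COLUMNS)
    height = pd.to_numeric(df["paw_height_mm"], errors="coerce").fillna(0)
    speed = pd.to_numeric(df["paw_speed_mm_per_s"], errors="coerce").fillna(0)
    for i in df.index[no_wd & ((beh_sum > 0) | (height != 0) | (speed != 0))]:
        problems.append((int(i), "withdrawal == 0 requires all behaviors and height/speed to be 0"))

    return sorted(set(problems))


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _STRING_COLUMNS:
        df[col] = df[col].astype(str)
    for col in ("withdrawal",) + BEHAVIOR_COLUMNS:
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    for col in ("paw_height_mm", "paw_speed_mm_per_s") + _OPTIONAL_FLOAT_COLUMNS:
        df[col] = pd.to_numeric(df[col]).astype(np.float64)
    return df


def read_trials(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a trial CSV.

    In strict mode any invariant violation raises
    :class:`TrialValidationError` naming the offending row.  In lenient
    mode violating rows are dropped; the drop count is logged and stored
    in ``df.attrs["n_dropped"]``.
    """
    path = Path(path)
    # round_trip parsing keeps reals bit-identical through write/read
    df = pd.read_csv(path, dtype={c: str for c in _STRING_COLUMNS}, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[list(TRIAL_COLUMNS)]

    problems = validate_trials(df)
    if problems:
        if strict:
            i, msg = problems[0]
            raise TrialValidationError(f"{path}: row {i}: {msg} ({len(problems)} problem(s) total)")
        bad_rows = sorted({i for i, _ in problems})
        logger.warning("%s: dropped %d invalid row(s): %s", path, len(bad_rows), bad_rows[:20])
        df = df.drop(index=bad_rows).reset_index(drop=True)
        df = _coerce_dtypes(df)
        df.attrs["n_dropped"] = len(bad_rows)
        return df

    df = _coerce_dtypes(df)
    df.attrs["n_dropped"] = 0
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated trial table to CSV (full float precision, empty
    cells for absent optional values); inverse of :func:`read_trials`."""
    problems = validate_trials(df)
    if problems:
        i, msg = problems[0]
        raise TrialValidationError(f"cannot write invalid table: row {i}: {msg}")
    path = Path(path)
    out = df[list(TRIAL_COLUMNS)]
    # str(float) round-trips float64 exactly in Python 3
    out.to_csv(path, index=False)
    return path


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Flatten Trial dataclasses into the canonical table layout."""
    rows = []
    for t in trials:
        k = t.kinematics
        rows.append(
            {
                "trial_id": t.trial_id,
                "subject_id": t.subject_id,
                "strain": t.strain,
                "sex": t.sex,
                "sire": t.sire,
                "stimulus": t.stimulus.name,
                "force_grams": np.nan if t.stimulus.force_grams is None else t.stimulus.force_grams,
                "timepoint": t.timepoint,
                "withdrawal": t.withdrawal,
                "orbital_tightening": t.behaviors.orbital_tightening,
                "paw_shake": t.behaviors.paw_shake,
                "jump": t.behaviors.jump,
                "paw_guard": t.behaviors.paw_guard,
                "paw_height_mm": k.paw_height_mm,
                "paw_speed_mm_per_s": k.paw_speed_mm_per_s,
                "lift_onset_s": np.nan if k.lift_onset_s is None else k.lift_onset_s,
                "apex_time_s": np.nan if k.apex_time_s is None else k.apex_time_s,
                "lift_before_orient": np.nan if k.lift_before_orient is None else float(k.lift_before_orient),
            }
        )
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return _coerce_dtypes(df) if len(df) else df


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    """Inflate table rows into Trial dataclasses (validates per row)."""
    out = []
    for _, r in df.iterrows():
        force = None if pd.isna(r["force_grams"]) else float(r["force_grams"])
        out.append(
            Trial(
                trial_id=str(r["trial_id"]),
                subject_id=str(r["subject_id"]),
                strain=str(r["strain"]),
                sex=str(r["sex"]),
                sire=str(r["sire"]),
                stimulus=StimulusSpec(str(r["stimulus"]), force),
                timepoint=str(r["timepoint"]),
                withdrawal=int(r["withdrawal"]),
                behaviors=Behaviors(*(int(r[c]) for c in BEHAVIOR_COLUMNS)),
                kinematics=Kinematics(
                    paw_height_mm=float(r["paw_height_mm"]),
                    paw_speed_mm_per_s=float(r["paw_speed_mm_per_s"]),
                    lift_onset_s=None if pd.isna(r["lift_onset_s"]) else float(r["lift_onset_s"]),
                    apex_time_s=None if pd.isna(r["apex_time_s"]) else float(r["apex_time_s"]),
                    lift_before_orient=None
                    if pd.isna(r["lift_before_orient"])
                    else int(r["lift_before_orient"]),
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# scale model
# ---------------------------------------------------------------------------

#: fixed feature order used everywhere a (n, 3) feature matrix appears.
FEATURE_NAMES = ("composite_score", "paw_speed", "paw_height")


@dataclass
class ScaleModel:
    """Fitted pain-scale parameters.

    z-score means/SDs and PC1 loadings are fit on all baseline trials
    pooled across the four natural stimuli; the RBF SVM (support vectors
    are scalar PC1 scores) and the Platt sigmoid P(pain | s) =
    1 / (1 + exp(a f(s) + b)) are fit on CS and HP trials only.
    ``pain_threshold_pc1`` is the PC1 value with calibrated probability 0.5.
    """

    feature_names: tuple[str, ...]
    zscore_means: np.ndarray
    zscore_sds: np.ndarray
    pc1_loadings: np.ndarray
    explained_variance_fraction: float
    sign_oriented: bool
    gamma: float
    C: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    pain_threshold_pc1: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.zscore_means = np.asarray(self.zscore_means, dtype=float)
        self.zscore_sds = np.asarray(self.zscore_sds, dtype=float)
        self.pc1_loadings = np.asarray(self.pc1_loadings, dtype=float)
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float)
        if np.any(self.zscore_sds <= 0):
            raise ModelIntegrityError("z-score SDs must be strictly positive")
        if abs(float(np.linalg.norm(self.pc1_loadings)) - 1.0) > 1e-9:
            raise ModelIntegrityError("pc1_loadings must have unit Euclidean norm (tol 1e-9)")

    def equals(self, other: "ScaleModel") -> bool:
        """Exact (bit-level) equality of every numeric field."""
        return (
            self.feature_names == other.feature_names
            and np.array_equal(self.zscore_means, other.zscore_means)
            and np.array_equal(self.zscore_sds, other.zscore_sds)
            and np.array_equal(self.pc1_loadings, other.pc1_loadings)
            and self.explained_variance_fraction == other.explained_variance_fraction
            and self.sign_oriented == other.sign_oriented
            and self.gamma == other.gamma
            and self.C == other.C
            and np.array_equal(self.support_vectors, other.support_vectors)
            and np.array_equal(self.dual_coef, other.dual_coef)
            and self.intercept == other.intercept
            and self.platt_a == other.platt_a
            and self.platt_b == other.platt_b
            and self.pain_threshold_pc1 == other.pain_threshold_pc1
            and self.provenance == other.provenance
        )


def save_model(model: ScaleModel, path: str | Path) -> Path:
    """Serialize a fitted model to a single JSON document."""
    doc = {
        "version": MODEL_FORMAT_VERSION,
        "features": list(model.feature_names),
        "zscore": {
            "means": model.zscore_means.tolist(),
            "sds": model.zscore_sds.tolist(),
        },
        "pca": {
            "loadings": model.pc1_loadings.tolist(),
            "explained_variance_fraction": model.explained_variance_fraction,
            "sign_oriented": bool(model.sign_oriented),
        },
        "svm": {
            "kernel": "rbf",
            "gamma": model.gamma,
            "C": model.C,
            "support_vectors": model.support_vectors.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "intercept": model.intercept,
        },
        "platt": {"a": model.platt_a, "b": model.platt_b},
        "threshold": {"pain_threshold_pc1": model.pain_threshold_pc1},
        "provenance": model.provenance,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_model(path: str | Path) -> ScaleModel:
    """Load a model JSON; refuses incompatible versions and corrupt fields."""
    path = Path(path)
    doc = json.loads(path.read_text())
    version = doc.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: model format version {version!r} incompatible with {MODEL_FORMAT_VERSION!r}"
        )
    try:
        model = ScaleModel(
            feature_names=tuple(doc["features"]),
            zscore_means=doc["zscore"]["means"],
            zscore_sds=doc["zscore"]["sds"],
            pc1_loadings=doc["pca"]["loadings"],
            explained_variance_fraction=float(doc["pca"]["explained_variance_fraction"]),
            sign_oriented=bool(doc["pca"]["sign_oriented"]),
            gamma=float(doc["svm"]["gamma"]),
            C=float(doc["svm"]["C"]),
            support_vectors=doc["svm"]["support_vectors"],
            dual_coef=doc["svm"]["dual_coef"],
            intercept=float(doc["svm"]["intercept"]),
            platt_a=float(doc["platt"]["a"]),
            platt_b=float(doc["platt"]["b"]),
            pain_threshold_pc1=float(doc["threshold"]["pain_threshold_pc1"]),
            provenance=doc.get("provenance", {}),
        )
    except KeyError as exc:
        raise ModelIntegrityError(f"{path}: missing model field {exc}") from exc
    return model
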