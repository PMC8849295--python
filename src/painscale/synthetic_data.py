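"""Synthetic cohorts and trajectories with the statistical structure the
analysis assumes.

The generator emulates four study designs: a baseline scale-construction
cohort (CS/DB/LP/HP with ordered effect sizes), a von Frey cohort whose
per-force feature distributions are anchored at dynamic-brush (touch)
levels and ramp only modestly with log-force, a 3 mg/kg morphine
timecourse, and a multigenerational design contrasting saline- and
morphine-sired males under 1 mg/kg morphine.

Generative families: Bernoulli for the four binary behaviors and for
withdrawal; lognormal for paw height and speed (positive, right-skewed).
Drug effects act *multiplicatively* on noxious-trial behavior
probabilities and kinematic location parameters and never on innocuous
trials; von Frey trials are generated morphine-insensitive (touch-like)
unless ``vfh_morphine_sensitive`` is set.  Every subject carries a shared
lognormal frailty so permutation tests can respect subject clustering.
All randomness flows from a single seed through a named stream per
subject group.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .kinematics import Trajectory
from .trial_model import TRIAL_COLUMNS, _coerce_dtypes

SCENARIOS = ("baseline_scale", "vfh", "morphine_timecourse", "multigenerational")

#: stimuli whose responses morphine attenuates (von Frey handled separately).
DRUG_AFFECTED_STIMULI = frozenset({"LP", "HP"})


@dataclass
class StimulusGenParams:
    """Generative parameters for one stimulus (or one von Frey force)."""

    behavior_probs: dict[str, float]        # per-behavior Bernoulli p
    height_median_mm: float                 # lognormal median (exp mu)
    height_sigma_log: float
    speed_median_mm_s: float
    speed_sigma_log: float
    withdrawal_prob: float
    lift_before_orient_prob: float

    def __post_init__(self):
        for name, p in {**self.behavior_probs,
                        "withdrawal": self.withdrawal_prob,
                        "lift_before_orient": self.lift_before_orient_prob}.items():
            if not 0.0 <= p <= 1.0:
                raise InputError(f"probability {name} = {p} outside [0, 1]")
        if self.height_sigma_log <= 0 or self.speed_sigma_log <= 0:
            raise InputError("lognormal sigma parameters must be > 0")


@dataclass
class CohortConfig:
    """Cohort design plus generative parameters per stimulus/timepoint/sire.

    The drug effect at timepoint T for sire lineage s multiplies
    noxious-trial behavior probabilities and kinematic medians by

        m(T, s) = 1 - timepoint_weights[T] * (1 - drug_factors[s])

    so ``drug_factors`` is the effective multiplier at full drug-effect
    weight (baseline weight is 0) and lineage modulates how much of the
    injected dose's effect is expressed.
    """

    scenario: str
    n_subjects: int
    trials_per_stimulus: int
    stimuli: list[str]
    vfh_forces: list[float]
    stim_params: dict[str, StimulusGenParams]
    timepoints: list[str]
    timepoint_weights: dict[str, float]
    sires: list[str]
    drug_factors: dict[str, float]
    vfh_morphine_sensitive: bool = False
    subject_frailty_sigma: float = 0.15
    strain: str = "SpragueDawley"
    sex: str = "M"
    morphine_dose_mg_per_kg: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise InputError("seed is mandatory")
        for s, f in self.drug_factors.items():
            if f < 0:
                raise InputError(f"drug factor for {s} must be >= 0, got {f}")
        for tp, w in self.timepoint_weights.items():
            if w < 0:
                raise InputError(f"timepoint weight for {tp} must be >= 0, got {w}")

    def stim_keys(self) -> list[str]:
        return list(self.stimuli) + [f"VFH@{f:g}" for f in self.vfh_forces]


def _vfh_interp(db: StimulusGenParams, lp: StimulusGenParams, force: float) -> StimulusGenParams:
    """Touch-like von Frey parameters: anchored at DB, ramping a modest
    fraction of the DB→LP gap with log-force (never approaching LP)."""
    frac = (math.log(force) - math.log(0.008)) / (math.log(300.0) - math.log(0.008))
    w = 0.15 * min(max(frac, 0.0), 1.0)
    probs = {
        k: db.behavior_probs[k] + w * (lp.behavior_probs[k] - db.behavior_probs[k])
        for k in db.behavior_probs
    }
    return StimulusGenParams(
        behavior_probs=probs,
        height_median_mm=db.height_median_mm + w * (lp.height_median_mm - db.height_median_mm),
        height_sigma_log=db.height_sigma_log,
        speed_median_mm_s=db.speed_median_mm_s + w * (lp.speed_median_mm_s - db.speed_median_mm_s),
        speed_sigma_log=db.speed_sigma_log,
        withdrawal_prob=0.5 + 0.45 * frac,
        lift_before_orient_prob=db.lift_before_orient_prob
        + w * (lp.lift_before_orient_prob - db.lift_before_orient_prob),
    )


def _base_stim_params() -> dict[str, StimulusGenParams]:
    return {
        "CS": StimulusGenParams(
            {"orbital_tightening": 0.04, "paw_shake": 0.03, "jump": 0.01, "paw_guard": 0.04},
            height_median_mm=4.0, height_sigma_log=0.35,
            speed_median_mm_s=60.0, speed_sigma_log=0.35,
            withdrawal_prob=0.6, lift_before_orient_prob=0.10,
        ),
        "DB": StimulusGenParams(
            {"orbital_tightening": 0.10, "paw_shake": 0.08, "jump": 0.02, "paw_guard": 0.10},
            height_median_mm=6.0, height_sigma_log=0.35,
            speed_median_mm_s=100.0, speed_sigma_log=0.35,
            withdrawal_prob=0.7, lift_before_orient_prob=0.20,
        ),
        "LP": StimulusGenParams(
            {"orbital_tightening": 0.70, "paw_shake": 0.60, "jump": 0.25, "paw_guard": 0.65},
            height_median_mm=18.0, height_sigma_log=0.35,
            speed_median_mm_s=350.0, speed_sigma_log=0.35,
            withdrawal_prob=0.95, lift_before_orient_prob=0.75,
        ),
        "HP": StimulusGenParams(
            {"orbital_tightening": 0.85, "paw_shake": 0.75, "jump": 0.45, "paw_guard": 0.90},
            height_median_mm=25.0, height_sigma_log=0.35,
            speed_median_mm_s=500.0, speed_sigma_log=0.35,
            withdrawal_prob=1.0, lift_before_orient_prob=0.90,
        ),
    }


def default_config(scenario: str, seed: int = 0, n_subjects: int | None = None) -> CohortConfig:
    """Documented defaults per study scenario.

    baseline_scale: ordered effect sizes CS < DB < LP < HP on every
    feature.  vfh: von Frey forces with touch-like parameters between the
    DB anchor and a modest step toward LP.  morphine_timecourse: 3 mg/kg,
    noxious-trial effect ordering post15 < post60 < 1.  multigenerational:
    1 mg/kg, morphine-sired effective factor 0.5 vs saline-sired 0.9.
    """
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}; valid scenarios: {', '.join(SCENARIOS)}")
    base = _base_stim_params()
    vfh_fig2_forces = [0.008, 10.0, 100.0, 300.0]

    def with_vfh(forces):
        params = dict(base)
        for f in forces:
            params[f"VFH@{f:g}"] = _vfh_interp(base["DB"], base["LP"], f)
        return params

    if scenario == "baseline_scale":
        return CohortConfig(
            scenario=scenario, n_subjects=n_subjects or 10, trials_per_stimulus=3,
            stimuli=["CS", "DB", "LP", "HP"], vfh_forces=[],
            stim_params=base,
            timepoints=["baseline"], timepoint_weights={"baseline": 0.0},
            sires=["naive"], drug_factors={"naive": 1.0}, seed=seed,
        )
    if scenario == "vfh":
        return CohortConfig(
            scenario=scenario, n_subjects=n_subjects or 10, trials_per_stimulus=3,
            stimuli=[], vfh_forces=vfh_fig2_forces,
            stim_params=with_vfh(vfh_fig2_forces),
            timepoints=["baseline"], timepoint_weights={"baseline": 0.0},
            sires=["naive"], drug_factors={"naive": 1.0}, seed=seed,
        )
    if scenario == "morphine_timecourse":
        forces = [10.0, 100.0, 300.0]
        return CohortConfig(
            scenario=scenario, n_subjects=n_subjects or 12, trials_per_stimulus=3,
            stimuli=["HP"], vfh_forces=forces,
            stim_params=with_vfh(forces),
            timepoints=["baseline", "post15min", "post60min"],
            timepoint_weights={"baseline": 0.0, "post15min": 1.0, "post60min": 0.6},
            sires=["naive"], drug_factors={"naive": 0.4},
            strain="LongEvans", morphine_dose_mg_per_kg=3.0, seed=seed,
        )
    # multigenerational
    forces = [10.0, 100.0, 300.0]
    return CohortConfig(
        scenario=scenario, n_subjects=n_subjects or 12, trials_per_stimulus=3,
        stimuli=["CS", "DB", "LP", "HP"], vfh_forces=forces,
        stim_params=with_vfh(forces),
        timepoints=["baseline", "post15min", "post60min"],
        timepoint_weights={"baseline": 0.0, "post15min": 1.0, "post60min": 0.6},
        sires=["saline_sired", "morphine_sired"],
        drug_factors={"saline_sired": 0.9, "morphine_sired": 0.5},
        morphine_dose_mg_per_kg=1.0, seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _drug_multiplier(config: CohortConfig, stim_key: str, timepoint: str, sire: str) -> float:
    is_vfh = stim_key.startswith("VFH@")
    affected = (stim_key in DRUG_AFFECTED_STIMULI) or (is_vfh and config.vfh_morphine_sensitive)
    if not affected:
        return 1.0
    w = config.timepoint_weights.get(timepoint, 0.0)
    factor = config.drug_factors.get(sire, 1.0)
    return max(0.0, 1.0 - w * (1.0 - factor))


def generate_cohort(config: CohortConfig, seed: int | None = None):
    """Generate a valid trial table plus a ground-truth sidecar dict.

    Deterministic given the seed; group sizes are exactly as configured;
    the returned table satisfies every trial-table invariant (including
    withdrawal == 0 implying all-zero features).
    """
    master = config.seed if seed is None else seed
    behaviors = ("orbital_tightening", "paw_shake", "jump", "paw_guard")
    rows = []
    truth_groups = {}

    for sire in config.sires:
        for subj in range(config.n_subjects):
            subject_id = f"{sire}-S{subj:02d}"
            rng = _stream(master, f"{sire}/{subject_id}")
            frailty = float(rng.lognormal(0.0, config.subject_frailty_sigma))
            for stim_key in config.stim_keys():
                params = config.stim_params[stim_key]
                is_vfh = stim_key.startswith("VFH@")
                stim_name = "VFH" if is_vfh else stim_key
                force = float(stim_key.split("@")[1]) if is_vfh else np.nan
                for tp in config.timepoints:
                    m = _drug_multiplier(config, stim_key, tp, sire)
                    gkey = f"{sire}|{stim_key}|{tp}"
                    if gkey not in truth_groups:
                        truth_groups[gkey] = {
                            "behavior_probs": {k: min(1.0, v * m) for k, v in params.behavior_probs.items()},
                            "height_median_mm": params.height_median_mm * m,
                            "speed_median_mm_s": params.speed_median_mm_s * m,
                            "withdrawal_prob": min(1.0, params.withdrawal_prob * (m if m < 1 else 1.0)),
                            "multiplier": m,
                        }
                    for k in range(config.trials_per_stimulus):
                        trial_id = f"{subject_id}-{stim_key}-{tp}-{k}"
                        # frailty scales response magnitude, never whether the
                        # spinal reflex occurs: withdrawal probability only sees
                        # the drug multiplier
                        p_w = min(1.0, params.withdrawal_prob * (m if m < 1 else 1.0))
                        withdrew = int(rng.random() < p_w)
                        if not withdrew:
                            row = dict(
                                withdrawal=0,
                                **{b: 0 for b in behaviors},
                                paw_height_mm=0.0, paw_speed_mm_per_s=0.0,
                                lift_onset_s=np.nan, apex_time_s=np.nan,
                                lift_before_orient=np.nan,
                            )
                        else:
                            beh = {
                                b: int(rng.random() < min(1.0, params.behavior_probs[b] * m * frailty))
                                for b in behaviors
                            }
                            height = float(rng.lognormal(
                                math.log(params.height_median_mm * m * frailty), params.height_sigma_log))
                            speed = float(rng.lognormal(
                                math.log(params.speed_median_mm_s * m * frailty), params.speed_sigma_log))
                            onset = float(rng.uniform(0.01, 0.05))
                            rise = float(rng.uniform(0.02, 0.08))
                            lbo = int(rng.random() < params.lift_before_orient_prob)
                            row = dict(
                                withdrawal=1, **beh,
                                paw_height_mm=height, paw_speed_mm_per_s=speed,
                                lift_onset_s=onset, apex_time_s=onset + rise,
                                lift_before_orient=float(lbo),
                            )
                        rows.append(
                            dict(
                                trial_id=trial_id, subject_id=subject_id,
                                strain=config.strain, sex=config.sex, sire=sire,
                                stimulus=stim_name, force_grams=force, timepoint=tp,
                                **row,
                            )
                        )

    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    df = _coerce_dtypes(df)
    truth = {
        "scenario": config.scenario,
        "seed": int(master),
        "n_subjects": config.n_subjects,
        "trials_per_stimulus": config.trials_per_stimulus,
        "subject_frailty_sigma": config.subject_frailty_sigma,
        "morphine_dose_mg_per_kg": config.morphine_dose_mg_per_kg,
        "groups": truth_groups,
    }
    return df, truth


def write_cohort(config: CohortConfig, csv_path: str | Path, seed: int | None = None) -> Path:
    """Write cohort CSV plus the ground-truth sidecar JSON next to it."""
    df, truth = generate_cohort(config, seed=seed)
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False)
    csv_path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))
    return csv_path


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryTruth:
    """Exact generative parameters for kinematics recovery tests.

    Times are relative to stimulus contact (seconds).
    """

    onset_s: float
    apex_time_s: float
    apex_height_mm: float
    speed_mm_per_s: float
    shake: int
    shake_cycles: int
    shake_freq_hz: float
    orient_time_s: float | None
    noise_sd_mm: float
    frame_rate_hz: float


def generate_trajectory(
    onset_s: float = 0.025,
    apex_height_mm: float = 35.0,
    rise_time_s: float = 0.040,
    shake_cycles: int = 4,
    shake_freq_hz: float = 20.0,
    orient_time_s: float | None = 0.2,
    noise_sd_mm: float = 0.0,
    frame_rate_hz: float = 2000.0,
    pre_stim_s: float = 0.1,
    duration_s: float = 0.7,
    horizontal_disp_mm: float = 0.0,
    guard_frac: float = 0.4,
    include_eye: bool = False,
    seed: int = 0,
) -> tuple[Trajectory, TrajectoryTruth]:
    """Piecewise paw-withdrawal trace with known ground truth.

    Event sequence mirrors a real noxious withdrawal: flat baseline on the
    floor, smooth (quarter-sine) rise to the apex over ``rise_time_s``, a
    truncated-cosine paw shake riding just below the apex envelope, then
    exponential decay to a guard height.  Optional head-orientation
    channel crosses 45 degrees at ``orient_time_s``; optional eye channel
    dips (orbital tightening) shortly after the stimulus.  Gaussian noise
    is added to the paw channels.  The noiseless trace maximum equals
    ``apex_height_mm`` exactly.
    """
    if min(onset_s, apex_height_mm, rise_time_s, frame_rate_hz) <= 0:
        raise InputError("physical parameters must be positive")
    if rise_time_s <= 2.0 / frame_rate_hz:
        raise InputError("rise_time_s must exceed 2 frame periods")
    if shake_cycles and shake_freq_hz >= frame_rate_hz / 2.0:
        raise InputError(f"shake frequency {shake_freq_hz} Hz at or above Nyquist ({frame_rate_hz / 2} Hz)")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"trajectory")]))
    n = int(round((pre_stim_s + duration_s) * frame_rate_hz)) + 1
    t = np.arange(n) / frame_rate_hz
    stim_time = pre_stim_s
    rel = t - stim_time

    H = apex_height_mm
    apex_rel = onset_s + rise_time_s
    y = np.zeros(n)

    rise = (rel > onset_s) & (rel <= apex_rel)
    u = (rel[rise] - onset_s) / rise_time_s
    y[rise] = H * np.sin(0.5 * np.pi * u)  # steep initial slope, flat at apex

    post = rel > apex_rel
    up = rel[post] - apex_rel
    guard = guard_frac * H
    base = guard + (H - guard) * np.exp(-up / 0.15)
    if shake_cycles > 0:
        a0 = float(np.clip(0.1 * H, 1.5, 4.0))
        shake_dur = shake_cycles / shake_freq_hz
        s = np.where(up <= shake_dur, a0 * (np.cos(2 * np.pi * shake_freq_hz * up) - 1.0), 0.0)
        # oscillation rides below the decay envelope: apex stays the max
        base = base + s
    y[post] = base

    x = np.zeros(n)
    if horizontal_disp_mm:
        x[rise] = horizontal_disp_mm * np.sin(0.5 * np.pi * u)
        x[post] = horizontal_disp_mm

    if noise_sd_mm > 0:
        y = y + rng.normal(0.0, noise_sd_mm, n)
        x = x + rng.normal(0.0, noise_sd_mm, n)
        y = np.maximum(y, -0.999)  # tracking can dip slightly below the floor

    head = None
    if orient_time_s is not None:
        head = 90.0 / (1.0 + np.exp(-(rel - orient_time_s) / 0.01))
    eye = None
    if include_eye:
        eye = 8.0 - 2.0 / (1.0 + np.exp(-(rel - 0.042) / 0.01))

    traj = Trajectory(
        t=t, paw_y_mm=y, paw_x_mm=x, frame_rate_hz=frame_rate_hz,
        stim_time_s=stim_time, head_orient_deg=head, eye_aperture_mm=eye,
    )
    speed = math.hypot(horizontal_disp_mm, H) / rise_time_s
    truth = TrajectoryTruth(
        onset_s=onset_s, apex_time_s=apex_rel, apex_height_mm=H,
        speed_mm_per_s=speed, shake=int(shake_cycles > 0), shake_cycles=int(shake_cycles),
        shake_freq_hz=shake_freq_hz, orient_time_s=orient_time_s,
        noise_sd_mm=noise_sd_mm, frame_rate_hz=frame_rate_hz,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# von Frey response series
# ---------------------------------------------------------------------------


def generate_vfh_response_series(
    sensitivity_g: float,
    forces=None,
    trials_per_force: int = 5,
    slope: float = 5.0,
    seed: int = 0,
) -> dict[float, tuple[int, int]]:
    """Simulate an ascending von Frey series for one subject.

    Withdrawal probability is logistic in log-force, centered on the
    subject's sensitivity (grams); an infinite sensitivity yields an
    all-zero map.  Deterministic per seed.
    """
    from .trial_model import VFH_FORCES

    forces = list(forces) if forces is not None else [f for f in VFH_FORCES if f >= 1.0]
    if any(b <= a for a, b in zip(forces, forces[1:])):
        raise InputError("forces must be strictly ascending")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"vfh_series")]))
    out: dict[float, tuple[int, int]] = {}
    for f in forces:
        if math.isinf(sensitivity_g):
            p = 0.0
        else:
            p = 1.0 / (1.0 + math.exp(-slope * (math.log(f) - math.log(sensitivity_g))))
        w = int(rng.binomial(trials_per_force, p))
        out[float(f)] = (w, trials_per_force)
    return out


def config_to_dict(config: CohortConfig) -> dict:
    """YAML/JSON-serializable view of a cohort config."""
    d = asdict(config)
    return d
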