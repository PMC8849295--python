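"""Subsecond paw-withdrawal feature extraction from keypoint trajectories.

A :class:`Trajectory` is a fixed-frame-rate keypoint time series (paw
vertical/horizontal position, optionally head orientation and eye
aperture) recorded around a stimulus contact at 2000 fps.  The floor is
the fixed reference ``y = 0``; paw height is measured from the floor,
not from the pre-stimulus paw posture.

Operations:

* :func:`detect_lift_onset` — first sustained post-stimulus rise above the
  pre-stimulus baseline, refined by back-extrapolation to the baseline
  (threshold crossing alone is biased late for slow, shallow lifts).
* :func:`extract_height_speed` — apex height above the floor and the
  lift-to-apex Euclidean (x, y) displacement over elapsed time.
* :func:`detect_shake` — oscillation counting (hysteresis sign changes of
  the detrended post-apex trace) plus a dominant-frequency check.
* :func:`orientation_order` — did the paw lift precede the head turning
  to look at the stimulus?
* :func:`trajectory_to_trial_features` — deterministic composition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateTrialError,
    FeatureUnavailableError,
    InputError,
    StageError,
)

logger = logging.getLogger(__name__)


@dataclass
class KinematicsParams:
    """All detector defaults in one place; no operation hard-codes them.

    Units: seconds, millimetres, Hz.
    """

    baseline_window_s: float = 0.05     # pre-stimulus window for the floor baseline
    delta_mm: float = 1.0               # rise above baseline that counts as a lift
    persistence_frames: int = 3         # consecutive frames required above threshold
    apex_search_window_s: float = 0.5   # later movements are guarding, not withdrawal
    speed_vertical_only: bool = False   # 2-D (x, y) lift-to-apex distance by default
    shake_window_s: float = 0.3
    shake_min_cycles: int = 2
    shake_min_freq_hz: float = 10.0
    shake_min_amp_mm: float = 0.5       # oscillations below this band are noise
    shake_peak_ratio: float = 20.0      # periodogram peak / median power required
    look_threshold_deg: float = 45.0


@dataclass
class Trajectory:
    """Keypoint time series at a fixed frame rate.

    ``t`` is strictly increasing with spacing ``1/frame_rate_hz``;
    ``stim_time_s`` marks stimulus contact on the same clock.  ``paw_y_mm``
    is vertical position with the mesh floor at 0 (up positive); values in
    ``[-1, 0)`` are tolerated as tracking noise and flagged.
    """

    t: np.ndarray
    paw_y_mm: np.ndarray
    paw_x_mm: np.ndarray
    frame_rate_hz: float = 2000.0
    stim_time_s: float = 0.0
    head_orient_deg: np.ndarray | None = None
    eye_aperture_mm: np.ndarray | None = None
    below_floor: bool = field(init=False, default=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.paw_y_mm = np.asarray(self.paw_y_mm, dtype=float)
        self.paw_x_mm = np.asarray(self.paw_x_mm, dtype=float)
        n = self.t.size
        channels = {"paw_y_mm": self.paw_y_mm, "paw_x_mm": self.paw_x_mm}
        if self.head_orient_deg is not None:
            self.head_orient_deg = np.asarray(self.head_orient_deg, dtype=float)
            channels["head_orient_deg"] = self.head_orient_deg
        if self.eye_aperture_mm is not None:
            self.eye_aperture_mm = np.asarray(self.eye_aperture_mm, dtype=float)
            channels["eye_aperture_mm"] = self.eye_aperture_mm
        for name, ch in channels.items():
            if ch.size != n:
                raise InputError(f"channel {name} length {ch.size} != time vector length {n}")
        if n < 2:
            raise InputError("trajectory needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InputError("time vector must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.frame_rate_hz) > 1e-9):
            raise InputError(
                f"time spacing must equal 1/frame_rate_hz = {1.0 / self.frame_rate_hz:.6g} s (tol 1e-9)"
            )
        ymin = float(np.min(self.paw_y_mm))
        if ymin < -1.0:
            raise InputError(f"paw_y_mm below -1 mm (min {ymin:.3f}); not plausible tracking noise")
        if ymin < 0:
            self.below_floor = True
            logger.debug("trajectory dips below floor (min %.3f mm); flagged as tracking noise", ymin)

    def shifted(self, delta_s: float) -> "Trajectory":
        """Time-translate the trajectory and its stimulus time by ``delta_s``."""
        return replace(self, t=self.t + delta_s, stim_time_s=self.stim_time_s + delta_s)


def _moving_average(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return y.astype(float)
    w = min(w, y.size if y.size % 2 == 1 else y.size - 1)
    if w < 3:
        return y.astype(float)
    if w % 2 == 0:
        w -= 1
    pad = w // 2
    ypad = np.pad(y, pad, mode="edge")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(ypad, kernel, mode="valid")


def detect_lift_onset(
    traj: Trajectory,
    baseline_window_s: float | None = None,
    delta_mm: float | None = None,
    params: KinematicsParams | None = None,
) -> float | None:
    """Return the paw-lift onset time (absolute, same clock as ``traj.t``).

    A lift exists when ``paw_y`` exceeds (pre-stimulus baseline median +
    ``delta_mm``) and stays above it for at least ``persistence_frames``
    consecutive frames; ``None`` (no withdrawal) if the threshold is
    never sustainedly exceeded.

    The reported time is then refined with a hinge (changepoint) least
    squares fit around the crossing — flat baseline switching to a linear
    rise — which removes the rise-time-dependent lag of a plain threshold
    crossing and is robust to tracking noise.
    """
    p = params or KinematicsParams()
    bw = p.baseline_window_s if baseline_window_s is None else baseline_window_s
    delta = p.delta_mm if delta_mm is None else delta_mm
    if bw <= 0 or delta <= 0:
        raise InputError("baseline_window_s and delta_mm must be positive")

    rel = traj.t - traj.stim_time_s
    base_mask = (rel >= -bw) & (rel < 0)
    if traj.t[0] - traj.stim_time_s > -bw + 1e-12 or not np.any(base_mask):
        raise InputError(
            f"trajectory shorter than baseline window: need {bw} s of pre-stimulus samples"
        )
    base = traj.paw_y_mm[base_mask]
    base_med = float(np.median(base))
    base_sd = float(np.std(base))
    thresh = base_med + delta

    post = np.flatnonzero(rel >= 0)
    if post.size < p.persistence_frames:
        return None
    i0 = post[0]
    above = traj.paw_y_mm[i0:] > thresh
    k = p.persistence_frames
    if above.size < k:
        return None
    runs = np.ones(above.size - k + 1, dtype=bool)
    for j in range(k):
        runs &= above[j : above.size - k + 1 + j]
    hits = np.flatnonzero(runs)
    if hits.size == 0:
        return None
    ic = i0 + int(hits[0])  # first index of the sustained exceedance

    # --- refinement: hinge changepoint fit around the crossing -----------
    # walk back from the crossing to the baseline noise band to bound the
    # rise region, then least-squares fit y = med + s * (t - t0)+ over a
    # window spanning it; the best-fitting knee t0 is the onset.
    band = base_med + max(3.0 * base_sd, 0.05 * delta)
    j = ic
    while j > i0 and traj.paw_y_mm[j - 1] > band:
        j -= 1
    half = max(ic - j, 4)
    lo = max(i0, j - 2 * half)
    hi = min(traj.t.size, ic + half + 2)
    tw = traj.t[lo:hi]
    yw = traj.paw_y_mm[lo:hi] - base_med
    best_sse, best_c = np.inf, ic - lo
    for c in range(tw.size - 2):
        w = np.maximum(tw - tw[c], 0.0)
        sw2 = float(np.dot(w, w))
        if sw2 <= 0:
            continue
        s = max(float(np.dot(w, yw)) / sw2, 0.0)
        r = yw - s * w
        sse = float(np.dot(r, r))
        if sse < best_sse:
            best_sse, best_c = sse, c
    onset = float(np.clip(tw[best_c], traj.t[i0], traj.t[ic]))
    return onset


def extract_height_speed(
    traj: Trajectory, onset: float, params: KinematicsParams | None = None
) -> tuple[float, float, float]:
    """Return ``(paw_height_mm, paw_speed_mm_per_s, apex_time_s)``.

    The apex is the global maximum of ``paw_y`` in
    ``(onset, onset + apex_search_window_s]``; height is the apex height
    above the floor (y = 0); speed is the (x, y) Euclidean distance from
    the paw position at onset to the apex, divided by the elapsed time
    (vertical-only displacement behind ``speed_vertical_only``).
    """
    p = params or KinematicsParams()
    eps = 0.5 / traj.frame_rate_hz
    mask = (traj.t > onset + 1e-12) & (traj.t <= onset + p.apex_search_window_s + 1e-12)
    if not np.any(mask):
        raise DegenerateTrialError("no samples after onset inside the apex search window")
    idx = np.flatnonzero(mask)
    apex_i = idx[int(np.argmax(traj.paw_y_mm[idx]))]
    apex_t = float(traj.t[apex_i])
    dt = apex_t - onset
    if dt <= eps * 1e-6:
        raise DegenerateTrialError("apex coincides with onset; paw speed undefined")
    height = float(traj.paw_y_mm[apex_i])
    onset_i = int(np.searchsorted(traj.t, onset - 1e-12))
    onset_i = min(onset_i, traj.t.size - 1)
    dy = traj.paw_y_mm[apex_i] - traj.paw_y_mm[onset_i]
    dx = traj.paw_x_mm[apex_i] - traj.paw_x_mm[onset_i]
    dist = abs(float(dy)) if p.speed_vertical_only else float(np.hypot(dx, dy))
    return height, dist / dt, apex_t


def _count_hysteresis_transitions(y: np.ndarray, h: float) -> int:
    """Sign changes of ``y`` with a deadband of ±h (noise-immune counting)."""
    s = np.where(y > h, 1, np.where(y < -h, -1, 0))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def detect_shake(
    traj: Trajectory,
    onset: float,
    apex_time: float,
    min_cycles: int | None = None,
    min_freq_hz: float | None = None,
    params: KinematicsParams | None = None,
) -> tuple[int, int]:
    """Detect the post-apex sinusoidal paw shake.

    Counts oscillation cycles in ``[apex_time, apex_time + shake_window_s]``
    as hysteresis sign changes (deadband ``shake_min_amp_mm / 2``) of the
    smoothed, detrended vertical trace, divided by two.  The slow
    post-apex guard-decay trend is estimated with a Savitzky-Golay filter
    (window about one period of the slowest accepted oscillation) so the
    residual isolates the shake.  The shake flag additionally requires
    the dominant oscillation frequency (periodogram peak) to be at least
    ``min_freq_hz`` with a peak-to-median power ratio of
    ``shake_peak_ratio`` and a half peak-to-peak amplitude of at least
    ``shake_min_amp_mm``.  A window running past the end of the trace is
    truncated and logged, not an error.
    """
    p = params or KinematicsParams()
    mc = p.shake_min_cycles if min_cycles is None else min_cycles
    mf = p.shake_min_freq_hz if min_freq_hz is None else min_freq_hz

    t_end = apex_time + p.shake_window_s
    if t_end > traj.t[-1] + 1e-12:
        logger.debug("shake window truncated at trace end (%.3f > %.3f s)", t_end, traj.t[-1])
    mask = (traj.t >= apex_time - 1e-12) & (traj.t <= t_end + 1e-12)
    y = traj.paw_y_mm[mask]
    if y.size < 16:
        return 0, 0
    w_trend = int(round(1.2 * traj.frame_rate_hz / mf)) | 1
    w_trend = min(w_trend, (y.size - 1) | 1)
    if w_trend <= 3:
        return 0, 0
    trend = signal.savgol_filter(y, w_trend, 2)
    detr = y - trend
    smooth = _moving_average(detr, 5)
    amp = 0.5 * float(np.max(smooth) - np.min(smooth))
    transitions = _count_hysteresis_transitions(smooth, 0.5 * p.shake_min_amp_mm)
    cycle_count = transitions // 2

    freqs, power = signal.periodogram(detr, fs=traj.frame_rate_hz)
    dom_freq = 0.0
    peak_ratio = 0.0
    if power.size > 2:
        pw = power[1:]
        peak_i = int(np.argmax(pw))
        dom_freq = float(freqs[1:][peak_i])
        med = float(np.median(pw))
        peak_ratio = float(pw[peak_i] / med) if med > 0 else np.inf

    shake = int(
        cycle_count >= mc
        and dom_freq >= mf
        and amp >= p.shake_min_amp_mm
        and peak_ratio >= p.shake_peak_ratio
    )
    return shake, cycle_count


def orientation_order(
    traj: Trajectory, onset: float | None, params: KinematicsParams | None = None
) -> int | None:
    """1 if the paw lifted before the head turned to look at the stimulus.

    The head-orientation time is the first post-stimulus crossing of the
    look threshold (default 45°) toward the stimulus.  Returns 0 if the
    head turned first (or only the head turned), ``None`` if neither
    event occurred.  A missing head channel is an error, never a silent
    ``None``.
    """
    p = params or KinematicsParams()
    if traj.head_orient_deg is None:
        raise FeatureUnavailableError("head_orient_deg channel required for orientation order")
    rel = traj.t - traj.stim_time_s
    post = rel >= 0
    crossing = post & (traj.head_orient_deg >= p.look_threshold_deg)
    look_t = float(traj.t[np.argmax(crossing)]) if np.any(crossing) else None
    if onset is None and look_t is None:
        return None
    if onset is None:
        return 0
    if look_t is None:
        return 1
    return int(onset < look_t)


@dataclass
class TrialFeatures:
    """Features extracted from one trajectory (shake is the only
    automatically detected behavior; grimace/jump/guard stay manual)."""

    withdrawal: int
    paw_height_mm: float
    paw_speed_mm_per_s: float
    lift_onset_s: float | None
    apex_time_s: float | None
    paw_shake: int
    shake_cycle_count: int
    lift_before_orient: int | None


def trajectory_to_trial_features(
    traj: Trajectory,
    params: KinematicsParams | None = None,
    require_orientation: bool = False,
) -> TrialFeatures:
    """Deterministic composition: onset → height/speed → shake → orientation.

    A flat trace yields a withdrawal-absent record (all zeros, no error).
    Constituent failures propagate as :class:`StageError` naming the stage.
    """
    p = params or KinematicsParams()

    try:
        onset = detect_lift_onset(traj, params=p)
    except Exception as exc:  # noqa: BLE001 - stage labeling
        raise StageError("detect_lift_onset", str(exc)) from exc

    if require_orientation and traj.head_orient_deg is None:
        raise StageError("orientation_order", "head_orient_deg channel required but absent")

    if onset is None:
        lbo = None
        if traj.head_orient_deg is not None:
            try:
                lbo = orientation_order(traj, None, params=p)
            except Exception as exc:  # noqa: BLE001
                raise StageError("orientation_order", str(exc)) from exc
        return TrialFeatures(0, 0.0, 0.0, None, None, 0, 0, lbo)

    try:
        height, speed, apex_t = extract_height_speed(traj, onset, params=p)
    except Exception as exc:  # noqa: BLE001
        raise StageError("extract_height_speed", str(exc)) from exc
    try:
        shake, cycles = detect_shake(traj, onset, apex_t, params=p)
    except Exception as exc:  # noqa: BLE001
        raise StageError("detect_shake", str(exc)) from exc
    lbo = None
    if traj.head_orient_deg is not None:
        try:
            lbo = orientation_order(traj, onset, params=p)
        except Exception as exc:  # noqa: BLE001
            raise StageError("orientation_order", str(exc)) from exc

    rel_onset = onset - traj.stim_time_s
    rel_apex = apex_t - traj.stim_time_s
    return TrialFeatures(1, height, speed, rel_onset, rel_apex, shake, cycles, lbo)


# ---------------------------------------------------------------------------
# trajectory file I/O (CSV + JSON sidecar)
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, csv_path: str | Path) -> Path:
    """Write channels to CSV plus a ``.json`` sidecar with frame rate and
    stimulus time."""
    csv_path = Path(csv_path)
    cols = {"t_s": traj.t, "paw_x_mm": traj.paw_x_mm, "paw_y_mm": traj.paw_y_mm}
    if traj.head_orient_deg is not None:
        cols["head_orient_deg"] = traj.head_orient_deg
    if traj.eye_aperture_mm is not None:
        cols["eye_aperture_mm"] = traj.eye_aperture_mm
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"frame_rate_hz": traj.frame_rate_hz, "stim_time_s": traj.stim_time_s})
    )
    return csv_path


def read_trajectory(csv_path: str | Path) -> Trajectory:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise InputError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("t_s", "paw_x_mm", "paw_y_mm"):
        if col not in df.columns:
            raise InputError(f"{csv_path}: missing trajectory column {col}")
    return Trajectory(
        t=df["t_s"].to_numpy(),
        paw_y_mm=df["paw_y_mm"].to_numpy(),
        paw_x_mm=df["paw_x_mm"].to_numpy(),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        stim_time_s=float(meta["stim_time_s"]),
        head_orient_deg=df["head_orient_deg"].to_numpy() if "head_orient_deg" in df.columns else None,
        eye_aperture_mm=df["eye_aperture_mm"].to_numpy() if "eye_aperture_mm" in df.columns else None,
    )
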