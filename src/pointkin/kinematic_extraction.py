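"""Preprocessing, movement segmentation and per-trial kinematic landmarks.

Pipeline per trial: zero-phase low-pass filtering of the marker positions
(3rd-order Butterworth, 5 Hz cutoff, forward-backward), three-point numerical
differentiation, tangential speed (Euclidean norm of the 3D velocity),
scalar acceleration (derivative of speed, signed so deceleration is
negative), onset/offset at the first/last samples where speed strictly
exceeds 10% of its peak, then the seven landmarks:

MD   movement duration (s), onset to offset
PV   peak speed (m/s) within [onset, offset]
PA   peak acceleration (m/s^2) on [onset, index(PV)]
PD   peak deceleration magnitude (m/s^2) on [index(PV), offset]
rDPV, rDPA, rDPD   relative time of the respective extremum, percent of MD

Two conventions are worth flagging because they change PD semantics: the
thresholded quantity is the *speed magnitude* (a signed axis projection would
make a 10%-of-peak rule ill-defined), and the scalar acceleration is the
derivative of speed rather than the norm of the vector acceleration, so
"deceleration" has a sign and PD is reported as a positive magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .trajectory_io import AnalysisConfig, TrialTrajectory


class SeriesValidationError(ValueError):
    """Input series violates a preprocessing precondition."""


class SegmentationError(ValueError):
    """Movement onset/offset cannot be determined."""


LANDMARK_COLUMNS = ["MD", "PV", "PA", "PD", "rDPV", "rDPA", "rDPD"]


@dataclass
class KinematicLandmarks:
    onset_index: int
    offset_index: int
    MD: float
    PV: float
    PA: float
    PD: float
    rDPV: float
    rDPA: float
    rDPD: float
    boundary_flag: bool = False
    tie_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "onset_index": self.onset_index, "offset_index": self.offset_index,
            "MD": self.MD, "PV": self.PV, "PA": self.PA, "PD": self.PD,
            "rDPV": self.rDPV, "rDPA": self.rDPA, "rDPD": self.rDPD,
            "boundary_flag": self.boundary_flag, "tie_flag": self.tie_flag,
        }


def lowpass_filter(series: np.ndarray, sampling_rate: float,
                   cutoff: float = 5.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, DC gain 1).

    Accepts a 1D series or an (n, k) array filtered column-wise. Missing
    samples are rejected, never interpolated.
    """
    series = np.asarray(series, dtype=float)
    if np.isnan(series).any():
        raise SeriesValidationError(
            "series contains missing samples; exclude the trial instead of "
            "interpolating")
    n = series.shape[0]
    padlen = 3 * (order + 1)          # filtfilt default for butter(order)
    if n <= padlen:
        raise SeriesValidationError(
            f"series of length {n} too short for order-{order} zero-phase "
            f"filtering (needs > {padlen})")
    if cutoff >= sampling_rate / 2:
        raise SeriesValidationError("cutoff must be below Nyquist")
    b, a = butter(order, cutoff / (sampling_rate / 2.0), btype="low")
    return filtfilt(b, a, series, axis=0)


def differentiate(series: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Three-point numerical differentiation.

    Interior samples use the central difference (x[i+1] - x[i-1]) * rate / 2;
    the endpoints use one-sided two-point differences. Output length equals
    input length.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise SeriesValidationError("differentiation needs at least 3 samples")
    return np.gradient(series, 1.0 / sampling_rate, axis=0, edge_order=1)


def tangential_kinematics(traj: TrialTrajectory,
                          config: AnalysisConfig | None = None,
                          filter_positions: bool = True,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Speed (m/s) and scalar acceleration (m/s^2) series for one trial.

    Positions are filtered first (unless ``filter_positions`` is False), then
    differentiated; the derivatives themselves are not re-filtered.
    """
    if traj.has_missing:
        raise SeriesValidationError(
            f"trial {traj.trial_id} has missing samples; route it to the "
            "exclusion stage")
    config = config or AnalysisConfig()
    pos = traj.positions
    if filter_positions:
        pos = lowpass_filter(pos, traj.sampling_rate, config.cutoff_hz,
                             config.filter_order)
    vel = differentiate(pos, traj.sampling_rate)
    speed = np.linalg.norm(vel, axis=1)
    accel = differentiate(speed, traj.sampling_rate)
    return speed, accel


def segment_movement(speed: np.ndarray,
                     threshold: float = 0.10) -> tuple[int, int, bool]:
    """Onset/offset as the first/last indices where speed strictly exceeds
    ``threshold`` x peak speed. Returns (onset, offset, boundary_flag); the
    flag marks a threshold crossing at the series boundary (no quiescent
    baseline)."""
    speed = np.asarray(speed, dtype=float)
    peak = float(np.max(speed)) if speed.size else 0.0
    if speed.size == 0 or peak <= 0:
        raise SegmentationError("speed has no strictly positive maximum")
    above = speed > threshold * peak
    idx = np.flatnonzero(above)
    onset, offset = int(idx[0]), int(idx[-1])
    boundary = onset == 0 or offset == speed.size - 1
    return onset, offset, boundary


def extract_landmarks(speed: np.ndarray, accel: np.ndarray,
                      onset: int, offset: int,
                      sampling_rate: float,
                      boundary_flag: bool = False) -> KinematicLandmarks:
    """Seven landmarks from segmented speed/acceleration series.

    PA is searched on [onset, index(PV)], PD on [index(PV), offset] — forced
    by the accelerate-then-brake logic of a unimodal profile. Ties at an
    extremum break to the earliest sample and set ``tie_flag``.
    """
    speed = np.asarray(speed, dtype=float)
    accel = np.asarray(accel, dtype=float)
    if not 0 <= onset < offset < speed.size:
        raise ValueError("invalid onset/offset for series length")
    seg = speed[onset:offset + 1]
    pv = float(np.max(seg))
    pv_candidates = np.flatnonzero(seg == pv)
    tie = pv_candidates.size > 1
    i_pv = onset + int(pv_candidates[0])
    if i_pv == onset or i_pv == offset:
        raise SegmentationError("peak speed lies on the segment boundary")

    acc_seg = accel[onset:i_pv + 1]
    pa = float(np.max(acc_seg))
    i_pa = onset + int(np.flatnonzero(acc_seg == pa)[0])
    tie = tie or np.flatnonzero(acc_seg == pa).size > 1

    dec_seg = accel[i_pv:offset + 1]
    dec_min = float(np.min(dec_seg))
    i_pd = i_pv + int(np.flatnonzero(dec_seg == dec_min)[0])
    tie = tie or np.flatnonzero(dec_seg == dec_min).size > 1

    span = offset - onset
    md = span / sampling_rate
    rel = lambda i: 100.0 * (i - onset) / span
    return KinematicLandmarks(
        onset_index=onset, offset_index=offset, MD=md, PV=pv, PA=pa,
        PD=abs(dec_min), rDPV=rel(i_pv), rDPA=rel(i_pa), rDPD=rel(i_pd),
        boundary_flag=boundary_flag, tie_flag=tie)


def analyze_trial(traj: TrialTrajectory,
                  config: AnalysisConfig | None = None,
                  ) -> tuple[KinematicLandmarks, np.ndarray, np.ndarray]:
    """Full per-trial pipeline; returns (landmarks, speed, acceleration)."""
    config = config or AnalysisConfig()
    speed, accel = tangential_kinematics(traj, config)
    onset, offset, boundary = segment_movement(speed, config.onset_threshold)
    lm = extract_landmarks(speed, accel, onset, offset, traj.sampling_rate,
                           boundary_flag=boundary)
    return lm, speed, accel


def analyze_trials(trials, config: AnalysisConfig | None = None,
                   keep_series: bool = False):
    """Landmark table for a trial collection.

    Returns (landmark DataFrame, series dict). Trials with missing samples
    get a row with ``missing=True`` and NaN landmarks so the exclusion stage
    can log them. ``series`` maps trial_id -> (speed, accel, onset, offset)
    when ``keep_series`` is set.
    """
    config = config or AnalysisConfig()
    rows = []
    series: dict = {}
    for traj in trials:
        labels = {
            "participant": traj.participant_id, "posture": traj.posture,
            "environment": traj.environment, "direction": traj.direction,
            "block": traj.block, "trial": traj.trial_index,
        }
        if traj.has_missing:
            rows.append({**labels, "missing": True,
                         **{c: np.nan for c in LANDMARK_COLUMNS},
                         "onset_index": -1, "offset_index": -1,
                         "boundary_flag": False, "tie_flag": False})
            continue
        lm, speed, accel = analyze_trial(traj, config)
        rows.append({**labels, "missing": False, **lm.as_dict()})
        if keep_series:
            series[traj.trial_id] = (speed, accel, lm.onset_index,
                                     lm.offset_index)
    frame = pd.DataFrame.from_records(rows)
    return frame, series


def exclude_trials(landmarks: pd.DataFrame,
                   md_outlier_sd: float = 3.0,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial-exclusion rules.

    Removes (a) trials with missing motion samples, then (b) trials whose MD
    strictly exceeds mean + ``md_outlier_sd`` x SD, with mean and SD taken
    over the grand pool of all non-missing trials. Returns (retained table,
    exclusion log with columns rule/statistic + trial labels).
    """
    log_rows = []
    missing_mask = landmarks["missing"].astype(bool)
    for _, row in landmarks[missing_mask].iterrows():
        log_rows.append({**_labels(row), "rule": "missing_samples",
                         "statistic": np.nan})
    pool = landmarks[~missing_mask]
    if len(pool) >= 2:
        md = pool["MD"].to_numpy(dtype=float)
        cut = float(np.mean(md) + md_outlier_sd * np.std(md, ddof=1))
        outlier_mask = pool["MD"] > cut      # strictly exceeded
        for _, row in pool[outlier_mask].iterrows():
            log_rows.append({**_labels(row), "rule": "md_outlier",
                             "statistic": float(row["MD"])})
        retained = pool[~outlier_mask]
    else:
        retained = pool
    log_cols = ["participant", "posture", "environment", "direction",
                "block", "trial", "rule", "statistic"]
    log = pd.DataFrame.from_records(log_rows, columns=log_cols)
    return retained.reset_index(drop=True), log


def _labels(row) -> dict:
    return {k: row[k] for k in ("participant", "posture", "environment",
                                "direction", "block", "trial")}
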