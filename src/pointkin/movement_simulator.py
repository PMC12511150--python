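"""Synthetic pointing-trial generator.

Emulates the factorial pointing study — 27 participants x 2 postures x 2
visual environments x 4 allocentric directions x 4 blocks x 3 trials (5184
trials), 30 cm amplitude, 120 Hz capture — with a controllable gravity-like
asymmetry of the speed profile and the two corruption modes the analysis
pipeline must catch (movement-duration outliers and missing motion samples).

The generative speed curve is beta-shaped, v(tau) ~ tau^(a-1) (1-tau)^(b-1)
on tau in [0, 1] with a + b fixed at 6, so a single parameter — the relative
time of peak speed (rdpv, in percent) — sets the profile's asymmetry through
the beta mode (a-1)/(a+b-2) = rdpv/100. At rdpv = 50 the curve reduces
exactly to the minimum-jerk speed profile 30 tau^2 (1-tau)^2.

Default rdpv targets encode the gravity signature reported for vertical arm
movements: upward peaks early (44%), downward late (50%), lateral in between
(47%), identical across environments and postures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .trajectory_io import (DIRECTION_VECTORS, StudyDesign, TrialTrajectory,
                            write_trials)

#: sum a + b of the beta shape exponents; 6 makes rdpv=50 the minimum-jerk curve
BETA_SHAPE_SUM = 6.0

DEFAULT_RDPV_TARGETS = {"up": 44.0, "down": 50.0, "left": 47.0, "right": 47.0}


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one simulated study.

    rdpv_targets maps direction (or (posture, environment, direction)) to the
    generative relative time of peak speed, in percent. Per-participant and
    per-trial Gaussian jitter is added on top (percent points). Durations are
    drawn from a normal distribution truncated at ``md_trunc_sd`` SDs so that
    injected outliers are the only trials beyond the 3-SD exclusion boundary.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    rdpv_targets: Mapping = field(default_factory=lambda: dict(DEFAULT_RDPV_TARGETS))
    participant_rdpv_sd: float = 1.5   # per participant x cell offset, % points
    trial_rdpv_sd: float = 3.0         # per-trial jitter, % points
    md_mean: float = 0.5               # s
    md_sd: float = 0.05                # s
    md_trunc_sd: float = 2.5
    noise_sd: float = 0.0005           # m, marker jitter before filtering
    pad: float = 0.4                   # s of quiescence before/after movement
    n_outlier_trials: int = 2
    n_missing_trials: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.md_mean <= 0 or self.md_sd < 0:
            raise ValueError("md_mean must be > 0 and md_sd >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pad < 0.25:
            raise ValueError("pad must be >= 0.25 s (segmentation needs a "
                             "quiescent baseline)")
        if self.n_outlier_trials < 0 or self.n_missing_trials < 0:
            raise ValueError("injection counts must be non-negative")
        for value in dict(self.rdpv_targets).values():
            if not 0 < value < 100:
                raise ValueError(f"rdpv target {value} outside (0, 100)")

    def rdpv_for(self, posture: str, environment: str, direction: str) -> float:
        targets = dict(self.rdpv_targets)
        if (posture, environment, direction) in targets:
            return float(targets[(posture, environment, direction)])
        return float(targets[direction])


def beta_exponents(rdpv_target: float,
                   shape_sum: float = BETA_SHAPE_SUM) -> tuple[float, float]:
    """Exponents (a, b) with a + b = shape_sum whose beta mode sits at
    rdpv_target percent."""
    if not 0 < rdpv_target < 100:
        raise ValueError(f"rdpv_target {rdpv_target} outside (0, 100)")
    mode = rdpv_target / 100.0
    a = 1.0 + mode * (shape_sum - 2.0)
    return a, shape_sum - a


def shape_speed_profile(rdpv_target: float, duration: float, amplitude: float,
                        sampling_rate: float) -> np.ndarray:
    """Unimodal speed series (m/s), zero at both ends, peaking at
    rdpv_target percent of duration, whose trapezoidal time-integral equals
    the movement amplitude."""
    if duration <= 0 or amplitude <= 0 or sampling_rate <= 0:
        raise ValueError("duration, amplitude and sampling_rate must be positive")
    a, b = beta_exponents(rdpv_target)
    n = int(round(duration * sampling_rate)) + 1
    if n < 3:
        raise ValueError("duration too short for the sampling rate")
    tau = np.linspace(0.0, 1.0, n)
    v = tau ** (a - 1.0) * (1.0 - tau) ** (b - 1.0)
    # realized duration is quantized to the sample grid; scale on that grid
    # so the trapezoidal displacement integral is the amplitude exactly
    v *= amplitude / np.trapezoid(v, dx=1.0 / sampling_rate)
    return v


def evaluate_speed_shape(rdpv_target: float, tau: np.ndarray) -> np.ndarray:
    """Unnormalized analytic speed shape on tau in [0, 1] (oracle helper)."""
    a, b = beta_exponents(rdpv_target)
    tau = np.asarray(tau, dtype=float)
    return tau ** (a - 1.0) * (1.0 - tau) ** (b - 1.0)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      trunc: float) -> float:
    if sd == 0:
        return mean
    while True:
        z = rng.standard_normal()
        if abs(z) <= trunc:
            return mean + sd * z


def synthesize_trial(config: SimConfig,
                     participant_id: str,
                     posture: str,
                     environment: str,
                     direction: str,
                     block: int,
                     trial_index: int,
                     rng: np.random.Generator,
                     rdpv_offset: float = 0.0,
                     duration: float | None = None,
                     ) -> tuple[TrialTrajectory, float, float]:
    """One straight-line pointing trial toward the labelled target.

    Returns (trajectory, generative rdpv used, generative duration).
    """
    design = config.design
    if direction not in DIRECTION_VECTORS:
        raise ValueError(f"unknown direction {direction!r}")
    rdpv = config.rdpv_for(posture, environment, direction) + rdpv_offset \
        + rng.normal(0.0, config.trial_rdpv_sd)
    rdpv = float(np.clip(rdpv, 5.0, 95.0))
    if duration is None:
        duration = _truncated_normal(rng, config.md_mean, config.md_sd,
                                     config.md_trunc_sd)
    fs = design.sampling_rate
    speed = shape_speed_profile(rdpv, duration, design.amplitude, fs)
    disp = cumulative_trapezoid(speed, dx=1.0 / fs, initial=0.0)
    unit = DIRECTION_VECTORS[direction]
    path = disp[:, None] * unit[None, :]

    n_pad = int(round(config.pad * fs))
    pos = np.vstack([
        np.repeat(path[:1], n_pad, axis=0),
        path,
        np.repeat(path[-1:], n_pad, axis=0),
    ])
    if config.noise_sd > 0:
        pos = pos + rng.normal(0.0, config.noise_sd, pos.shape)
    t = np.arange(pos.shape[0]) / fs
    traj = TrialTrajectory(
        participant_id=participant_id, posture=posture,
        environment=environment, direction=direction, block=block,
        trial_index=trial_index, time=t, positions=pos, sampling_rate=fs)
    return traj, rdpv, float(duration)


def simulate_study(config: SimConfig,
                   ) -> tuple[list[TrialTrajectory], pd.DataFrame]:
    """Full factorial trial set plus a ground-truth ledger.

    The ledger has one row per trial (labels, generative rdpv and duration,
    corruption flag in {'', 'duration_outlier', 'missing_samples'}). Duration
    outliers are regenerated with a duration drawn uniformly in
    [mean + 6 SD, mean + 8 SD]; missing-sample trials have a contiguous span
    of coordinates blanked (NaN).
    """
    design = config.design
    rng = np.random.default_rng(config.seed)
    n_total = design.n_trials
    if config.n_outlier_trials + config.n_missing_trials > n_total:
        raise ValueError("injection counts exceed the total trial count")

    corrupt_idx = rng.choice(n_total, config.n_outlier_trials +
                             config.n_missing_trials, replace=False)
    outlier_set = set(corrupt_idx[:config.n_outlier_trials].tolist())
    missing_set = set(corrupt_idx[config.n_outlier_trials:].tolist())

    trials: list[TrialTrajectory] = []
    records = []
    flat = 0
    for p_idx in range(design.n_participants):
        pid = f"P{p_idx + 1:02d}"
        cell_offsets = {cell: rng.normal(0.0, config.participant_rdpv_sd)
                        for cell in design.cells()}
        for posture, environment, direction in design.cells():
            offset = cell_offsets[(posture, environment, direction)]
            for block in range(1, design.blocks_per_condition + 1):
                for trial in range(1, design.trials_per_direction_per_block + 1):
                    duration = None
                    corruption = ""
                    if flat in outlier_set:
                        duration = config.md_mean + config.md_sd * rng.uniform(6.0, 8.0)
                        corruption = "duration_outlier"
                    traj, rdpv, dur = synthesize_trial(
                        config, pid, posture, environment, direction, block,
                        trial, rng, rdpv_offset=offset, duration=duration)
                    if flat in missing_set:
                        n = traj.n_samples
                        span = max(3, n // 10)
                        start = rng.integers(n // 4, 3 * n // 4 - span)
                        traj.positions[start:start + span, :] = np.nan
                        corruption = "missing_samples"
                    trials.append(traj)
                    records.append({
                        "participant": pid, "posture": posture,
                        "environment": environment, "direction": direction,
                        "block": block, "trial": trial,
                        "generative_rdpv": rdpv, "generative_md": dur,
                        "corruption": corruption,
                    })
                    flat += 1
    ledger = pd.DataFrame.from_records(records)
    assert len(trials) == n_total
    return trials, ledger


def write_study(trials: list[TrialTrajectory], ledger: pd.DataFrame,
                out_dir) -> dict:
    """Write trials.csv and ground_truth.csv under out_dir."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"trials": write_trials(trials, out / "trials.csv")}
    ledger_path = out / "ground_truth.csv"
    ledger.to_csv(ledger_path, index=False, float_format="%.6f")
    paths["ledger"] = ledger_path
    return paths
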