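"""Trajectory tables, study-design metadata, configuration and result artifacts.

The on-disk trajectory format is a long-format CSV with one row per motion
sample (columns ``participant, posture, environment, direction, block, trial,
t, x, y, z``; coordinates in metres, time in seconds). Missing motion samples
are encoded as empty coordinate cells, never as omitted rows, so gaps stay
detectable downstream.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

POSTURES = ("upright", "lying")
ENVIRONMENTS = ("virtual", "physical")
DIRECTIONS = ("up", "down", "left", "right")

#: allocentric unit vectors (room frame: x rightward, y anterior, z vertical)
DIRECTION_VECTORS = {
    "up": np.array([0.0, 0.0, 1.0]),
    "down": np.array([0.0, 0.0, -1.0]),
    "left": np.array([-1.0, 0.0, 0.0]),
    "right": np.array([1.0, 0.0, 0.0]),
}

TRAJECTORY_COLUMNS = [
    "participant", "posture", "environment", "direction",
    "block", "trial", "t", "x", "y", "z",
]

LABEL_COLUMNS = ["participant", "posture", "environment", "direction", "block", "trial"]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (bad header, unparsable labels)."""


class TrajectoryValidationError(ValueError):
    """Well-formed file whose contents violate a trajectory invariant."""


@dataclass(frozen=True)
class StudyDesign:
    """Factorial structure of the pointing experiment.

    Defaults mirror the study protocol: 27 analysed participants, 2 postures
    x 2 visual environments x 4 allocentric directions, 4 blocks of 3 trials
    per direction in every posture-environment combination, 30 cm movement
    amplitude, 120 Hz optical capture.
    """

    n_participants: int = 27
    postures: tuple[str, ...] = POSTURES
    environments: tuple[str, ...] = ENVIRONMENTS
    directions: tuple[str, ...] = DIRECTIONS
    blocks_per_condition: int = 4
    trials_per_direction_per_block: int = 3
    amplitude: float = 0.30
    sampling_rate: float = 120.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("n_participants", "blocks_per_condition",
                     "trials_per_direction_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.postures) * len(self.environments) * len(self.directions)

    @property
    def trials_per_cell(self) -> int:
        return self.blocks_per_condition * self.trials_per_direction_per_block

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.n_cells * self.trials_per_cell

    def cells(self) -> list[tuple[str, str, str]]:
        """All (posture, environment, direction) cells in canonical order."""
        return [(p, e, d) for p in self.postures for e in self.environments
                for d in self.directions]


@dataclass
class TrialTrajectory:
    """One trial's 3D fingertip samples plus factorial labels.

    ``positions`` is an (n, 3) array in metres; missing samples are NaN rows.
    """

    participant_id: str
    posture: str
    environment: str
    direction: str
    block: int
    trial_index: int
    time: np.ndarray
    positions: np.ndarray
    sampling_rate: float = 120.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrajectoryValidationError(
                f"trial {self.trial_id}: positions must be (n, 3)")
        if self.time.shape[0] != self.positions.shape[0]:
            raise TrajectoryValidationError(
                f"trial {self.trial_id}: time/position length mismatch")
        if self.time.size < 24:
            raise TrajectoryValidationError(
                f"trial {self.trial_id}: needs at least 24 samples (0.2 s "
                "at 120 Hz)")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise TrajectoryValidationError(
                f"trial {self.trial_id}: timestamps not strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise TrajectoryValidationError(
                f"trial {self.trial_id}: non-uniform sampling (spread {np.ptp(dt):.2e} s)")
        if self.sampling_rate <= 0:
            raise TrajectoryValidationError(
                f"trial {self.trial_id}: sampling_rate must be positive")

    @property
    def trial_id(self) -> tuple:
        return (self.participant_id, self.posture, self.environment,
                self.direction, self.block, self.trial_index)

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.positions).any())

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.posture, self.environment, self.direction)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants; defaults are the protocol values."""

    cutoff_hz: float = 5.0
    filter_order: int = 3
    onset_threshold: float = 0.10     # fraction of peak speed
    alpha: float = 0.05
    md_outlier_sd: float = 3.0        # MD exclusion: mean + k*SD, strictly exceeded
    n_nodes: int = 101                # SPM time-normalization grid
    two_tailed: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.onset_threshold < 1:
            raise ValueError("onset_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.filter_order < 1 or self.cutoff_hz <= 0:
            raise ValueError("invalid filter settings")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")


def load_config(path: str | os.PathLike | None) -> tuple[StudyDesign, AnalysisConfig, dict]:
    """Load a YAML config with ``design:``, ``analysis:`` and ``simulation:`` blocks.

    Absent keys fall back to protocol defaults. Returns the design, the
    analysis constants, and the raw simulation overrides (interpreted by
    :mod:`pointkin.movement_simulator`).
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    design_kw = dict(raw.get("design", {}))
    for key in ("postures", "environments", "directions"):
        if key in design_kw:
            design_kw[key] = tuple(design_kw[key])
    design = StudyDesign(**design_kw)
    analysis = AnalysisConfig(**raw.get("analysis", {}))
    return design, analysis, dict(raw.get("simulation", {}))


# ---------------------------------------------------------------------------
# trajectory CSV round trip
# ---------------------------------------------------------------------------

_T_FMT = "%.9f"
_COORD_FMT = "%.9f"


def _canonical_frame(trials: Iterable[TrialTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in sorted(trials, key=lambda t: (str(t.participant_id),) + t.trial_id[1:]):
        frame = pd.DataFrame({
            "participant": tr.participant_id,
            "posture": tr.posture,
            "environment": tr.environment,
            "direction": tr.direction,
            "block": tr.block,
            "trial": tr.trial_index,
            "t": tr.time,
            "x": tr.positions[:, 0],
            "y": tr.positions[:, 1],
            "z": tr.positions[:, 2],
        })
        rows.append(frame)
    if not rows:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_trials(trials: Iterable[TrialTrajectory], path: str | os.PathLike) -> Path:
    """Write trials as canonical long-format CSV (deterministic formatting)."""
    frame = _canonical_frame(trials)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(",".join(TRAJECTORY_COLUMNS) + "\n")
    for row in frame.itertuples(index=False):
        coords = ",".join(
            "" if np.isnan(v) else _COORD_FMT % v for v in (row.x, row.y, row.z))
        buf.write(f"{row.participant},{row.posture},{row.environment},"
                  f"{row.direction},{row.block},{row.trial},"
                  f"{_T_FMT % row.t},{coords}\n")
    path.write_text(buf.getvalue())
    return path


def read_trials(path: str | os.PathLike,
                design: StudyDesign | None = None) -> list[TrialTrajectory]:
    """Read a long-format trajectory CSV into :class:`TrialTrajectory` objects.

    Rows are grouped by the six label columns; grouping is label-driven, so
    row order within the file is irrelevant. Rows with empty or non-numeric
    coordinates are retained as NaN (missing) samples.
    """
    frame = pd.read_csv(path, dtype={"participant": str})
    missing_cols = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise TrajectoryFormatError(
            f"{path}: missing required columns {missing_cols}")
    if frame.empty:
        return []
    for col in ("t", "x", "y", "z"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    if frame["t"].isna().any():
        raise TrajectoryFormatError(f"{path}: non-numeric time values")

    trials: list[TrialTrajectory] = []
    rate = design.sampling_rate if design is not None else None
    for key, grp in frame.groupby(LABEL_COLUMNS, sort=True):
        participant, posture, environment, direction, block, trial = key
        grp = grp.sort_values("t", kind="mergesort")
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrajectoryValidationError(
                f"trial {key}: duplicate or non-monotonic timestamps")
        dt = float(np.median(np.diff(t)))
        fs = rate if rate is not None else 1.0 / dt
        trials.append(TrialTrajectory(
            participant_id=str(participant), posture=str(posture),
            environment=str(environment), direction=str(direction),
            block=int(block), trial_index=int(trial),
            time=t, positions=grp[["x", "y", "z"]].to_numpy(dtype=float),
            sampling_rate=fs))
    return trials


# ---------------------------------------------------------------------------
# result artifacts
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def _write_table(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_results(landmarks: pd.DataFrame,
                  comparisons: pd.DataFrame,
                  out_dir: str | os.PathLike,
                  spm_report: pd.DataFrame | None = None,
                  log_lines: Sequence[str] = (),
                  ) -> dict[str, Path]:
    """Write the landmark table, comparison table, optional SPM report and a
    plain-text analysis log. Column order and float formatting are fixed so
    identical inputs give byte-identical files."""
    if landmarks is None or landmarks.empty:
        raise ValueError("landmark table is empty; refusing to write results")
    if comparisons is None or comparisons.empty:
        raise ValueError("comparison table is empty; refusing to write results")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "landmarks": _write_table(landmarks, out / "landmarks.csv"),
            "comparisons": _write_table(comparisons, out / "comparisons.csv"),
        }
        if spm_report is not None and not spm_report.empty:
            paths["spm"] = _write_table(spm_report, out / "spm_report.csv")
        log_path = out / "analysis_log.txt"
        log_path.write_text("".join(line.rstrip("\n") + "\n" for line in log_lines))
        paths["log"] = log_path
    except OSError as exc:
        raise OSError(f"cannot write results to {out}: {exc}") from exc
    return paths


def design_to_dict(design: StudyDesign) -> dict:
    return dataclasses.asdict(design)
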