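"""Time-normalized velocity/acceleration profiles and 1D SPM{t} inference.

Each trial's speed (or scalar-acceleration) series is linearly interpolated
onto 101 nodes spanning movement onset to offset (0..100% of movement time),
trials are averaged to participant x condition-cell mean profiles, and
paired comparisons are tested node-wise with a paired t statistic — the
SPM{t} curve. Family-wise inference across the 101 correlated nodes uses the
random-field-theory (RFT) expected-Euler-characteristic bound for a smooth
1D t-field: the critical threshold t* solves

    alpha_tail = P(T_nu > t) + resels * EC1(t),
    EC1(t) = sqrt(4 ln 2) / (2 pi) * (1 + t^2 / nu)^(-(nu - 1) / 2),

with resels = (n_nodes - 1) / FWHM and the field smoothness FWHM estimated
from the normalized residual gradients (FWHM = sqrt(4 ln 2) / RMS gradient
of unit-variance residuals). Two-tailed inference splits alpha across the
tails. Suprathreshold clusters are maximal runs of nodes with |t| > t*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .condition_statistics import planned_pairs
from .trajectory_io import StudyDesign

_SQRT_4LN2 = float(np.sqrt(4.0 * np.log(2.0)))


class SPMError(ValueError):
    pass


@dataclass
class SPMResult:
    """Node-wise t-curve with RFT threshold and suprathreshold clusters."""

    t_curve: np.ndarray
    df: float
    fwhm: float
    resels: float
    t_star: float
    alpha: float
    two_tailed: bool
    clusters: list = field(default_factory=list)   # (start%, end%, sign)
    comparison: str = ""
    quantity: str = ""

    @property
    def has_suprathreshold(self) -> bool:
        return len(self.clusters) > 0


def time_normalize(series: np.ndarray, onset: int, offset: int,
                   n_nodes: int = 101) -> np.ndarray:
    """Linear interpolation of ``series[onset:offset]`` onto ``n_nodes``
    equally spaced points; node 0 is the onset sample, the last node the
    offset sample."""
    series = np.asarray(series, dtype=float)
    if offset - onset < 2:
        raise SPMError("degenerate segment: offset - onset must be >= 2")
    if not 0 <= onset < offset < series.size:
        raise SPMError("onset/offset outside the series")
    src = np.arange(onset, offset + 1, dtype=float)
    nodes = np.linspace(onset, offset, n_nodes)
    return np.interp(nodes, src, series[onset:offset + 1])


def paired_spm_t(profiles_a: np.ndarray, profiles_b: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise paired t statistic and residuals.

    ``profiles_a`` and ``profiles_b`` are (n_participants, n_nodes) arrays
    matched by row. Returns (t_curve, residuals) where residuals are the
    mean-centred paired differences used for smoothness estimation.
    """
    A = np.asarray(profiles_a, dtype=float)
    B = np.asarray(profiles_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise SPMError("profile sets must be matching (n, nodes) arrays")
    n = A.shape[0]
    if n < 3:
        raise SPMError("paired SPM{t} needs at least 3 participants")
    d = A - B
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise SPMError(f"zero variance at node(s) {zero.tolist()}; "
                       "t is undefined there")
    t = mean / (sd / np.sqrt(n))
    residuals = d - mean
    return t, residuals


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, node units) from normalized residual
    gradients: FWHM = sqrt(4 ln 2) / RMS(d/dx of unit-variance residuals),
    clamped to [1, n_nodes]."""
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 3:
        raise SPMError("need >= 2 residual curves over >= 3 nodes")
    sd = R.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise SPMError("constant residuals: smoothness undefined")
    Z = R / sd
    grad = np.gradient(Z, axis=1)
    v = float(np.mean(grad ** 2))
    if v == 0:
        raise SPMError("flat residual field: smoothness undefined")
    fwhm = _SQRT_4LN2 / np.sqrt(v)
    return float(np.clip(fwhm, 1.0, R.shape[1]))


def _ec1_t(t: float, df: float) -> float:
    """1D Euler-characteristic density of a t-field."""
    return _SQRT_4LN2 / (2.0 * np.pi) * (1.0 + t * t / df) ** (-(df - 1) / 2.0)


def rft_threshold(df: float, fwhm: float, n_nodes: int,
                  alpha: float = 0.05, two_tailed: bool = True) -> float:
    """Critical threshold t* of the expected-Euler-characteristic bound
    P(T > t) + resels * EC1(t) = alpha_tail, solved by root-finding."""
    if not 0 < alpha < 1:
        raise SPMError("alpha must lie in (0, 1)")
    if df < 2 or fwhm <= 0:
        raise SPMError("df must be >= 2 and fwhm positive")
    resels = (n_nodes - 1) / fwhm
    a_tail = alpha / 2.0 if two_tailed else alpha

    def excess(t: float) -> float:
        return stats.t.sf(t, df) + resels * _ec1_t(t, df) - a_tail

    lo, hi = 1e-6, 10.0
    while excess(hi) > 0 and hi < 1e4:
        hi *= 2.0
    if excess(lo) < 0:
        return lo
    return float(brentq(excess, lo, hi, xtol=1e-6))


def find_clusters(t_curve: np.ndarray, t_star: float) -> list[tuple]:
    """Maximal runs of consecutive nodes with |t| > t*, as
    (start%, end%, sign) with percentages on the 0..100 node scale."""
    t = np.asarray(t_curve, dtype=float)
    if not np.all(np.isfinite(t)):
        raise SPMError("t-curve contains non-finite values")
    n = t.size
    above = np.abs(t) > t_star
    clusters = []
    i = 0
    scale = 100.0 / (n - 1)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            sign = int(np.sign(t[i:j + 1].mean()))
            clusters.append((i * scale, j * scale, sign))
            i = j + 1
        else:
            i += 1
    return clusters


def spm_paired_test(profiles_a: np.ndarray, profiles_b: np.ndarray,
                    alpha: float = 0.05, two_tailed: bool = True,
                    comparison: str = "", quantity: str = "") -> SPMResult:
    """Complete paired SPM{t} inference for one comparison."""
    t, residuals = paired_spm_t(profiles_a, profiles_b)
    fwhm = estimate_fwhm(residuals)
    n_nodes = t.size
    df = profiles_a.shape[0] - 1
    t_star = rft_threshold(df, fwhm, n_nodes, alpha, two_tailed)
    clusters = find_clusters(t, t_star)
    return SPMResult(t_curve=t, df=float(df), fwhm=fwhm,
                     resels=(n_nodes - 1) / fwhm, t_star=t_star, alpha=alpha,
                     two_tailed=two_tailed, clusters=clusters,
                     comparison=comparison, quantity=quantity)


# ---------------------------------------------------------------------------
# study-level orchestration
# ---------------------------------------------------------------------------

def participant_cell_profiles(landmarks: pd.DataFrame, series: dict,
                              quantity: str = "speed",
                              n_nodes: int = 101,
                              design: StudyDesign | None = None,
                              ) -> tuple[np.ndarray, list, list]:
    """Participant x cell mean time-normalized profiles.

    ``series`` maps trial_id -> (speed, accel, onset, offset) as produced by
    :func:`pointkin.kinematic_extraction.analyze_trials`. Only trials present
    in the retained ``landmarks`` table contribute. Returns a
    (n_participants, n_cells, n_nodes) array plus participant and cell lists.
    """
    design = design or StudyDesign()
    cells = design.cells()
    cell_idx = {c: j for j, c in enumerate(cells)}
    q = 0 if quantity == "speed" else 1

    acc: dict = {}
    for row in landmarks.itertuples(index=False):
        tid = (row.participant, row.posture, row.environment, row.direction,
               row.block, row.trial)
        if tid not in series:
            continue
        speed, accel, onset, offset = series[tid]
        prof = time_normalize((speed, accel)[q], onset, offset, n_nodes)
        acc.setdefault((row.participant, tid[1:4]), []).append(prof)

    participants = sorted({k[0] for k in acc})
    out = np.full((len(participants), len(cells), n_nodes), np.nan)
    for (pid, cell), profs in acc.items():
        out[participants.index(pid), cell_idx[cell]] = np.mean(profs, axis=0)
    if np.isnan(out).any():
        missing = [(participants[i], cells[j])
                   for i, j in zip(*np.nonzero(np.isnan(out[:, :, 0])))]
        raise SPMError(f"missing participant cells: {missing[:5]}")
    return out, participants, cells


def run_spm_comparisons(profiles: np.ndarray, cells: list,
                        quantity: str, alpha: float = 0.05,
                        two_tailed: bool = True) -> list[SPMResult]:
    """One SPMResult per planned comparison for one quantity (16 results)."""
    cell_idx = {c: j for j, c in enumerate(cells)}
    results = []
    for pair in planned_pairs():
        A = profiles[:, cell_idx[pair["cell_a"]], :]
        B = profiles[:, cell_idx[pair["cell_b"]], :]
        name = "-".join(pair["cell_a"]) + " vs " + "-".join(pair["cell_b"])
        res = spm_paired_test(A, B, alpha, two_tailed,
                              comparison=name, quantity=quantity)
        res.comparison_id = pair["pair_id"]
        res.family = pair["family"]
        results.append(res)
    return results


def spm_report(results: list[SPMResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "comparison_id": getattr(r, "comparison_id", ""),
            "family": getattr(r, "family", ""),
            "comparison": r.comparison, "quantity": r.quantity,
            "df": r.df, "fwhm": r.fwhm, "resels": r.resels,
            "t_star": r.t_star, "alpha": r.alpha,
            "n_clusters": len(r.clusters),
            "clusters": ";".join(f"{a:.1f}-{b:.1f}({'+' if s > 0 else '-'})"
                                 for a, b, s in r.clusters),
        })
    return pd.DataFrame.from_records(rows)


def plot_spm(result: SPMResult, ax=None):
    """t-curve with dashed +-t* lines and shaded suprathreshold clusters."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    x = np.linspace(0, 100, result.t_curve.size)
    ax.plot(x, result.t_curve, color="black", lw=1.2)
    ax.axhline(result.t_star, color="red", ls="--", lw=0.8)
    if result.two_tailed:
        ax.axhline(-result.t_star, color="red", ls="--", lw=0.8)
    for a, b, _ in result.clusters:
        ax.axvspan(a, b, color="0.8", zorder=0)
    ax.axhline(0, color="0.5", lw=0.5)
    ax.set_xlabel("movement time (%)")
    ax.set_ylabel("SPM{t}")
    ax.set_title(f"{result.comparison} ({result.quantity})", fontsize=8)
    return ax
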