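"""Participant-level aggregation and the inferential branch.

For each kinematic parameter the pipeline (mirroring the study's scheme):

1. aggregates retained trials to participant x (posture, environment,
   direction) cell means (16 cells per participant);
2. gates on normality — Shapiro-Wilk per cell, nonparametric branch if any
   of the 16 cells rejects at 0.05;
3. parametric branch: three-way repeated-measures ANOVA (posture x
   environment x direction, all within-participant), each effect tested
   against its own participant-interaction error term, partial eta squared
   effect sizes, Mauchly's sphericity test per multi-df effect and the
   Greenhouse-Geisser correction when sphericity is rejected;
   nonparametric branch: Friedman test over the 16 cells;
4. sixteen planned pairwise comparisons (8 environment contrasts, 8
   direction contrasts — vertical-vs-lateral pairs are never tested) with
   the Bonferroni-corrected per-test threshold 0.05 / 16 = 0.003125; paired
   t contrasts on the parametric branch, Wilcoxon signed-rank on the
   nonparametric branch.

The Wilcoxon signed-rank test drops zero differences and is exact (full
enumeration of the 2^n sign assignments, computed by dynamic programming
over the rank generating function) for n <= 25 pairs, switching to the
tie-corrected normal approximation with continuity correction above that —
so study-scale data (n = 27) use the approximation while small samples stay
exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space

from .kinematic_extraction import LANDMARK_COLUMNS
from .trajectory_io import StudyDesign

WILCOXON_EXACT_MAX_N = 25


class DegenerateDataError(ValueError):
    """Input data carry no usable variation for the requested test."""


@dataclass
class TestResult:
    """One inferential test outcome."""

    test: str
    statistic: float
    df: tuple
    p: float
    effect: str = ""
    eta_p2: float | None = None
    epsilon: float | None = None
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_applied: bool = False
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_cells(landmarks: pd.DataFrame,
                    parameters=tuple(LANDMARK_COLUMNS)) -> pd.DataFrame:
    """Participant x cell means of each landmark over retained trials.

    Returns a tidy table (participant, posture, environment, direction,
    parameter, value, n_trials).
    """
    keys = ["participant", "posture", "environment", "direction"]
    grouped = landmarks.groupby(keys, sort=True)
    means = grouped[list(parameters)].mean()
    counts = grouped.size().rename("n_trials")
    wide = means.join(counts).reset_index()
    tidy = wide.melt(id_vars=keys + ["n_trials"], value_vars=list(parameters),
                     var_name="parameter", value_name="value")
    return tidy[keys + ["parameter", "value", "n_trials"]]


def cell_matrix(cell_means: pd.DataFrame, parameter: str,
                design: StudyDesign | None = None,
                ) -> tuple[np.ndarray, list, list]:
    """(n_participants, n_cells) value matrix in canonical cell order.

    Raises if any participant is missing a cell (no imputation).
    """
    design = design or StudyDesign()
    cells = design.cells()
    sub = cell_means[cell_means["parameter"] == parameter]
    pivot = sub.pivot_table(index="participant",
                            columns=["posture", "environment", "direction"],
                            values="value", aggfunc="first")
    try:
        pivot = pivot[cells]
    except KeyError as exc:
        raise DegenerateDataError(f"missing condition cells: {exc}") from exc
    if pivot.isna().any().any():
        bad = pivot.index[pivot.isna().any(axis=1)].tolist()
        raise DegenerateDataError(
            f"participants with missing cells (no imputation): {bad}")
    return pivot.to_numpy(dtype=float), list(pivot.index), cells


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def shapiro_wilk(values: np.ndarray) -> TestResult:
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise DegenerateDataError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(values) == 0:
        raise DegenerateDataError("Shapiro-Wilk undefined for a constant vector")
    w, p = stats.shapiro(values)
    return TestResult(test="shapiro_wilk", statistic=float(w),
                      df=(values.size,), p=float(p))


def normality_gate(matrix: np.ndarray, cells: list,
                   alpha: float = 0.05) -> tuple[str, pd.DataFrame]:
    """Branch decision: 'nonparametric' iff any cell-wise Shapiro-Wilk test
    rejects at ``alpha``; per-cell W and p are returned for the log."""
    rows = []
    any_reject = False
    for j, cell in enumerate(cells):
        res = shapiro_wilk(matrix[:, j])
        reject = res.p < alpha
        any_reject = any_reject or reject
        rows.append({"posture": cell[0], "environment": cell[1],
                     "direction": cell[2], "W": res.statistic, "p": res.p,
                     "reject": reject})
    branch = "nonparametric" if any_reject else "parametric"
    return branch, pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# three-way repeated-measures ANOVA
# ---------------------------------------------------------------------------

_FACTORS = ("posture", "environment", "direction")


def _effect_terms(y: np.ndarray) -> dict[tuple, np.ndarray]:
    """Inclusion-exclusion decomposition of a fully crossed array.

    ``y`` has one axis per factor (subject first). Returns, for every
    non-empty axis subset F, the centered effect array u_F with
    y = grand_mean + sum_F u_F (broadcast).
    """
    axes = tuple(range(y.ndim))
    grand = y.mean()
    terms: dict[tuple, np.ndarray] = {}
    for r in range(1, len(axes) + 1):
        for subset in itertools.combinations(axes, r):
            comp = tuple(a for a in axes if a not in subset)
            eta = y.mean(axis=comp, keepdims=True) - grand
            for sub2 in terms:
                if set(sub2) < set(subset):
                    eta = eta - terms[sub2]
            terms[subset] = eta
    return terms


def _ss(y: np.ndarray, term: np.ndarray) -> float:
    # each distinct value of the (broadcast) term appears N / prod(kept dims)
    # times; summing the squared broadcast array over y's shape handles that
    return float(np.sum(np.broadcast_to(term, y.shape) ** 2))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Orthonormal (k-1, k) contrast rows spanning the mean-zero subspace."""
    c = null_space(np.ones((1, k))).T
    return c


def _effect_contrast(effect: tuple[str, ...], levels: dict[str, int]) -> np.ndarray:
    """Contrast matrix acting on the flattened cell vector (canonical
    posture x environment x direction order) for one within effect."""
    mats = []
    for f in _FACTORS:
        k = levels[f]
        if f in effect:
            mats.append(_orthonormal_contrasts(k))
        else:
            mats.append(np.full((1, k), 1.0 / k))
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def _sphericity(matrix: np.ndarray, effect: tuple[str, ...],
                levels: dict[str, int]) -> tuple[float, float, float]:
    """Greenhouse-Geisser epsilon and Mauchly's test for one effect.

    Returns (epsilon, mauchly_W, mauchly_p). Operates on the covariance of
    the orthonormal contrast scores Z = Y C'; epsilon =
    tr(S)^2 / (p * ||S||_F^2) with p = effect df.
    """
    C = _effect_contrast(effect, levels)
    Z = matrix @ C.T
    n, p = Z.shape
    S = np.cov(Z, rowvar=False)
    S = np.atleast_2d(S)
    tr = np.trace(S)
    if tr == 0 or np.sum(S ** 2) == 0:
        return 1.0, float("nan"), float("nan")
    eps = tr ** 2 / (p * np.sum(S ** 2))
    eps = float(np.clip(eps, 1.0 / p, 1.0))
    # Mauchly's W with the chi-square approximation
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or n - 1 <= p:
        return eps, float("nan"), float("nan")
    log_w = logdet - p * np.log(tr / p)
    d = 1.0 - (2.0 * p ** 2 + p + 2.0) / (6.0 * p * (n - 1))
    chi2 = -(n - 1) * d * log_w
    df_chi = p * (p + 1) / 2.0 - 1.0
    p_mauchly = float(stats.chi2.sf(chi2, df_chi))
    return eps, float(np.exp(log_w)), p_mauchly


def rm_anova_3way(matrix: np.ndarray,
                  design: StudyDesign | None = None,
                  sphericity_alpha: float = 0.05) -> list[TestResult]:
    """Three-way fully-within-participant ANOVA on an (n, 16) cell matrix.

    Seven effects (3 mains, 3 two-way, 1 three-way); each F-ratio uses the
    effect-by-participant interaction as its error term. For effects with
    more than 1 df, Mauchly's test is run and the Greenhouse-Geisser
    correction multiplies both degrees of freedom whenever Mauchly rejects
    at ``sphericity_alpha``.
    """
    design = design or StudyDesign()
    levels = {"posture": len(design.postures),
              "environment": len(design.environments),
              "direction": len(design.directions)}
    n = matrix.shape[0]
    if n < 2:
        raise DegenerateDataError("RM-ANOVA needs at least 2 participants")
    if matrix.shape[1] != np.prod(list(levels.values())):
        raise DegenerateDataError("cell matrix does not match the design")
    y = matrix.reshape(n, levels["posture"], levels["environment"],
                       levels["direction"])
    terms = _effect_terms(y)
    axis_of = {"posture": 1, "environment": 2, "direction": 3}
    # numerical zero: SS this far below the total variation is roundoff
    ss_tol = 1e-12 * float(np.sum((y - y.mean()) ** 2))

    results = []
    for r in range(1, 4):
        for effect in itertools.combinations(_FACTORS, r):
            eff_axes = tuple(sorted(axis_of[f] for f in effect))
            err_axes = tuple(sorted((0,) + eff_axes))
            ss_eff = _ss(y, terms[eff_axes])
            ss_err = _ss(y, terms[err_axes])
            if ss_eff < ss_tol:
                ss_eff = 0.0
            if ss_err < ss_tol:
                ss_err = 0.0
            df1 = int(np.prod([levels[f] - 1 for f in effect]))
            df2 = df1 * (n - 1)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            if ms_err == 0:
                F = 0.0 if ms_eff == 0 else float("inf")
            else:
                F = ms_eff / ms_err
            eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0

            eps = mw = mp = None
            gg = False
            d1, d2 = float(df1), float(df2)
            if df1 > 1:
                eps, mw, mp = _sphericity(matrix, effect, levels)
                if np.isfinite(mp) and mp < sphericity_alpha:
                    gg = True
                    d1, d2 = df1 * eps, df2 * eps
            p = float(stats.f.sf(F, d1, d2)) if np.isfinite(F) else 0.0
            if F == 0.0:
                p = 1.0
            results.append(TestResult(
                test="rm_anova_effect", effect=" x ".join(effect),
                statistic=float(F), df=(d1, d2), p=p, eta_p2=float(eta),
                epsilon=eps, mauchly_w=mw, mauchly_p=mp, gg_applied=gg,
                extra={"SS_effect": ss_eff, "SS_error": ss_err,
                       "uncorrected_df": (df1, df2)}))
    return results


def anova_table(results: list[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "effect": r.effect, "SS": r.extra.get("SS_effect"),
            "SS_error": r.extra.get("SS_error"), "df1": r.df[0],
            "df2": r.df[1], "F": r.statistic, "p": r.p, "eta_p2": r.eta_p2,
            "epsilon": r.epsilon if r.epsilon is not None else "",
            "gg_applied": r.gg_applied,
        })
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# nonparametric branch
# ---------------------------------------------------------------------------

def friedman(matrix: np.ndarray) -> TestResult:
    """Friedman chi-square over the condition columns of an (n, k) matrix,
    average ranks for ties, asymptotic chi-square(k-1) p-value."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise DegenerateDataError("Friedman needs >= 2 rows and >= 2 columns")
    if np.all(np.ptp(matrix, axis=1) == 0):
        # every participant's row is constant: ranks carry no information
        return TestResult(test="friedman", statistic=0.0, df=(k - 1,), p=1.0)
    stat, p = stats.friedmanchisquare(*(matrix[:, j] for j in range(k)))
    return TestResult(test="friedman", statistic=float(stat), df=(k - 1,),
                      p=float(p))


def _signed_rank_pmf(double_ranks: np.ndarray) -> np.ndarray:
    """Exact pmf of W+ (on the doubled-rank integer grid) over all 2^n sign
    assignments, by dynamic programming over the generating function."""
    total = int(double_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:total + 1 - r]
        pmf = pmf + shifted
    return pmf / pmf.sum()


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None,
                         exact_max_n: int = WILCOXON_EXACT_MAX_N) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or on a
    difference vector if ``y`` is None). Zero differences are dropped."""
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= exact_max_n:
        dr = np.round(2 * ranks).astype(int)   # doubled ranks are integers
        pmf = _signed_rank_pmf(dr)
        grid = np.arange(pmf.size)             # doubled-rank scale
        w2 = int(round(2 * w_plus))
        mu2 = dr.sum() / 2.0
        p = float(pmf[np.abs(grid - mu2) >= abs(w2 - mu2) - 1e-9].sum())
        method = "exact"
        z = float("nan")
    else:
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if sigma2 <= 0:
            raise DegenerateDataError("zero variance in signed ranks")
        diff = w_plus - mu
        cc = 0.5 * np.sign(diff)               # continuity correction
        z = (diff - cc) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal_approx"
    return TestResult(test="wilcoxon_signed_rank", statistic=w_plus,
                      df=(n,), p=min(p, 1.0),
                      extra={"method": method, "z": z})


# ---------------------------------------------------------------------------
# planned comparisons
# ---------------------------------------------------------------------------

def planned_pairs(design: StudyDesign | None = None) -> list[dict]:
    """The 16 planned pairs: 8 environment contrasts (same posture and
    direction, virtual vs physical) then 8 direction contrasts (up vs down,
    right vs left, within each posture x environment). Vertical-vs-lateral
    pairs are deliberately absent."""
    design = design or StudyDesign()
    postures = design.postures
    pairs = []
    pid = 1
    for posture in postures:
        for direction in ("up", "down", "right", "left"):
            pairs.append({
                "pair_id": pid, "family": "environment",
                "cell_a": (posture, "virtual", direction),
                "cell_b": (posture, "physical", direction)})
            pid += 1
    for posture in postures:
        for environment in design.environments:
            pairs.append({
                "pair_id": pid, "family": "direction",
                "cell_a": (posture, environment, "up"),
                "cell_b": (posture, environment, "down")})
            pid += 1
            pairs.append({
                "pair_id": pid, "family": "direction",
                "cell_a": (posture, environment, "right"),
                "cell_b": (posture, environment, "left")})
            pid += 1
    return pairs


def corrected_threshold(alpha: float = 0.05,
                        n_comparisons: int = 16) -> float:
    """Bonferroni per-test threshold for the planned-comparison family."""
    return alpha / n_comparisons


def planned_comparisons(matrix: np.ndarray, cells: list, branch: str,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Run the 16 planned pairwise tests on an (n, 16) cell matrix.

    Parametric branch: paired t contrasts on the cell means; nonparametric
    branch: Wilcoxon signed-rank. The significance flag compares the raw p
    against the Bonferroni-corrected threshold alpha / 16.
    """
    pairs = planned_pairs()
    threshold = corrected_threshold(alpha, len(pairs))
    index = {cell: j for j, cell in enumerate(cells)}
    rows = []
    for pair in pairs:
        a = matrix[:, index[pair["cell_a"]]]
        b = matrix[:, index[pair["cell_b"]]]
        if branch == "nonparametric":
            try:
                res = wilcoxon_signed_rank(a, b)
                stat, p = res.statistic, res.p
                test = "wilcoxon_signed_rank"
            except DegenerateDataError:
                stat, p, test = 0.0, 1.0, "wilcoxon_signed_rank"
        else:
            t, p = stats.ttest_rel(a, b)
            stat, p, test = float(t), float(p), "paired_t"
        rows.append({
            "pair_id": pair["pair_id"], "family": pair["family"],
            "cell_a": "-".join(pair["cell_a"]),
            "cell_b": "-".join(pair["cell_b"]),
            "test": test, "statistic": stat, "p": p,
            "threshold": threshold, "significant": bool(p < threshold),
        })
    return pd.DataFrame.from_records(rows)


def simple_main_effects_posture_direction(matrix: np.ndarray, cells: list,
                                          alpha: float = 0.05) -> pd.DataFrame:
    """Follow-up contrasts for a posture x direction interaction: up-vs-down
    and right-vs-left paired t contrasts within each posture, collapsed over
    environment, Bonferroni-corrected within the family of 4."""
    cell_idx = {c: j for j, c in enumerate(cells)}
    postures = sorted({c[0] for c in cells}, key=[c[0] for c in cells].index)
    environments = sorted({c[1] for c in cells}, key=[c[1] for c in cells].index)
    rows = []
    threshold = alpha / 4.0
    for posture in postures:
        for d1, d2 in (("up", "down"), ("right", "left")):
            a = np.mean([matrix[:, cell_idx[(posture, e, d1)]]
                         for e in environments], axis=0)
            b = np.mean([matrix[:, cell_idx[(posture, e, d2)]]
                         for e in environments], axis=0)
            t, p = stats.ttest_rel(a, b)
            rows.append({"posture": posture, "contrast": f"{d1}-vs-{d2}",
                         "t": float(t), "p": float(p),
                         "threshold": threshold,
                         "significant": bool(p < threshold)})
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# per-parameter orchestration
# ---------------------------------------------------------------------------

def analyze_parameter(cell_means: pd.DataFrame, parameter: str,
                      design: StudyDesign | None = None,
                      alpha: float = 0.05) -> dict:
    """Gate, omnibus test and planned comparisons for one landmark."""
    design = design or StudyDesign()
    matrix, participants, cells = cell_matrix(cell_means, parameter, design)
    branch, gate_table = normality_gate(matrix, cells, alpha)
    out = {"parameter": parameter, "branch": branch, "gate": gate_table,
           "participants": participants}
    if branch == "parametric":
        out["anova"] = rm_anova_3way(matrix, design)
        out["anova_table"] = anova_table(out["anova"])
    else:
        out["friedman"] = friedman(matrix)
    out["comparisons"] = planned_comparisons(matrix, cells, branch, alpha)
    return out
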