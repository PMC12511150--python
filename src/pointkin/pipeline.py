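"""End-to-end orchestration: trials -> landmarks -> statistics -> SPM."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import condition_statistics as cstats
from . import kinematic_extraction as kx
from . import spm_timeseries as spm
from .trajectory_io import AnalysisConfig, StudyDesign


def run_landmark_analysis(trials, design: StudyDesign | None = None,
                          config: AnalysisConfig | None = None,
                          keep_series: bool = False) -> dict:
    """Extraction + exclusion + aggregation for a trial collection."""
    design = design or StudyDesign()
    config = config or AnalysisConfig()
    landmarks, series = kx.analyze_trials(trials, config,
                                          keep_series=keep_series)
    retained, exclusion_log = kx.exclude_trials(landmarks,
                                                config.md_outlier_sd)
    cell_means = cstats.aggregate_cells(retained)
    return {
        "landmarks": landmarks, "retained": retained,
        "exclusion_log": exclusion_log, "cell_means": cell_means,
        "series": series, "design": design, "config": config,
    }


def run_statistics(cell_means: pd.DataFrame,
                   design: StudyDesign | None = None,
                   parameters=tuple(kx.LANDMARK_COLUMNS),
                   alpha: float = 0.05) -> dict:
    """Gate + omnibus + planned comparisons for every landmark parameter."""
    design = design or StudyDesign()
    results = {}
    for parameter in parameters:
        results[parameter] = cstats.analyze_parameter(cell_means, parameter,
                                                      design, alpha)
    return results


def comparison_summary(stats_results: dict) -> pd.DataFrame:
    frames = []
    for parameter, res in stats_results.items():
        frame = res["comparisons"].copy()
        frame.insert(0, "parameter", parameter)
        frame.insert(1, "branch", res["branch"])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_spm_analysis(analysis: dict, quantities=("speed", "acceleration"),
                     alpha: float = 0.05) -> list:
    """Planned SPM{t} comparisons on participant cell-mean profiles for each
    requested quantity (16 results per quantity)."""
    design = analysis["design"]
    config = analysis["config"]
    results = []
    for quantity in quantities:
        profiles, _, cells = spm.participant_cell_profiles(
            analysis["retained"], analysis["series"], quantity,
            config.n_nodes, design)
        results.extend(spm.run_spm_comparisons(profiles, cells, quantity,
                                               alpha, config.two_tailed))
    return results


def analysis_log(analysis: dict, stats_results: dict,
                 seed: int | None = None) -> list[str]:
    lines = []
    if seed is not None:
        lines.append(f"seed: {seed}")
    n_total = len(analysis["landmarks"])
    n_kept = len(analysis["retained"])
    lines.append(f"trials analyzed: {n_total}")
    lines.append(f"trials retained: {n_kept}")
    for row in analysis["exclusion_log"].itertuples(index=False):
        stat = "" if not np.isfinite(row.statistic) else f" (MD={row.statistic:.4f} s)"
        lines.append(f"excluded [{row.rule}] {row.participant} {row.posture}-"
                     f"{row.environment}-{row.direction} block {row.block} "
                     f"trial {row.trial}{stat}")
    for parameter, res in stats_results.items():
        lines.append(f"{parameter}: branch={res['branch']}")
        if res["branch"] == "nonparametric":
            fr = res["friedman"]
            lines.append(f"{parameter}: friedman chi2={fr.statistic:.3f} "
                         f"df={fr.df[0]} p={fr.p:.4g}")
        else:
            for eff in res["anova"]:
                gg = " (GG)" if eff.gg_applied else ""
                lines.append(
                    f"{parameter}: {eff.effect} F({eff.df[0]:.3g},"
                    f"{eff.df[1]:.3g})={eff.statistic:.3f} p={eff.p:.4g} "
                    f"eta_p2={eff.eta_p2:.3f}{gg}")
    return lines
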