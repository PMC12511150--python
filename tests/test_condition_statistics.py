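"""Aggregation, normality gate, RM-ANOVA, Friedman, Wilcoxon and the 16
planned comparisons — each checked against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pointkin.condition_statistics import (DegenerateDataError,
                                           aggregate_cells, analyze_parameter,
                                           cell_matrix, corrected_threshold,
                                           friedman, normality_gate,
                                           planned_comparisons, planned_pairs,
                                           rm_anova_3way, shapiro_wilk,
                                           wilcoxon_signed_rank)
from pointkin.condition_statistics import (_sphericity,
                                           simple_main_effects_posture_direction)
from pointkin.trajectory_io import StudyDesign

DESIGN = StudyDesign()
CELLS = DESIGN.cells()


def _random_cell_matrix(rng, n, effects=None):
    mat = rng.normal(50.0, 4.0, (n, 16))
    if effects is not None:
        mat = mat + effects
    return mat


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregateCells:
    def test_single_trial_cell_mean_is_that_value(self):
        lm = pd.DataFrame({
            "participant": ["P1"], "posture": ["upright"],
            "environment": ["virtual"], "direction": ["up"],
            "block": [1], "trial": [1],
            **{c: [float(i)] for i, c in enumerate(
                ("MD", "PV", "PA", "PD", "rDPV", "rDPA", "rDPD"))},
        })
        tidy = aggregate_cells(lm)
        assert tidy.loc[tidy["parameter"] == "rDPV", "value"].item() == 4.0
        assert (tidy["n_trials"] == 1).all()

    def test_full_study_has_16_cells_per_participant(self, default_analysis):
        cm = default_analysis["cell_means"]
        per = cm.groupby(["participant", "parameter"]).size()
        assert (per == 16).all()
        assert cm["parameter"].nunique() == 7

    def test_permutation_invariance(self, small_analysis):
        retained = small_analysis["retained"]
        shuffled = retained.sample(frac=1.0, random_state=5)
        a = aggregate_cells(retained).reset_index(drop=True)
        b = aggregate_cells(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

class TestNormalityGate:
    def test_shapiro_type_one_calibration(self):
        rng = np.random.default_rng(8)
        rejections = sum(shapiro_wilk(rng.standard_normal(500)).p < 0.05
                         for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_shapiro_power_on_skewed_data(self):
        rng = np.random.default_rng(9)
        hits = sum(shapiro_wilk(rng.exponential(1.0, 500)).p < 0.001
                   for _ in range(200))
        assert hits >= 198

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk(np.full(30, 1.0))

    def test_gaussian_cells_pass_gate_often_enough(self):
        # 16 tests at alpha 0.05 => family pass rate ~ 0.95^16 ~ 0.44
        rng = np.random.default_rng(10)
        parametric = sum(
            normality_gate(_random_cell_matrix(rng, 27), CELLS)[0]
            == "parametric" for _ in range(300))
        assert parametric / 300 >= 0.40

    def test_one_lognormal_cell_trips_the_gate(self):
        rng = np.random.default_rng(11)
        trips = 0
        for _ in range(100):
            mat = _random_cell_matrix(rng, 27)
            mat[:, 3] = rng.lognormal(1.0, 1.0, 27)
            trips += normality_gate(mat, CELLS)[0] == "nonparametric"
        assert trips >= 99

    def test_gate_is_deterministic(self):
        mat = _random_cell_matrix(np.random.default_rng(12), 27)
        assert normality_gate(mat, CELLS)[0] == normality_gate(mat, CELLS)[0]


# ---------------------------------------------------------------------------
# three-way RM-ANOVA
# ---------------------------------------------------------------------------

def _projection_oracle(mat):
    """Brute-force SS decomposition via explicit orthogonal projections."""
    n = mat.shape[0]
    y = mat.reshape(-1)                      # subject-major, cell order p,e,d
    k = {"s": n, "p": 2, "e": 2, "d": 4}

    def contrasts(m):
        from scipy.linalg import null_space
        return null_space(np.ones((1, m)))   # m x (m-1), orthonormal

    def ones(m):
        return np.ones((m, 1)) / np.sqrt(m)

    def basis(effect):
        cols = []
        for f in ("s", "p", "e", "d"):
            cols.append(contrasts(k[f]) if f in effect else ones(k[f]))
        X = cols[0]
        for c in cols[1:]:
            X = np.kron(X, c)
        return X

    ss = {}
    for r in range(1, 5):
        for eff in itertools.combinations(("s", "p", "e", "d"), r):
            X = basis(eff)
            proj = X @ (X.T @ y)             # orthonormal basis
            ss[eff] = float(proj @ proj)
    return ss


class TestRmAnova:
    def test_zero_variation_gives_f_zero_p_one(self):
        mat = np.tile(np.random.default_rng(0).normal(50, 3, (27, 1)),
                      (1, 16))
        for res in rm_anova_3way(mat, DESIGN):
            assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_projection_oracle_n5(self):
        rng = np.random.default_rng(13)
        mat = _random_cell_matrix(rng, 5, effects=np.linspace(0, 4, 16))
        ss = _projection_oracle(mat)
        axis = {"posture": "p", "environment": "e", "direction": "d"}
        results = rm_anova_3way(mat, DESIGN)
        for res in results:
            eff = tuple(axis[f] for f in res.effect.split(" x "))
            err = tuple(f for f in ("s", "p", "e", "d")
                         if f in ("s",) + eff)
            ss_eff, ss_err = ss[eff], ss[err]
            assert res.extra["SS_effect"] == pytest.approx(ss_eff, rel=1e-9)
            assert res.extra["SS_error"] == pytest.approx(ss_err, rel=1e-9)
            df1, df2 = res.extra["uncorrected_df"]
            f_oracle = (ss_eff / df1) / (ss_err / df2)
            assert res.statistic == pytest.approx(f_oracle, rel=1e-9)
            assert res.eta_p2 == pytest.approx(
                ss_eff / (ss_eff + ss_err), rel=1e-9)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(14)
        mat = _random_cell_matrix(rng, 6, effects=np.linspace(0, 3, 16))
        rows = [{"subj": s, "posture": p, "env": e, "dir": d,
                 "y": mat[s, j]}
                for s in range(6) for j, (p, e, d) in enumerate(CELLS)]
        table = AnovaRM(pd.DataFrame(rows), "y", "subj",
                        within=["posture", "env", "dir"]).fit().anova_table
        name_map = {"posture": "posture", "env": "environment",
                    "dir": "direction"}
        mine = {r.effect: r for r in rm_anova_3way(mat, DESIGN)}
        for sm_name, row in table.iterrows():
            effect = " x ".join(name_map[p] for p in sm_name.split(":"))
            assert mine[effect].statistic == pytest.approx(row["F Value"],
                                                           rel=1e-8)
            assert mine[effect].extra["uncorrected_df"] == (
                int(row["Num DF"]), int(row["Den DF"]))

    def test_ss_decomposition_conserves_total(self):
        rng = np.random.default_rng(15)
        mat = _random_cell_matrix(rng, 8)
        ss = _projection_oracle(mat)
        total = float(np.sum((mat - mat.mean()) ** 2))
        assert sum(ss.values()) == pytest.approx(total, rel=1e-9)

    def test_direction_df_is_3_by_3n_minus_1(self):
        mat = _random_cell_matrix(np.random.default_rng(16), 27)
        res = {r.effect: r for r in rm_anova_3way(mat, DESIGN)}
        assert res["direction"].extra["uncorrected_df"] == (3, 78)

    def test_epsilon_matches_pingouin_and_bounds(self):
        import pingouin as pg
        rng = np.random.default_rng(17)
        mat = _random_cell_matrix(rng, 9)
        levels = {"posture": 2, "environment": 2, "direction": 4}
        eps, w, _ = _sphericity(mat, ("direction",), levels)
        collapsed = mat.reshape(9, 2, 2, 4).mean(axis=(1, 2))
        rows = [{"s": s, "dir": d, "y": collapsed[s, d]}
                for s in range(9) for d in range(4)]
        df = pd.DataFrame(rows)
        eps_pg = pg.epsilon(df, dv="y", subject="s", within="dir",
                            correction="gg")
        spher = pg.sphericity(df, dv="y", subject="s", within="dir")
        assert eps == pytest.approx(float(eps_pg), rel=1e-9)
        assert w == pytest.approx(float(spher.W), rel=1e-9)
        assert 1.0 / 3.0 <= eps <= 1.0

    def test_gg_correction_applied_under_nonsphericity(self):
        # strongly heteroscedastic direction levels violate sphericity
        rng = np.random.default_rng(18)
        base = rng.normal(0, 1, (27, 1))
        mat = np.zeros((27, 16))
        for j, (p, e, d) in enumerate(CELLS):
            scale = {"up": 0.05, "down": 8.0, "left": 0.05,
                     "right": 0.1}[d]
            mat[:, j] = 50 + base[:, 0] + rng.normal(0, scale, 27)
        res = {r.effect: r for r in rm_anova_3way(mat, DESIGN)}
        direction = res["direction"]
        assert direction.mauchly_p < 0.05 and direction.gg_applied
        df1, df2 = direction.df
        assert df1 == pytest.approx(3 * direction.epsilon)
        assert df2 == pytest.approx(78 * direction.epsilon)

    def test_missing_cells_refused(self):
        cm = pd.DataFrame({
            "participant": ["P1"], "posture": ["upright"],
            "environment": ["virtual"], "direction": ["up"],
            "parameter": ["rDPV"], "value": [50.0], "n_trials": [1]})
        with pytest.raises(DegenerateDataError):
            cell_matrix(cm, "rDPV", DESIGN)


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

class TestFriedman:
    def test_constant_rows_give_zero_statistic(self):
        res = friedman(np.full((5, 16), 3.0))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_concordant_toy_matrix_matches_exact_enumeration(self):
        # n=4, k=3, all rows rank-concordant: exact null p from all (3!)^4
        # rank permutations vs the chi-square asymptotic
        X = np.array([[1.0, 2.0, 3.0],
                      [1.1, 2.2, 3.1],
                      [0.9, 2.1, 2.9],
                      [1.3, 2.4, 3.3]])
        res = friedman(X)
        perms = list(itertools.permutations(range(3)))
        null = []
        for combo in itertools.product(perms, repeat=4):
            Xp = np.vstack([X[i, list(combo[i])] for i in range(4)])
            null.append(friedman(Xp).statistic)
        p_exact = np.mean(np.asarray(null) >= res.statistic - 1e-9)
        assert res.statistic == pytest.approx(8.0)
        assert p_exact == pytest.approx(6 / 1296)
        assert abs(res.p - p_exact) < 0.02

    def test_rank_invariance_to_row_shifts(self):
        rng = np.random.default_rng(19)
        X = rng.normal(0, 1, (10, 16))
        Y = X.copy()
        Y[3] += 100.0
        assert friedman(X).statistic == pytest.approx(friedman(Y).statistic)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(20)
        X = rng.normal(0, 1, (10, 16))
        assert friedman(np.exp(X)).statistic == pytest.approx(
            friedman(X).statistic)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _wilcoxon_brute(d):
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    ws = np.array([np.asarray(signs) @ ranks
                   for signs in itertools.product([0, 1], repeat=n)])
    return float(np.mean(np.abs(ws - mu) >= abs(w - mu) - 1e-9))


class TestWilcoxon:
    def test_antisymmetric_multiset_gives_p_one(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0, 2.0, -2.0]))
        assert res.p == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for n in (6, 9, 12):
            d = rng.normal(0.4, 1.0, n)
            res = wilcoxon_signed_rank(d)
            assert res.extra["method"] == "exact"
            assert res.p == pytest.approx(_wilcoxon_brute(d), abs=1e-12)

    def test_exact_p_with_ties_matches_enumeration(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, -2.0, 3.0, 0.5])
        assert wilcoxon_signed_rank(d).p == pytest.approx(_wilcoxon_brute(d),
                                                          abs=1e-12)

    def test_agrees_with_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.5, 1.0, 10)
        assert wilcoxon_signed_rank(d).p == pytest.approx(
            stats.wilcoxon(d, method="exact").pvalue, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(np.zeros(10))

    def test_null_calibration_at_bonferroni_level(self):
        # n=27 pairs (normal-approximation regime), per-test alpha 0.003125
        rng = np.random.default_rng(22)
        alpha = corrected_threshold(0.05, 16)
        rejects = sum(
            wilcoxon_signed_rank(rng.standard_normal(27)).p < alpha
            for _ in range(10000))
        assert rejects / 10000 <= 0.004

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(23)
        a = rng.normal(5, 1, 12)
        b = rng.normal(5, 1, 12)
        # strictly monotone transform applied to both sides preserves the
        # sign and rank structure of paired differences only if applied to
        # the differences; check the rank property on differences directly
        d = a - b
        assert wilcoxon_signed_rank(np.sign(d) * np.abs(d) ** 3).p == \
            pytest.approx(wilcoxon_signed_rank(d).p, abs=1e-12)


# ---------------------------------------------------------------------------
# planned comparisons
# ---------------------------------------------------------------------------

class TestPlannedComparisons:
    def test_exactly_16_pairs_partitioned_8_and_8(self):
        pairs = planned_pairs(DESIGN)
        assert len(pairs) == 16
        fams = [p["family"] for p in pairs]
        assert fams.count("environment") == 8
        assert fams.count("direction") == 8
        for p in pairs:
            vertical = {"up", "down"}
            a, b = p["cell_a"][2], p["cell_b"][2]
            # vertical-vs-lateral contrasts are never produced
            assert not ((a in vertical) ^ (b in vertical))

    def test_bonferroni_threshold_is_exact(self):
        assert corrected_threshold(0.05, 16) == 0.003125
        rng = np.random.default_rng(24)
        table = planned_comparisons(_random_cell_matrix(rng, 27), CELLS,
                                    "nonparametric")
        assert (table["threshold"] == 0.003125).all()
        assert len(table) == 16
        assert (table["significant"] == (table["p"] < 0.003125)).all()

    def test_parametric_branch_uses_paired_t(self):
        rng = np.random.default_rng(25)
        mat = _random_cell_matrix(rng, 27)
        table = planned_comparisons(mat, CELLS, "parametric")
        assert (table["test"] == "paired_t").all()
        # spot-check row 1 against scipy directly
        row = table.iloc[0]
        a = mat[:, CELLS.index(("upright", "virtual", "up"))]
        b = mat[:, CELLS.index(("upright", "physical", "up"))]
        t, p = stats.ttest_rel(a, b)
        assert row["statistic"] == pytest.approx(t)
        assert row["p"] == pytest.approx(p)

    def test_simple_main_effects_flag_direction_within_posture(self):
        rng = np.random.default_rng(27)
        mat = _random_cell_matrix(rng, 27)
        for j, (p, e, d) in enumerate(CELLS):
            mat[:, j] += {"up": -3.0, "down": 3.0}.get(d, 0.0)
        table = simple_main_effects_posture_direction(mat, CELLS)
        assert len(table) == 4
        assert (table["threshold"] == 0.05 / 4).all()
        updown = table[table["contrast"] == "up-vs-down"]
        assert updown["significant"].all()
        assert not table[table["contrast"] == "right-vs-left"][
            "significant"].any()

    def test_null_familywise_rate_bounded(self):
        # Bonferroni guarantee over the 16-test family (cell-mean level)
        rng = np.random.default_rng(26)
        fw = sum(planned_comparisons(_random_cell_matrix(rng, 27), CELLS,
                                     "parametric")["significant"].any()
                 for _ in range(400))
        assert fw / 400 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 400)


# ---------------------------------------------------------------------------
# per-parameter orchestration
# ---------------------------------------------------------------------------

class TestAnalyzeParameter:
    def test_full_branch_output_structure(self, default_analysis):
        res = analyze_parameter(default_analysis["cell_means"], "rDPV",
                                DESIGN)
        assert res["branch"] in ("parametric", "nonparametric")
        assert len(res["comparisons"]) == 16
        assert len(res["gate"]) == 16
        if res["branch"] == "parametric":
            assert len(res["anova"]) == 7
        else:
            assert res["friedman"].df == (15,)
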