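import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from vrepm import (
    MixedAnova,
    PowerSpec,
    ReliabilityModel,
    icc_consistency,
    paired_t,
    pearson_matrix,
    power_paired_t,
    required_n_paired_t,
    rm_anova,
)
from vrepm.errors import DesignError, InsufficientDataError


def long_table(y, factor="occ"):
    n, k = y.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n), k),
            factor: np.tile(np.arange(k), n),
            "v": y.flatten(),
        }
    )


# ---------------------------------------------------------------------------
# Pearson matrix
# ---------------------------------------------------------------------------

class TestPearsonMatrix:
    def make_table(self, rng, n=10):
        rows = []
        for i in range(n):
            a = rng.normal(50, 10)
            for e in (1, 2):
                rows.append(
                    {"participant_id": f"P{i}", "exposure": e,
                     "m1": a + rng.normal(0, 2), "m2": 2 * a + 1}
                )
        return pd.DataFrame(rows)

    def test_unit_diagonal_and_symmetry(self, rng):
        mat = pearson_matrix(self.make_table(rng), ["m1", "m2"])
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)

    def test_perfect_linear_relation(self, rng):
        mat = pearson_matrix(self.make_table(rng), ["m1", "m2"])
        # m2 is exactly 2*a+1 at both exposures -> r = 1 between exposures
        assert mat.loc["m2_1", "m2_2"] == pytest.approx(1.0)

    def test_matches_covariance_definition(self, rng):
        table = self.make_table(rng)
        mat = pearson_matrix(table, ["m1"])
        w = table.pivot(index="participant_id", columns="exposure", values="m1")
        x, y = w[1].to_numpy(), w[2].to_numpy()
        r = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert mat.loc["m1_1", "m1_2"] == pytest.approx(r)

    def test_constant_column_is_nan(self, rng):
        t = self.make_table(rng)
        t["m1"] = 3.0
        mat = pearson_matrix(t, ["m1", "m2"])
        assert math.isnan(mat.loc["m1_1", "m2_1"])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    def test_duplicated_occasion_gives_one(self, rng):
        x = rng.normal(50, 10, 8)
        r = icc_consistency(np.column_stack([x, x]))
        assert r.estimate == pytest.approx(1.0)

    def test_constant_shift_invariance(self, rng):
        x = rng.normal(50, 10, 8)
        r = icc_consistency(np.column_stack([x, x + 7.5]))
        assert r.estimate == pytest.approx(1.0)

    def test_hand_computed_mean_squares(self):
        # crafted 8-subject table; oracle = from-scratch two-way decomposition
        y = np.array(
            [[10.0, 12.0], [14.0, 15.0], [9.0, 11.0], [20.0, 19.0],
             [13.0, 16.0], [8.0, 7.0], [17.0, 18.0], [11.0, 14.0]]
        )
        n, k = y.shape
        grand = y.mean()
        ss_rows = sum(k * (row.mean() - grand) ** 2 for row in y)
        ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
        ss_tot = sum((v - grand) ** 2 for v in y.flatten())
        ms_rows = ss_rows / (n - 1)
        ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        expect = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        r = icc_consistency(y)
        assert r.estimate == pytest.approx(expect, abs=1e-9)
        assert r.ms_between == pytest.approx(ms_rows, abs=1e-9)
        assert r.ms_error == pytest.approx(ms_err, abs=1e-9)

    def test_matches_pingouin_icc3(self, rng):
        y = rng.normal(50, 10, (12, 2))
        y[:, 1] = 0.7 * y[:, 0] + rng.normal(0, 5, 12)
        mine = icc_consistency(y)
        df = long_table(y)
        ref = pg.intraclass_corr(df, "participant_id", "occ", "v").set_index("Type")
        icc3 = ref.loc["ICC(C,1)"]
        assert mine.estimate == pytest.approx(icc3["ICC"], abs=1e-10)
        lo, hi = icc3["CI95"]
        assert mine.ci_low == pytest.approx(lo, abs=0.01)
        assert mine.ci_high == pytest.approx(hi, abs=0.01)

    def test_ci_brackets_estimate(self, rng):
        y = rng.normal(0, 1, (15, 2))
        y[:, 1] += 0.5 * y[:, 0]
        r = icc_consistency(y)
        assert r.ci_low <= r.estimate <= r.ci_high <= 1.0

    def test_agrees_with_pearson_asymptotically(self, rng):
        # equal occasion means/variances: ICC ~ r on large cohorts
        n = 4000
        x = rng.normal(0, 1, n)
        y1 = x + rng.normal(0, 1, n)
        y2 = x + rng.normal(0, 1, n)
        r = icc_consistency(np.column_stack([y1, y2]))
        assert r.estimate == pytest.approx(np.corrcoef(y1, y2)[0, 1], abs=0.02)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InsufficientDataError):
            icc_consistency(np.ones((3, 2)))


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_identical_vectors(self, rng):
        x = rng.normal(0, 1, 10)
        r = paired_t(x, x.copy())
        assert r.t == 0.0 and r.p == 1.0 and r.degenerate

    def test_constant_nonzero_difference_degenerate(self, rng):
        x = rng.normal(0, 1, 10)
        r = paired_t(x + 2.0, x)
        assert r.degenerate and math.isinf(r.t)

    def test_matches_longhand_formula(self, rng):
        x = rng.normal(5, 2, 10)
        y = rng.normal(4, 2, 10)
        d = x - y
        t_expect = d.mean() / (d.std(ddof=1) / math.sqrt(10))
        r = paired_t(x, y)
        assert r.t == pytest.approx(t_expect, abs=1e-12)
        assert r.df == 9
        ref = pg.ttest(x, y, paired=True)
        assert r.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


# ---------------------------------------------------------------------------
# split-plot repeated-measures ANOVA
# ---------------------------------------------------------------------------

class TestMixedAnova:
    def test_two_level_within_reproduces_paired_t(self, rng):
        y = rng.normal(10, 3, (12, 2))
        res = rm_anova(long_table(y), "v", ["occ"])
        t = paired_t(y[:, 0], y[:, 1])
        row = res.table.loc["occ"]
        assert row["F"] == pytest.approx(t.t**2, abs=1e-6)
        assert row["eps"] == 1.0  # single-df effect needs no correction
        assert row["p_GG"] == pytest.approx(t.p, abs=1e-10)

    def test_equal_cell_means_give_zero_f(self, rng):
        subj = rng.normal(0, 5, (8, 1))
        y = subj + rng.normal(0, 1, (8, 3))
        y -= y.mean(axis=0)  # force exactly equal cell means, keep noise
        res = rm_anova(long_table(y), "v", ["occ"])
        assert res.table.loc["occ", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_split_plot_matches_hand_computation(self, rng):
        # 6 subjects, 3-level within, 2 balanced groups; classical formulas
        n, a = 6, 3
        groups = np.array(["A"] * 3 + ["B"] * 3)
        y = rng.normal(0, 1, (n, a)) + rng.normal(0, 1, (n, 1))
        y[groups == "B"] += 0.8
        y += np.array([0.0, 0.5, 1.0])
        df = long_table(y, factor="time")
        df["grp"] = np.repeat(groups, a)
        res = rm_anova(df, "v", ["time"], "grp").table

        grand = y.mean()
        subj_means = y.mean(axis=1)
        grp_means = {g: y[groups == g].mean() for g in "AB"}
        time_means = y.mean(axis=0)
        ss_between_subj = a * sum((m - grand) ** 2 for m in subj_means)
        ss_grp = a * 3 * sum((grp_means[g] - grand) ** 2 for g in "AB")
        ss_sub_in_grp = ss_between_subj - ss_grp
        ss_time = n * sum((m - grand) ** 2 for m in time_means)
        cell = {(g, j): y[groups == g][:, j].mean() for g in "AB" for j in range(a)}
        ss_cells = 3 * sum((cell[g, j] - grand) ** 2 for g in "AB" for j in range(a))
        ss_interaction = ss_cells - ss_grp - ss_time
        ss_total = ((y - grand) ** 2).sum()
        ss_err_within = ss_total - ss_between_subj - ss_time - ss_interaction

        f_grp = (ss_grp / 1) / (ss_sub_in_grp / (n - 2))
        f_time = (ss_time / (a - 1)) / (ss_err_within / ((a - 1) * (n - 2)))
        f_int = (ss_interaction / (a - 1)) / (ss_err_within / ((a - 1) * (n - 2)))

        assert res.loc["grp", "SS"] == pytest.approx(ss_grp, abs=1e-9)
        assert res.loc["time", "SS"] == pytest.approx(ss_time, abs=1e-9)
        assert res.loc["time*grp", "SS"] == pytest.approx(ss_interaction, abs=1e-9)
        assert res.loc["grp", "F"] == pytest.approx(f_grp, abs=1e-9)
        assert res.loc["time", "F"] == pytest.approx(f_time, abs=1e-9)
        assert res.loc["time*grp", "F"] == pytest.approx(f_int, abs=1e-9)
        # partial eta squared from its definition
        assert res.loc["time", "np2"] == pytest.approx(
            ss_time / (ss_time + ss_err_within), abs=1e-9
        )

    def test_pure_within_matches_pingouin_incl_epsilon(self, rng):
        n, a = 10, 4
        y = rng.normal(0, 1, (n, a)) + rng.normal(0, 1, (n, 1))
        y += np.array([0.0, 0.5, 1.0, 0.3])
        df = long_table(y, factor="time")
        mine = rm_anova(df, "v", ["time"]).table.loc["time"]
        ref = pg.rm_anova(df, "v", "time", "participant_id",
                          correction=True, detailed=True).iloc[0]
        assert mine["SS"] == pytest.approx(ref["SS"], abs=1e-9)
        assert mine["F"] == pytest.approx(ref["F"], abs=1e-9)
        assert mine["eps"] == pytest.approx(ref["eps"], abs=1e-9)
        assert mine["p_GG"] == pytest.approx(ref["p_GG_corr"], abs=1e-9)

    def test_two_within_factors_with_between(self, rng):
        # 2 within x 3 within x 2 groups: check SS additivity and dfs
        n, a, b = 8, 2, 3
        rows = []
        for s in range(n):
            base = rng.normal(0, 1)
            grp = "A" if s < 4 else "B"
            for i in range(a):
                for j in range(b):
                    rows.append({"participant_id": s, "grp": grp, "expo": i,
                                 "time": j,
                                 "v": base + 0.3 * i + 0.2 * j + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        res = MixedAnova(df, "v", ["expo", "time"], "participant_id", "grp").fit()
        t = res.table
        assert set(t.index) == {
            "grp", "expo", "expo*grp", "time", "time*grp",
            "expo*time", "expo*time*grp",
        }
        assert t.loc["expo", "df1"] == 1
        assert t.loc["time", "df1"] == 2
        assert t.loc["expo*time", "df1"] == 2
        assert t.loc["time", "df2"] == 2 * (n - 2)
        # epsilon bounds for the multi-df within effects
        for eff in ("time", "expo*time"):
            assert 0.5 <= t.loc[eff, "eps"] <= 1.0
        assert t.loc["expo", "eps"] == 1.0

    def test_missing_cell_excluded_listwise(self, rng):
        y = rng.normal(0, 1, (8, 3))
        df = long_table(y, factor="time")
        df.loc[(df.participant_id == 2) & (df.time == 1), "v"] = np.nan
        res = rm_anova(df, "v", ["time"])
        assert res.excluded_subjects == [2]
        assert res.n_subjects == 7

    def test_tiny_group_rejected(self, rng):
        y = rng.normal(0, 1, (5, 2))
        df = long_table(y)
        df["grp"] = ["A"] * 2 + ["B"] * 8
        with pytest.raises(DesignError):
            rm_anova(df, "v", ["occ"], "grp")


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

class TestPower:
    def test_published_a_priori_sample_size(self):
        assert required_n_paired_t(PowerSpec(0.50, 0.05, 0.85, 2)) == 38

    def test_eighty_percent_power(self):
        # oracle: numeric integration over the noncentral t (scipy.stats.nct)
        assert required_n_paired_t(PowerSpec(0.50, 0.05, 0.80, 2)) == 34

    def test_minimality(self):
        spec = PowerSpec(0.50, 0.05, 0.85, 2)
        n = required_n_paired_t(spec)
        assert power_paired_t(0.50, n, 0.05, 2) >= 0.85
        assert power_paired_t(0.50, n - 1, 0.05, 2) < 0.85

    def test_power_monotone_in_n_and_d(self):
        powers_n = [power_paired_t(0.5, n) for n in range(5, 60, 5)]
        assert all(a <= b for a, b in zip(powers_n, powers_n[1:]))
        ns = [required_n_paired_t(PowerSpec(d, 0.05, 0.85, 2)) for d in (0.3, 0.5, 0.8)]
        assert ns[0] >= ns[1] >= ns[2]

    def test_one_sided_needs_fewer(self):
        assert required_n_paired_t(PowerSpec(0.5, 0.05, 0.85, 1)) < 38


# ---------------------------------------------------------------------------
# top-level reliability model
# ---------------------------------------------------------------------------

class TestReliabilityModel:
    def make_cohort(self, rng, n=20):
        rows = []
        for i in range(n):
            trait = rng.normal(90, 40)
            for e in (1, 2):
                rows.append(
                    {"participant_id": f"P{i:02d}", "exposure": e,
                     "epm_version": "Sea" if e == 1 else ("Desert" if i % 2 else "VideoGame"),
                     "time_open": trait + rng.normal(0, 20),
                     "total_distance": rng.normal(13, 3)}
                )
        return pd.DataFrame(rows)

    def test_fit_produces_consistent_components(self, rng):
        table = self.make_cohort(rng)
        res = ReliabilityModel(table, ["time_open", "total_distance"]).fit()
        # ICC equals a direct call on the pivoted scores
        wide = table.pivot(index="participant_id", columns="exposure", values="time_open")
        direct = icc_consistency(wide.to_numpy())
        assert res.icc["time_open"].estimate == pytest.approx(direct.estimate)
        assert set(res.correlations.index) == {
            "time_open_1", "time_open_2", "total_distance_1", "total_distance_2"
        }
        # repeated-exposure ANOVA reproduces paired t on the same measure
        t = paired_t(wide[1].to_numpy(), wide[2].to_numpy())
        row = res.anovas["time_open"].table.loc["exposure"]
        assert row["F"] == pytest.approx(t.t**2, abs=1e-6)

    def test_summary_mentions_each_measure(self, rng):
        res = ReliabilityModel(self.make_cohort(rng)).fit()
        text = res.summary()
        assert "time_open" in text and "total_distance" in text
        assert "ICC" in text
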