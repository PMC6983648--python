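"""Mixed-design ANOVA, sphericity, Tukey HSD, HR confound, clustering."""

import io

import numpy as np
import pandas as pd
import pytest

from dcenirs.dtof import InputError
from dcenirs.perfusion import aggregate_measurements
from dcenirs.study import (
    cohort_clustering,
    complete_timepoints,
    hr_confound,
    mauchly_sphericity,
    rm_anova,
    tukey_hsd_time,
)
from dcenirs.synthetic import StudyDesign, generate_cohort_study

# ---------------------------------------------------------------------------
# a balanced 2x3x3x2 fixture with reference values frozen from R 4.3
# aov(bf ~ group*day*side + Error(subject/(day*side)))

R_FIXTURE_CSV = """animal,group,day,side,bf
c0,control,B1,L,9.56945
c0,control,B1,R,11.359885
c0,control,B2,L,12.049999
c0,control,B2,R,9.158399
c0,control,B3,L,10.307255
c0,control,B3,R,11.737275
c1,control,B1,L,9.350714
c1,control,B1,R,8.514471
c1,control,B2,L,10.746913
c1,control,B2,R,10.645307
c1,control,B3,L,10.433546
c1,control,B3,R,11.494756
c2,control,B1,L,10.075726
c2,control,B1,R,11.303769
c2,control,B2,L,10.476136
c2,control,B2,R,12.313469
c2,control,B3,L,11.885093
c2,control,B3,R,11.750156
e0,experimental,B1,L,9.860682
e0,experimental,B1,R,8.483611
e0,experimental,B2,L,10.209813
e0,experimental,B2,R,10.286007
e0,experimental,B3,L,13.17045
e0,experimental,B3,R,13.003585
e1,experimental,B1,L,11.256286
e1,experimental,B1,R,12.967113
e1,experimental,B2,L,12.41905
e1,experimental,B2,R,12.313222
e1,experimental,B3,L,14.011692
e1,experimental,B3,R,15.441445
e2,experimental,B1,L,12.143997
e2,experimental,B1,R,11.417788
e2,experimental,B2,L,13.433463
e2,experimental,B2,R,14.908537
e2,experimental,B3,L,17.001199
e2,experimental,B3,R,16.801099
"""

R_REFERENCE = {  # effect -> (SS, F, p)
    "group": (35.9134920322, 3.5581, 0.13232),
    "time": (39.7656670130, 29.57877, 0.00020136),
    "time*group": (12.2990748328, 9.14838, 0.00856546),
    "side": (0.839798124025, 1.33746, 0.31185),
    "group*side": (0.044582914844, 0.07100, 0.80305),
    "time*side": (0.40830883761, 0.16353, 0.85191),
    "time*group*side": (1.21116731902, 0.48509, 0.63264),
}
R_ERROR_SS = {"between": 40.3738105423, "time": 5.3775964959,
              "side": 2.511613225357, "time*side": 9.98723320680}


def _r_fixture():
    df = pd.read_csv(io.StringIO(R_FIXTURE_CSV))
    df["day_num"] = df["day"].map({"B1": 0, "B2": 1, "B3": 2})
    df["repeat"] = 1
    return df


def _balanced_random_table(n_per_group=3, T=3, D=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("a", "b"):
        for s in range(n_per_group):
            for t in range(T):
                for d in range(D):
                    rows.append(dict(animal=f"{g}{s}", group=g, day=str(t),
                                     day_num=t, side="LR"[d], repeat=1,
                                     bf=rng.normal(10 + 2 * t * (g == "b"), 1.5)))
    return pd.DataFrame(rows)


def _oracle_balanced_ss(table):
    """Classic split-plot marginal-means formulas (balanced groups)."""
    agg = aggregate_measurements(table)
    days = sorted(agg["day"].unique(), key=lambda d: agg.loc[agg.day == d, "day_num"].iloc[0])
    sides = sorted(agg["side"].unique())
    subjects = sorted(agg["animal"].unique())
    groups = agg.drop_duplicates("animal").set_index("animal")["group"]
    y = (agg.pivot_table(index="animal", columns=["day", "side"], values="bf")
         .reindex(index=subjects)[[(d, s) for d in days for s in sides]]
         .to_numpy().reshape(len(subjects), len(days), len(sides)))
    glabels = groups.loc[subjects].to_numpy()
    levels = sorted(set(glabels))
    T, D = len(days), len(sides)
    n_g = {g: (glabels == g).sum() for g in levels}
    grand = y.mean()
    yg = {g: y[glabels == g].mean() for g in levels}
    m_s = y.mean(axis=(1, 2))
    yt = y.mean(axis=(0, 2))
    yd = y.mean(axis=(0, 1))
    ytg = {g: y[glabels == g].mean(axis=(0, 2)) for g in levels}
    ydg = {g: y[glabels == g].mean(axis=(0, 1)) for g in levels}
    ytd = y.mean(axis=0)
    ytdg = {g: y[glabels == g].mean(axis=0) for g in levels}
    yst = y.mean(axis=2)
    ysd = y.mean(axis=1)

    ss = {}
    ss["group"] = T * D * sum(n_g[g] * (yg[g] - grand) ** 2 for g in levels)
    ss["between_err"] = T * D * sum(
        ((m_s[glabels == g] - yg[g]) ** 2).sum() for g in levels
    )
    ss["time"] = len(subjects) * D * ((yt - grand) ** 2).sum()
    ss["time*group"] = D * sum(
        n_g[g] * ((ytg[g] - yt - yg[g] + grand) ** 2).sum() for g in levels
    )
    ss["time_err"] = D * sum(
        ((yst[glabels == g] - m_s[glabels == g][:, None]
          - ytg[g][None, :] + yg[g]) ** 2).sum() for g in levels
    )
    ss["side"] = len(subjects) * T * ((yd - grand) ** 2).sum()
    ss["group*side"] = T * sum(
        n_g[g] * ((ydg[g] - yd - yg[g] + grand) ** 2).sum() for g in levels
    )
    ss["side_err"] = T * sum(
        ((ysd[glabels == g] - m_s[glabels == g][:, None]
          - ydg[g][None, :] + yg[g]) ** 2).sum() for g in levels
    )
    ss["time*side"] = len(subjects) * ((ytd - yt[:, None] - yd[None, :] + grand) ** 2).sum()
    ss["time*group*side"] = sum(
        n_g[g] * ((ytdg[g] - ytg[g][:, None] - ydg[g][None, :] - ytd
                   + yt[:, None] + yd[None, :] + yg[g] - grand) ** 2).sum()
        for g in levels
    )
    ss["ts_err"] = sum(
        ((y[glabels == g] - yst[glabels == g][:, :, None] - ysd[glabels == g][:, None, :]
          + m_s[glabels == g][:, None, None]
          - (ytdg[g] - ytg[g][:, None] - ydg[g][None, :] + yg[g])[None]) ** 2).sum()
        for g in levels
    )
    return ss


class TestRmAnova:
    def test_matches_r_aov_reference(self):
        res = rm_anova(_r_fixture())
        tab = res.table.set_index("effect")
        for effect, (ss, f, p) in R_REFERENCE.items():
            assert tab.loc[effect, "ss"] == pytest.approx(ss, abs=1e-6)
            assert tab.loc[effect, "F"] == pytest.approx(f, abs=2e-4)
            assert tab.loc[effect, "p"] == pytest.approx(p, abs=1e-4)
        strata = tab.drop_duplicates("stratum").set_index("stratum")["error_ss"]
        for stratum, ss in R_ERROR_SS.items():
            assert strata.loc[stratum] == pytest.approx(ss, abs=1e-6)

    def test_matches_brute_force_projection_oracle(self):
        table = _balanced_random_table(seed=3)
        res = rm_anova(table).table.set_index("effect")
        oracle = _oracle_balanced_ss(table)
        for effect in ("group", "time", "time*group", "side", "group*side",
                       "time*side", "time*group*side"):
            assert res.loc[effect, "ss"] == pytest.approx(oracle[effect], abs=1e-8)
        assert res.loc["group", "error_ss"] == pytest.approx(oracle["between_err"], abs=1e-8)
        assert res.loc["time", "error_ss"] == pytest.approx(oracle["time_err"], abs=1e-8)
        assert res.loc["side", "error_ss"] == pytest.approx(oracle["side_err"], abs=1e-8)
        assert res.loc["time*side", "error_ss"] == pytest.approx(oracle["ts_err"], abs=1e-8)

    def test_ss_additivity_balanced(self):
        res = rm_anova(_balanced_random_table(seed=5))
        assert res.ss_decomposition_sum == pytest.approx(res.ss_total, rel=1e-10)

    def test_reference_df_structure(self, study_table):
        table, _ = study_table
        res = rm_anova(table)
        tab = res.table.set_index("effect")
        assert (tab.loc["group", "df1"], tab.loc["group", "df2"]) == (1, 10)
        assert (tab.loc["time*group", "df1"], tab.loc["time*group", "df2"]) == (5, 50)
        assert res.days == ["B1", "B2", "B3", "5", "10", "15"]

    def test_zero_variance_flags_f_undefined(self):
        design = StudyDesign(time_effect={}, group_effect={}, cohort_effect_sd=0,
                             cohort_severity_sd=0, animal_effect_sd=0,
                             within_animal_sd=0, hr_bf_slope=0, hep_hazard=0,
                             missing_repeat_prob=0)
        table, _ = generate_cohort_study(design, seed=0)
        res = rm_anova(table)
        assert np.allclose(res.table["ss"], 0.0, atol=1e-18)
        assert res.table["F"].isna().all()

    def test_unbalanced_cells_rejected_with_guidance(self):
        table = _balanced_random_table()
        # empty one animal x day x side cell entirely
        mask = (table.animal == "a0") & (table.day == "1") & (table.side == "L")
        with pytest.raises(InputError, match="aggregate|complete"):
            rm_anova(table[~mask])

    def test_group_and_interaction_match_pingouin(self, study_table):
        """Independent implementation check on the unbalanced (4 vs 8) design."""
        pg = pytest.importorskip("pingouin")
        table, _ = study_table
        res = rm_anova(table)
        agg = aggregate_measurements(table)
        agg = agg[agg.day.isin(res.days)]
        sa = agg.groupby(["animal", "day", "group"], as_index=False)["bf"].mean()
        mix = pg.mixed_anova(sa, dv="bf", within="day", subject="animal",
                             between="group").set_index("Source")
        tab = res.table.set_index("effect")
        assert tab.loc["group", "F"] == pytest.approx(mix.loc["group", "F"], rel=1e-9)
        assert tab.loc["time*group", "F"] == pytest.approx(
            mix.loc["Interaction", "F"], rel=1e-9
        )
        assert tab.loc["group", "partial_eta_sq"] == pytest.approx(
            mix.loc["group", "np2"], rel=1e-9
        )

    def test_unweighted_time_effect_matches_statsmodels_type3(self, study_table):
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")
        from scipy.linalg import helmert

        from dcenirs.study import _pivot_balanced

        table, _ = study_table
        y, _, days, groups, _ = _pivot_balanced(table)
        n, T, D = y.shape
        u_t = np.sqrt(D) * (y.mean(axis=2) @ helmert(T, full=False).T)
        ss_time = ss_inter = 0.0
        for j in range(T - 1):
            fit = smf.ols("z ~ C(g, Sum)", pd.DataFrame({"z": u_t[:, j], "g": groups})).fit()
            a3 = sm.stats.anova_lm(fit, typ=3)
            ss_time += a3.loc["Intercept", "sum_sq"]
            ss_inter += a3.loc["C(g, Sum)", "sum_sq"]
        tab = rm_anova(table).table.set_index("effect")
        assert tab.loc["time", "ss"] == pytest.approx(ss_time, rel=1e-9)
        assert tab.loc["time*group", "ss"] == pytest.approx(ss_inter, rel=1e-9)


class TestMauchly:
    def test_near_identity_covariance_gives_w_near_one(self):
        design = StudyDesign(n_control=0, n_experimental=40, cohort_size=2,
                             time_effect={}, group_effect={}, cohort_effect_sd=0,
                             cohort_severity_sd=0, animal_effect_sd=0,
                             hr_bf_slope=0, hep_hazard=0, missing_repeat_prob=0,
                             timepoints=("B1", "B2", "B3"))
        table, _ = generate_cohort_study(design, seed=8)
        res = mauchly_sphericity(table, "time")
        assert res["W"] > 0.8
        assert res["p"] > 0.05

    def test_two_level_effect_trivially_spherical(self, study_table):
        table, _ = study_table
        res = mauchly_sphericity(table, "side")
        assert res["p"] == 1.0
        assert "trivially" in res["note"]

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        design = StudyDesign(n_control=0, n_experimental=8, cohort_size=2,
                             missing_repeat_prob=0.0, hep_hazard=0.0,
                             timepoints=("B1", "B2", "B3", "5"))
        table, _ = generate_cohort_study(design, seed=3)
        mine = mauchly_sphericity(table, "time")
        agg = table.groupby(["animal", "day"], as_index=False)["bf"].mean()
        ref = pg.sphericity(agg, dv="bf", within="day", subject="animal")
        assert mine["W"] == pytest.approx(ref.W, rel=1e-9)
        assert mine["chi2"] == pytest.approx(ref.chi2, rel=1e-9)
        assert mine["p"] == pytest.approx(ref.pval, abs=1e-9)


class TestTukey:
    def test_equal_means_nothing_significant(self):
        design = StudyDesign(time_effect={}, group_effect={}, cohort_effect_sd=0,
                             cohort_severity_sd=0, animal_effect_sd=0.5,
                             within_animal_sd=1.0, hr_bf_slope=0, hep_hazard=0)
        table, _ = generate_cohort_study(design, seed=12)
        tk = tukey_hsd_time(table)
        assert not tk["reject"].any()

    def test_q_statistic_matches_hand_computation(self):
        table = _balanced_random_table(n_per_group=4, T=3, seed=9)
        anova = rm_anova(table)
        tk = tukey_hsd_time(table, anova)
        # independent arithmetic: means and time-stratum error MS by hand
        agg = aggregate_measurements(table)
        cell = agg.pivot_table(index="animal", columns=["day", "side"], values="bf")
        y = cell.to_numpy().reshape(8, 3, 2)
        means = y.mean(axis=(0, 2))
        tab = anova.table.set_index("effect")
        mse = tab.loc["time", "error_ss"] / tab.loc["time", "df2"]
        se = np.sqrt(mse / (8 * 2))
        q01 = abs(means[0] - means[1]) / se
        row = tk[(tk.day_a == "0") & (tk.day_b == "1")].iloc[0]
        assert row["q"] == pytest.approx(q01, rel=1e-9)
        from scipy.stats import studentized_range

        assert row["p"] == pytest.approx(
            float(studentized_range.sf(q01, 3, tab.loc["time", "df2"])), rel=1e-9
        )

    def test_day10_elevation_detected_in_most_seeds(self):
        """A planted day-10 elevation separates B1 from day 10 in >=80% of runs."""
        n_detect = 0
        n_seeds = 100
        for seed in range(n_seeds):
            table, _ = generate_cohort_study(StudyDesign(), seed=seed)
            tk = tukey_hsd_time(table)
            hit = tk[((tk.day_a == "B1") & (tk.day_b == "10"))
                     | ((tk.day_a == "10") & (tk.day_b == "B1"))]
            if hit["reject"].any():
                n_detect += 1
        assert n_detect >= 0.8 * n_seeds


class TestHrConfound:
    def _manual_table(self, bf, hr):
        rows = []
        for i, (b, h) in enumerate(zip(bf, hr)):
            rows.append(dict(animal="a1", day="B1", day_num=0, side="LR"[i % 2],
                             repeat=i // 2 + 1, bf=b, hr=h))
        return pd.DataFrame(rows)

    def test_proportional_hr_gives_unit_correlation(self):
        table = self._manual_table([10.0, 12.0, 11.0, 13.0], [100.0, 120.0, 110.0, 130.0])
        assert hr_confound(table).average_r == pytest.approx(1.0)

    def test_fixed_four_point_closed_form(self):
        # Pearson r of (10,12,11,13) vs (300,310,305,312) = 20.5/sqrt(5*86.75)
        table = self._manual_table([10.0, 12.0, 11.0, 13.0], [300.0, 310.0, 305.0, 312.0])
        assert hr_confound(table).average_r == pytest.approx(
            20.5 / np.sqrt(5.0 * 86.75), rel=1e-12
        )

    def test_independent_hr_averages_to_zero(self):
        design = StudyDesign(hr_bf_slope=0.0, missing_repeat_prob=0.0, hep_hazard=0.0,
                             n_control=0, n_experimental=40, cohort_size=2)
        table, _ = generate_cohort_study(design, seed=4)
        res = hr_confound(table)
        n = len(res.per_day)
        se = res.per_day["r"].std(ddof=1) / np.sqrt(n)
        assert abs(res.average_r) <= 3 * se

    def test_incomplete_animal_days_skipped(self):
        design = StudyDesign(missing_repeat_prob=0.3)
        table, _ = generate_cohort_study(design, seed=2)
        res = hr_confound(table)
        assert res.n_skipped > 0


PLANTED_PROFILES = {
    # four distinct disease trajectories: transient flares peaking on
    # different days plus one sustained elevation (mutually equidistant)
    "C1": {"5": 15.0},
    "C2": {"10": 15.0},
    "C3": {"15": 15.0},
    "C4": {"5": 15.0, "10": 15.0, "15": 15.0},
}


def planted_cohort_design(**overrides):
    kwargs = dict(cohort_day_profiles=PLANTED_PROFILES, cohort_effect_sd=0.0,
                  cohort_severity_sd=0.0, animal_effect_sd=0.5,
                  within_animal_sd=1.0, hep_hazard=0.0, missing_repeat_prob=0.0)
    kwargs.update(overrides)
    return StudyDesign(**kwargs)


class TestClustering:
    def test_recovers_planted_cohorts(self):
        table, truth = generate_cohort_study(planted_cohort_design(), seed=6)
        res = cohort_clustering(table, seed=1)
        assert res.k == 4
        cohorts = truth.animal_effects.set_index("animal")["cohort"]
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(cohorts.loc[res.labels.index], res.labels)
        assert ari > 0.9
        assert res.kmeans_agreement > 0.9

    def test_identical_rows_give_single_cluster(self):
        design = StudyDesign(time_effect={}, group_effect={}, cohort_effect_sd=0,
                             cohort_severity_sd=0, animal_effect_sd=0,
                             within_animal_sd=0, hr_bf_slope=0, hep_hazard=0,
                             missing_repeat_prob=0)
        table, _ = generate_cohort_study(design, seed=0)
        res = cohort_clustering(table)
        assert res.k == 1

    def test_partition_invariant_to_row_order(self):
        table, _ = generate_cohort_study(planted_cohort_design(), seed=6)
        res = cohort_clustering(table, seed=1)
        assert res.stable
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res2 = cohort_clustering(shuffled, seed=2)
        assert res2.k == res.k
        assert (res2.labels.sort_index().groupby(res.labels.sort_index()).nunique() == 1).all()

    def test_k_max_clipped_to_animal_count(self):
        design = StudyDesign(n_experimental=4, cohort_size=2, n_control=2)
        table, _ = generate_cohort_study(design, seed=1)
        res = cohort_clustering(table, k_max=10)
        assert res.k <= 4


class TestCompleteTimepoints:
    def test_days_with_dropout_excluded(self, study_table):
        table, truth = study_table
        days = complete_timepoints(table)
        first_hep = truth.animal_effects["hep_day"].min()
        day_nums = table.drop_duplicates("day").set_index("day")["day_num"]
        assert all(day_nums[d] < first_hep for d in days)

    def test_effect_detection_improves_with_effect_size(self):
        """Interaction rejection rate rises monotonically with the group effect."""
        rates = []
        for scale in (0.0, 1.0, 2.5):
            rejections = 0
            for seed in range(60):
                design = StudyDesign(
                    group_effect={d: scale * v for d, v in
                                  StudyDesign().group_effect.items()},
                    cohort_effect_sd=0.0, cohort_severity_sd=0.0,
                )
                table, _ = generate_cohort_study(design, seed=1000 + seed)
                tab = rm_anova(table).table.set_index("effect")
                rejections += tab.loc["time*group", "p"] < 0.05
            rates.append(rejections / 60)
        assert rates[0] < rates[1] < rates[2] or (rates[0] <= rates[1] <= rates[2]
                                                  and rates[2] > rates[0])
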