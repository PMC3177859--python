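"""Growth fits, factorial ANOVA, laterality contrasts and report shapes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scalpmap.growthstats import (AGE_GROUPS, anova_nway, assign_age_group,
                                  fit_growth, fit_growth_mean, growth_chart,
                                  laterality_contrast)
from scalpmap.io_formats import CANONICAL_LANDMARKS
from scalpmap.phantom import (GrowthParams, GrowthStratum,
                              default_growth_params, simulate_cohort)


def _cohort(rows):
    return pd.DataFrame(rows)


def _single_stratum_table(t, d, landmark="vertex", hemisphere="midline"):
    return _cohort([
        {"subject": f"s{i}", "age_months": ti, "handedness": "right",
         "landmark": landmark, "hemisphere": hemisphere, "distance_mm": di}
        for i, (ti, di) in enumerate(zip(t, d))
    ])


class TestAssignAgeGroup:
    @pytest.mark.parametrize("t,expected", [
        (0.0, "infants"), (18.0, "infants"), (19.0, "younger"),
        (60.0, "younger"), (61.0, "older"), (144.0, "older"),
    ])
    def test_group_boundaries(self, t, expected):
        assert assign_age_group(t) == expected

    def test_out_of_range_rejected_without_override(self):
        with pytest.raises(ValueError, match="outside the studied"):
            assign_age_group(200.0)
        assert assign_age_group(200.0, allow_out_of_range=True) == "older"

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            assign_age_group(-1.0)

    @given(st.floats(0.0, 144.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_study_range(self, t):
        """Every age in the studied range maps to exactly one group."""
        group = assign_age_group(t)
        matches = [g for g, lo, hi in AGE_GROUPS if lo <= t <= hi]
        assert [group] == matches or group in matches  # boundary halves open


class TestFitGrowth:
    def test_noise_free_exact_recovery(self):
        t = np.linspace(0, 144, 40)
        table = _single_stratum_table(t, 0.02 * t + 8.0)
        fit = fit_growth(table, "vertex", "midline")
        assert fit.a == pytest.approx(0.02, abs=1e-12)
        assert fit.b == pytest.approx(8.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0, 144, 60)
        d = 0.02 * t + 8.0 + rng.normal(0, 2.0, 60)
        fit = fit_growth(_single_stratum_table(t, d), "vertex", "midline")
        t_stat = fit.a / fit.se_a
        assert fit.F == pytest.approx(t_stat**2, rel=1e-9)
        # and the F test p-value matches statsmodels-style OLS
        slope, intercept, r, p, se = stats.linregress(t, d)
        assert fit.a == pytest.approx(slope, rel=1e-12)
        assert fit.p == pytest.approx(p, rel=1e-9)
        assert fit.r2 == pytest.approx(r**2, rel=1e-12)

    def test_permutation_null_p_uniform(self):
        """Under a permuted (null) cohort, regression p-values are uniform."""
        rng = np.random.default_rng(9)
        t = rng.uniform(0, 144, 90)
        d = 8.5 + rng.normal(0, 2.0, 90)
        n_perm = 1000
        pvals = np.empty(n_perm)
        tc = t - t.mean()
        sxx = tc @ tc
        for i in range(n_perm):
            dp = rng.permutation(d)
            a = tc @ (dp - dp.mean()) / sxx
            resid = dp - dp.mean() - a * tc
            ss_res = resid @ resid
            ss_tot = ((dp - dp.mean()) ** 2).sum()
            r2 = 1 - ss_res / ss_tot
            F = (len(t) - 2) * r2 / (1 - r2)
            pvals[i] = stats.f.sf(F, 1, len(t) - 2)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_identical_ages_rejected(self):
        table = _single_stratum_table(np.full(10, 24.0), np.arange(10) + 5.0)
        with pytest.raises(ValueError, match="identical"):
            fit_growth(table, "vertex", "midline")

    def test_too_few_rows_rejected(self):
        table = _single_stratum_table([1.0, 2.0], [5.0, 6.0])
        with pytest.raises(ValueError, match=">= 3"):
            fit_growth(table, "vertex", "midline")

    def test_mean_fit_pools_subjects(self):
        table = simulate_cohort(default_growth_params(), 40, seed=6)
        fit = fit_growth_mean(table)
        assert fit.n == 40
        assert fit.landmark == "mean"
        assert 0.0 < fit.a < 0.1


class TestAnova:
    def test_ss_additivity_balanced(self):
        rng = np.random.default_rng(1)
        rows = []
        for gi, age in enumerate([9.0, 40.0, 100.0]):
            for si in range(10):
                for name, hemi in CANONICAL_LANDMARKS:
                    rows.append({
                        "subject": f"g{gi}s{si}", "age_months": age,
                        "handedness": "right", "landmark": name,
                        "hemisphere": hemi,
                        "distance_mm": 9.0 + rng.standard_normal(),
                    })
        table = _cohort(rows)
        result = anova_nway(table, factors=("age_group", "landmark_code"),
                            interactions=("age_group:landmark_code",))
        n = len(table)
        model_terms = result.drop(index="residual")
        total = (table["distance_mm"] - table["distance_mm"].mean()).pow(2).sum()
        ss = result["sum_sq"].sum()
        assert ss == pytest.approx(total, rel=1e-9)
        assert model_terms["df"].sum() + result.loc["residual", "df"] == n - 1

    def test_planted_age_effect_detected(self):
        rng = np.random.default_rng(2)
        params = default_growth_params()
        strata = {k: GrowthStratum(0.03, 9.0, 1.0) for k in params.strata}
        table = simulate_cohort(GrowthParams(strata=strata), 200, seed=2)
        result = anova_nway(table, factors=("age_group", "landmark_code"))
        assert result.loc["age_group", "PR(>F)"] < 1e-3
        # all strata share identical parameters: landmark term is null
        assert result.loc["landmark_code", "PR(>F)"] > 1e-3

    def test_single_level_factor_rejected(self):
        table = simulate_cohort(default_growth_params(), 10, seed=1)
        table["handedness"] = "right"
        with pytest.raises(ValueError, match="level"):
            anova_nway(table, factors=("age_group", "handedness"))

    def test_empty_interaction_cell_rejected(self):
        table = simulate_cohort(default_growth_params(), 30, seed=3)
        # force an empty (age_group, landmark) cell
        drop = (table["age_months"] <= 18.0) & (table["landmark"] == "vertex")
        table = table[~drop]
        with pytest.raises(ValueError, match="empty cells"):
            anova_nway(table, factors=("age_group", "landmark_code"),
                       interactions=("age_group:landmark_code",))

    def test_unknown_handedness_rows_dropped(self):
        table = simulate_cohort(default_growth_params(), 60, seed=4)
        table.loc[table.index[:90], "handedness"] = "unknown"
        result = anova_nway(table, factors=("age_group", "landmark_code",
                                            "handedness"))
        assert result.attrs["n"] == len(table) - 90


class TestLaterality:
    def test_planted_heschl_offset_recovered(self):
        params = default_growth_params()
        strata = dict(params.strata)
        strata[("heschl_gyrus", "left")] = GrowthStratum(0.013, 7.2, 1.8)
        strata[("heschl_gyrus", "right")] = GrowthStratum(0.013, 8.8, 1.8)
        table = simulate_cohort(GrowthParams(strata=strata), 500, seed=5)
        res = laterality_contrast(table, "heschl_gyrus")
        assert res["difference"] == pytest.approx(1.6, abs=0.2)
        assert res["p"] < 0.01

    def test_null_offset_p_uniform(self):
        params = default_growth_params()
        st0 = GrowthStratum(0.02, 8.0, 2.0)
        strata = {("heschl_gyrus", "left"): st0, ("heschl_gyrus", "right"): st0,
                  ("vertex", "midline"): st0}
        pvals = []
        for seed in range(200):
            table = simulate_cohort(GrowthParams(strata=strata), 20, seed=seed)
            pvals.append(laterality_contrast(table, "heschl_gyrus")["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_identical_hemispheres_null(self):
        rows = []
        for i in range(10):
            for hemi in ("left", "right"):
                rows.append({"subject": f"s{i}", "age_months": 12.0,
                             "handedness": "right", "landmark": "heschl_gyrus",
                             "hemisphere": hemi, "distance_mm": 8.0 + i})
        res = laterality_contrast(_cohort(rows), "heschl_gyrus")
        assert res["t"] == 0.0
        assert res["p"] == 1.0

    def test_too_few_pairs_rejected(self):
        rows = [{"subject": "s0", "age_months": 1.0, "handedness": "right",
                 "landmark": "heschl_gyrus", "hemisphere": h,
                 "distance_mm": 8.0} for h in ("left", "right")]
        with pytest.raises(ValueError, match="pairs"):
            laterality_contrast(_cohort(rows), "heschl_gyrus")


class TestGrowthChart:
    def test_summary_matrix_shape(self, tmp_path):
        table = simulate_cohort(default_growth_params(), 60, seed=8)
        fits = [fit_growth(table, n, h) for n, h in CANONICAL_LANDMARKS]
        report = growth_chart(fits, table, out_dir=tmp_path)
        assert report["summary_mean"].shape == (3, 9)
        assert report["summary_sd"].shape == (3, 9)
        assert (tmp_path / "fits.csv").exists()
        fits_df = pd.read_csv(tmp_path / "fits.csv")
        assert set(["a", "b", "r2", "F", "df1", "df2", "p", "n"]) <= set(
            fits_df.columns)
        assert (fits_df["df1"] == 1).all()

    def test_constant_cohort_zero_sd(self):
        rows = [{"subject": f"s{i}", "age_months": float(i), "handedness":
                 "right", "landmark": "vertex", "hemisphere": "midline",
                 "distance_mm": 9.0} for i in range(6)]
        table = _cohort(rows)
        report = growth_chart([], table)
        sd = report["summary_sd"]["vertex_midline"].dropna()
        assert (sd == 0).all()

    def test_missing_stratum_is_nan_not_zero(self):
        table = simulate_cohort(default_growth_params(), 20, seed=9)
        table = table[table["landmark"] != "vertex"]
        report = growth_chart([], table)
        assert report["summary_mean"]["vertex_midline"].isna().all()

    def test_infant_group_mean_near_intercept(self):
        # over 0-18 months the slope contributes < 0.4 mm at the occipital
        # pole, so the infant group mean sits near the generator intercept
        table = simulate_cohort(default_growth_params(), 400, seed=10)
        report = growth_chart([], table)
        infant_mean = report["summary_mean"].loc["infants",
                                                 "occipital_pole_midline"]
        params = default_growth_params()
        b = params.strata[("occipital_pole", "midline")].intercept
        a = params.strata[("occipital_pole", "midline")].slope
        expected = b + a * 9.0
        assert infant_mean == pytest.approx(expected, abs=0.75)
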