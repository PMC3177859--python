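"""Developmental statistics for brain-to-scalp distance cohorts.

Covers the analysis stages applied to a long-format cohort table: age-group
binning, per-landmark linear growth fits D = a*t + b with r^2 / F / p,
factorial fixed-effects ANOVA (age group x landmark x handedness, Type III
sums of squares with sum-to-zero contrasts by default), paired laterality
contrasts, and growth-chart report generation (per-landmark scatter plus a
3 age-group x 9 landmark matrix of group means +/- SD).

No multiple-testing correction is applied; p-values are reported at full
precision and flagged uncorrected in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CANONICAL_LANDMARKS, validate_cohort

__all__ = [
    "GrowthFit",
    "AGE_GROUPS",
    "assign_age_group",
    "fit_growth",
    "fit_growth_mean",
    "anova_nway",
    "laterality_contrast",
    "growth_chart",
]

#: Age groups in months, inclusive bounds: infants 0-18, younger
#: 19 months - 5 years, older 6 - 12 years.
AGE_GROUPS = (
    ("infants", 0.0, 18.0),
    ("younger", 18.0 + 1e-12, 60.0),
    ("older", 60.0 + 1e-12, 144.0),
)


def assign_age_group(t: float, allow_out_of_range: bool = False) -> str:
    """Bin an age in months into infants / younger / older.

    Ages above 144 months fall outside the studied range and raise unless
    ``allow_out_of_range`` is set (they then map to ``"older"``).
    """
    if t < 0:
        raise ValueError("negative age")
    if t <= 18.0:
        return "infants"
    if t <= 60.0:
        return "younger"
    if t <= 144.0 or allow_out_of_range:
        return "older"
    raise ValueError(
        f"age {t} months is outside the studied 0-144 month range; "
        "pass allow_out_of_range=True to override"
    )


@dataclass
class GrowthFit:
    """OLS fit of D = a*t + b for one (landmark, hemisphere) stratum."""

    landmark: str
    hemisphere: str
    a: float           # slope, mm/month
    b: float           # intercept, mm
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    n: int
    se_a: float        # standard error of the slope

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.5 + level / 2, self.df[1])
        return (self.a - tcrit * self.se_a, self.a + tcrit * self.se_a)


def _ols_line(t: np.ndarray, d: np.ndarray) -> GrowthFit:
    n = len(t)
    if n < 3:
        raise ValueError("need >= 3 observations for a growth fit")
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    st = t - t.mean()
    sxx = float(st @ st)
    if sxx == 0:
        raise ValueError("all ages identical: slope unidentifiable")
    a = float(st @ (d - d.mean()) / sxx)
    b = float(d.mean() - a * t.mean())
    resid = d - (a * t + b)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df = (1, n - 2)
    if df[1] <= 0:
        raise ValueError("no residual degrees of freedom")
    if r2 >= 1.0:
        F, p = np.inf, 0.0
    else:
        F = df[1] * r2 / (1.0 - r2)
        p = float(stats.f.sf(F, *df))
    sigma2 = ss_res / df[1]
    se_a = float(np.sqrt(sigma2 / sxx))
    return GrowthFit(landmark="", hemisphere="", a=a, b=b, r2=r2, F=float(F),
                     df=df, p=p, n=n, se_a=se_a)


def fit_growth(table: pd.DataFrame, landmark: str,
               hemisphere: str) -> GrowthFit:
    """Fit the linear growth model for one (landmark, hemisphere) stratum."""
    table = validate_cohort(table)
    sel = (table["landmark"] == landmark) & (table["hemisphere"] == hemisphere)
    sub = table[sel]
    if len(sub) < 3:
        raise ValueError(
            f"stratum ({landmark}, {hemisphere}) has {len(sub)} rows; need >= 3"
        )
    fit = _ols_line(sub["age_months"].to_numpy(), sub["distance_mm"].to_numpy())
    fit.landmark = landmark
    fit.hemisphere = hemisphere
    return fit


def fit_growth_mean(table: pd.DataFrame) -> GrowthFit:
    """Fit the growth model to each subject's mean distance across landmarks."""
    table = validate_cohort(table)
    per_subject = table.groupby("subject").agg(
        age_months=("age_months", "first"), distance_mm=("distance_mm", "mean")
    )
    fit = _ols_line(per_subject["age_months"].to_numpy(),
                    per_subject["distance_mm"].to_numpy())
    fit.landmark = "mean"
    fit.hemisphere = "pooled"
    return fit


def anova_nway(table: pd.DataFrame,
               factors: tuple[str, ...] = ("age_group", "landmark_code"),
               interactions: tuple[str, ...] = (),
               ss_type: int = 3) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA on landmark distances.

    Factors may include ``age_group`` (derived from age), ``landmark_code``
    (the nine landmark/hemisphere combinations as one categorical factor)
    and ``handedness``.  When handedness is a factor, rows with unknown
    handedness are dropped (the analysis is restricted to subjects whose
    handedness is on record).  Sums of squares are Type III with
    sum-to-zero contrasts by default (``ss_type=2`` for Type II).
    Interactions are requested as ``"factor1:factor2"`` strings and
    require every factor-level cell to be populated.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    table = validate_cohort(table)
    df = table.copy()
    df["age_group"] = [assign_age_group(t) for t in df["age_months"]]
    df["landmark_code"] = df["landmark"] + "_" + df["hemisphere"]
    if "handedness" in factors:
        unknown = df["handedness"] == "unknown"
        df = df[~unknown]
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"unknown factor {f!r}")
        levels = df[f].nunique()
        if levels < 2:
            raise ValueError(f"factor {f!r} has {levels} level(s); need >= 2")
    for inter in interactions:
        parts = inter.split(":")
        if any(p not in factors for p in parts):
            raise ValueError(f"interaction {inter!r} uses non-factor terms")
        counts = df.groupby(parts, observed=True).size()
        full = np.prod([df[p].nunique() for p in parts])
        if len(counts) < full or (counts == 0).any():
            present = set(counts.index)
            all_cells = set(pd.MultiIndex.from_product(
                [sorted(df[p].unique()) for p in parts]))
            empty = sorted(all_cells - present)
            raise ValueError(
                f"design is rank deficient: empty cells for {inter}: {empty}"
            )
    terms = [f"C({f}, Sum)" for f in factors]
    terms += [":".join(f"C({p}, Sum)" for p in inter.split(":"))
              for inter in interactions]
    formula = "distance_mm ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    typ = ss_type
    anova = sm.stats.anova_lm(model, typ=typ)
    anova = anova.drop(index="Intercept", errors="ignore")
    anova = anova.rename(
        index=lambda s: (s.replace("C(", "").replace(", Sum)", "")
                         .replace("Residual", "residual")))
    anova.attrs["ss_type"] = typ
    anova.attrs["p_values_uncorrected"] = True
    anova.attrs["n"] = len(df)
    return anova


def laterality_contrast(table: pd.DataFrame, landmark: str,
                        paired: bool = True) -> dict:
    """Left-vs-right distance contrast for a paired landmark.

    Pairs observations by subject (default) and runs a two-sided paired
    t-test; means are reported averaged across ages.  ``paired=False``
    gives the unpaired pooled-variance alternative.
    """
    table = validate_cohort(table)
    sub = table[table["landmark"] == landmark]
    wide = sub.pivot_table(index="subject", columns="hemisphere",
                           values="distance_mm", aggfunc="mean")
    if "left" not in wide.columns or "right" not in wide.columns:
        raise ValueError(f"landmark {landmark!r} lacks both hemispheres")
    if paired:
        both = wide.dropna(subset=["left", "right"])
        if len(both) < 2:
            raise ValueError("fewer than 2 complete left/right pairs")
        left = both["left"].to_numpy()
        right = both["right"].to_numpy()
        diff = right - left
        if diff.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(right, left)
        df = len(both) - 1
    else:
        left = wide["left"].dropna().to_numpy()
        right = wide["right"].dropna().to_numpy()
        if len(left) < 2 or len(right) < 2:
            raise ValueError("fewer than 2 observations per hemisphere")
        t, p = stats.ttest_ind(right, left, equal_var=True)
        df = len(left) + len(right) - 2
    return {
        "landmark": landmark,
        "mean_left": float(np.mean(left)),
        "mean_right": float(np.mean(right)),
        "difference": float(np.mean(right) - np.mean(left)),
        "t": float(t),
        "df": int(df),
        "p": float(p),
        "paired": paired,
    }


_CHART_COLUMNS = [f"{name}_{hemi}" for name, hemi in CANONICAL_LANDMARKS]


def growth_chart(fits: list[GrowthFit], table: pd.DataFrame,
                 out_dir: str | Path | None = None) -> dict:
    """Growth-chart report: per-landmark fits plus a group-mean matrix.

    Returns scatter data per landmark, the fitted lines, and a summary
    matrix of mean +/- SD distances with one row per age group and one
    column per landmark/hemisphere (missing strata stay NaN, never 0).
    With ``out_dir`` set, writes ``fits.csv``, ``summary_mean.csv``,
    ``summary_sd.csv`` and one PNG scatter per fitted stratum.
    """
    table = validate_cohort(table)
    df = table.copy()
    df["age_group"] = [assign_age_group(t) for t in df["age_months"]]
    df["landmark_code"] = df["landmark"] + "_" + df["hemisphere"]
    group_order = [g for g, _, _ in AGE_GROUPS]
    mean = df.pivot_table(index="age_group", columns="landmark_code",
                          values="distance_mm", aggfunc="mean")
    sd = df.pivot_table(index="age_group", columns="landmark_code",
                        values="distance_mm", aggfunc=lambda x: x.std(ddof=1))
    mean = mean.reindex(index=group_order, columns=_CHART_COLUMNS)
    sd = sd.reindex(index=group_order, columns=_CHART_COLUMNS)

    fit_rows = [{
        "landmark": f.landmark, "hemisphere": f.hemisphere, "a": f.a,
        "b": f.b, "r2": f.r2, "F": f.F, "df1": f.df[0], "df2": f.df[1],
        "p": f.p, "n": f.n,
    } for f in fits]
    fits_df = pd.DataFrame(fit_rows)

    scatter = {
        (f.landmark, f.hemisphere): df[
            (df["landmark"] == f.landmark) & (df["hemisphere"] == f.hemisphere)
        ][["age_months", "distance_mm"]].to_numpy()
        for f in fits if f.landmark != "mean"
    }

    report = {"fits": fits_df, "summary_mean": mean, "summary_sd": sd,
              "scatter": scatter}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fits_df.to_csv(out_dir / "fits.csv", index=False)
        mean.to_csv(out_dir / "summary_mean.csv")
        sd.to_csv(out_dir / "summary_sd.csv")
        _plot_charts(fits, scatter, out_dir)
    return report


def _plot_charts(fits, scatter, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for f in fits:
        key = (f.landmark, f.hemisphere)
        if key not in scatter or len(scatter[key]) == 0:
            continue
        pts = scatter[key]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(pts[:, 0], pts[:, 1], "s", ms=3, alpha=0.6)
        tt = np.linspace(pts[:, 0].min(), pts[:, 0].max(), 2)
        ax.plot(tt, f.a * tt + f.b, "k-")
        ax.set_xlabel("age (months)")
        ax.set_ylabel("brain-scalp distance (mm)")
        ax.set_title(f"{f.landmark} ({f.hemisphere}): "
                     f"a={f.a:.3f}, b={f.b:.1f}, r2={f.r2:.2f}")
        fig.tight_layout()
        fig.savefig(out_dir / f"growth_{f.landmark}_{f.hemisphere}.png", dpi=100)
        plt.close(fig)
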