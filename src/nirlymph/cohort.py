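"""Cohort-level statistics: baseline normalization, swelling
classification, and the swelling-function analysis.

Analysis surface:

* every per-animal metric is normalized to its pre-surgery (day-0)
  baseline, so group curves read as fractions of healthy function;
* animals are classified by peak swelling: more vs. less than a 20 %
  increase in maximum tail circumference at ANY timepoint (strict >);
* the swelling-function association is ordinary least squares of the
  normalized metric on normalized circumference with an F-test of zero
  slope;
* group time courses are compared with per-timepoint Welch t-tests,
  Holm-Sidak adjusted across timepoints (alpha = 0.05).

Welch (unequal-variance) t is used for the per-timepoint tests; the test
family and adjustment method are stamped into the output tables.  A
two-way ANOVA + Tukey HSD wrapper is provided for completeness.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import SwellingSeries, ValidationError

__all__ = [
    "RegressionResult",
    "normalize_to_baseline",
    "classify_swelling",
    "regress_metric_on_swelling",
    "compare_groups_timecourse",
    "anova_timecourse",
]

from dataclasses import dataclass


@dataclass
class RegressionResult:
    """OLS fit of a normalized metric on normalized circumference."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError("r_squared must lie in [0, 1]")
        if self.n < 3:
            raise ValidationError("regression needs n >= 3")


def normalize_to_baseline(table: pd.DataFrame,
                          baseline_day: float = 0.0) -> pd.DataFrame:
    """Add a ``normalized_value`` column: value / value(day 0), per animal
    per metric.  Baseline rows normalize to exactly 1.0; a zero baseline
    yields missing normalized values (with a warning), never infinities.
    """
    df = table.copy()
    out = np.full(len(df), np.nan)
    for (animal, metric), idx in df.groupby(["animal_id", "metric"]).groups.items():
        sub = df.loc[idx]
        base_rows = sub[sub["day"] == baseline_day]
        if base_rows.empty:
            raise ValidationError(
                f"animal {animal!r} metric {metric!r} lacks a day-"
                f"{baseline_day} baseline row"
            )
        base = float(base_rows["value"].iloc[0])
        if base == 0:
            warnings.warn(
                f"zero baseline for animal {animal!r} metric {metric!r}; "
                "normalized values reported as missing",
                stacklevel=2,
            )
            continue
        out[df.index.get_indexer(idx)] = sub["value"].to_numpy() / base
    df["normalized_value"] = out
    # make baselines exactly 1 where defined (guards against float noise)
    is_base = (df["day"] == baseline_day) & np.isfinite(df["normalized_value"])
    df.loc[is_base, "normalized_value"] = 1.0
    return df


def classify_swelling(series, threshold_frac: float = 0.20) -> str:
    """Classify an animal's swelling time course.

    Returns ``"gt20"`` when the normalized circumference exceeds
    1 + threshold at ANY post-baseline timepoint (strict inequality),
    else ``"le20"`` (labels follow the threshold percentage).
    ``series`` may be a :class:`SwellingSeries` or an array of normalized
    circumference values (the baseline 1.0 entry may be included).
    """
    if isinstance(series, SwellingSeries):
        days = series.days
        norm = series.normalized_circumference
        post = norm[days != series.baseline_day]
    else:
        arr = np.asarray(series, dtype=float)
        post = arr[np.isfinite(arr)]
    if post.size == 0:
        raise ValidationError("no post-baseline swelling data to classify")
    pct = round(100 * threshold_frac)
    peak_increase = float(post.max()) - 1.0
    return f"gt{pct}" if peak_increase > threshold_frac else f"le{pct}"


def regress_metric_on_swelling(x: Sequence[float],
                               y: Sequence[float]) -> RegressionResult:
    """OLS of normalized metric (y) on normalized circumference (x),
    with the overall F-test of zero slope (two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y differ in length")
    if x.size < 3:
        raise ValidationError("regression needs n >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("regression inputs must be finite")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in the predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(min(model.rsquared, 1.0)),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(x.size),
    )


def swelling_function_pairs(table: pd.DataFrame, metric: str,
                            day: Optional[float] = None,
                            value_col: str = "normalized_value"):
    """Matched (normalized circumference, normalized metric) pairs.

    ``day`` selects a single timepoint (one independent pair per animal,
    appropriate when regression p-values must be exactly calibrated);
    ``day=None`` pools all post-baseline timepoints (the usual
    swelling-function correlation plot over a disease course; points from
    one animal then share its baseline, so p-values are approximate).
    """
    if value_col not in table.columns:
        raise ValidationError(f"column {value_col!r} missing; normalize first")
    sub = table[table["day"] > 0] if day is None else table[table["day"] == day]
    x = sub[sub["metric"] == "circumference"].set_index(
        ["animal_id", "day"])[value_col]
    y = sub[sub["metric"] == metric].set_index(["animal_id", "day"])[value_col]
    common = x.index.intersection(y.index)
    x, y = x[common], y[common]
    keep = np.isfinite(x.to_numpy()) & np.isfinite(y.to_numpy())
    return x.to_numpy()[keep], y.to_numpy()[keep]


def compare_groups_timecourse(table: pd.DataFrame, metric: str,
                              groups: Tuple[str, str],
                              value_col: str = "normalized_value",
                              alpha: float = 0.05) -> pd.DataFrame:
    """Per-timepoint Welch t-tests between two groups with Holm-Sidak
    adjustment across timepoints.

    Timepoints with fewer than 2 animals per group are skipped (with a
    warning) and excluded from the adjustment family.  Returns a tidy
    frame: day, n per group, t, raw and adjusted p, significance flag.
    """
    g1, g2 = groups
    sub = table[table["metric"] == metric]
    if value_col not in sub.columns:
        raise ValidationError(f"column {value_col!r} missing; normalize first")
    days = np.sort(sub["day"].unique())
    rows = []
    for d in days:
        a = sub[(sub["group"] == g1) & (sub["day"] == d)][value_col].dropna()
        b = sub[(sub["group"] == g2) & (sub["day"] == d)][value_col].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"day {d}: <2 animals per group for {metric!r}; skipped",
                stacklevel=2,
            )
            continue
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            tstat, p = 0.0, 1.0
        else:
            tstat, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({"day": float(d), f"n_{g1}": len(a), f"n_{g2}": len(b),
                     "t": float(tstat), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValidationError("no timepoint had >=2 animals per group")
    reject, p_adj, _, _ = multipletests(
        out["p_raw"].to_numpy(), alpha=alpha, method="holm-sidak"
    )
    out["p_adj"] = p_adj
    out["significant"] = reject
    out.attrs["test"] = "welch_t"
    out.attrs["adjustment"] = "holm-sidak"
    out.attrs["alpha"] = alpha
    return out


def anova_timecourse(table: pd.DataFrame, metric: str,
                     value_col: str = "normalized_value"):
    """Two-way (group x day) ANOVA plus Tukey HSD on group — a thin
    wrapper over standard methodology for pipeline completeness."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = table[table["metric"] == metric].dropna(subset=[value_col]).copy()
    sub["day_f"] = sub["day"].astype(str)
    model = smf.ols(f"{value_col} ~ C(group) + C(day_f)", data=sub).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(sub[value_col], sub["group"])
    return aov, tukey
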