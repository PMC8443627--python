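"""Power-law fitting, exponent comparisons and island-size regressions.

Power laws (S = c*T^w for species-time, S = c*A^z / c*V^z for
species-area / species-volume) are fitted by ordinary least squares of
log10(S) on log10(T), the standard convention in the STR/SAR literature:
the exponent is the slope and c = 10^intercept.  Nonlinear least squares on
the original scale is available as an option but is never the default.
One-way ANOVA compares sets of per-island exponents between construction
methods; plain OLS handles every island-size regression.  No
multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .dataset import CommunityTimeSeries, IslandMetadata
from .str_curves import STRCurve

__all__ = [
    "RegressionResult",
    "PowerLawFit",
    "GroupComparison",
    "SizeSummary",
    "regress_pairs",
    "fit_power_law",
    "fit_str_curve",
    "compare_exponent_sets",
    "island_size_summary",
]


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS summary: slope, intercept, R^2 and the F test (df 1, n-2).

    ``degenerate`` flags fits with fewer than 3 points, where the residual
    F test has no degrees of freedom and F/p are NaN.
    """

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    n_points: int
    x_label: str = "x"
    y_label: str = "y"
    degenerate: bool = False


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted power law y = c * x^exponent (log10-log10 OLS)."""

    coefficient_c: float
    exponent: float
    r_squared: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA across groups of per-island values.

    ``r_squared`` is the eta-squared effect size (between-group sum of
    squares over total), reported because ANOVA summaries in this field
    conventionally print an R^2 alongside F.
    """

    labels: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    r_squared: float


@dataclass(frozen=True)
class SizeSummary:
    """Per-island time-averaged richness and size, each as (mean, sample SD)."""

    island_id: str
    mean_richness: float
    sd_richness: float
    mean_area: float
    sd_area: float
    mean_volume: float
    sd_volume: float


def regress_pairs(
    x: np.ndarray,
    y: np.ndarray,
    log_x: bool = False,
    log_y: bool = False,
    x_label: str = "x",
    y_label: str = "y",
) -> RegressionResult:
    """OLS of y on x with optional log10 transforms of either axis.

    Used for every pairwise regression in the pipeline: exponent w versus
    island volume, process frequency versus volume, cross-method w-vs-w,
    and robustness regressions of w on series duration or sequencing depth.
    A constant y returns slope 0 with R^2 = 0 (F = 0, p = 1) rather than an
    undefined ratio.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if log_x:
        if (x <= 0).any():
            raise ValueError("log transform requested but x has non-positive values")
        x = np.log10(x)
        x_label = f"log10({x_label})"
    if log_y:
        if (y <= 0).any():
            raise ValueError("log transform requested but y has non-positive values")
        y = np.log10(y)
        y_label = f"log10({y_label})"
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    if np.ptp(y) == 0:  # flat response: slope 0 by convention, no signal
        slope, intercept = 0.0, float(y.mean())
        r2, fstat, p = 0.0, 0.0, 1.0
    else:
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = (float(v) for v in ols.params)
        r2 = float(ols.rsquared)
        if n < 3:
            fstat, p = float("nan"), float("nan")
        else:
            fstat, p = float(ols.fvalue), float(ols.f_pvalue)
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        f_statistic=fstat,
        df_num=1,
        df_den=max(n - 2, 0),
        p_value=p,
        n_points=n,
        x_label=x_label,
        y_label=y_label,
        degenerate=n < 3,
    )


def fit_power_law(
    x: np.ndarray,
    y: np.ndarray,
    nonlinear: bool = False,
) -> PowerLawFit:
    """Fit y = c * x^exponent.

    Default is OLS on log10-log10 scale (exponent = slope,
    c = 10^intercept).  ``nonlinear=True`` instead refines (c, exponent) by
    least squares on the original scale, seeded from the log-log fit, while
    regression statistics are still reported from the log-log fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("power-law fitting requires strictly positive coordinates")
    res = regress_pairs(x, y, log_x=True, log_y=True, x_label="T", y_label="S")
    c, expo = 10.0**res.intercept, res.slope
    if nonlinear:
        (c, expo), _ = optimize.curve_fit(
            lambda t, c_, w_: c_ * t**w_, x, y, p0=[c, expo], maxfev=10000
        )
    return PowerLawFit(
        coefficient_c=float(c),
        exponent=float(expo),
        r_squared=res.r_squared,
        f_statistic=res.f_statistic,
        df_num=res.df_num,
        df_den=res.df_den,
        p_value=res.p_value,
        n_points=res.n_points,
        degenerate=res.degenerate,
    )


def fit_str_curve(
    curve: STRCurve,
    span_unit: str = "censuses",
    include_span1: bool = True,
    nonlinear: bool = False,
) -> PowerLawFit:
    """Fit the STR power law S = c*T^w to a constructed curve.

    ``span_unit="censuses"`` fits against T = 1..n.  ``span_unit="days"``
    fits against the mean day extent of each point's windows, offset by the
    median inter-census gap so the single-census point (extent 0) stays in
    the positive domain.  The span-1 point is included by default; set
    ``include_span1=False`` to drop it.
    """
    spans = curve.spans
    species = curve.species
    if span_unit == "days":
        day_spans = curve.spans_days
        offset = float(np.median(np.diff(day_spans))) if len(day_spans) > 1 else 1.0
        spans = day_spans + max(offset, 1.0)
    elif span_unit != "censuses":
        raise ValueError(f"unknown span unit {span_unit!r}")
    if not include_span1:
        keep = curve.spans > 1
        spans, species = spans[keep], species[keep]
    return fit_power_law(spans, species, nonlinear=nonlinear)


def compare_exponent_sets(
    group_a: np.ndarray,
    group_b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """One-way ANOVA between two sets of per-island exponents.

    The groups must pair the same islands (equal sizes); F carries
    df (1, N-2).  Group means +/- sample SD are reported in the usual
    "mean w = 0.0xx +/- 0.0yy" form, and eta-squared is given as the
    comparison's R^2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size != b.size:
        raise ValueError("exponent sets must cover the same islands (equal sizes)")
    if a.size < 2:
        raise ValueError("need at least 2 islands per group")
    grand = np.concatenate([a, b]).mean()
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_total = float(np.sum((np.concatenate([a, b]) - grand) ** 2))
    if ss_total == 0:
        fstat, p, eta2 = 0.0, 1.0, 0.0
    else:
        fstat, p = stats.f_oneway(a, b)
        if np.isnan(fstat):  # identical groups with zero within-variance
            fstat, p = 0.0, 1.0
        eta2 = ss_between / ss_total
    return GroupComparison(
        labels=tuple(labels),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        f_statistic=float(fstat),
        df_num=1,
        df_den=a.size + b.size - 2,
        p_value=float(p),
        r_squared=float(eta2),
    )


def island_size_summary(ts: CommunityTimeSeries, meta: IslandMetadata) -> SizeSummary:
    """Time-averaged richness and island size with their sample SDs.

    Richness is averaged over censuses; area and volume are averaged over
    their per-census series when available (error bars of richness-vs-size
    plots), otherwise the single measurement is used with SD 0.
    """
    rich = ts.richness_per_census().astype(float)
    mean_area, sd_area = meta.mean_area()
    mean_vol, sd_vol = meta.mean_volume()
    return SizeSummary(
        island_id=ts.island_id,
        mean_richness=float(rich.mean()),
        sd_richness=float(rich.std(ddof=1)) if rich.size > 1 else 0.0,
        mean_area=mean_area,
        sd_area=sd_area,
        mean_volume=mean_vol,
        sd_volume=sd_vol,
    )
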