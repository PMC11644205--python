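"""Temporal aggregation, trend fitting and driver attribution.

Scene-mean FUI values are aggregated to yearly means or to month-of-year
composites (12 values pooling all years, matching the single seasonal
cycle used for seasonal driver analysis).  Change rates are OLS slopes;
driver screening uses Pearson r with two-sided t-distribution p-values;
the joint attribution fits all drivers, standardized, in one least-squares
model and splits the explained variance R^2 among drivers by their
absolute standardized coefficients:

    contribution_i = |beta_i| / sum_j |beta_j| * R^2 * 100%
    residual       = (1 - R^2) * 100%

so contributions and the residual always total 100%.  A driver dominates
the FUI trend when its contribution exceeds 35%, or when it reaches 10-35%
with |r| >= 0.6 and p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DRIVER_NAMES",
    "InsufficientDataError",
    "TrendResult",
    "AttributionResult",
    "SensitivityResult",
    "aggregate",
    "fit_trend",
    "pearson_screen",
    "contribution_glm",
    "dominance",
    "sensitivity_excluding_sparse_years",
]

DRIVER_NAMES = ("precipitation", "sunshine", "air_temperature", "ndvi", "water_level")

CONTRIBUTION_STRONG = 35.0   # % of variance: dominant outright
CONTRIBUTION_WEAK = 10.0     # % of variance: dominant only with corroborating r, p
R_THRESHOLD = 0.6
P_THRESHOLD = 0.05


class InsufficientDataError(ValueError):
    """Too few non-missing periods for the requested statistic."""


@dataclass(frozen=True)
class TrendResult:
    """OLS line through (period index, mean FUI); slope is the change rate."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    stderr: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class AttributionResult:
    """Joint driver attribution for one FUI series.

    table: one row per driver with r, p, beta (standardized), contribution
    (% of total variance) and the dominance flag; residual_pct is the
    unexplained share, so table.contribution.sum() + residual_pct == 100.
    """

    table: pd.DataFrame
    residual_pct: float
    r_squared: float
    n: int
    dropped: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class SensitivityResult:
    """Cloud-gap sensitivity: trend with and without sparsely imaged years."""

    full: TrendResult
    filtered: TrendResult
    excluded_periods: tuple
    outliers_full: int
    outliers_filtered: int


def aggregate(scene_means: pd.DataFrame, mode: str = "yearly") -> pd.DataFrame:
    """Aggregate dated scene means into a FUI series.

    scene_means: DataFrame with columns date (datetime-like) and mean_fui;
    rows with missing mean_fui (all-cloud scenes) are ignored.
    yearly  -> mean per calendar year;
    monthly -> month-of-year composite, pooling scenes across years.

    Returns a DataFrame with columns period, mean_fui, n_scenes.
    """
    if mode not in ("yearly", "monthly"):
        raise ValueError("mode must be 'yearly' or 'monthly'")
    df = scene_means.copy()
    if df.empty:
        return pd.DataFrame(columns=["period", "mean_fui", "n_scenes"])
    dates = pd.to_datetime(df["date"])
    df = df.loc[df["mean_fui"].notna()]
    dates = dates.loc[df.index]
    key = dates.dt.year if mode == "yearly" else dates.dt.month
    grouped = df.groupby(key.rename("period"))["mean_fui"].agg(["mean", "size"])
    out = grouped.reset_index()
    out.columns = ["period", "mean_fui", "n_scenes"]
    return out


def _series_arrays(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s = series.dropna(subset=["mean_fui"])
    return s["period"].to_numpy(float), s["mean_fui"].to_numpy(float)


def fit_trend(series: pd.DataFrame, alpha: float = 0.05) -> TrendResult:
    """OLS trend line on (period, mean_fui); missing periods are skipped."""
    t, y = _series_arrays(series)
    if t.size < 3:
        raise InsufficientDataError(
            f"trend needs >= 3 non-missing periods, got {t.size}"
        )
    model = sm.OLS(y, sm.add_constant(t)).fit()
    ci = model.conf_int(alpha=alpha)
    return TrendResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        stderr=float(model.bse[1]),
        pvalue=float(model.pvalues[1]),
        n=int(t.size),
    )


def pearson_screen(series: pd.DataFrame, drivers: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p per driver, pairwise-complete.

    drivers: DataFrame with a 'period' column plus one column per driver,
    aligned to the series by period.  Zero-variance pairs yield NaN r
    (the undefined-correlation signal).  Returns driver, r, p, n.
    """
    merged = series.merge(drivers, on="period", how="inner")
    rows = []
    for name in (c for c in drivers.columns if c != "period"):
        pair = merged[["mean_fui", name]].dropna()
        n = len(pair)
        if n < 3:
            raise InsufficientDataError(
                f"driver {name!r}: needs >= 3 complete pairs, got {n}"
            )
        x = pair["mean_fui"].to_numpy(float)
        d = pair[name].to_numpy(float)
        if np.std(x) == 0 or np.std(d) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, d)
        rows.append({"driver": name, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=0)


def contribution_glm(
    series: pd.DataFrame,
    drivers: pd.DataFrame,
    flag_dominant: bool = True,
) -> AttributionResult:
    """Joint standardized least-squares attribution of the FUI series.

    All drivers are z-scored and fit together against the z-scored FUI
    (listwise deletion over periods).  Rank-deficient designs drop the
    offending driver(s) with a warning; dropped drivers keep their Pearson
    r/p but get zero contribution.
    """
    names = [c for c in drivers.columns if c != "period"]
    merged = series.merge(drivers, on="period", how="inner").dropna(
        subset=["mean_fui", *names]
    )
    n = len(merged)
    if n <= len(names):
        raise InsufficientDataError(
            f"attribution needs more complete periods ({n}) than drivers ({len(names)})"
        )
    y = _standardize(merged["mean_fui"].to_numpy(float))

    kept, dropped = [], []
    cols = []
    for name in names:
        v = merged[name].to_numpy(float)
        if v.std(ddof=0) == 0:
            dropped.append(name)
            warnings.warn(f"driver {name!r} has zero variance; dropped", stacklevel=2)
            continue
        z = _standardize(v)
        if cols and np.linalg.matrix_rank(np.column_stack(cols + [z])) <= len(cols):
            dropped.append(name)
            warnings.warn(
                f"driver {name!r} is collinear with earlier drivers; dropped",
                stacklevel=2,
            )
            continue
        kept.append(name)
        cols.append(z)

    design = np.column_stack(cols) if cols else np.empty((n, 0))
    if design.shape[1]:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        r2 = float(1.0 - resid @ resid / (y @ y))
        r2 = min(max(r2, 0.0), 1.0)
    else:
        beta = np.array([])
        r2 = 0.0

    abs_sum = np.abs(beta).sum()
    shares = np.abs(beta) / abs_sum if abs_sum > 0 else np.zeros_like(beta)
    contrib = {name: share * r2 * 100.0 for name, share in zip(kept, shares)}
    betas = dict(zip(kept, beta))

    screen = pearson_screen(series, drivers).set_index("driver")
    table = pd.DataFrame(
        {
            "driver": names,
            "r": [screen.loc[m, "r"] for m in names],
            "p": [screen.loc[m, "p"] for m in names],
            "beta": [betas.get(m, 0.0) for m in names],
            "contribution": [contrib.get(m, 0.0) for m in names],
        }
    )
    result = AttributionResult(
        table=table,
        residual_pct=(1.0 - r2) * 100.0,
        r_squared=r2,
        n=n,
        dropped=tuple(dropped),
    )
    if flag_dominant:
        result.table["dominant"] = dominance(result)
    return result


def dominance(attribution: AttributionResult) -> np.ndarray:
    """Per-driver dominance flags.

    Dominant iff contribution > 35%, or 10% <= contribution < 35% together
    with |r| >= 0.6 and p < 0.05.
    """
    t = attribution.table
    c = t["contribution"].to_numpy(float)
    r = t["r"].to_numpy(float)
    p = t["p"].to_numpy(float)
    strong = c > CONTRIBUTION_STRONG
    corroborated = (
        (c >= CONTRIBUTION_WEAK)
        & (c < CONTRIBUTION_STRONG)
        & (np.abs(r) >= R_THRESHOLD)
        & (p < P_THRESHOLD)
    )
    return strong | corroborated


def _outliers_outside_pi(series: pd.DataFrame, alpha: float = 0.05) -> int:
    """Count points outside the OLS 95% prediction interval."""
    t, y = _series_arrays(series)
    model = sm.OLS(y, sm.add_constant(t)).fit()
    frame = model.get_prediction(sm.add_constant(t)).summary_frame(alpha=alpha)
    lo = frame["obs_ci_lower"].to_numpy()
    hi = frame["obs_ci_upper"].to_numpy()
    return int(((y < lo) | (y > hi)).sum())


def sensitivity_excluding_sparse_years(
    series: pd.DataFrame, min_scenes: int = 1
) -> SensitivityResult:
    """Cloud-gap sensitivity: refit the trend without sparsely imaged years.

    Years (periods) with fewer than `min_scenes` scenes are excluded from
    the second fit; `min_scenes=1` removes only imagery-free years, and
    `min_scenes=0` is a no-op.  Also reports, for each fit, the number of
    points outside the 95% prediction interval.
    """
    full = fit_trend(series)
    keep = series["n_scenes"] >= min_scenes
    excluded = tuple(series.loc[~keep, "period"].tolist())
    sub = series.loc[keep]
    if sub.dropna(subset=["mean_fui"]).shape[0] < 3:
        raise InsufficientDataError(
            "excluding sparse years leaves fewer than 3 periods"
        )
    filtered = fit_trend(sub)
    return SensitivityResult(
        full=full,
        filtered=filtered,
        excluded_periods=excluded,
        outliers_full=_outliers_outside_pi(series),
        outliers_filtered=_outliers_outside_pi(sub),
    )
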