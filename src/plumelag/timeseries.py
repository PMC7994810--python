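"""Weekly timeseries pipeline: subsampling, decomposition, PACF, and
per-season cross-correlation with peak-lag extraction.

The analysis follows the pulsed-upwelling workflow: daily wind and SST
series are reduced to weekly resolution (weekly means for wind, every
7th day for SST and call density) to suppress day-scale autocorrelation;
a classical additive decomposition with a 52-week period removes the
seasonal cycle and long-term trend; the residuals are subset to the
austral spring–summer (October–March) seasons; and the cross-correlation
function (CCF) between driver and response is computed per season at
integer weekly lags 0..max_lag. Per-lag correlations are averaged across
seasons (mean ± SE), with marine-heatwave seasons partitioned out a
priori and reported separately, and the lag of the strongest correlation
in the expected direction is the estimated physical-to-biological delay.

Sign convention, used everywhere: the *driver* series is the first CCF
argument, and a positive lag k means the response trails the driver by
k weeks (x_t is paired with y_{t+k}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .config import AnalysisConfig
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "weekly_mean",
    "weekly_subsample",
    "pacf",
    "decompose",
    "DecomposedSeries",
    "season_subset",
    "ccf",
    "aggregate_ccf",
    "CCFResult",
    "peak_lag",
    "PeakLag",
    "circular_linear_correlation",
    "CircularLinearResult",
]


def _as_daily_series(daily) -> pd.Series:
    """Coerce input to a date-indexed daily Series."""
    if isinstance(daily, pd.DataFrame):
        if "date" not in daily.columns:
            raise ValidationError("daily table must have a 'date' column")
        value_cols = [c for c in daily.columns if c != "date"]
        s = pd.Series(
            daily[value_cols[0]].to_numpy(float), index=pd.DatetimeIndex(daily["date"])
        )
    else:
        s = pd.Series(np.asarray(daily.values, float), index=pd.DatetimeIndex(daily.index))
    if not s.index.is_monotonic_increasing:
        raise ValidationError("daily values must be sorted by date")
    return s


def weekly_mean(daily) -> pd.Series:
    """Weekly means over non-overlapping 7-day blocks.

    Blocks are anchored at the first date of the series; the block value
    is the mean over its non-missing days and is missing only when all
    seven days are missing. Returns a Series indexed by block start date.
    """
    s = _as_daily_series(daily)
    if len(s) == 0:
        return pd.Series(dtype=float)
    t0 = s.index[0]
    week = ((s.index - t0).days // 7).to_numpy()
    grouped = s.groupby(week).mean()  # nan-skipping mean per block
    idx = t0 + pd.to_timedelta(grouped.index * 7, unit="D")
    return pd.Series(grouped.to_numpy(), index=idx)


def weekly_subsample(daily, phase: int = 0) -> pd.Series:
    """One daily value per week, taken every 7th day at the given phase.

    The sample for the block starting at t0+7k is the daily value at
    t0+7k+phase; the returned index is the block start date so that
    differently phased subsamples stay aligned on a common weekly grid.
    Missing sampled days stay missing.
    """
    if not 0 <= int(phase) <= 6:
        raise ValidationError(f"phase must be in [0, 6], got {phase}")
    s = _as_daily_series(daily)
    if len(s) == 0:
        return pd.Series(dtype=float)
    t0 = s.index[0]
    n_weeks = (s.index[-1] - t0).days // 7 + 1
    starts = t0 + pd.to_timedelta(np.arange(n_weeks) * 7, unit="D")
    sample_days = starts + pd.Timedelta(days=int(phase))
    vals = s.reindex(sample_days).to_numpy()
    return pd.Series(vals, index=starts)


def pacf(series, max_lag: int) -> tuple[np.ndarray, float]:
    """Partial autocorrelations at lags 1..max_lag with 95% bounds.

    Computed by the Durbin–Levinson recursion on the sample
    autocorrelations. Returns ``(pacf_values, bound)`` where the null
    95% bounds are ±bound = ±1.96/√n.
    """
    x = np.asarray(pd.Series(series).dropna(), float)
    n = len(x)
    if n < max_lag + 2:
        raise InsufficientDataError(
            f"need at least {max_lag + 2} non-missing points, got {n}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant series has no defined PACF")
    vals = _sm_pacf(x, nlags=max_lag, method="ywm")[1:]
    return vals, 1.96 / np.sqrt(n)


@dataclass
class DecomposedSeries:
    """Classical additive decomposition: observed = trend + seasonal + residual."""

    observed: pd.Series
    trend: pd.Series
    seasonal: pd.Series
    residual: pd.Series
    period: int


def decompose(series: pd.Series, period: int = 52) -> DecomposedSeries:
    """Classical additive decomposition of a weekly series.

    The trend is a centred moving average of length *period* (the
    standard 2×period average when the period is even); the seasonal
    component is the per-phase mean of the detrended values, re-centred
    to sum to zero over one period; the residual is what remains. The
    trend (and hence residual) is undefined for half a period at each
    end, which is how the first and last calendar years drop out of a
    multi-year analysis.
    """
    x = np.asarray(series.values, float)
    n = len(x)
    if n < 2 * period:
        raise InsufficientDataError(
            f"series spans {n} points; decomposition needs at least 2 periods ({2 * period})"
        )
    half = period // 2
    if period % 2 == 0:
        weights = np.full(period + 1, 1.0 / period)
        weights[0] = weights[-1] = 0.5 / period
    else:
        weights = np.full(period, 1.0 / period)
    # NaN-strict centred moving average: trend undefined wherever the
    # window touches a gap or an edge.
    trend = np.full(n, np.nan)
    wlen = len(weights)
    valid = np.isfinite(x)
    for i in range(half, n - half):
        window = x[i - half : i - half + wlen]
        if np.isfinite(window).all():
            trend[i] = window @ weights
    detrended = x - trend
    phase = np.arange(n) % period
    seasonal_means = np.full(period, np.nan)
    for p in range(period):
        vals = detrended[phase == p]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            seasonal_means[p] = vals.mean()
    seasonal_means -= np.nanmean(seasonal_means)
    seasonal = seasonal_means[phase]
    seasonal[~valid] = np.nan
    residual = x - trend - seasonal
    idx = series.index
    return DecomposedSeries(
        observed=pd.Series(x, index=idx),
        trend=pd.Series(trend, index=idx),
        seasonal=pd.Series(seasonal, index=idx),
        residual=pd.Series(residual, index=idx),
        period=period,
    )


def season_subset(series: pd.Series, config: AnalysisConfig) -> dict[int, pd.Series]:
    """Split a weekly series into spring–summer season segments.

    A week belongs to the season containing its start date; both season
    bounds are inclusive. Seasons are labelled by their January year and
    returned in chronological order; seasons with no data are omitted.
    """
    labels = [config.season_label(d) for d in series.index]
    out: dict[int, pd.Series] = {}
    for lab in sorted({l for l in labels if l is not None}):
        mask = np.array([l == lab for l in labels])
        seg = series[mask]
        if len(seg):
            out[lab] = seg
    return out


def ccf(x, y, max_lag: int) -> np.ndarray:
    """Cross-correlation of driver *x* with response *y* at lags 0..max_lag.

    The value at lag k is the Pearson correlation between x_t and
    y_{t+k} over pairs where both are non-missing (pairwise deletion).
    Lags with fewer than 3 valid pairs or zero variance in either window
    are returned as NaN.
    """
    x = np.asarray(pd.Series(x).values, float)
    y = np.asarray(pd.Series(y).values, float)
    if len(x) != len(y):
        raise ValidationError("ccf requires aligned segments of equal length")
    n = len(x)
    out = np.full(max_lag + 1, np.nan)
    for k in range(max_lag + 1):
        if n - k < 3:
            break
        a = x[: n - k]
        b = y[k:]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            continue
        a, b = a[ok], b[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        out[k] = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return out


@dataclass
class PeakLag:
    lag: int
    value: float
    degenerate: bool = False  # no value in the expected direction existed


def peak_lag(values, expected_sign: str = "either") -> PeakLag:
    """Lag of the strongest correlation in the expected direction.

    ``expected_sign`` is "positive", "negative" or "either" (max |r|).
    Ties break toward the smallest lag, preferring the physically
    proximate explanation. If no finite value has the expected sign the
    least-contradictory lag is returned with ``degenerate=True``.
    """
    v = np.asarray(values, float)
    finite = np.isfinite(v)
    if not finite.any():
        raise DegenerateDataError("all correlation values missing")
    if expected_sign == "negative":
        key = v
        best = int(np.nanargmin(key))
        return PeakLag(best, float(v[best]), degenerate=v[best] > 0)
    if expected_sign == "positive":
        best = int(np.nanargmax(v))
        return PeakLag(best, float(v[best]), degenerate=v[best] < 0)
    if expected_sign == "either":
        best = int(np.nanargmax(np.abs(v)))
        return PeakLag(best, float(v[best]))
    raise ValidationError(f"expected_sign must be positive|negative|either, got {expected_sign!r}")


@dataclass
class CCFResult:
    """Cross-season summary of per-season CCF curves."""

    lags: np.ndarray
    per_season_acf: dict[int, np.ndarray]
    mean_acf: np.ndarray
    se_acf: np.ndarray
    heatwave_acf: dict[int, np.ndarray]
    peak_lag: int
    peak_acf: float
    degenerate_peak: bool = False


def aggregate_ccf(
    per_season: dict[int, np.ndarray],
    heatwave_seasons=(),
    expected_sign: str = "either",
) -> CCFResult:
    """Mean ± SE of per-season CCF curves, heatwave seasons partitioned out.

    The mean and standard error at each lag are taken across non-heatwave
    seasons only; curves from heatwave seasons are carried separately.
    The peak lag is selected on the mean curve with :func:`peak_lag`.
    """
    heat = {int(s) for s in heatwave_seasons}
    included = {s: np.asarray(v, float) for s, v in per_season.items() if int(s) not in heat}
    excluded = {s: np.asarray(v, float) for s, v in per_season.items() if int(s) in heat}
    if not included:
        raise InsufficientDataError("all seasons excluded as heatwave seasons")
    mat = np.vstack(list(included.values()))
    n_lags = mat.shape[1]
    mean = np.nanmean(mat, axis=0)
    counts = np.isfinite(mat).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(mat, axis=0, ddof=1)
        se = np.where(counts >= 2, sd / np.sqrt(counts), np.nan)
    pk = peak_lag(mean, expected_sign)
    return CCFResult(
        lags=np.arange(n_lags),
        per_season_acf=included,
        mean_acf=mean,
        se_acf=se,
        heatwave_acf=excluded,
        peak_lag=pk.lag,
        peak_acf=pk.value,
        degenerate_peak=pk.degenerate,
    )


@dataclass
class CircularLinearResult:
    """Linear–circular association between wind speed and direction."""

    r_squared: float
    statistic: float  # n * R², chi-square with 2 df under the null
    p_value: float
    n: int


def circular_linear_correlation(speeds, directions_deg) -> CircularLinearResult:
    """Correlation between a linear variable and an angle (Mardia).

    With c = cos θ and s = sin θ,
    R² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs) / (1 − r_cs²),
    and n·R² is referred to a chi-square distribution with 2 df.
    """
    x = np.asarray(speeds, float)
    theta = np.deg2rad(np.asarray(directions_deg, float))
    ok = np.isfinite(x) & np.isfinite(theta)
    x, theta = x[ok], theta[ok]
    n = len(x)
    if n < 5:
        raise InsufficientDataError(f"need n >= 5 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in the linear variable")
    c, s = np.cos(theta), np.sin(theta)

    def _r(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))

    r_xc, r_xs, r_cs = _r(x, c), _r(x, s), _r(c, s)
    denom = 1.0 - r_cs**2
    if denom <= 1e-12:
        raise DegenerateDataError("degenerate angular sample (cos and sin collinear)")
    r2 = (r_xc**2 + r_xs**2 - 2.0 * r_xc * r_xs * r_cs) / denom
    r2 = float(min(max(r2, 0.0), 1.0))
    stat = n * r2
    p = float(stats.chi2.sf(stat, df=2))
    return CircularLinearResult(r_squared=r2, statistic=stat, p_value=p, n=n)
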