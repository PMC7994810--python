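"""End-to-end analyses composed from the stage modules.

Two headline analyses:

* :func:`wind_sst_lag_analysis` — the weekly cross-correlation pipeline
  from daily wind and per-box SST to a per-box :class:`CCFResult`
  (per-season CCF curves, cross-season mean ± SE with heatwave seasons
  partitioned out, and the peak lag in weeks);
* :func:`aggregation_lag_analysis` — the event-based pipeline from
  daily wind and sightings to wind events, aggregations, start-to-start
  lags, and the Poisson GLM of lag on prior windy days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import InsufficientDataError
from .events import (
    Aggregation,
    WindEvent,
    compute_lags,
    detect_aggregations,
    detect_wind_events,
    fit_poisson_glm,
)
from .timeseries import (
    CCFResult,
    aggregate_ccf,
    ccf,
    decompose,
    season_subset,
    weekly_mean,
    weekly_subsample,
)

__all__ = [
    "weekly_residual",
    "seasonal_ccf",
    "wind_sst_lag_analysis",
    "aggregation_lag_analysis",
]


def weekly_residual(
    daily,
    config: AnalysisConfig,
    how: str = "subsample",
    detrend: bool = True,
    phase: int | None = None,
) -> pd.Series:
    """Reduce a daily series to its weekly stationary residual.

    ``how="mean"`` takes weekly means (wind); ``how="subsample"`` takes
    every 7th day at the configured phase (SST, call density). When
    *detrend* is true the classical decomposition removes the 52-week
    seasonal cycle and trend and the residual is returned; a series too
    short to decompose (like a single-season call-density record) must
    be passed with ``detrend=False`` to use the observed values.
    """
    if how == "mean":
        weekly = weekly_mean(daily)
    elif how == "subsample":
        weekly = weekly_subsample(daily, config.subsample_phase if phase is None else phase)
    else:
        raise ValueError(f"how must be 'mean' or 'subsample', got {how!r}")
    if not detrend:
        return weekly
    return decompose(weekly, config.decomposition_period).residual


def seasonal_ccf(
    driver_weekly: pd.Series,
    response_weekly: pd.Series,
    config: AnalysisConfig,
    expected_sign: str = "either",
) -> CCFResult:
    """Per-season CCF between two weekly series, aggregated across seasons.

    The series are aligned on their common weekly dates, split into
    spring–summer seasons, cross-correlated at lags 0..max_lag within
    each season with enough paired data, and summarised with heatwave
    seasons partitioned out.
    """
    common = driver_weekly.index.intersection(response_weekly.index)
    if len(common) == 0:
        raise InsufficientDataError(
            "driver and response share no weekly dates; use a common anchor date"
        )
    x = driver_weekly.loc[common]
    y = response_weekly.loc[common]
    seasons_x = season_subset(x, config)
    seasons_y = season_subset(y, config)
    per_season = {}
    for label in seasons_x:
        if label not in seasons_y:
            continue
        xs, ys = seasons_x[label], seasons_y[label]
        paired = np.isfinite(xs.to_numpy()) & np.isfinite(ys.to_numpy())
        if paired.sum() < config.max_lag + 3:
            continue
        per_season[label] = ccf(xs, ys, config.max_lag)
    if not per_season:
        raise InsufficientDataError("no season has enough paired weekly data for the CCF")
    return aggregate_ccf(per_season, config.heatwave_seasons, expected_sign)


def wind_sst_lag_analysis(
    wind: pd.DataFrame,
    sst_boxes: dict[str, pd.Series],
    config: AnalysisConfig,
) -> dict[str, CCFResult]:
    """Peak lags between wind speed and SST at each box along the plume.

    Wind is reduced to weekly means, SST subsampled weekly; both are
    decomposed (52-week classical decomposition) and their residuals
    cross-correlated per season with a negative expected sign (more
    wind → colder SST). Returns a per-box :class:`CCFResult`.
    """
    driver = weekly_residual(wind[["date", "speed"]], config, how="mean")
    out = {}
    for box, series in sst_boxes.items():
        response = weekly_residual(series, config, how="subsample")
        out[box] = seasonal_ccf(driver, response, config, expected_sign="negative")
    return out


def aggregation_lag_analysis(
    wind: pd.DataFrame,
    sightings: pd.DataFrame,
    config: AnalysisConfig,
    season_only: bool = True,
) -> dict:
    """Wind events → aggregations → lags → Poisson GLM, in one call.

    With ``season_only`` (default) only aggregations starting within a
    spring–summer season are analysed, matching the seasonal scope of
    the wind-event definition. Returns a dict with the detected events,
    aggregations, per-aggregation lag records, lag summary (mean ± SE
    in weeks), and the GLM fit (None when there is too little data).
    """
    events = detect_wind_events(
        wind, config.wind_event_threshold, min_days=config.wind_event_min_days
    )
    aggregations = detect_aggregations(
        sightings,
        min_whales=config.aggregation_min_whales,
        window_days=config.aggregation_window_days,
        radius_km=config.aggregation_radius_km,
        mode=config.aggregation_mode,
    )
    if season_only:
        aggregations = [a for a in aggregations if config.season_label(a.start_date) is not None]
    lag_df, summary = compute_lags(aggregations, events, wind, config)
    glm = None
    if summary["n_lags"] >= 3 and lag_df["windy_days_prior30"].nunique() > 1:
        glm = fit_poisson_glm(lag_df["lag_days"], lag_df["windy_days_prior30"])
    return {
        "events": events,
        "aggregations": aggregations,
        "lags": lag_df,
        "summary": summary,
        "glm": glm,
    }
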