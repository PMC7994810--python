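"""Event-based analysis: wind events, sighting aggregations, the lag
between them, and the Poisson regression of lag on prior wind input.

A *wind event* is a maximal run of ≥2 consecutive days with daily wind
speed strictly above a threshold (default 5.5 m s⁻¹, the regional
spring–summer mean). An *aggregation* is a cluster of sightings
totalling ≥5 whales seen within one week and 50 km of one another. The
lag for each aggregation is the number of days from the start of the
most recent previous wind event to the aggregation start, and the
variation in lag is modelled as Poisson with log-mean linear in the
number of windy days in the preceding 30 days — a proxy for how
well-mixed the water column already is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import AnalysisConfig
from .errors import DegenerateDataError, InsufficientDataError, ValidationError

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "WindEvent",
    "Aggregation",
    "PoissonGlmFit",
    "detect_wind_events",
    "summarize_events",
    "haversine_km",
    "detect_aggregations",
    "windy_days_prior",
    "compute_lags",
    "fit_poisson_glm",
    "threshold_sensitivity",
]


@dataclass(frozen=True)
class WindEvent:
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    duration_days: int
    peak_speed: float
    threshold: float


@dataclass(frozen=True)
class Aggregation:
    id: str
    member_sightings: tuple
    start_date: pd.Timestamp
    total_whales: int
    centroid: tuple  # (lat, lon)


def detect_wind_events(wind: pd.DataFrame, threshold: float, min_days: int = 2) -> list[WindEvent]:
    """Maximal runs of consecutive days with speed strictly above *threshold*.

    Runs shorter than *min_days* are dropped; gaps in the daily record
    break runs. Events are returned ordered by start date.
    """
    if len(wind) == 0:
        return []
    dates = pd.DatetimeIndex(wind["date"])
    speeds = np.asarray(wind["speed"], float)
    events: list[WindEvent] = []
    run_start = None
    run_speeds: list[float] = []
    prev_date = None

    def _close(end_idx_date):
        if run_start is not None:
            duration = (end_idx_date - run_start).days + 1
            if duration >= min_days:
                events.append(
                    WindEvent(
                        start_date=run_start,
                        end_date=end_idx_date,
                        duration_days=duration,
                        peak_speed=float(max(run_speeds)),
                        threshold=float(threshold),
                    )
                )

    for d, v in zip(dates, speeds):
        contiguous = prev_date is not None and (d - prev_date).days == 1
        if v > threshold:
            if run_start is None or not contiguous:
                _close(prev_date)
                run_start = d
                run_speeds = []
            run_speeds.append(v)
        else:
            _close(prev_date)
            run_start = None
        prev_date = d
    _close(prev_date)
    return sorted(events, key=lambda e: e.start_date)


def summarize_events(events: list[WindEvent], config: AnalysisConfig) -> dict:
    """Per-season counts plus duration and inter-event gap statistics.

    Events are assigned to the spring–summer season containing their
    start date (events outside any season are uncounted). Gaps are
    next-start minus previous-end, in days, between consecutive events
    within the same season.
    """
    per_season: dict[int, int] = {}
    gaps: list[int] = []
    durations = [e.duration_days for e in events]
    by_season: dict[int, list[WindEvent]] = {}
    for e in events:
        lab = config.season_label(e.start_date)
        if lab is None:
            continue
        per_season[lab] = per_season.get(lab, 0) + 1
        by_season.setdefault(lab, []).append(e)
    for lab, evs in by_season.items():
        for prev, nxt in zip(evs, evs[1:]):
            gaps.append((nxt.start_date - prev.end_date).days)
    return {
        "per_season_counts": dict(sorted(per_season.items())),
        "mean_events_per_season": float(np.mean(list(per_season.values()))) if per_season else np.nan,
        "duration_mean": float(np.mean(durations)) if durations else np.nan,
        "duration_range": (min(durations), max(durations)) if durations else (None, None),
        "gap_mean": float(np.mean(gaps)) if gaps else np.nan,
        "gap_range": (min(gaps), max(gaps)) if gaps else (None, None),
    }


def haversine_km(p1, p2) -> float:
    """Great-circle distance in km between (lat, lon) points, R = 6371 km."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValidationError(f"latitude {lat} outside [-90, 90]")
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = phi2 - phi1
    dlam = np.deg2rad(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _linkage_matrix(
    dates: pd.DatetimeIndex, lats: np.ndarray, lons: np.ndarray,
    window_days: float, radius_km: float,
) -> np.ndarray:
    """Boolean adjacency: pairs within the week/50-km rule of one another."""
    t = dates.to_numpy().astype("datetime64[D]").astype(np.int64)
    near_time = np.abs(t[:, None] - t[None, :]) <= window_days
    phi = np.deg2rad(lats)
    lam = np.deg2rad(lons)
    a = (
        np.sin((phi[:, None] - phi[None, :]) / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin((lam[:, None] - lam[None, :]) / 2.0) ** 2
    )
    dist = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return near_time & (dist <= radius_km)


def detect_aggregations(
    sightings: pd.DataFrame,
    min_whales: int = 5,
    window_days: int = 7,
    radius_km: float = 50.0,
    mode: str = "chain",
) -> list[Aggregation]:
    """Cluster sightings into whale aggregations.

    In the default "chain" mode, sightings are linked when within
    *window_days* and *radius_km* of one another and clusters are the
    connected components of that graph (single linkage). In "clique"
    mode a sighting joins a cluster only if linked to every current
    member (greedy, in date order). Clusters whose summed whale counts
    reach *min_whales* become aggregations, with start date the earliest
    member date and centroid the arithmetic mean of member coordinates.
    """
    n = len(sightings)
    if n == 0:
        return []
    rows = sightings.reset_index(drop=True)
    dates = pd.DatetimeIndex(rows["date"])
    lats = rows["lat"].to_numpy(float)
    lons = rows["lon"].to_numpy(float)
    counts = rows["count"].to_numpy(int)
    ids = rows["id"].astype(str).to_numpy()
    adj = _linkage_matrix(dates, lats, lons, window_days, radius_km)

    if mode == "chain":
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        _, labels = connected_components(csr_matrix(adj), directed=False)
        clusters = [np.flatnonzero(labels == lab).tolist() for lab in np.unique(labels)]
    elif mode == "clique":
        order = sorted(range(n), key=lambda i: (dates[i], ids[i]))
        clusters = []
        for i in order:
            for cluster in clusters:
                if all(adj[i, j] for j in cluster):
                    cluster.append(i)
                    break
            else:
                clusters.append([i])
    else:
        raise ValidationError(f"mode must be 'chain' or 'clique', got {mode!r}")

    out: list[Aggregation] = []
    for members in clusters:
        total = int(counts[members].sum())
        if total < min_whales:
            continue
        out.append(
            Aggregation(
                id="",
                member_sightings=tuple(ids[members]),
                start_date=dates[members].min(),
                total_whales=total,
                centroid=(float(lats[members].mean()), float(lons[members].mean())),
            )
        )
    out.sort(key=lambda a: a.start_date)
    return [
        Aggregation(f"agg{k:03d}", a.member_sightings, a.start_date, a.total_whales, a.centroid)
        for k, a in enumerate(out)
    ]


def windy_days_prior(
    wind: pd.DataFrame, date, window_days: int = 30, threshold: float = 5.5
) -> int:
    """Count of days in [date − window_days, date − 1] with speed > threshold.

    The aggregation start day itself is excluded; the day exactly
    window_days before is included. Days missing from the record count
    as not windy.
    """
    d = pd.Timestamp(date)
    lo = d - pd.Timedelta(days=int(window_days))
    hi = d - pd.Timedelta(days=1)
    mask = (wind["date"] >= lo) & (wind["date"] <= hi)
    return int((wind.loc[mask, "speed"] > threshold).sum())


def compute_lags(
    aggregations: list[Aggregation],
    events: list[WindEvent],
    wind: pd.DataFrame,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, dict]:
    """Lag from the most recent previous wind event to each aggregation.

    For each aggregation the latest event with start ≤ aggregation start
    and within ``config.max_lookback_days`` is selected; the lag is the
    start-to-start difference in days. Aggregations with no qualifying
    event are excluded and counted. The summary reports the lag mean and
    standard error in weeks (days / 7, unrounded).
    """
    starts = [e.start_date for e in events]
    records = []
    n_excluded = 0
    for agg in aggregations:
        candidates = [
            (s, e)
            for s, e in zip(starts, events)
            if s <= agg.start_date and (agg.start_date - s).days <= config.max_lookback_days
        ]
        if not candidates:
            n_excluded += 1
            continue
        s, e = max(candidates, key=lambda t: t[0])
        lag = int((agg.start_date - s).days)
        records.append(
            {
                "aggregation_id": agg.id,
                "aggregation_start": agg.start_date,
                "wind_event_start": s,
                "lag_days": lag,
                "event_ongoing": e.end_date >= agg.start_date,
                "windy_days_prior30": windy_days_prior(
                    wind,
                    agg.start_date,
                    window_days=config.prior_wind_window_days,
                    threshold=config.wind_event_threshold,
                ),
            }
        )
    df = pd.DataFrame(
        records,
        columns=[
            "aggregation_id",
            "aggregation_start",
            "wind_event_start",
            "lag_days",
            "event_ongoing",
            "windy_days_prior30",
        ],
    )
    lag_weeks = df["lag_days"].to_numpy(float) / 7.0
    n = len(lag_weeks)
    summary = {
        "n_lags": n,
        "n_excluded": n_excluded,
        "mean_lag_weeks": float(np.mean(lag_weeks)) if n else np.nan,
        "se_lag_weeks": float(np.std(lag_weeks, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan,
    }
    return df, summary


@dataclass
class PoissonGlmFit:
    """Log-link Poisson regression of lag days on prior windy days."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    deviance: float
    null_deviance: float
    lr_chi2: float
    df: int
    p_value: float
    aic: float
    n: int


def fit_poisson_glm(response, covariate) -> PoissonGlmFit:
    """Fit lag ~ windy-days with a Poisson GLM (log link, IRLS).

    Reports coefficients with standard errors, residual deviance, and a
    likelihood-ratio chi-square (1 df) against the intercept-only model.
    """
    y = np.asarray(response, float)
    x = np.asarray(covariate, float)
    if len(y) != len(x):
        raise ValidationError("response and covariate must be paired")
    if len(y) < 3:
        raise InsufficientDataError(f"need n >= 3, got {len(y)}")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValidationError("Poisson response must be nonnegative integers")
    if np.ptp(x) == 0:
        raise DegenerateDataError("covariate has zero variance")
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-10)
    if not fit.converged:
        raise DegenerateDataError("Poisson IRLS failed to converge")
    null = sm.GLM(y, np.ones_like(y), family=sm.families.Poisson()).fit()
    lr = float(null.deviance - fit.deviance)
    return PoissonGlmFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        se_intercept=float(fit.bse[0]),
        se_slope=float(fit.bse[1]),
        deviance=float(fit.deviance),
        null_deviance=float(null.deviance),
        lr_chi2=lr,
        df=1,
        p_value=float(stats.chi2.sf(lr, df=1)),
        aic=float(fit.aic),
        n=len(y),
    )


def threshold_sensitivity(
    wind: pd.DataFrame,
    sightings: pd.DataFrame,
    config: AnalysisConfig,
    thresholds=(3.0, 5.5, 8.0, 10.5),
) -> pd.DataFrame:
    """Sensitivity of the lag–wind relationship to the event threshold.

    For each threshold the event detection, lag computation and GLM fit
    are rerun; the returned table has one row per threshold with event
    count, mean lag, GLM deviance/AIC/slope, and a flag marking the
    best-fitting threshold by lowest AIC. Thresholds yielding no events
    (or too few lags) get missing GLM fields.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValidationError("thresholds must be positive and ascending")
    aggregations = detect_aggregations(
        sightings,
        min_whales=config.aggregation_min_whales,
        window_days=config.aggregation_window_days,
        radius_km=config.aggregation_radius_km,
        mode=config.aggregation_mode,
    )
    rows = []
    for thr in thresholds:
        events = detect_wind_events(wind, thr, min_days=config.wind_event_min_days)
        row = {
            "threshold": thr,
            "n_events": len(events),
            "n_lags": 0,
            "mean_lag_weeks": np.nan,
            "deviance": np.nan,
            "aic": np.nan,
            "slope": np.nan,
            "p_value": np.nan,
        }
        if events:
            cfg = AnalysisConfig(
                **{
                    **{f: getattr(config, f) for f in config.__dataclass_fields__},
                    "wind_event_threshold": thr,
                }
            )
            lag_df, summary = compute_lags(aggregations, events, wind, cfg)
            row["n_lags"] = summary["n_lags"]
            row["mean_lag_weeks"] = summary["mean_lag_weeks"]
            if summary["n_lags"] >= 3 and lag_df["windy_days_prior30"].nunique() > 1:
                fit = fit_poisson_glm(lag_df["lag_days"], lag_df["windy_days_prior30"])
                row.update(
                    deviance=fit.deviance, aic=fit.aic, slope=fit.slope, p_value=fit.p_value
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    table["best_fit"] = False
    if table["aic"].notna().any():
        table.loc[table["aic"].idxmin(), "best_fit"] = True
    return table
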