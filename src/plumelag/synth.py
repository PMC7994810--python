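"""Synthetic wind, SST, sighting, and audio generators.

These generators produce data with the statistical structure the
analysis assumes, so every pipeline stage can be exercised and its
injected ground truth recovered without any external download:

* wind — seasonal background plus pulsed high-wind events (a seasonally
  modulated Poisson process) and a direction model in which stronger
  winds are increasingly westerly;
* SST per spatial box — seasonal cycle, warming trend, noise, optional
  marine-heatwave offsets, and a negative response to smoothed wind
  anomaly delayed by a box-specific lag of 0–3 weeks (the upwelling
  plume's spatial progression);
* sightings — aggregations of ≥5 whales placed after wind events with a
  Poisson lag whose log-mean decreases with the amount of wind in the
  prior 30 days, plus background singletons;
* audio — ~100→20 Hz downswept calls in colored noise at a controlled
  band signal-to-noise ratio, with ground-truth annotations.

All generators are pure functions of ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .acoustic import Spectrogram, spectrogram
from .errors import ParameterError
from .events import WindEvent, haversine_km, windy_days_prior

__all__ = [
    "WindSimParams",
    "PlumeSimParams",
    "SightingSimParams",
    "AudioSimParams",
    "NoiseSimParams",
    "gen_wind",
    "gen_sst",
    "gen_sightings",
    "gen_audio_with_calls",
    "gen_hourly_noise",
    "make_call_templates",
]


# --------------------------------------------------------------------------
# wind


@dataclass(frozen=True)
class WindSimParams:
    """Daily wind simulation settings.

    The event process is identifiable by construction: event days sit
    strictly above ``event_threshold`` and background days are capped
    just below it, so run detection at that threshold recovers exactly
    the injected events.
    """

    n_years: int = 11
    start_date: str = "2009-01-01"
    base_speed: float = 4.0  # m/s background level
    seasonal_amplitude: float = 1.2  # m/s, peaking in late spring
    event_rate_per_season: float = 18.0
    event_duration_days: tuple = (2, 8)
    event_excess_speed: float = 3.0  # mean excess above threshold on event days
    noise_sd: float = 0.8
    westerly_concentration: float = 0.15  # 0 = direction independent of speed
    event_threshold: float = 5.5
    offseason_rate_factor: float = 0.5

    def __post_init__(self):
        if self.n_years < 1:
            raise ParameterError(f"n_years must be >= 1, got {self.n_years}")
        if self.event_rate_per_season <= 0:
            raise ParameterError("event_rate_per_season must be positive")
        lo, hi = self.event_duration_days
        if not (2 <= lo <= hi):
            raise ParameterError(f"invalid event duration range {self.event_duration_days}")
        for name in (
            "base_speed",
            "seasonal_amplitude",
            "event_excess_speed",
            "noise_sd",
            "westerly_concentration",
            "offseason_rate_factor",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _season_windows(dates: pd.DatetimeIndex) -> list[tuple[int, int, bool]]:
    """(start_idx, stop_idx, in_season) windows covering the date span.

    In-season windows run 1 October – 31 March; the rest of each year is
    off-season.
    """
    months = dates.month
    in_season = (months >= 10) | (months <= 3)
    windows = []
    i = 0
    n = len(dates)
    while i < n:
        j = i
        while j < n and in_season[j] == in_season[i]:
            j += 1
        windows.append((i, j, bool(in_season[i])))
        i = j
    return windows


def _draw_event_duration(rng, lo: int, hi: int) -> int:
    """Truncated-geometric event duration: most events short, range lo..hi.

    Matches the observed event statistics (mean near three days with a
    2–8 day range) better than a uniform draw would.
    """
    d = lo + rng.geometric(0.45) - 1
    return int(min(d, hi))


def gen_wind(params: WindSimParams, seed: int) -> pd.DataFrame:
    """Generate a daily wind table (date, speed, direction).

    speed = seasonal background + noise, capped below the event
    threshold, with injected event runs strictly above it; direction is
    a mixture of a uniform component and a westerly (270°) von Mises
    component whose weight grows with speed.
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(params.start_date)
    end = start + pd.DateOffset(years=params.n_years) - pd.Timedelta(days=1)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)

    background = (
        params.base_speed
        + params.seasonal_amplitude * np.cos(2 * np.pi * (doy - 315.0) / 365.25)
        + rng.normal(0.0, params.noise_sd, n)
    )
    speed = np.clip(background, 0.0, params.event_threshold - 0.1)

    lo, hi = params.event_duration_days
    event_mask = np.zeros(n, bool)
    blocked = np.zeros(n, bool)  # event days plus 1-day buffers
    for i0, i1, in_season in _season_windows(dates):
        span = i1 - i0
        rate = params.event_rate_per_season * (span / 182.0)
        if not in_season:
            rate *= params.offseason_rate_factor
        n_events = rng.poisson(rate)
        for _ in range(n_events):
            dur = _draw_event_duration(rng, lo, hi)
            for _try in range(100):
                s = i0 + int(rng.integers(0, max(span - dur, 1)))
                e = min(s + dur, i1)
                if e - s >= lo and not blocked[max(s - 1, 0) : min(e + 1, n)].any():
                    event_mask[s:e] = True
                    blocked[max(s - 1, 0) : min(e + 1, n)] = True
                    amp = 0.5 + rng.exponential(max(params.event_excess_speed - 0.5, 0.1))
                    speed[s:e] = params.event_threshold + amp * (
                        0.7 + 0.6 * rng.random(e - s)
                    )
                    break

    # direction: westerly component weight grows with speed
    p_west = 1.0 - np.exp(-params.westerly_concentration * speed)
    westerly = (np.degrees(rng.vonmises(0.0, 3.0, n)) + 270.0) % 360.0
    uniform = rng.uniform(0.0, 360.0, n)
    direction = np.where(rng.random(n) < p_west, westerly, uniform)

    return pd.DataFrame({"date": dates, "speed": speed, "direction": direction})


# --------------------------------------------------------------------------
# SST


@dataclass(frozen=True)
class PlumeSimParams:
    """SST response settings for the boxes along the upwelling plume."""

    box_lags_weeks: dict = field(
        default_factory=lambda: {
            "Kahurangi": 1,
            "CapeFarewell": 2,
            "CentralSTB": 2,
            "Hydrophone": 2,
        }
    )
    plume_order: tuple = ("Kahurangi", "CapeFarewell", "CentralSTB", "Hydrophone")
    response_gain: float = -0.35  # °C per (m/s) of smoothed wind anomaly
    sst_mean: float = 15.0
    seasonal_amplitude: float = 2.5  # °C, peaking in February
    warming_trend: float = 0.03  # °C per year
    noise_sd: float = 0.3
    heatwave_offsets: dict = field(default_factory=dict)  # season label -> °C

    def __post_init__(self):
        if self.response_gain > 0:
            raise ParameterError(
                "response_gain must be <= 0 (upwelling cools SST; 0 disables the response)"
            )
        lags = [self.box_lags_weeks[b] for b in self.plume_order if b in self.box_lags_weeks]
        if any(l < 0 for l in self.box_lags_weeks.values()):
            raise ParameterError("box lags must be >= 0 weeks")
        if any(b > a for a, b in zip(lags[1:], lags)):
            raise ParameterError("box lags must be nondecreasing along the plume order")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0:
            raise ParameterError("noise_sd and seasonal_amplitude must be >= 0")


def _simple_season_label(dates: pd.DatetimeIndex) -> np.ndarray:
    """October–March season label per date (NaN outside the season)."""
    years = dates.year.to_numpy()
    months = dates.month.to_numpy()
    label = np.where(months >= 10, years + 1, np.where(months <= 3, years, -1))
    return label


def gen_sst(wind: pd.DataFrame, params: PlumeSimParams, seed: int) -> dict[str, pd.Series]:
    """SST per box: seasonal cycle + trend + lagged wind response + noise.

    The wind anomaly (speed minus its long-run mean) is smoothed with a
    centred 3-day moving average — upwelling integrates wind over an
    event — then delayed by each box's lag and scaled by the (negative)
    response gain. Days earlier than a box's lag carry no wind response.
    Heatwave offsets are added to all in-season days of flagged seasons.
    """
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(wind["date"])
    n = len(dates)
    max_lag_days = max(params.box_lags_weeks.values()) * 7
    if max_lag_days >= n:
        raise ParameterError(
            f"box lag of {max_lag_days} days exceeds the available wind history ({n} days)"
        )
    speed = np.asarray(wind["speed"], float)
    anom = speed - speed.mean()
    smooth = pd.Series(anom).rolling(3, center=True, min_periods=1).mean().to_numpy()

    doy = dates.dayofyear.to_numpy(float)
    years_since = (dates - dates[0]).days.to_numpy(float) / 365.25
    seasonal = params.sst_mean + params.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - 45.0) / 365.25
    )
    trend = params.warming_trend * years_since
    labels = _simple_season_label(dates)
    heat = np.zeros(n)
    for season, offset in params.heatwave_offsets.items():
        heat[labels == int(season)] += float(offset)

    out: dict[str, pd.Series] = {}
    for box, lag_weeks in params.box_lags_weeks.items():
        shift = int(lag_weeks) * 7
        response = np.zeros(n)
        if shift == 0:
            response = params.response_gain * smooth
        else:
            response[shift:] = params.response_gain * smooth[:-shift]
        sst = seasonal + trend + response + heat + rng.normal(0.0, params.noise_sd, n)
        out[box] = pd.Series(sst, index=dates, name=box)
    return out


# --------------------------------------------------------------------------
# sightings


@dataclass(frozen=True)
class SightingSimParams:
    """Aggregation placement after wind events.

    For a random subset of wind events an aggregation is seeded with a
    start delayed by lag_days ~ Poisson(exp(lag_intercept +
    lag_slope_per_windy_day × windy days in the prior 30 days)).
    """

    lag_intercept: float = 2.5  # log-days
    lag_slope_per_windy_day: float = -0.05
    whales_per_aggregation: tuple = (5, 12)
    scatter_radius_km: float = 15.0
    background_rate: float = 0.02  # singleton sightings per day
    aggregation_prob: float = 0.3  # fraction of events that seed an aggregation
    spread_days: int = 2
    lat_range: tuple = (-41.3, -39.9)
    lon_range: tuple = (171.8, 174.4)
    min_separation_km: float = 120.0

    def __post_init__(self):
        if self.lag_slope_per_windy_day >= 0:
            raise ParameterError("lag_slope_per_windy_day must be negative")
        if self.scatter_radius_km <= 0:
            raise ParameterError("scatter_radius_km must be positive")
        lo, hi = self.whales_per_aggregation
        if not 1 <= lo <= hi:
            raise ParameterError("invalid whales_per_aggregation range")
        if self.background_rate < 0:
            raise ParameterError("background_rate must be >= 0")
        if not 0 <= self.aggregation_prob <= 1:
            raise ParameterError("aggregation_prob must be in [0, 1]")


def _offset_latlon(lat: float, lon: float, dx_km: float, dy_km: float) -> tuple[float, float]:
    new_lat = lat + dy_km / 111.195
    new_lon = lon + dx_km / (111.195 * np.cos(np.deg2rad(lat)))
    return new_lat, new_lon


def gen_sightings(
    wind: pd.DataFrame,
    events: list[WindEvent],
    params: SightingSimParams,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an opportunistic sighting table and its ground truth.

    Returns ``(sightings, truth)``: the sighting table in the io
    dialect, and one truth row per seeded aggregation with the
    generating event start, the true lag, and the windy-day covariate —
    the quantities the event-lag analysis is meant to recover.
    """
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(wind["date"])
    t_min, t_max = dates[0], dates[-1]
    sightings: list[dict] = []
    truth: list[dict] = []
    active: list[tuple[pd.Timestamp, float, float]] = []  # (start, lat, lon)
    sid = 0

    for event in events:
        if rng.random() >= params.aggregation_prob:
            continue
        wd = windy_days_prior(wind, event.start_date, 30, event.threshold)
        mu = np.exp(params.lag_intercept + params.lag_slope_per_windy_day * wd)
        lag = int(rng.poisson(mu))
        start = event.start_date + pd.Timedelta(days=lag)
        if start > t_max:
            continue
        center = None
        for _try in range(200):
            lat = rng.uniform(*params.lat_range)
            lon = rng.uniform(*params.lon_range)
            ok = all(
                haversine_km((lat, lon), (alat, alon)) >= params.min_separation_km
                for astart, alat, alon in active
                if abs((start - astart).days) <= 21
            )
            if ok:
                center = (lat, lon)
                break
        if center is None:
            continue
        active.append((start, *center))
        lo, hi = params.whales_per_aggregation
        total = int(rng.integers(lo, hi + 1))
        placed = 0
        first = True
        while placed < total:
            count = int(min(rng.integers(1, 4), total - placed))
            day = start if first else start + pd.Timedelta(days=int(rng.integers(0, params.spread_days + 1)))
            first = False
            r = params.scatter_radius_km * np.sqrt(rng.random())
            ang = rng.uniform(0, 2 * np.pi)
            lat, lon = _offset_latlon(center[0], center[1], r * np.cos(ang), r * np.sin(ang))
            sightings.append(
                {"id": f"s{sid:04d}", "date": day, "lat": lat, "lon": lon, "count": count}
            )
            sid += 1
            placed += count
        truth.append(
            {
                "event_start": event.start_date,
                "aggregation_start": start,
                "true_lag_days": lag,
                "windy_days_prior30": wd,
                "n_whales": total,
                "center_lat": center[0],
                "center_lon": center[1],
            }
        )

    n_days = (t_max - t_min).days + 1
    n_bg = rng.poisson(params.background_rate * n_days)
    for _ in range(n_bg):
        day = t_min + pd.Timedelta(days=int(rng.integers(0, n_days)))
        sightings.append(
            {
                "id": f"s{sid:04d}",
                "date": day,
                "lat": rng.uniform(*params.lat_range),
                "lon": rng.uniform(*params.lon_range),
                "count": 1,
            }
        )
        sid += 1

    cols = ["id", "date", "lat", "lon", "count"]
    sightings_df = pd.DataFrame(sightings, columns=cols)
    if len(sightings_df):
        sightings_df = sightings_df.sort_values("date", kind="stable").reset_index(drop=True)
    truth_df = pd.DataFrame(
        truth,
        columns=[
            "event_start",
            "aggregation_start",
            "true_lag_days",
            "windy_days_prior30",
            "n_whales",
            "center_lat",
            "center_lon",
        ],
    )
    return sightings_df, truth_df


# --------------------------------------------------------------------------
# audio


@dataclass(frozen=True)
class AudioSimParams:
    """Synthetic single-channel recording with injected D calls."""

    duration_s: float = 600.0
    fs: int = 2000
    call_times: tuple = ()  # call start times, s
    call_band: tuple = (20.0, 100.0)  # (low, high); sweep runs high -> low
    call_duration_s: float = 1.8
    snr_db: float = 10.0  # call RMS over in-band noise RMS
    noise_spectrum: str = "pink"  # or "white"
    noise_rms: float = 1.0  # 0 -> noiseless

    def __post_init__(self):
        lo, hi = self.call_band
        if not 0 < lo < hi:
            raise ParameterError(f"invalid call band {self.call_band}")
        if hi >= self.fs / 2:
            raise ParameterError("call band must lie below the Nyquist frequency")
        if self.noise_spectrum not in ("white", "pink"):
            raise ParameterError("noise_spectrum must be 'white' or 'pink'")
        if self.noise_rms < 0:
            raise ParameterError("noise_rms must be >= 0")
        for t in self.call_times:
            if t < 0 or t + self.call_duration_s > self.duration_s:
                raise ParameterError(f"call at {t} s does not fit within the clip")


def _colored_noise(n: int, spectrum: str, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    if spectrum == "white":
        out = white
    else:  # pink: power ~ 1/f
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0)
        scale = 1.0 / np.sqrt(np.maximum(f, f[1] if len(f) > 1 else 1.0))
        out = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _downsweep(fs: int, duration_s: float, high_hz: float, low_hz: float) -> np.ndarray:
    t = np.arange(int(round(duration_s * fs))) / fs
    x = signal.chirp(t, f0=high_hz, t1=duration_s, f1=low_hz, method="linear")
    return x * signal.windows.tukey(len(t), 0.25)


def gen_audio_with_calls(params: AudioSimParams, seed: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize a clip with downswept calls over colored noise.

    The call amplitude is set so the call RMS is ``snr_db`` above the
    RMS of the noise within the call band (unit amplitude when the clip
    is noiseless). Returns ``(samples, annotations)`` where annotations
    carry the true (start_s, end_s, low_hz, high_hz) per call and an
    ``overlapped`` flag for calls whose spans intersect another call.
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.fs))
    lo, hi = params.call_band

    if params.noise_rms > 0:
        noise = params.noise_rms * _colored_noise(n, params.noise_spectrum, rng)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=params.fs, output="sos")
        band_rms = float(np.sqrt(np.mean(signal.sosfiltfilt(sos, noise) ** 2)))
        call_amp_rms = band_rms * 10.0 ** (params.snr_db / 20.0)
    else:
        noise = np.zeros(n)
        call_amp_rms = 1.0

    call = _downsweep(params.fs, params.call_duration_s, hi, lo)
    call_rms = float(np.sqrt(np.mean(call**2)))
    call = call * (call_amp_rms / call_rms)

    samples = noise.copy()
    rows = []
    spans = [(t, t + params.call_duration_s) for t in params.call_times]
    for (t0, t1) in spans:
        i0 = int(round(t0 * params.fs))
        samples[i0 : i0 + len(call)] += call[: n - i0]
        overlapped = any(
            (o0 < t1 and t0 < o1) for (o0, o1) in spans if (o0, o1) != (t0, t1)
        )
        rows.append(
            {
                "start_s": t0,
                "end_s": t1,
                "low_hz": lo,
                "high_hz": hi,
                "overlapped": overlapped,
            }
        )
    annotations = pd.DataFrame(rows, columns=["start_s", "end_s", "low_hz", "high_hz", "overlapped"])
    return samples, annotations


def make_call_templates(
    fs: int = 2000,
    n_templates: int = 13,
    window_samples: int = 2048,
    overlap: float = 0.5,
    band: tuple = (20.0, 100.0),
    durations: tuple = (1.8, 1.5, 2.1),
    dynamic_range_db: float = 25.0,
) -> list[Spectrogram]:
    """Spectrogram templates built from example downsweeps.

    Mirrors the practice of selecting a set of example calls spanning
    the call type's variability: the bank cycles over call durations
    and over sub-hop onset phases (a call can start anywhere within a
    spectrogram hop, and a phase-matched template must exist for the
    correlation to peak). Each template is the call's spectrogram
    cropped to the call band, padded with one window of context either
    side, and clipped to *dynamic_range_db* below its maximum so its
    contrast matches what a call embedded in ambient noise looks like.
    """
    lo, hi = band
    hop = int(round(window_samples * (1.0 - overlap)))
    n_phases = 4
    templates = []
    for i in range(n_templates):
        dur = float(durations[(i // n_phases) % len(durations)])
        phase = (i % n_phases) * hop // n_phases
        call = _downsweep(fs, dur, hi, lo)
        clip = np.concatenate(
            [np.zeros(window_samples + phase), call, np.zeros(window_samples)]
        )
        spec = spectrogram(clip, fs, window_samples=window_samples, overlap=overlap)
        power = np.maximum(spec.power, spec.power.max() - dynamic_range_db)
        fidx = np.flatnonzero((spec.freqs >= lo) & (spec.freqs <= hi))
        templates.append(
            Spectrogram(
                power=power[:, fidx],
                times=spec.times,
                freqs=spec.freqs[fidx],
                window_samples=spec.window_samples,
                overlap_fraction=spec.overlap_fraction,
                fs=spec.fs,
                call_start_s=(window_samples + phase) / fs,
                call_end_s=(window_samples + phase) / fs + dur,
            )
        )
    return templates


# --------------------------------------------------------------------------
# hourly ambient noise


@dataclass(frozen=True)
class NoiseSimParams:
    """Hourly 20–100 Hz band noise level simulation (dB)."""

    baseline_db: float = 108.0  # dB re 1 µPa², 20–100 Hz band, shallow coastal
    diurnal_amplitude_db: float = 2.0
    spike_rate_per_day: float = 0.5  # episodic sources: airguns, vessels, storms
    spike_excess_db: float = 25.0
    spike_duration_h: tuple = (1, 6)
    noise_sd_db: float = 1.0
    start: str = "2016-10-01"

    def __post_init__(self):
        if self.spike_rate_per_day < 0 or self.noise_sd_db < 0:
            raise ParameterError("rates and noise SD must be >= 0")
        lo, hi = self.spike_duration_h
        if not 1 <= lo <= hi:
            raise ParameterError("invalid spike duration range")


def gen_hourly_noise(duration_h: int, params: NoiseSimParams, seed: int) -> pd.Series:
    """Hourly band-noise series: baseline + diurnal cycle + spikes + jitter."""
    rng = np.random.default_rng(seed)
    duration_h = int(duration_h)
    if duration_h < 1:
        raise ParameterError("duration_h must be >= 1")
    idx = pd.date_range(pd.Timestamp(params.start), periods=duration_h, freq="h")
    hours = np.arange(duration_h)
    level = (
        params.baseline_db
        + params.diurnal_amplitude_db * np.sin(2 * np.pi * hours / 24.0)
        + rng.normal(0.0, params.noise_sd_db, duration_h)
    )
    n_spikes = rng.poisson(params.spike_rate_per_day * duration_h / 24.0)
    lo, hi = params.spike_duration_h
    for _ in range(n_spikes):
        s = int(rng.integers(0, duration_h))
        d = int(rng.integers(lo, hi + 1))
        level[s : s + d] += params.spike_excess_db * rng.uniform(0.6, 1.0)
    return pd.Series(level, index=idx)
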