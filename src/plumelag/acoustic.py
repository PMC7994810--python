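"""D-call detection and call-density standardization.

Blue whale D calls (~100→20 Hz downsweeps) are found with a spectrogram
template correlation detector: the recording's spectrogram (2048-sample
Hann window, 50% overlap at 2 kHz) is scanned with a set of example-call
template spectrograms, scoring each time offset by the normalized 2-D
correlation within the template's frequency band, and offsets scoring at
or above the detection threshold (default 0.8) become detection events.
Detector output is evaluated against manual annotations by one-to-one
greedy matching with a 50% intersection-over-union criterion in both
time and frequency.

Raw daily call counts are standardized to call *density* (calls km⁻²
day⁻¹) by dividing by the daily mean detection area. The detection
range per bearing comes from a passive-sonar-equation propagation model
(geometric spreading plus linear absorption, solved by bisection)
driven by the hourly 95th-percentile 20–100 Hz band noise level, and
the detection area is the polygon spanned by the ranges along 8 radials
at 45° spacing around the hydrophone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .errors import DegenerateDataError, ParameterError, ValidationError

SPEC_FLOOR_DB = -120.0

__all__ = [
    "Spectrogram",
    "DetectionEvent",
    "DetectorEvaluation",
    "spectrogram",
    "detect_calls",
    "evaluate_detector",
    "band_noise_level",
    "detection_range",
    "polygon_area",
    "hourly_detection_geometry",
    "daily_density",
]


@dataclass
class Spectrogram:
    """Time × frequency power matrix in dB (arbitrary reference).

    Template excerpts may carry ``call_start_s``/``call_end_s``, the
    call's span in template-local time; context frames around the call
    sharpen the correlation but detections are reported at call bounds.
    """

    power: np.ndarray  # shape (n_times, n_freqs)
    times: np.ndarray  # bin centres, s
    freqs: np.ndarray  # Hz
    window_samples: int
    overlap_fraction: float
    fs: int
    call_start_s: float | None = None
    call_end_s: float | None = None

    @property
    def hop_s(self) -> float:
        return self.window_samples * (1.0 - self.overlap_fraction) / self.fs


@dataclass
class DetectionEvent:
    start_s: float
    end_s: float
    low_hz: float
    high_hz: float
    score: float | None = None
    template_id: str | None = None


@dataclass
class DetectorEvaluation:
    precision: float
    recall: float
    fp_per_hour: float
    n_true: int
    n_detected: int
    n_matched: int


def spectrogram(
    samples: np.ndarray,
    fs: int,
    window_samples: int = 2048,
    overlap: float = 0.5,
    floor_db: float = SPEC_FLOOR_DB,
) -> Spectrogram:
    """Short-time power spectrogram with a Hann window.

    Frame count is floor((n − w) / hop) + 1. Power is in dB with zero
    power guarded to the finite *floor_db* so correlations stay defined
    on silent audio.
    """
    x = np.asarray(samples, float)
    if len(x) < window_samples:
        raise ParameterError(
            f"audio of {len(x)} samples is shorter than one window ({window_samples})"
        )
    if not 0.0 <= overlap < 1.0:
        raise ParameterError(f"overlap must be in [0, 1), got {overlap}")
    noverlap = int(round(window_samples * overlap))
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=fs,
        window=signal.windows.hann(window_samples, sym=False),
        nperseg=window_samples,
        noverlap=noverlap,
        detrend=False,
        mode="psd",
    )
    floor_lin = 10.0 ** (floor_db / 10.0)
    power_db = 10.0 * np.log10(np.maximum(sxx.T, floor_lin))
    return Spectrogram(
        power=power_db,
        times=times,
        freqs=freqs,
        window_samples=window_samples,
        overlap_fraction=overlap,
        fs=int(fs),
    )


def _band_indices(freqs: np.ndarray, low_hz: float, high_hz: float) -> np.ndarray:
    return np.flatnonzero((freqs >= low_hz) & (freqs <= high_hz))


def _check_compatible(spec: Spectrogram, template: Spectrogram) -> None:
    if (
        template.fs != spec.fs
        or template.window_samples != spec.window_samples
        or template.overlap_fraction != spec.overlap_fraction
    ):
        raise ValidationError(
            "template and spectrogram parameters differ "
            f"(fs {template.fs}/{spec.fs}, window {template.window_samples}/"
            f"{spec.window_samples}, overlap {template.overlap_fraction}/"
            f"{spec.overlap_fraction})"
        )


DETECTOR_FREQ_SMOOTH_BINS = 5


def _detector_image(power_db: np.ndarray, smooth_bins: int) -> np.ndarray:
    """Detector preprocessing: linear amplitude, smoothed across frequency.

    The correlation score is computed on linear spectral amplitude
    (10^(dB/20)) boxcar-smoothed over a few adjacent frequency bins;
    amplitude keeps the call's contrast against the background while
    the smoothing suppresses the per-bin power fluctuations of noise
    that otherwise cap the attainable correlation.
    """
    amp = 10.0 ** (power_db / 20.0)
    k = int(smooth_bins)
    if k <= 1:
        return amp
    kernel = np.ones(k) / k
    return np.apply_along_axis(lambda row: np.convolve(row, kernel, mode="same"), 1, amp)


def _template_scores(
    spec: Spectrogram, template: Spectrogram, smooth_bins: int = DETECTOR_FREQ_SMOOTH_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized correlation of the template against every time offset.

    Returns (offsets, scores): the Pearson correlation between the
    (preprocessed) template matrix and the equally shaped spectrogram
    window starting at each frame, restricted to the template's
    frequency band.
    """
    band = _band_indices(spec.freqs, template.freqs.min(), template.freqs.max())
    if len(band) != len(template.freqs) or not np.allclose(
        spec.freqs[band], template.freqs, atol=1e-9
    ):
        raise ValidationError("template frequency bins do not align with the spectrogram")
    tmpl = _detector_image(template.power, smooth_bins)
    tw = tmpl.shape[0]
    sub = _detector_image(spec.power[:, band], smooth_bins)
    if sub.shape[0] < tw:
        return np.arange(0), np.zeros(0)
    windows = sliding_window_view(sub, (tw, sub.shape[1]))[:, 0]  # (n_off, tw, fb)
    n_el = tmpl.size
    t_centered = tmpl - tmpl.mean()
    t_norm = np.sqrt((t_centered**2).sum())
    w_mean = windows.mean(axis=(1, 2))
    cross = np.tensordot(windows, t_centered, axes=([1, 2], [0, 1]))
    w_ss = (windows**2).sum(axis=(1, 2)) - n_el * w_mean**2
    w_ss = np.maximum(w_ss, 0.0)
    denom = t_norm * np.sqrt(w_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, cross / denom, 0.0)
    if t_norm == 0:
        scores = np.zeros(len(windows))
    return np.arange(len(windows)), scores


def detect_calls(
    spec: Spectrogram,
    templates: list[Spectrogram],
    threshold: float = 0.8,
    smooth_bins: int = DETECTOR_FREQ_SMOOTH_BINS,
) -> list[DetectionEvent]:
    """Spectrogram template correlation detection.

    Each template is slid along time within its own frequency band;
    offsets scoring ≥ *threshold* become candidates, reported at the
    template's call span (context frames around the call contribute to
    the score, not to the event bounds). Overlapping candidates (within
    or across templates) are merged into one event that keeps the
    highest-scoring candidate's template, band, start and duration.
    """
    if not templates:
        raise ValidationError("at least one template is required")
    for t in templates:
        _check_compatible(spec, t)
    hop = spec.hop_s
    candidates = []  # (score, start_s, end_s, low, high, template_id)
    for ti, tmpl in enumerate(templates):
        offsets, scores = _template_scores(spec, tmpl, smooth_bins)
        span = tmpl.power.shape[0] * hop
        c0 = tmpl.call_start_s if tmpl.call_start_s is not None else 0.0
        c1 = tmpl.call_end_s if tmpl.call_end_s is not None else span
        hits = np.flatnonzero(scores >= threshold)
        for i in hits:
            t_off = float(offsets[i]) * hop
            candidates.append(
                (
                    float(scores[i]),
                    t_off + c0,
                    t_off + c1,
                    float(tmpl.freqs.min()),
                    float(tmpl.freqs.max()),
                    f"t{ti}",
                )
            )
    if not candidates:
        return []
    candidates.sort(key=lambda c: c[1])
    # merge candidates whose time spans overlap; the best score wins
    groups: list[list] = [[candidates[0]]]
    group_end = candidates[0][2]
    for c in candidates[1:]:
        if c[1] < group_end:
            groups[-1].append(c)
            group_end = max(group_end, c[2])
        else:
            groups.append([c])
            group_end = c[2]
    events = []
    for grp in groups:
        best = max(grp, key=lambda c: c[0])
        score, start, end, low, high, tid = best
        events.append(
            DetectionEvent(
                start_s=start, end_s=end, low_hz=low, high_hz=high, score=score, template_id=tid
            )
        )
    return events


def _iou(a0, a1, b0, b1) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    union = max(a1, b1) - min(a0, b0)
    return inter / union


def event_pair_matches(det: DetectionEvent, ann: DetectionEvent, min_overlap: float = 0.5) -> bool:
    """True when the pair overlaps ≥ min_overlap (IoU) in time AND frequency."""
    return (
        _iou(det.start_s, det.end_s, ann.start_s, ann.end_s) >= min_overlap
        and _iou(det.low_hz, det.high_hz, ann.low_hz, ann.high_hz) >= min_overlap
    )


def evaluate_detector(
    detections: list[DetectionEvent],
    annotations: list[DetectionEvent],
    duration_h: float,
    min_overlap: float = 0.5,
) -> DetectorEvaluation:
    """Precision / recall / false-alarm rate against manual annotations.

    Matching is greedy one-to-one in descending detection score: each
    detection claims the first unclaimed annotation it overlaps by at
    least *min_overlap* intersection-over-union in both time and
    frequency. Precision is matched/detected (1 by convention when
    nothing was detected), recall matched/true (1 when nothing is true),
    and the false-alarm rate is unmatched detections per hour.
    """
    if duration_h <= 0:
        raise ParameterError(f"duration_h must be positive, got {duration_h}")
    order = sorted(
        range(len(detections)),
        key=lambda i: -(detections[i].score if detections[i].score is not None else 0.0),
    )
    claimed = [False] * len(annotations)
    matched = 0
    for i in order:
        det = detections[i]
        for j, ann in enumerate(annotations):
            if claimed[j]:
                continue
            if event_pair_matches(det, ann, min_overlap):
                claimed[j] = True
                matched += 1
                break
    n_det, n_true = len(detections), len(annotations)
    return DetectorEvaluation(
        precision=matched / n_det if n_det else 1.0,
        recall=matched / n_true if n_true else 1.0,
        fp_per_hour=(n_det - matched) / duration_h,
        n_true=n_true,
        n_detected=n_det,
        n_matched=matched,
    )


def band_noise_level(
    spec: Spectrogram,
    band: tuple[float, float] = (20.0, 100.0),
    percentile: float = 95.0,
    block_s: float = 3600.0,
) -> pd.Series:
    """Blockwise percentile of the in-band level (dB), default hourly.

    Per frame the power spectral density is integrated over the band;
    per block the given percentile of the frame levels (in dB) is
    reported. The series index is the block start time in seconds.
    Empty blocks are missing.
    """
    lo, hi = band
    if not 0 <= lo < hi <= spec.fs / 2:
        raise ParameterError(f"band {band} outside [0, fs/2]")
    idx = _band_indices(spec.freqs, lo, hi)
    if len(idx) == 0:
        raise ParameterError(f"band {band} contains no frequency bins")
    df = float(spec.freqs[1] - spec.freqs[0]) if len(spec.freqs) > 1 else 1.0
    band_power = (10.0 ** (spec.power[:, idx] / 10.0)).sum(axis=1) * df
    level_db = 10.0 * np.log10(np.maximum(band_power, 1e-300))
    blocks = np.floor(spec.times / block_s).astype(int)
    n_blocks = int(blocks.max()) + 1 if len(blocks) else 0
    out = {}
    for b in range(n_blocks):
        vals = level_db[blocks == b]
        out[b * block_s] = float(np.percentile(vals, percentile)) if len(vals) else np.nan
    return pd.Series(out, dtype=float)


def detection_range(
    noise_db: float,
    source_level_db: float = 174.0,
    detection_threshold_db: float = 10.0,
    spreading_coefficient: float = 15.0,
    absorption_db_per_km: float = 0.0,
    max_range_km: float = 100.0,
) -> float:
    """Maximum detection distance (km) from the passive sonar equation.

    Solves for the largest r ≤ max_range_km with

        SL − [k·log10(r_m) + α·r_km] ≥ NL + DT

    (spreading coefficient k, absorption α) by bisection; returns 0 when
    the budget is already exceeded at 1 m.
    """
    if max_range_km <= 0:
        raise ParameterError(f"max_range_km must be positive, got {max_range_km}")
    for name, v in (
        ("noise_db", noise_db),
        ("source_level_db", source_level_db),
        ("detection_threshold_db", detection_threshold_db),
    ):
        if not np.isfinite(v):
            raise ParameterError(f"{name} must be finite, got {v}")
    budget = source_level_db - noise_db - detection_threshold_db

    def excess(r_km: float) -> float:
        return budget - (
            spreading_coefficient * np.log10(r_km * 1000.0) + absorption_db_per_km * r_km
        )

    r_min = 1e-3  # 1 m
    if excess(r_min) < 0:
        return 0.0
    if excess(max_range_km) >= 0:
        return float(max_range_km)
    lo, hi = r_min, max_range_km
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) >= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return float(lo)


def polygon_area(radial_ranges) -> float:
    """Area (km²) of the polygon spanned by 8 radial ranges at 45° spacing.

    area = Σᵢ ½ · rᵢ · rᵢ₊₁ · sin 45°, wrapping around the receiver.
    """
    r = np.asarray(radial_ranges, float)
    if r.shape != (8,):
        raise ParameterError(f"expected 8 radial ranges, got shape {r.shape}")
    if (r < 0).any():
        raise ParameterError("radial ranges must be nonnegative")
    s = np.sin(np.pi / 4.0)
    return float(0.5 * s * np.sum(r * np.roll(r, -1)))


def hourly_detection_geometry(
    hourly_noise_db: pd.Series,
    source_level_db: float = 174.0,
    detection_threshold_db: float = 10.0,
    spreading_coefficient: float = 15.0,
    absorption_db_per_km: float = 0.0,
    max_range_km: float = 100.0,
    n_radials: int = 8,
) -> pd.DataFrame:
    """Hourly detection ranges and areas from hourly band-noise levels.

    The sonar-equation model has no bearing dependence, so the range is
    the same along all radials; the area is the enclosed polygon. The
    index of *hourly_noise_db* (timestamps) is carried through.
    """
    if n_radials != 8:
        raise ParameterError("the polygon area model is defined for 8 radials")
    rows = []
    for ts, nl in hourly_noise_db.items():
        if not np.isfinite(nl):
            rows.append({"hour": ts, "range_km": np.nan, "area_km2": np.nan})
            continue
        r = detection_range(
            nl,
            source_level_db=source_level_db,
            detection_threshold_db=detection_threshold_db,
            spreading_coefficient=spreading_coefficient,
            absorption_db_per_km=absorption_db_per_km,
            max_range_km=max_range_km,
        )
        rows.append({"hour": ts, "range_km": r, "area_km2": polygon_area(np.full(8, r))})
    return pd.DataFrame(rows)


def daily_density(call_times, hourly_geometry: pd.DataFrame) -> pd.DataFrame:
    """Daily D-call density: calls per day over daily mean detection area.

    *call_times* are detection timestamps; *hourly_geometry* must carry
    a datetime "hour" column and "area_km2" (from
    :func:`hourly_detection_geometry`). Every day covered by the
    geometry is reported, zero-call days included. Days whose mean area
    is zero or undefined get a missing density and a flag.
    """
    geo = hourly_geometry.copy()
    geo["date"] = pd.DatetimeIndex(geo["hour"]).normalize()
    daily_area = geo.groupby("date")["area_km2"].mean()
    times = pd.DatetimeIndex(call_times)
    counts = pd.Series(1, index=times).groupby(times.normalize()).sum() if len(times) else pd.Series(dtype=int)
    rows = []
    for date, area in daily_area.items():
        n = int(counts.get(date, 0))
        ok = np.isfinite(area) and area > 0
        rows.append(
            {
                "date": date,
                "n_calls": n,
                "mean_area_km2": area,
                "density": n / area if ok else np.nan,
                "flagged": not ok,
            }
        )
    return pd.DataFrame(rows)
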