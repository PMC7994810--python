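"""Run configuration for the wind–upwelling–whale lag analysis.

All tunable constants of the pipeline live in :class:`AnalysisConfig`:
the austral spring–summer season window (1 October – 31 March), the
weekly subsampling phase, the decomposition period, the wind-event
threshold (5.5 m s⁻¹, the regional spring–summer mean wind speed), the
sighting-aggregation rule (≥5 whales within one week and 50 km), the
spectrogram-correlation detector threshold (0.8), and the parameters of
the sonar-equation detection-range model (source level 174 dB, 8 radials).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from .errors import ValidationError

_MONTH_DAY = re.compile(r"^(\d{2})-(\d{2})$")


def _parse_month_day(value: str, name: str) -> tuple[int, int]:
    m = _MONTH_DAY.match(str(value))
    if not m:
        raise ValidationError(f"{name}: expected 'MM-DD', got {value!r}")
    month, day = int(m.group(1)), int(m.group(2))
    if not (1 <= month <= 12 and 1 <= day <= 31):
        raise ValidationError(f"{name}: invalid month-day {value!r}")
    return month, day


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated analysis constants with the study's defaults."""

    season_start: str = "10-01"
    season_end: str = "03-31"
    subsample_phase: int = 0
    decomposition_period: int = 52
    max_lag: int = 8
    wind_event_threshold: float = 5.5
    wind_event_min_days: int = 2
    aggregation_min_whales: int = 5
    aggregation_window_days: int = 7
    aggregation_radius_km: float = 50.0
    prior_wind_window_days: int = 30
    heatwave_seasons: tuple = ()
    detector_threshold: float = 0.8
    noise_band: tuple = (20.0, 100.0)
    noise_percentile: float = 95.0
    source_level_db: float = 174.0
    detection_threshold_db: float = 10.0
    spreading_coefficient: float = 15.0
    absorption_db_per_km: float = 0.0
    n_radials: int = 8
    max_lookback_days: int = 60
    aggregation_mode: str = "chain"
    seed: int = 0

    def __post_init__(self):
        sm, _ = _parse_month_day(self.season_start, "season_start")
        em, _ = _parse_month_day(self.season_end, "season_end")
        if not sm > em:
            raise ValidationError(
                "season_start must precede season_end across the year "
                f"boundary (got {self.season_start} .. {self.season_end})"
            )
        if not 0 <= self.subsample_phase <= 6:
            raise ValidationError(
                f"subsample_phase must be in [0, 6], got {self.subsample_phase}"
            )
        for name in (
            "decomposition_period",
            "max_lag",
            "wind_event_threshold",
            "wind_event_min_days",
            "aggregation_min_whales",
            "aggregation_window_days",
            "aggregation_radius_km",
            "prior_wind_window_days",
            "noise_percentile",
            "spreading_coefficient",
            "n_radials",
            "max_lookback_days",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.detector_threshold <= 1.0:
            raise ValidationError("detector_threshold must lie in [0, 1]")
        lo, hi = self.noise_band
        if not lo < hi:
            raise ValidationError(f"noise_band low must be < high, got {self.noise_band}")
        if self.absorption_db_per_km < 0:
            raise ValidationError("absorption_db_per_km must be >= 0")
        if self.aggregation_mode not in ("chain", "clique"):
            raise ValidationError("aggregation_mode must be 'chain' or 'clique'")
        object.__setattr__(self, "heatwave_seasons", tuple(self.heatwave_seasons))
        object.__setattr__(self, "noise_band", (float(lo), float(hi)))

    # ---- season helpers -------------------------------------------------

    def season_label(self, date) -> int | None:
        """Label of the spring–summer season containing *date*, or None.

        A season spanning October–March is labelled by the year of its
        January (the 2016-10-01 .. 2017-03-31 season is "2017").
        """
        d = pd.Timestamp(date)
        sm, sd = _parse_month_day(self.season_start, "season_start")
        em, ed = _parse_month_day(self.season_end, "season_end")
        if (d.month, d.day) >= (sm, sd):
            return d.year + 1
        if (d.month, d.day) <= (em, ed):
            return d.year
        return None

    def season_bounds(self, label: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Inclusive (start, end) dates of the season with the given label."""
        sm, sd = _parse_month_day(self.season_start, "season_start")
        em, ed = _parse_month_day(self.season_end, "season_end")
        return (
            pd.Timestamp(year=label - 1, month=sm, day=sd),
            pd.Timestamp(year=label, month=em, day=ed),
        )


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key–value file.

    Absent keys take the defaults above; unknown keys and invalid values
    raise :class:`ValidationError` naming the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "heatwave_seasons" in raw and isinstance(raw["heatwave_seasons"], Sequence):
        raw["heatwave_seasons"] = tuple(int(s) for s in raw["heatwave_seasons"])
    if "noise_band" in raw:
        raw["noise_band"] = tuple(raw["noise_band"])
    return AnalysisConfig(**raw)
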