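"""Tabular and audio I/O in the pipeline's documented dialects.

CSV dialects (comma-separated, ISO-8601 dates, UTF-8, header required):

* wind       — ``date,speed,direction``; one row per station-day
* sst        — ``date,box_id,sst``; daily per named spatial box, gaps allowed
* sightings  — ``id,date,lat,lon,count``; opportunistic whale sightings
* selections — ``start_s,end_s,low_hz,high_hz[,score,template_id]``;
  call annotations / detector output

Audio is mono PCM or float WAV; the study's recordings are 2 kHz.
All downstream modules consume the containers produced here (or by
:mod:`plumelag.synth`) and never touch files themselves.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import FormatError, RowParseError

logger = logging.getLogger(__name__)

WIND_COLUMNS = ("date", "speed", "direction")
SST_COLUMNS = ("date", "box_id", "sst")
SIGHTING_COLUMNS = ("id", "date", "lat", "lon", "count")
SELECTION_COLUMNS = ("start_s", "end_s", "low_hz", "high_hz")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column: {col}")


def _parse_dates(df: pd.DataFrame, path) -> pd.Series:
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise RowParseError(line, f"{path}: unparseable date {df['date'][bad].iloc[0]!r}")
    if parsed.isna().any():
        line = int(df.index[parsed.isna()][0]) + 2
        raise RowParseError(line, f"{path}: empty date")
    return parsed.dt.normalize()


def read_daily_table(path, kind: str):
    """Read a wind / SST / sightings CSV in the documented dialect.

    Returns a date-sorted ``DataFrame`` for ``kind="wind"`` and
    ``kind="sightings"``, and a ``dict[box_id, pandas.Series]`` of daily
    SST (indexed by date, NaN for gaps) for ``kind="sst"``.
    """
    path = Path(path)
    if kind not in ("wind", "sst", "sightings"):
        raise ValueError(f"kind must be wind|sst|sightings, got {kind!r}")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    if kind == "wind":
        _require_columns(df, WIND_COLUMNS, path)
        df = df.copy()
        df["date"] = _parse_dates(df, path)
        dup = df["date"].duplicated()
        if dup.any():
            d = df["date"][dup].iloc[0].date()
            raise FormatError(f"{path}: duplicated date {d}")
        speed = pd.to_numeric(df["speed"], errors="coerce")
        if not np.isfinite(speed).all():
            raise FormatError(f"{path}: non-finite wind speed")
        if (speed < 0).any():
            raise FormatError(f"{path}: negative wind speed")
        direction = pd.to_numeric(df["direction"], errors="coerce") % 360.0
        out = pd.DataFrame({"date": df["date"], "speed": speed, "direction": direction})
        return out.sort_values("date").reset_index(drop=True)

    if kind == "sst":
        _require_columns(df, SST_COLUMNS, path)
        df = df.copy()
        df["date"] = _parse_dates(df, path)
        boxes: dict[str, pd.Series] = {}
        for box_id, grp in df.groupby("box_id", sort=False):
            dup = grp["date"].duplicated()
            if dup.any():
                d = grp["date"][dup].iloc[0].date()
                raise FormatError(f"{path}: box {box_id}: duplicated date {d}")
            vals = pd.to_numeric(grp["sst"], errors="coerce")
            if np.isinf(vals).any():
                raise FormatError(f"{path}: box {box_id}: infinite SST")
            s = pd.Series(vals.to_numpy(), index=pd.DatetimeIndex(grp["date"]), name=str(box_id))
            boxes[str(box_id)] = s.sort_index()
        return boxes

    # sightings
    _require_columns(df, SIGHTING_COLUMNS, path)
    df = df.copy()
    df["date"] = _parse_dates(df, path)
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    count = pd.to_numeric(df["count"], errors="coerce")
    if lat.abs().max() > 90:
        raise FormatError(f"{path}: latitude outside [-90, 90]")
    if not np.isfinite(count).all() or (count < 1).any() or (count % 1 != 0).any():
        raise FormatError(f"{path}: count must be an integer >= 1")
    lon = ((lon + 180.0) % 360.0) - 180.0
    out = pd.DataFrame(
        {
            "id": df["id"].astype(str),
            "date": df["date"],
            "lat": lat,
            "lon": lon,
            "count": count.astype(int),
        }
    )
    return out.sort_values("date", kind="stable").reset_index(drop=True)


def write_daily_table(obj, path, kind: str) -> None:
    """Write a container from :func:`read_daily_table` back to CSV.

    The output is byte-stable under a read/write round trip for valid
    input in the documented dialect.
    """
    path = Path(path)
    if kind == "wind":
        out = obj.copy()
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
    elif kind == "sst":
        frames = [
            pd.DataFrame(
                {
                    "date": s.index.strftime("%Y-%m-%d"),
                    "box_id": box,
                    "sst": s.to_numpy(),
                }
            )
            for box, s in obj.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif kind == "sightings":
        out = obj.copy()
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"kind must be wind|sst|sightings, got {kind!r}")


def read_audio(path) -> tuple[np.ndarray, int]:
    """Read a WAV file, returning ``(samples, sample_rate_hz)``.

    Integer PCM is rescaled to [-1, 1); stereo files use the first
    channel with a logged warning. Zero-length or malformed files raise
    :class:`FormatError`.
    """
    path = Path(path)
    import struct

    try:
        fs, data = wavfile.read(path)
    except (ValueError, EOFError, struct.error) as exc:
        raise FormatError(f"{path}: not a readable WAV file ({exc})") from exc
    if data.size == 0:
        raise FormatError(f"{path}: zero-length audio")
    if data.ndim > 1:
        logger.warning("%s: %d channels, using the first", path, data.shape[1])
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return data, int(fs)


def write_audio(path, samples: np.ndarray, fs: int) -> None:
    """Write mono float32 WAV."""
    wavfile.write(Path(path), int(fs), np.asarray(samples, dtype=np.float32))


def read_selections(path) -> pd.DataFrame:
    """Read a selection table (call annotations or detections)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    _require_columns(df, SELECTION_COLUMNS, path)
    if (df["start_s"] >= df["end_s"]).any():
        raise FormatError(f"{path}: selection with start_s >= end_s")
    if (df["low_hz"] >= df["high_hz"]).any():
        raise FormatError(f"{path}: selection with low_hz >= high_hz")
    return df


def write_selections(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)
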