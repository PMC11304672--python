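"""Reading, validating and summarising GPS relocation tables.

A telemetry dataset is a table with one row per fix: an animal identifier,
a timezone-aware timestamp (normalised to UTC internally) and a pair of
coordinates, either projected (metres easting/northing) or geographic
(longitude/latitude in degrees).  Datasets are sorted by (animal, time)
and carry no duplicate (animal, timestamp) rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: default CSV column names per coordinate mode
DEFAULT_COLUMNS = {
    "projected": {"animal_id": "animal_id", "timestamp": "timestamp", "x": "x", "y": "y"},
    "geographic": {"animal_id": "animal_id", "timestamp": "timestamp", "x": "lon", "y": "lat"},
}


class ConfigurationError(ValueError):
    """A required column is missing or an option value is invalid."""


class EmptyInputError(ValueError):
    """No valid relocations remain after validation."""


@dataclass(frozen=True)
class TelemetryDataset:
    """Validated relocation streams for a set of tagged animals.

    Parameters
    ----------
    fixes
        DataFrame with columns ``animal_id`` (str), ``timestamp``
        (tz-aware, UTC), ``x`` and ``y``.  In geographic mode ``x`` is
        longitude and ``y`` latitude, in degrees; in projected mode both
        are metres.
    coordinate_mode
        ``"projected"`` or ``"geographic"``.
    day_timezone
        Timezone used to segment streams into calendar days (datastream
        permutation); UTC by default.
    """

    fixes: pd.DataFrame
    coordinate_mode: str = "projected"
    day_timezone: str = "UTC"

    def __post_init__(self) -> None:
        if self.coordinate_mode not in ("projected", "geographic"):
            raise ConfigurationError(
                f"coordinate_mode must be 'projected' or 'geographic', got {self.coordinate_mode!r}"
            )
        df = self.fixes
        missing = {"animal_id", "timestamp", "x", "y"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"fixes table lacks columns: {sorted(missing)}")
        if len(df) == 0:
            raise EmptyInputError("telemetry dataset has no relocations")

    @property
    def animals(self) -> list[str]:
        return sorted(self.fixes["animal_id"].unique())

    @property
    def n_animals(self) -> int:
        return self.fixes["animal_id"].nunique()

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def for_animal(self, animal_id: str) -> pd.DataFrame:
        return self.fixes[self.fixes["animal_id"] == animal_id]

    def with_fixes(self, fixes: pd.DataFrame) -> "TelemetryDataset":
        """A copy of this dataset backed by a different (already valid) fix table."""
        return TelemetryDataset(
            fixes=fixes.reset_index(drop=True),
            coordinate_mode=self.coordinate_mode,
            day_timezone=self.day_timezone,
        )


def _validate_fixes(df: pd.DataFrame) -> pd.DataFrame:
    """Drop unparseable / non-finite / duplicate rows; sort; log tallies."""
    n_raw = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="mixed")
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    out = pd.DataFrame(
        {"animal_id": df["animal_id"].astype(str), "timestamp": ts, "x": x, "y": y}
    )
    valid = ts.notna() & np.isfinite(x) & np.isfinite(y)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning("dropped %d rows with unparseable timestamps or non-finite coordinates", n_invalid)
    out = out[valid]
    out = out.sort_values(["animal_id", "timestamp"], kind="mergesort")
    dup = out.duplicated(subset=["animal_id", "timestamp"], keep="first")
    n_dup = int(dup.sum())
    if n_dup:
        logger.warning("dropped %d duplicate (animal_id, timestamp) rows (kept first)", n_dup)
    out = out[~dup].reset_index(drop=True)
    if len(out) == 0:
        raise EmptyInputError(f"no valid relocations remain ({n_raw} raw rows)")
    return out


def make_dataset(
    df: pd.DataFrame,
    coordinate_mode: str = "projected",
    day_timezone: str = "UTC",
) -> TelemetryDataset:
    """Validate an in-memory fix table (columns animal_id/timestamp/x/y)."""
    return TelemetryDataset(_validate_fixes(df), coordinate_mode, day_timezone)


def read_telemetry(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    coordinate_mode: str = "projected",
    day_timezone: str = "UTC",
) -> TelemetryDataset:
    """Read a relocation CSV into a validated :class:`TelemetryDataset`.

    Parameters
    ----------
    path
        CSV file with one row per fix.
    column_map
        Mapping from internal names (``animal_id``, ``timestamp``, ``x``,
        ``y``) to the file's column names.  Defaults depend on mode:
        ``x``/``y`` for projected data, ``lon``/``lat`` for geographic.

    Raises
    ------
    ConfigurationError
        A mapped column is absent from the file.
    EmptyInputError
        No valid rows survive validation.
    """
    if coordinate_mode not in DEFAULT_COLUMNS:
        raise ConfigurationError(f"unknown coordinate_mode {coordinate_mode!r}")
    cmap = dict(DEFAULT_COLUMNS[coordinate_mode])
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}; found {list(raw.columns)}")
    df = raw.rename(columns={v: k for k, v in cmap.items()})[["animal_id", "timestamp", "x", "y"]]
    return make_dataset(df, coordinate_mode, day_timezone)


def write_telemetry(ds: TelemetryDataset, path: str | Path) -> None:
    """Write the normalised schema back to CSV (ISO-8601 UTC timestamps)."""
    out = ds.fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    names = DEFAULT_COLUMNS[ds.coordinate_mode]
    out.rename(columns={"x": names["x"], "y": names["y"]}).to_csv(path, index=False)


def pairwise_distance(
    xa: float, ya: float, xb: float, yb: float, coordinate_mode: str = "projected"
) -> float:
    """Distance in metres between two fixes.

    Projected mode: Euclidean.  Geographic mode (x=lon, y=lat, degrees):
    haversine great-circle distance on a sphere of radius 6,371,000 m.
    """
    if coordinate_mode == "projected":
        return float(np.hypot(xb - xa, yb - ya))
    if coordinate_mode == "geographic":
        return float(haversine_m(xa, ya, xb, yb))
    raise ConfigurationError(f"unknown coordinate_mode {coordinate_mode!r}")


def haversine_m(lon1, lat1, lon2, lat2):
    """Vectorised haversine distance (metres) on the mean-Earth sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_matrix_m(
    x1: np.ndarray, y1: np.ndarray, x2: np.ndarray, y2: np.ndarray, coordinate_mode: str
) -> np.ndarray:
    """Elementwise distances between coordinate arrays (same shape)."""
    if coordinate_mode == "projected":
        return np.hypot(np.asarray(x2) - np.asarray(x1), np.asarray(y2) - np.asarray(y1))
    return haversine_m(x1, y1, x2, y2)


def summarize_dataset(ds: TelemetryDataset) -> pd.DataFrame:
    """Per-animal summary: fix count, date span, median fix interval.

    Returns one row per animal plus a ``TOTAL`` row.  The median fix
    interval (minutes) is computed from consecutive-fix gaps; animals
    with a single fix get NA.
    """
    rows = []
    for animal, grp in ds.fixes.groupby("animal_id", sort=True):
        ts = grp["timestamp"]
        gaps = ts.diff().dropna().dt.total_seconds() / 60.0
        rows.append(
            {
                "animal_id": animal,
                "n_fixes": len(grp),
                "first_fix": ts.iloc[0],
                "last_fix": ts.iloc[-1],
                "median_fix_interval_min": float(gaps.median()) if len(gaps) else np.nan,
            }
        )
    all_ts = ds.fixes["timestamp"]
    intervals = [r["median_fix_interval_min"] for r in rows if np.isfinite(r["median_fix_interval_min"])]
    rows.append(
        {
            "animal_id": "TOTAL",
            "n_fixes": ds.n_fixes,
            "first_fix": all_ts.min(),
            "last_fix": all_ts.max(),
            "median_fix_interval_min": float(np.median(intervals)) if intervals else np.nan,
        }
    )
    return pd.DataFrame(rows)
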