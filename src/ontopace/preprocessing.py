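"""From raw GPS fixes to per-individual daily maximum displacement.

The analysis currency downstream is the *daily maximum displacement*: the
furthest great-circle distance of any fix on a calendar day from that day's
first fix, which is assumed to be the night roost.  Fixes are first
resampled to a common (coarsest) interval, days with too few locations are
dropped, and day 1 is anchored at fledging (first day at least 200 m from
the nest) or at release.

A fix table is a :class:`pandas.DataFrame` with columns ``individual``,
``timestamp`` (UTC), ``lon``, ``lat``.  Movebank-dialect CSV I/O is
provided by :func:`read_movebank_csv` / :func:`write_movebank_csv`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "DISPLACEMENT_FLOOR_KM",
    "DisplacementSeries",
    "great_circle_m",
    "resample_fixes",
    "detect_fledging",
    "daily_max_displacement",
    "read_movebank_csv",
    "write_movebank_csv",
    "cohort_to_frame",
    "cohort_from_frame",
]

#: Spherical earth radius in metres (WGS84 equatorial radius, the default of
#: common geo-distance tools).
EARTH_RADIUS_M = 6_378_137.0

#: Zero/near-zero displacement days are floored here (km) so the log
#: response stays finite.
DISPLACEMENT_FLOOR_KM = 0.001

_MOVEBANK_COLS = {
    "individual-local-identifier": "individual",
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
}


@dataclass
class DisplacementSeries:
    """Per-individual daily maximum displacement series.

    Attributes
    ----------
    individual : str
        Individual identifier.
    group : str
        Rearing group (``wild``, ``spring`` or ``winter`` in the study
        design; free-form otherwise).
    day : ndarray of int
        Day index since fledging/release, starting at 1, strictly
        increasing.  Days dropped by the fix filter are simply absent.
    km : ndarray of float
        Maximum displacement (km), strictly positive.
    n_fixes : ndarray of int
        Number of fixes contributing to each retained day.
    """

    individual: str
    group: str
    day: np.ndarray
    km: np.ndarray
    n_fixes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.km = np.asarray(self.km, dtype=float)
        if self.n_fixes is None:
            self.n_fixes = np.zeros_like(self.day)
        self.n_fixes = np.asarray(self.n_fixes, dtype=int)
        if self.day.shape != self.km.shape or self.day.shape != self.n_fixes.shape:
            raise ValueError("day, km and n_fixes must have equal length")
        if self.day.size and np.any(np.diff(self.day) <= 0):
            raise ValueError("day indices must be strictly increasing")
        if np.any(~np.isfinite(self.km)) or np.any(self.km <= 0):
            raise ValueError("displacement must be finite and positive")

    def __len__(self) -> int:
        return self.day.size

    @property
    def log_km(self) -> np.ndarray:
        return np.log(self.km)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individual,
                "group": self.group,
                "day": self.day,
                "km": self.km,
                "n_fixes": self.n_fixes,
            }
        )


def cohort_to_frame(cohort: Iterable[DisplacementSeries]) -> pd.DataFrame:
    """Stack a cohort of series into one tidy frame."""
    frames = [s.to_frame() for s in cohort]
    if not frames:
        return pd.DataFrame(columns=["individual", "group", "day", "km", "n_fixes"])
    return pd.concat(frames, ignore_index=True)


def cohort_from_frame(df: pd.DataFrame) -> list[DisplacementSeries]:
    """Inverse of :func:`cohort_to_frame` (one series per individual)."""
    out = []
    for ind, sub in df.groupby("individual", sort=False):
        sub = sub.sort_values("day")
        out.append(
            DisplacementSeries(
                individual=str(ind),
                group=str(sub["group"].iloc[0]),
                day=sub["day"].to_numpy(),
                km=sub["km"].to_numpy(),
                n_fixes=sub["n_fixes"].to_numpy()
                if "n_fixes" in sub
                else None,
            )
        )
    return out


def _validate_coords(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValueError("coordinates out of range (lon in [-180,180], lat in [-90,90])")


def great_circle_m(p, q, radius_m: float = EARTH_RADIUS_M):
    """Haversine great-circle distance in metres between ``p`` and ``q``.

    ``p`` and ``q`` are ``(lon, lat)`` pairs in degrees; either may be an
    array of shape ``(n, 2)`` for vectorized use.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    lon1, lat1 = np.moveaxis(p, -1, 0)
    lon2, lat2 = np.moveaxis(q, -1, 0)
    _validate_coords(lon1, lat1)
    _validate_coords(lon2, lat2)
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius_m * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def _as_fix_table(fixes: pd.DataFrame) -> pd.DataFrame:
    missing = {"individual", "timestamp", "lon", "lat"} - set(fixes.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    return out


def resample_fixes(fixes: pd.DataFrame, interval_minutes: int = 60) -> pd.DataFrame:
    """Thin fixes to at most one per ``interval_minutes`` bin per individual.

    Bins are aligned to the epoch; within each bin the earliest fix is kept
    (a deterministic, order-stable rule).  An empty table passes through.
    """
    if interval_minutes < 1:
        raise ValueError("interval_minutes must be >= 1")
    if fixes.empty:
        return fixes.copy()
    fixes = _as_fix_table(fixes)
    fixes = fixes.sort_values(["individual", "timestamp"], kind="stable")
    bins = fixes["timestamp"].dt.floor(f"{interval_minutes}min")
    keep = ~pd.DataFrame({"i": fixes["individual"], "b": bins}).duplicated()
    return fixes.loc[keep].reset_index(drop=True)


def detect_fledging(
    fixes: pd.DataFrame,
    nest,
    threshold_m: float = 200.0,
) -> Optional[pd.Timestamp]:
    """First calendar day with any fix at least ``threshold_m`` from the nest.

    Returns the (UTC) date of fledging or ``None`` if the bird never moved
    that far.  The 200 m default clears typical in-nest GPS scatter
    (~100 m) while catching the first true departure; the comparison is
    inclusive (exactly 200 m counts as fledged).
    """
    _validate_coords(*np.asarray(nest, dtype=float))
    if fixes.empty:
        return None
    fixes = _as_fix_table(fixes)
    coords = fixes[["lon", "lat"]].to_numpy()
    d = great_circle_m(coords, np.asarray(nest, dtype=float))
    away = fixes.loc[np.asarray(d) >= threshold_m, "timestamp"]
    if away.empty:
        return None
    return away.min().normalize()


def daily_max_displacement(
    fixes: pd.DataFrame,
    min_fixes: int = 10,
    start_dates: Optional[Mapping[str, pd.Timestamp]] = None,
    groups: Optional[Mapping[str, str]] = None,
    floor_km: float = DISPLACEMENT_FLOOR_KM,
    radius_m: float = EARTH_RADIUS_M,
) -> list[DisplacementSeries]:
    """Compute per-individual daily maximum displacement series.

    For every calendar day with at least ``min_fixes`` fixes, displacement
    is the maximum great-circle distance of the day's fixes from the day's
    *first* fix (the assumed roost).  Day indexing starts at 1 on the
    individual's ``start_dates`` entry (fledging or release day); when no
    start date is given, the first retained day becomes day 1.

    Days below ``floor_km`` are floored there so that the log transform
    downstream stays finite.  Individuals retaining zero days produce an
    empty series and a warning.
    """
    if min_fixes < 1:
        raise ValueError("min_fixes must be >= 1")
    fixes = _as_fix_table(fixes)
    start_dates = dict(start_dates or {})
    groups = dict(groups or {})
    out: list[DisplacementSeries] = []
    for ind, sub in fixes.groupby("individual", sort=False):
        sub = sub.sort_values("timestamp", kind="stable")
        date = sub["timestamp"].dt.normalize()
        days, kms, nfx = [], [], []
        for d, day_fixes in sub.groupby(date, sort=True):
            if len(day_fixes) < min_fixes:
                continue
            coords = day_fixes[["lon", "lat"]].to_numpy()
            dist = great_circle_m(coords, coords[0], radius_m=radius_m)
            km = float(np.max(dist)) / 1000.0
            days.append(d)
            kms.append(max(km, floor_km))
            nfx.append(len(day_fixes))
        if not days:
            warnings.warn(f"individual {ind!r}: no days with >= {min_fixes} fixes")
            out.append(
                DisplacementSeries(
                    individual=str(ind),
                    group=groups.get(str(ind), "unknown"),
                    day=np.array([], dtype=int),
                    km=np.array([], dtype=float),
                    n_fixes=np.array([], dtype=int),
                )
            )
            continue
        start = pd.Timestamp(start_dates.get(str(ind), days[0])).normalize()
        if start.tz is None:
            start = start.tz_localize("UTC")
        day_idx = np.array([(d - start).days + 1 for d in days], dtype=int)
        keep = day_idx >= 1  # pre-fledging days are not part of ontogeny
        out.append(
            DisplacementSeries(
                individual=str(ind),
                group=groups.get(str(ind), "unknown"),
                day=day_idx[keep],
                km=np.asarray(kms)[keep],
                n_fixes=np.asarray(nfx)[keep],
            )
        )
    return out


def read_movebank_csv(path) -> pd.DataFrame:
    """Read a Movebank-dialect CSV into the internal fix-table layout."""
    df = pd.read_csv(path)
    missing = set(_MOVEBANK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"not a Movebank-dialect CSV; missing {sorted(missing)}")
    df = df.rename(columns=_MOVEBANK_COLS)[list(_MOVEBANK_COLS.values())]
    df["individual"] = df["individual"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_movebank_csv(fixes: pd.DataFrame, path) -> None:
    """Write a fix table as Movebank-dialect CSV (ISO-8601 UTC timestamps)."""
    fixes = _as_fix_table(fixes)
    out = fixes.rename(columns={v: k for k, v in _MOVEBANK_COLS.items()})
    out = out[list(_MOVEBANK_COLS)]
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
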