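"""Winter storm statistics from extratropical cyclone tracks.

Tracks are 6-hourly point sequences (time, lon, lat, minimum sea-level
pressure).  Following the standard screening for significant extratropical
cyclones, tracks are retained only if they last more than 48 hours and travel
more than 1000 great-circle kilometres.  Per winter (1 December - end of
February, UTC) and wintering box (closed lon/lat rectangle), a storm counts if
any of its points falls inside the box during the window; its occupancy runs
give the in-box duration, its minimum in-box sea-level pressure the intensity,
and the exit-to-next-entry times the gaps between storms.  Daily maxima of
wind gust and significant wave height yield threshold-exceedance day counts
(a day "exceeds" at value >= threshold; the tie rule is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StormTrack",
    "WinterStormStats",
    "haversine_km",
    "read_tracks_csv",
    "write_tracks_csv",
    "filter_tracks",
    "winter_window",
    "winter_storm_stats",
    "exceedance_days",
    "winter_storm_table",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class StormTrack:
    track_id: str
    times: np.ndarray      # datetime64[s], strictly increasing
    lon: np.ndarray        # degrees east, [-180, 180]
    lat: np.ndarray        # degrees north, [-90, 90]
    mslp: np.ndarray       # minimum sea-level pressure, hPa

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.lon = np.asarray(self.lon, float)
        self.lat = np.asarray(self.lat, float)
        self.mslp = np.asarray(self.mslp, float)
        n = len(self.times)
        if n < 2:
            raise ValueError(f"track {self.track_id}: needs at least 2 points")
        if not all(len(a) == n for a in (self.lon, self.lat, self.mslp)):
            raise ValueError(f"track {self.track_id}: ragged point arrays")
        if (np.diff(self.times).astype(float) <= 0).any():
            raise ValueError(f"track {self.track_id}: timestamps not strictly increasing")
        if (np.abs(self.lon) > 180).any() or (np.abs(self.lat) > 90).any():
            raise ValueError(f"track {self.track_id}: coordinates out of range")

    @property
    def lifetime_hours(self) -> float:
        return float((self.times[-1] - self.times[0]) / np.timedelta64(1, "h"))

    @property
    def path_length_km(self) -> float:
        return float(
            haversine_km(self.lon[:-1], self.lat[:-1], self.lon[1:], self.lat[1:]).sum()
        )


def read_tracks_csv(path) -> list[StormTrack]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("timestamp")
        tracks.append(
            StormTrack(
                str(tid),
                grp["timestamp"].to_numpy(),
                grp["lon"].to_numpy(float),
                grp["lat"].to_numpy(float),
                grp["mslp_hpa"].to_numpy(float),
            )
        )
    return tracks


def write_tracks_csv(tracks: Sequence[StormTrack], path) -> None:
    frames = [
        pd.DataFrame(
            {"track_id": t.track_id, "timestamp": t.times, "lon": t.lon,
             "lat": t.lat, "mslp_hpa": t.mslp}
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def filter_tracks(
    tracks: Iterable[StormTrack],
    min_lifetime_hours: float = 48.0,
    min_path_km: float = 1000.0,
) -> list[StormTrack]:
    """Keep tracks lasting strictly over 48 h and travelling strictly over 1000 km."""
    return [
        t for t in tracks
        if t.lifetime_hours > min_lifetime_hours and t.path_length_km > min_path_km
    ]


def winter_window(start_year: int) -> tuple[np.datetime64, np.datetime64]:
    """[Dec 1 00:00 UTC, Mar 1 00:00 UTC) for the winter labelled by its December year."""
    return (
        np.datetime64(f"{start_year}-12-01T00:00:00"),
        np.datetime64(f"{start_year + 1}-03-01T00:00:00"),
    )


@dataclass
class WinterStormStats:
    winter: str
    n_storms: int
    mean_intensity: float | None     # hPa, min SLP while inside the box
    mean_duration: float | None      # hours inside box
    mean_gap: float | None           # hours, exit of one storm to entry of next
    exceedance: dict[str, int] | None = None


def _occupancy(track: StormTrack, box, window) -> tuple | None:
    """(entry, exit, duration_h, min_slp) of a track's in-box, in-window points."""
    lon0, lon1, lat0, lat1 = box
    t0, t1 = window
    inside = (
        (track.lon >= lon0) & (track.lon <= lon1)
        & (track.lat >= lat0) & (track.lat <= lat1)
        & (track.times >= t0) & (track.times < t1)
    )
    if not inside.any():
        return None
    idx = np.flatnonzero(inside)
    # split into consecutive runs; duration sums each run's first-to-last span
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    dur = sum(
        float((track.times[idx[e]] - track.times[idx[s]]) / np.timedelta64(1, "h"))
        for s, e in zip(starts, ends)
    )
    return (
        track.times[idx[0]],
        track.times[idx[-1]],
        dur,
        float(track.mslp[inside].min()),
    )


def winter_storm_stats(
    tracks: Iterable[StormTrack],
    box: tuple[float, float, float, float],
    winter_start_year: int,
) -> WinterStormStats:
    """Storm count, mean in-box intensity/duration, and mean gap for one winter.

    ``box`` is (lon_min, lon_max, lat_min, lat_max), closed on all edges.
    Gaps between overlapping occupancies count as zero; the mean gap is
    undefined (None) with fewer than two storms.
    """
    window = winter_window(winter_start_year)
    occ = [o for o in (_occupancy(t, box, window) for t in tracks) if o is not None]
    label = f"{winter_start_year}/{str(winter_start_year + 1)[-2:]}"
    if not occ:
        return WinterStormStats(label, 0, None, None, None)
    occ.sort(key=lambda o: o[0])
    durations = [o[2] for o in occ]
    intensities = [o[3] for o in occ]
    gaps = [
        max(0.0, float((b[0] - a[1]) / np.timedelta64(1, "h")))
        for a, b in zip(occ, occ[1:])
    ]
    return WinterStormStats(
        winter=label,
        n_storms=len(occ),
        mean_intensity=float(np.mean(intensities)),
        mean_duration=float(np.mean(durations)),
        mean_gap=float(np.mean(gaps)) if gaps else None,
    )


def exceedance_days(
    daily_series: pd.Series,
    thresholds: Sequence[float],
    allow_gaps: bool = False,
    expected_days: int | None = None,
) -> dict[float, int]:
    """Days with daily maximum >= each threshold over the winter window."""
    vals = daily_series.dropna()
    missing = daily_series.isna().sum() + (
        max(0, expected_days - len(daily_series)) if expected_days else 0
    )
    if missing and not allow_gaps:
        raise ValueError(f"{missing} missing days in daily series (set allow_gaps=True)")
    return {float(th): int((vals >= th).sum()) for th in thresholds}


def winter_storm_table(
    tracks: Sequence[StormTrack],
    box: tuple[float, float, float, float],
    winter_start_years: Sequence[int],
    daily: pd.DataFrame | None = None,
    wind_thresholds: Sequence[float] = (30.0, 35.0),
    wave_thresholds: Sequence[float] = (5.0, 7.0, 10.0),
    allow_gaps: bool = False,
) -> pd.DataFrame:
    """Per-winter storm-characteristic table (one row per winter).

    ``daily`` has a datetime ``date`` column plus ``max_wind_ms`` and
    ``max_wave_m``; exceedance counts are restricted to each winter window.
    """
    kept = filter_tracks(tracks)
    rows = []
    for year in winter_start_years:
        st = winter_storm_stats(kept, box, year)
        row = {
            "winter": st.winter,
            "winter_start_year": year,
            "n_storms": st.n_storms,
            "mean_intensity": st.mean_intensity,
            "mean_duration": st.mean_duration,
            "mean_gap": st.mean_gap,
        }
        if daily is not None:
            t0, t1 = winter_window(year)
            dates = pd.to_datetime(daily["date"])
            sel = daily[(dates >= pd.Timestamp(t0)) & (dates < pd.Timestamp(t1))]
            for th, cnt in exceedance_days(
                sel["max_wind_ms"], wind_thresholds, allow_gaps=allow_gaps
            ).items():
                row[f"days_wind_ge_{int(th)}"] = cnt
            for th, cnt in exceedance_days(
                sel["max_wave_m"], wave_thresholds, allow_gaps=allow_gaps
            ).items():
                row[f"days_wave_ge_{int(th)}"] = cnt
        rows.append(row)
    return pd.DataFrame(rows)
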