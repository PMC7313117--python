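"""Weather association and wind decomposition for foraging trips.

Hourly station records are matched to trip timestamps by nearest time.  The
trip direction (TD) is the initial bearing from the nest to the farthest
point of the trip, assumed to point at the goal foraging area.  With WS the
mean of the departure and return wind speeds and WD the circular mean of the
corresponding wind directions, the tailwind and crosswind components are

    TWC = WS * cos(TD - WD)        (signed; > 0 means wind assistance)
    CWC = |WS * sin(TD - WD)|      (side-wind magnitude)

These equations require WD in the "blowing toward" convention; station files
usually report the direction the wind blows FROM, so the reader converts
(``wind_convention="from"``, the default) by adding 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import haversine_distance, initial_bearing

MAX_MATCH_GAP_H = 3.0


@dataclass
class WindComponents:
    td_deg: float
    twc_ms: float
    cwc_ms: float
    solar_at_departure: float
    rain_present: int


def match_weather(t, records: pd.DataFrame) -> pd.Series | None:
    """Nearest-in-time weather record; ties resolved to the earlier record.

    Returns ``None`` (missing) when the nearest record is more than 3 h away.
    """
    if records is None or len(records) == 0:
        raise ValueError("no weather records")
    rt = pd.to_datetime(records["t"])
    dt = (rt - pd.Timestamp(t)).dt.total_seconds().to_numpy()
    absdt = np.abs(dt)
    best = absdt.min()
    if best > MAX_MATCH_GAP_H * 3600.0:
        return None
    cand = np.flatnonzero(absdt == best)
    if len(cand) > 1:  # tie: prefer the earlier record
        cand = [cand[np.argmin(dt[cand])]]
    return records.iloc[int(cand[0])]


def trip_direction(trip, nest: tuple[float, float]) -> float:
    """Bearing (deg from north, [0, 360)) from the nest to the trip's farthest fix."""
    lat = trip.fixes["lat"].to_numpy(dtype=float)
    lon = trip.fixes["lon"].to_numpy(dtype=float)
    d = haversine_distance(lat, lon, nest[0], nest[1])
    far = int(np.argmax(d))
    if d[far] <= 0:
        raise ValueError("farthest point coincides with the nest; TD undefined")
    return float(initial_bearing(nest[0], nest[1], lat[far], lon[far]))


def _to_toward(wd_deg: float, convention: str) -> float:
    if convention == "from":
        return (wd_deg + 180.0) % 360.0
    if convention == "toward":
        return wd_deg % 360.0
    raise ValueError("wind_convention must be 'from' or 'toward'")


def circular_mean_deg(angles_deg) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


def tail_cross_components(ws: float, td_deg: float, wd_toward_deg: float) -> tuple[float, float]:
    """Closed-form TWC/CWC for a single wind speed and direction."""
    delta = np.radians(td_deg - wd_toward_deg)
    return float(ws * np.cos(delta)), float(abs(ws * np.sin(delta)))


def wind_components(
    trip,
    records: pd.DataFrame,
    nest: tuple[float, float],
    wind_convention: str = "from",
) -> WindComponents | None:
    """Trip-level weather covariates.

    WS is the arithmetic mean of the wind speeds matched at departure and
    return; WD the circular mean of the two (toward-convention) directions.
    ``rain_present`` is 1 when any hourly record matched to a trip fix
    recorded rain.  Returns ``None`` when departure or return weather cannot
    be matched within 3 h.
    """
    dep = match_weather(trip.fixes["t"].iloc[0], records)
    ret = match_weather(trip.fixes["t"].iloc[-1], records)
    if dep is None or ret is None:
        return None
    td = trip_direction(trip, nest)
    ws = 0.5 * (float(dep["wind_speed_ms"]) + float(ret["wind_speed_ms"]))
    wd = circular_mean_deg(
        [
            _to_toward(float(dep["wind_dir_deg"]), wind_convention),
            _to_toward(float(ret["wind_dir_deg"]), wind_convention),
        ]
    )
    twc, cwc = tail_cross_components(ws, td, wd)
    rain = trip_rain_presence(trip.fixes["t"], records)
    return WindComponents(
        td_deg=td,
        twc_ms=twc,
        cwc_ms=cwc,
        solar_at_departure=float(dep["solar_wm2"]),
        rain_present=rain,
    )


def trip_rain_presence(fix_times, records: pd.DataFrame) -> int:
    """1 iff any record matched to any trip fix has rain > 0."""
    rt = pd.to_datetime(records["t"]).to_numpy()
    ts = pd.to_datetime(pd.Series(list(fix_times))).to_numpy()
    # nearest hourly record per fix (ties -> earlier, consistent with match_weather)
    diffs = np.abs(ts[:, None] - rt[None, :]).astype("timedelta64[ns]").astype(np.int64)
    nearest = diffs.argmin(axis=1)
    rain = records["rain_mm"].to_numpy(dtype=float)
    return int(bool(np.any(rain[np.unique(nearest)] > 0)))
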