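"""Trajectory primitives: great-circle geometry, step metrics and foraging-trip
segmentation for a central-place forager.

A foraging trip is a maximal run of GPS fixes outside a 50-m buffer around the
nest (and optional roost sites), bounded by inside-buffer fixes where those
exist.  Bounding fixes are included in the trip so that a trip that departs
from and returns to the central place has ``length >= 2 * max_distance``
(tortuosity >= 2) by the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

HABITAT_CLASSES = (
    "artificial",
    "arable",
    "permanent_crop",
    "grassland",
    "heterogeneous_agri",
    "wooded",
)

STAGE_INCUBATION = "incubation"
STAGE_NESTLING = "nestling_rearing"


# ---------------------------------------------------------------------------
# Spherical geometry
# ---------------------------------------------------------------------------

def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("latitude must be in [-90, 90], longitude in [-180, 180]")


def haversine_distance(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres (spherical Earth, R = 6371 km).

    Accepts scalars or broadcastable arrays of WGS84 decimal degrees.
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    return float(d) if np.ndim(d) == 0 else d


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2.

    Returned in degrees clockwise from true north, in [0, 360).
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return float(theta) if np.ndim(theta) == 0 else theta


def destination_point(lat, lon, bearing_deg, distance_m):
    """Point reached travelling ``distance_m`` along ``bearing_deg`` on the sphere."""
    _check_coords(lat, lon)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(bearing_deg)
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lat2 = np.degrees(phi2)
    lon2 = (np.degrees(lam2) + 540.0) % 360.0 - 180.0
    return lat2, lon2


def wrap_angle_pi(angle_rad):
    """Wrap an angular difference to [0, pi] (absolute turning magnitude)."""
    a = np.abs(np.asarray(angle_rad, dtype=float)) % (2.0 * np.pi)
    a = np.where(a > np.pi, 2.0 * np.pi - a, a)
    return float(a) if np.ndim(a) == 0 else a


# ---------------------------------------------------------------------------
# Step metrics
# ---------------------------------------------------------------------------

def step_metrics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Instantaneous velocity and turning angle between successive positions.

    Parameters
    ----------
    fixes : DataFrame with columns ``t`` (datetime64), ``lat``, ``lon``,
        strictly time-ordered.

    Returns
    -------
    DataFrame indexed like ``fixes`` with columns ``step_length`` (m, fix i ->
    i+1), ``speed`` (m/s), ``heading`` (deg from north of the outgoing step)
    and ``turn`` (rad in [0, pi], absolute heading change at interior fixes).
    Quantities that are undefined at the trajectory ends are NaN.
    """
    if len(fixes) < 3:
        raise ValueError("step metrics require at least 3 fixes")
    t = pd.to_datetime(fixes["t"]).to_numpy()
    dt = np.diff(t).astype("timedelta64[ns]").astype(float) / 1e9
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    d = haversine_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
    heading = initial_bearing(lat[:-1], lon[:-1], lat[1:], lon[1:])
    n = len(fixes)
    out = pd.DataFrame(
        {
            "step_length": np.full(n, np.nan),
            "speed": np.full(n, np.nan),
            "heading": np.full(n, np.nan),
            "turn": np.full(n, np.nan),
        },
        index=fixes.index,
    )
    out.iloc[:-1, out.columns.get_loc("step_length")] = d
    out.iloc[:-1, out.columns.get_loc("speed")] = d / dt
    out.iloc[:-1, out.columns.get_loc("heading")] = heading
    # turn at interior fix i compares incoming step (i-1 -> i) to outgoing (i -> i+1)
    dturn = wrap_angle_pi(np.radians(heading[1:] - heading[:-1]))
    out.iloc[1:-1, out.columns.get_loc("turn")] = dturn
    return out


# ---------------------------------------------------------------------------
# Trips
# ---------------------------------------------------------------------------

@dataclass
class Trip:
    """A foraging excursion of one individual."""

    trip_id: str
    individual_id: str
    fixes: pd.DataFrame = field(repr=False)
    start_t: pd.Timestamp = None
    end_t: pd.Timestamp = None
    has_start_bound: bool = True
    has_end_bound: bool = True
    stage: str | None = None
    duration_h: float | None = None
    length_km: float | None = None
    max_distance_km: float | None = None
    tortuosity: float | None = None

    @property
    def incomplete(self) -> bool:
        """True when the device switched off before the bird returned."""
        return not self.has_end_bound

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


def _inside_buffer(lat, lon, centres, buffer_m):
    inside = np.zeros(np.shape(lat), dtype=bool)
    for clat, clon in centres:
        inside |= haversine_distance(lat, lon, clat, clon) <= buffer_m
    return inside


def segment_trips(
    fixes: pd.DataFrame,
    nest: tuple[float, float],
    roosts: list[tuple[float, float]] | None = None,
    buffer_m: float = 50.0,
    first_fix_discard_km: float = 2.0,
    tz_offset_h: float = 0.0,
) -> list[Trip]:
    """Segment one individual's fixes into foraging trips.

    Rules applied per local day (devices record 05:00-21:00 local time):

    * a trip is a maximal run of consecutive fixes outside all ``buffer_m``
      buffers around the nest/roosts, extended by the bounding inside-buffer
      fixes where present;
    * the first run of a day with no preceding inside-buffer fix is discarded
      when its first fix lies more than ``first_fix_discard_km`` from the nest
      (the bird was already in the countryside when the device switched on);
    * runs whose fixes all carry the ``artificial`` habitat code are dropped
      (urban-only excursions are not foraging);
    * a run truncated by device-off is kept but flagged incomplete.
    """
    if nest is None:
        raise ValueError("nest coordinates are required")
    if fixes is None or len(fixes) == 0:
        return []
    fixes = fixes.sort_values("t").reset_index(drop=True)
    individual = str(fixes["individual_id"].iloc[0]) if "individual_id" in fixes else ""
    centres = [tuple(nest)] + [tuple(r) for r in (roosts or [])]
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    t = pd.to_datetime(fixes["t"])
    inside = _inside_buffer(lat, lon, centres, buffer_m)
    local_date = (t + pd.to_timedelta(tz_offset_h, unit="h")).dt.date.to_numpy()

    trips: list[Trip] = []
    counter = 0
    for day in pd.unique(local_date):
        day_ix = np.flatnonzero(local_date == day)
        day_inside = inside[day_ix]
        # runs of consecutive outside fixes within the day
        i = 0
        n = len(day_ix)
        while i < n:
            if day_inside[i]:
                i += 1
                continue
            j = i
            while j < n and not day_inside[j]:
                j += 1
            run = day_ix[i:j]
            has_start = i > 0
            has_end = j < n
            keep = True
            if not has_start:
                d0 = haversine_distance(lat[run[0]], lon[run[0]], nest[0], nest[1])
                if d0 > first_fix_discard_km * 1000.0:
                    keep = False
            if keep and "habitat" in fixes.columns:
                hab = fixes["habitat"].iloc[run]
                if hab.notna().all() and (hab == "artificial").all():
                    keep = False
            if keep:
                sel = list(run)
                if has_start:
                    sel = [day_ix[i - 1]] + sel
                if has_end:
                    sel = sel + [day_ix[j]]
                if len(sel) >= 3:
                    trip_fixes = fixes.iloc[sel].reset_index(drop=True)
                    counter += 1
                    trips.append(
                        Trip(
                            trip_id=f"{individual}_t{counter:03d}",
                            individual_id=individual,
                            fixes=trip_fixes,
                            start_t=trip_fixes["t"].iloc[0],
                            end_t=trip_fixes["t"].iloc[-1],
                            has_start_bound=has_start,
                            has_end_bound=has_end,
                        )
                    )
            i = j
    return trips


def trip_descriptors(trip: Trip, nest: tuple[float, float]) -> dict:
    """Spatio-temporal descriptors: duration (h), length (km), maximum
    distance from the nest (km) and tortuosity (length / max distance).
    """
    fx = trip.fixes
    if len(fx) < 2:
        raise ValueError("descriptors require at least 2 fixes")
    t = pd.to_datetime(fx["t"])
    duration_h = (t.iloc[-1] - t.iloc[0]).total_seconds() / 3600.0
    lat = fx["lat"].to_numpy(dtype=float)
    lon = fx["lon"].to_numpy(dtype=float)
    steps = haversine_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
    length_km = float(np.sum(steps)) / 1000.0
    dnest = haversine_distance(lat, lon, nest[0], nest[1])
    max_km = float(np.max(dnest)) / 1000.0
    tortuosity = length_km / max_km if max_km > 0 else np.nan
    trip.duration_h = duration_h
    trip.length_km = length_km
    trip.max_distance_km = max_km
    trip.tortuosity = tortuosity
    return {
        "duration_h": duration_h,
        "length_km": length_km,
        "max_distance_km": max_km,
        "tortuosity": tortuosity,
    }


def assign_stage(trip_date, nest_records: pd.DataFrame) -> str:
    """Breeding stage on the trip date from the nest-content timeline.

    ``incubation`` when only eggs are present, ``nestling_rearing`` when at
    least one nestling is present.
    """
    dates = pd.to_datetime(nest_records["date"]).dt.date
    trip_date = pd.to_datetime(trip_date).date() if not hasattr(trip_date, "year") else trip_date
    match = nest_records.loc[dates == pd.Timestamp(trip_date).date()]
    if len(match) == 0:
        raise ValueError(f"no nest record covering {trip_date}")
    eggs = int(match["eggs"].iloc[0])
    nestlings = int(match["nestlings"].iloc[0])
    if nestlings >= 1:
        return STAGE_NESTLING
    if eggs >= 1:
        return STAGE_INCUBATION
    raise ValueError("nest record has neither eggs nor nestlings")


def habitat_time(habitats, behaviours) -> dict:
    """Proportion of trip fixes in each habitat class.

    Relocation fixes are excluded: habitat use is meaningful only where the
    bird is actually foraging/perching, not commuting.  Returns NaN for all
    classes when every fix is relocation.
    """
    habitats = pd.Series(list(habitats))
    behaviours = pd.Series(list(behaviours))
    if len(habitats) != len(behaviours):
        raise ValueError("habitat and behaviour sequences differ in length")
    mask = behaviours != "relocation"
    sub = habitats[mask]
    if len(sub) == 0:
        return {c: np.nan for c in HABITAT_CLASSES}
    counts = sub.value_counts()
    total = float(len(sub))
    return {c: float(counts.get(c, 0)) / total for c in HABITAT_CLASSES}
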