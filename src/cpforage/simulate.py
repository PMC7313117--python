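"""Synthetic central-place foraging study with known ground truth.

Emulates the design of a colonial-raptor biologging campaign: 36 breeding
birds tracked for 2-5 days in June (one GPS fix per minute, 05:00-21:00
local; tri-axial acceleration at 25 Hz), hourly weather from a nearby
station, nest contents monitored through hatching, nestlings weighed twice,
and adult morphometrics at capture.

Generative model
----------------
* Each individual carries a latent logit intercept b_i ~ N(0, sigma_id^2).
* For every planned trip, weather covariates (solar radiation at departure,
  rain presence during the trip, tailwind and crosswind components along the
  planned trip direction) and breeding stage are computed, z-scored across
  the study, and the trip tactic is drawn from
  logit P(DF) = beta0 + beta . z + b_i.
* Within a trip, behaviour follows a first-order Markov chain whose
  stationary distribution is the tactic's target behaviour composition
  (perch-dominated for SF, relocation/search-dominated for DF); transition
  matrix T = alpha I + (1 - alpha) 1 pi', which has stationary law pi and
  geometric run lengths controlled by the persistence alpha.
* Movement is simulated in a local planar frame around the nest (trips span
  well under 20 km, where planar error is negligible) and converted to
  WGS84.  Speeds and absolute turning angles are drawn from truncated
  normals per behavioural mode; headings blend persistence with a pull
  toward the goal (outbound) or the nest (return).  At-nest fixes sit
  exactly on the nest coordinates: GPS error is not emulated.
* Acceleration streams have a constant gravity static component (0, 0, 1) g
  and zero-mean Gaussian dynamic noise whose SD depends on the behaviour,
  flight modes being strictly noisier than perching.
* Nestling daily relative mass gain is coupled to the parent's latent
  intercept (more DF-prone parents foster faster growth), which gives the
  fitness-correlation analyses a known positive target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .trajectory import EARTH_RADIUS_M

MODES = ("perch", "intensive_search", "extensive_search", "relocation")
TACTICS = ("SF", "DF")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviourParams:
    """Per-mode kinematics (truncated-normal speed and |turn|) and dynamic
    acceleration SD."""

    speed_mean: float   # m/s
    speed_sd: float
    turn_mean: float    # rad, absolute
    turn_sd: float
    dyn_sd: float       # g


DEFAULT_BEHAVIOUR = {
    "perch": BehaviourParams(0.3, 0.25, 0.25, 0.18, 0.03),
    "intensive_search": BehaviourParams(2.5, 1.0, 2.2, 0.45, 0.15),
    "extensive_search": BehaviourParams(9.0, 1.8, 2.0, 0.45, 0.18),
    "relocation": BehaviourParams(10.0, 2.0, 0.2, 0.15, 0.22),
}

# target behaviour composition per tactic (perch, intensive, extensive, reloc)
TACTIC_COMPOSITION = {
    "SF": np.array([0.53, 0.15, 0.04, 0.28]),
    "DF": np.array([0.07, 0.26, 0.07, 0.60]),
}
TACTIC_PERSISTENCE = {"SF": 0.92, "DF": 0.85}


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 36
    trips_mean: float = 14.0
    trips_range: tuple[int, int] = (1, 45)
    tracking_days_range: tuple[int, int] = (2, 5)
    fix_interval_s: int = 60
    acc_rate_hz: int = 25
    behaviour: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOUR))
    sigma_id: float = 0.773          # latent intercept SD (-> R_adj ~ 0.13 at pbar 0.5)
    beta0: float = 0.62              # marginal log-odds of DF (~65% DF trips)
    beta: dict = field(
        default_factory=lambda: {
            "solar": 0.70,
            "rain": -0.12,
            "twc": -0.16,
            "cwc": 0.32,
            "stage": 0.53,
        }
    )
    nest_coords: tuple[float, float] = (40.65, 16.60)
    years: tuple[int, ...] = (2016, 2017, 2018)
    season_days: int = 20            # June 1-20
    duration_mean_h: float = 1.5
    duration_sd_h: float = 0.8
    duration_range_h: tuple[float, float] = (0.25, 4.0)
    maxdist_mean_km: float = 6.0
    maxdist_sd_km: float = 2.5
    maxdist_range_km: tuple[float, float] = (1.5, 18.0)
    female_frac: float = 13.0 / 36.0
    dbmi_base: float = 0.0145        # daily relative nestling mass gain
    dbmi_per_logit: float = 0.004    # coupling of gain to the parent intercept
    dbmi_noise_sd: float = 0.004
    brood_fail_prob: float = 0.12
    nestling_survival: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0 or self.trips_range[0] <= 0:
            raise ValueError("counts must be positive")
        if self.fix_interval_s <= 0 or self.acc_rate_hz <= 0:
            raise ValueError("fix interval and accelerometer rate must be positive")
        if self.sigma_id < 0:
            raise ValueError("sigma_id must be non-negative")
        bp = self.behaviour
        for m in MODES:
            p = bp[m]
            if min(p.speed_sd, p.turn_sd, p.dyn_sd) < 0:
                raise ValueError("behaviour SDs must be non-negative")
        search = (bp["intensive_search"].speed_mean, bp["extensive_search"].speed_mean)
        if not (bp["perch"].speed_mean < min(search) <= max(search) <
                bp["relocation"].speed_mean):
            raise ValueError("speed means must be ordered perch < search < relocation")


@dataclass
class SyntheticTruth:
    fix_behaviour: pd.DataFrame        # individual_id, t, mode, trip_uid
    trip_tactic: pd.DataFrame          # one row per realized trip
    individual_intercept: pd.DataFrame
    true_params: dict


@dataclass
class StudyBundle:
    fixes: pd.DataFrame
    weather: pd.DataFrame
    nests: pd.DataFrame
    nestlings: pd.DataFrame
    adults: pd.DataFrame
    config: SimConfig
    acc: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def _truncnorm(mean, sd, lo, hi, size, rng):
    if sd <= 0:
        return np.full(size, mean, dtype=float)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_speed(mode: str, n: int, cfg: SimConfig, rng) -> np.ndarray:
    p = cfg.behaviour[mode]
    return _truncnorm(p.speed_mean, p.speed_sd, 0.0, np.inf, n, rng)


def sample_turn(mode: str, n: int, cfg: SimConfig, rng) -> np.ndarray:
    p = cfg.behaviour[mode]
    return _truncnorm(p.turn_mean, p.turn_sd, 0.0, np.pi, n, rng)


def transition_matrix(tactic: str) -> np.ndarray:
    pi = TACTIC_COMPOSITION[tactic]
    alpha = TACTIC_PERSISTENCE[tactic]
    return alpha * np.eye(4) + (1.0 - alpha) * np.outer(np.ones(4), pi)


def markov_behaviours(tactic: str, n: int, rng) -> list[str]:
    T = transition_matrix(tactic)
    pi = TACTIC_COMPOSITION[tactic]
    seq = np.empty(n, dtype=int)
    seq[0] = rng.choice(4, p=pi)  # stationary start keeps trip composition on target
    for k in range(1, n):
        seq[k] = rng.choice(4, p=T[seq[k - 1]])
    seq[0] = 3
    seq[-1] = 3  # departure / return commute
    return [MODES[i] for i in seq]


# ---------------------------------------------------------------------------
# Accelerometry
# ---------------------------------------------------------------------------

def simulate_acc_stream(
    fix_behaviours, cfg: SimConfig, rng=None, start_t=None
) -> pd.DataFrame:
    """25 Hz tri-axial stream for a sequence of per-fix behaviours.

    Static component is the gravity vector (0, 0, 1) g; the dynamic component
    is zero-mean Gaussian noise with the behaviour's configured SD.  Stream
    length is ``n_fixes * fix_interval_s * acc_rate_hz`` samples.
    """
    behaviours = list(fix_behaviours)
    if len(behaviours) == 0:
        raise ValueError("behaviour sequence is empty")
    unknown = set(behaviours) - set(MODES)
    if unknown:
        raise ValueError(f"unknown behaviour labels: {unknown}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    per_fix = cfg.fix_interval_s * cfg.acc_rate_hz
    n = len(behaviours) * per_fix
    sd = np.repeat([cfg.behaviour[b].dyn_sd for b in behaviours], per_fix)
    dyn = rng.standard_normal((n, 3)) * sd[:, None]
    out = pd.DataFrame(dyn, columns=["ax", "ay", "az"])
    out["az"] += 1.0  # gravity
    if start_t is not None:
        out.insert(
            0,
            "t",
            pd.Timestamp(start_t)
            + pd.to_timedelta(np.arange(n) / cfg.acc_rate_hz, unit="s"),
        )
    return out


class AccSimulator:
    """On-demand acceleration streams for arbitrary time windows.

    Streams are generated per minute from the study's per-fix truth
    behaviours with a seed derived from (study seed, individual, epoch
    minute), so any window is reproducible independently of query order.
    Raw 25 Hz data for a whole study would be several gigabytes; generating
    windows lazily keeps memory flat.
    """

    def __init__(self, truth: SyntheticTruth, cfg: SimConfig):
        self.cfg = cfg
        self.seed = cfg.seed
        fb = truth.fix_behaviour
        self._modes = {
            (row.individual_id, row.t.value // 60_000_000_000): row.mode
            for row in fb.itertuples()
        }
        self._ind_code = {
            ind: i for i, ind in enumerate(pd.unique(fb["individual_id"]))
        }

    def stream(self, individual_id, start_t, end_t) -> pd.DataFrame:
        start = pd.Timestamp(start_t).floor("min")
        end = pd.Timestamp(end_t)
        chunks = []
        minute = start
        code = self._ind_code.get(individual_id, 0)
        while minute <= end:
            key = (individual_id, minute.value // 60_000_000_000)
            mode = self._modes.get(key)
            if mode is not None:
                ss = np.random.SeedSequence(
                    entropy=(self.seed % (2**31), 0xACC, code, key[1] % (2**31))
                )
                chunk = simulate_acc_stream(
                    [mode], self.cfg, rng=np.random.default_rng(ss), start_t=minute
                )
                chunks.append(chunk)
            minute += pd.Timedelta(minutes=1)
        if not chunks:
            return pd.DataFrame(columns=["t", "ax", "ay", "az"])
        return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def simulate_weather(cfg: SimConfig, rng) -> pd.DataFrame:
    """Hourly station table for every study year (June 1 .. June ``season_days``).

    Solar radiation follows a truncated sine over the 05:30-21:00 daylight
    window modulated by a daily cloudiness factor; rain is clustered into
    rainy days; wind speed is AR(1) and wind direction (FROM convention) a
    wrapped random walk.
    """
    rows = []
    for year in cfg.years:
        t0 = pd.Timestamp(year=year, month=6, day=1)
        hours = pd.date_range(t0, periods=cfg.season_days * 24, freq="h")
        cloud = rng.uniform(0.4, 1.0, size=cfg.season_days)
        rainy_day = rng.random(cfg.season_days) < 0.25
        ws = np.empty(len(hours))
        wd = np.empty(len(hours))
        ws[0] = max(rng.normal(3.5, 1.5), 0.3)
        wd[0] = rng.uniform(0, 360)
        for k in range(1, len(hours)):
            ws[k] = np.clip(3.5 + 0.85 * (ws[k - 1] - 3.5) + rng.normal(0, 0.8), 0.3, 15.0)
            wd[k] = (wd[k - 1] + rng.normal(0, 15.0)) % 360.0
        for k, t in enumerate(hours):
            day = (t - t0).days
            hl = t.hour + t.minute / 60.0
            if 5.5 <= hl <= 21.0:
                base = np.sin(np.pi * (hl - 5.5) / 15.5)
            else:
                base = 0.0
            solar = max(cloud[day] * 900.0 * base * (1.0 + 0.05 * rng.standard_normal()), 0.0)
            rain = float(rng.exponential(1.5)) if (rainy_day[day] and rng.random() < 0.30) else 0.0
            rows.append(
                {
                    "t": t,
                    "solar_wm2": solar,
                    "rain_mm": rain,
                    "wind_speed_ms": ws[k],
                    "wind_dir_deg": wd[k],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trip paths
# ---------------------------------------------------------------------------

def _planar_to_latlon(x, y, nest):
    lat0 = np.radians(nest[0])
    lat = nest[0] + np.degrees(np.asarray(y) / EARTH_RADIUS_M)
    lon = nest[1] + np.degrees(np.asarray(x) / (EARTH_RADIUS_M * np.cos(lat0)))
    return lat, lon


def _blend_heading(h, target, w):
    d = (target - h + 180.0) % 360.0 - 180.0
    return (h + w * d) % 360.0


def simulate_trip_path(cfg: SimConfig, tactic: str, n_fix: int, td_deg: float, rng):
    """Planar trip path; returns (behaviours, x_east_m, y_north_m) of the
    outside fixes.  The path departs along ``td_deg``, wanders according to
    the behaviour kinematics, and snaps back onto the nest at the end."""
    behaviours = markov_behaviours(tactic, n_fix, rng)
    dmax = _truncnorm(
        cfg.maxdist_mean_km, cfg.maxdist_sd_km, *cfg.maxdist_range_km, 1, rng
    )[0] * 1000.0
    far = np.array([dmax * np.sin(np.radians(td_deg)), dmax * np.cos(np.radians(td_deg))])
    dt = float(cfg.fix_interval_s)
    pos = np.zeros(2)
    h = td_deg
    xs, ys, used = [], [], []
    returning = False
    for k, mode in enumerate(behaviours):
        if not returning and (k >= n_fix // 2 or np.linalg.norm(pos - far) < 700.0):
            returning = True
        target_pt = np.zeros(2) if returning else far
        to_target = target_pt - pos
        target_bearing = np.degrees(np.arctan2(to_target[0], to_target[1])) % 360.0
        speed = sample_speed(mode, 1, cfg, rng)[0]
        turn = sample_turn(mode, 1, cfg, rng)[0] * rng.choice([-1.0, 1.0])
        w = 0.5 if returning else 0.25
        h = _blend_heading((h + np.degrees(turn)) % 360.0, target_bearing, w)
        step = speed * dt
        if returning and np.linalg.norm(pos) <= step:
            break  # home: trip ends here
        pos = pos + step * np.array([np.sin(np.radians(h)), np.cos(np.radians(h))])
        if not returning and np.linalg.norm(pos) < 100.0:
            # keep early perch wander clear of the nest buffer
            pos = 150.0 * np.array([np.sin(np.radians(td_deg)), np.cos(np.radians(td_deg))])
        xs.append(pos[0])
        ys.append(pos[1])
        used.append(mode)
    return used, np.array(xs), np.array(ys)


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

def _draw_trip_counts(cfg: SimConfig, rng) -> np.ndarray:
    r = 2.0
    p = r / (r + cfg.trips_mean)
    counts = rng.negative_binomial(r, p, size=cfg.n_individuals)
    return np.clip(counts, cfg.trips_range[0], cfg.trips_range[1])


def _habitat_for_fix(rng, at_nest: bool) -> str:
    if at_nest:
        return "artificial"
    return rng.choice(
        ["arable", "grassland", "permanent_crop", "heterogeneous_agri", "wooded"],
        p=[0.55, 0.20, 0.08, 0.10, 0.07],
    )


def simulate_study(cfg: SimConfig) -> tuple[StudyBundle, SyntheticTruth]:
    """Generate a full synthetic study; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    weather = simulate_weather(cfg, rng)

    n = cfg.n_individuals
    ids = [f"B{k:03d}" for k in range(1, n + 1)]
    sex = (rng.random(n) < cfg.female_frac).astype(int)  # 1 = female
    intercepts = rng.standard_normal(n) * cfg.sigma_id
    years = rng.choice(list(cfg.years), size=n)
    keel = rng.normal(39.0, 1.5, size=n)
    base_mass = np.where(sex == 1, 132.0, 115.0)
    mass = base_mass * (keel / 39.0) ** 2.0 * np.exp(rng.normal(0, 0.04, size=n))
    device = rng.uniform(5.9, 7.2, size=n)
    hatch_day = rng.integers(3, 18, size=n)  # June day-of-month of hatching
    brood0 = rng.integers(1, 5, size=n)
    track_start = rng.integers(1, cfg.season_days - 4, size=n)
    track_days = rng.integers(
        cfg.tracking_days_range[0], cfg.tracking_days_range[1] + 1, size=n
    )
    n_trips = _draw_trip_counts(cfg, rng)
    brood_failed = rng.random(n) < cfg.brood_fail_prob  # eggs never hatch

    # --- plan trips (schedule + direction), then draw covariates and tactics
    plans = []  # dicts, one per planned trip
    for i in range(n):
        remaining = int(n_trips[i])
        for d in range(int(track_days[i])):
            if remaining <= 0:
                break
            day = pd.Timestamp(year=int(years[i]), month=6, day=int(track_start[i])) + pd.Timedelta(days=d)
            cur = day + pd.Timedelta(hours=5)
            day_end = day + pd.Timedelta(hours=21)
            cur += pd.Timedelta(minutes=float(rng.uniform(5, 40)))
            while remaining > 0:
                dur_h = _truncnorm(
                    cfg.duration_mean_h, cfg.duration_sd_h, *cfg.duration_range_h, 1, rng
                )[0]
                n_fix = max(int(round(dur_h * 3600.0 / cfg.fix_interval_s)), 10)
                dep = cur.ceil("min")
                ret = dep + pd.Timedelta(seconds=n_fix * cfg.fix_interval_s)
                if ret + pd.Timedelta(minutes=2) >= day_end:
                    break
                plans.append(
                    {
                        "ind": i,
                        "dep_t": dep,
                        "n_fix_planned": n_fix,
                        "td_deg": float(rng.uniform(0, 360)),
                        "stage": int(dep.day >= hatch_day[i] and not brood_failed[i]),
                    }
                )
                remaining -= 1
                cur = ret + pd.Timedelta(minutes=float(rng.uniform(5, 40)))

    if not plans:
        raise ValueError("no trips could be scheduled; check configuration")

    # --- covariates per planned trip (same matching rules as the analysis)
    from .weather import circular_mean_deg, match_weather, tail_cross_components, trip_rain_presence

    wt = weather
    cov = np.zeros((len(plans), 5))  # solar, rain, twc, cwc, stage
    for j, pl in enumerate(plans):
        ret_t = pl["dep_t"] + pd.Timedelta(seconds=pl["n_fix_planned"] * cfg.fix_interval_s)
        dep_rec = match_weather(pl["dep_t"], wt)
        ret_rec = match_weather(ret_t, wt)
        ws = 0.5 * (dep_rec["wind_speed_ms"] + ret_rec["wind_speed_ms"])
        wd_toward = circular_mean_deg(
            [(dep_rec["wind_dir_deg"] + 180.0) % 360.0, (ret_rec["wind_dir_deg"] + 180.0) % 360.0]
        )
        twc, cwc = tail_cross_components(ws, pl["td_deg"], wd_toward)
        minutes = pd.date_range(pl["dep_t"], ret_t, freq="min")
        rain = trip_rain_presence(minutes, wt)
        cov[j] = [dep_rec["solar_wm2"], rain, twc, cwc, pl["stage"]]

    mean = cov.mean(axis=0)
    sd = cov.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (cov - mean) / sd
    beta_vec = np.array(
        [cfg.beta["solar"], cfg.beta["rain"], cfg.beta["twc"], cfg.beta["cwc"], cfg.beta["stage"]]
    )
    logits = cfg.beta0 + z @ beta_vec + intercepts[[pl["ind"] for pl in plans]]
    p_df = 1.0 / (1.0 + np.exp(-logits))
    tactic_draw = rng.random(len(plans)) < p_df

    # --- realize paths and the per-minute fix tables
    fix_rows = []
    truth_fix_rows = []
    truth_trip_rows = []
    trip_minutes: dict[tuple[int, int], tuple] = {}
    for j, pl in enumerate(plans):
        tactic = "DF" if tactic_draw[j] else "SF"
        behaviours, xs, ys = simulate_trip_path(
            cfg, tactic, pl["n_fix_planned"], pl["td_deg"], rng
        )
        lat, lon = _planar_to_latlon(xs, ys, cfg.nest_coords)
        uid = f"truth_{j:05d}"
        n_used = len(behaviours)
        for k in range(n_used):
            t = pl["dep_t"] + pd.Timedelta(seconds=(k + 1) * cfg.fix_interval_s)
            # label the fix with the mode of its outgoing step, matching the
            # step-metrics convention (speed_i describes fix i -> i+1)
            mode_k = behaviours[k + 1] if k + 1 < n_used else behaviours[k]
            trip_minutes[(pl["ind"], t.value // 60_000_000_000)] = (
                lat[k], lon[k], mode_k, uid,
            )
        ret_actual = pl["dep_t"] + pd.Timedelta(seconds=(len(behaviours) + 1) * cfg.fix_interval_s)
        truth_trip_rows.append(
            {
                "trip_uid": uid,
                "individual_id": ids[pl["ind"]],
                "dep_t": pl["dep_t"],
                "ret_t": ret_actual,
                "tactic": tactic,
                "stage": "nestling_rearing" if pl["stage"] else "incubation",
                "year": int(years[pl["ind"]]),
                "solar_wm2": cov[j, 0],
                "rain_present": int(cov[j, 1]),
                "twc_ms": cov[j, 2],
                "cwc_ms": cov[j, 3],
                "td_deg": pl["td_deg"],
                "p_df": p_df[j],
            }
        )

    for i in range(n):
        for d in range(int(track_days[i])):
            day = pd.Timestamp(year=int(years[i]), month=6, day=int(track_start[i])) + pd.Timedelta(days=d)
            minutes = pd.date_range(
                day + pd.Timedelta(hours=5), day + pd.Timedelta(hours=21), freq="min"
            )
            for t in minutes:
                key = (i, t.value // 60_000_000_000)
                hit = trip_minutes.get(key)
                if hit is None:
                    lat, lon, mode, uid = cfg.nest_coords[0], cfg.nest_coords[1], "perch", ""
                    habitat = "artificial"
                else:
                    lat, lon, mode, uid = hit
                    habitat = _habitat_for_fix(rng, at_nest=False)
                fix_rows.append(
                    {"individual_id": ids[i], "t": t, "lat": lat, "lon": lon, "habitat": habitat}
                )
                truth_fix_rows.append(
                    {"individual_id": ids[i], "t": t, "mode": mode, "trip_uid": uid}
                )

    fixes = pd.DataFrame(fix_rows)
    truth_fix = pd.DataFrame(truth_fix_rows)
    truth_trips = pd.DataFrame(truth_trip_rows)

    # --- nests: daily contents through the season
    nest_rows = []
    for i in range(n):
        year = int(years[i])
        for d in range(1, cfg.season_days + 1):
            date = pd.Timestamp(year=year, month=6, day=d)
            if brood_failed[i] or d < hatch_day[i]:
                eggs, nestl = int(brood0[i]) + 1, 0
            else:
                eggs, nestl = 0, int(brood0[i])
            nest_rows.append(
                {
                    "individual_id": ids[i],
                    "date": date,
                    "eggs": eggs,
                    "nestlings": nestl,
                    "lat": cfg.nest_coords[0],
                    "lon": cfg.nest_coords[1],
                }
            )
    nests = pd.DataFrame(nest_rows)

    # --- nestlings: two mass measurements, growth coupled to the intercept
    nestling_rows = []
    success = np.zeros(n, dtype=int)
    for i in range(n):
        if brood_failed[i]:
            continue
        day_n = int(rng.integers(5, 10))
        i_days = int(rng.integers(6, 10))
        alive = 0
        for jn in range(int(brood0[i])):
            bm1 = max(rng.normal(40.0, 6.0), 12.0)
            survived = rng.random() < cfg.nestling_survival
            gain = np.clip(
                cfg.dbmi_base + cfg.dbmi_per_logit * intercepts[i]
                + rng.normal(0, cfg.dbmi_noise_sd),
                0.002,
                0.05,
            )
            bm2 = bm1 * (1.0 + i_days * gain) if survived else np.nan
            alive += int(survived)
            nestling_rows.append(
                {
                    "individual_id": ids[i],
                    "brood_id": f"N{i:03d}",
                    "nestling_id": f"N{i:03d}_{jn}",
                    "day_first": day_n,
                    "i_days": i_days,
                    "bm_first": bm1,
                    "bm_second": bm2,
                }
            )
        success[i] = int(alive >= 1)
    nestlings = pd.DataFrame(nestling_rows)

    adults = pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sex,
            "body_mass_g": mass,
            "keel_mm": keel,
            "device_mass_g": device,
            "device_load": device / mass,
            "year": years,
            "breeding_success": success,
        }
    )

    truth = SyntheticTruth(
        fix_behaviour=truth_fix,
        trip_tactic=truth_trips,
        individual_intercept=pd.DataFrame(
            {"individual_id": ids, "intercept": intercepts, "sex": sex}
        ),
        true_params={
            "beta0": cfg.beta0,
            "beta": dict(cfg.beta),
            "sigma_id": cfg.sigma_id,
            "dbmi_per_logit": cfg.dbmi_per_logit,
        },
    )
    bundle = StudyBundle(
        fixes=fixes,
        weather=weather,
        nests=nests,
        nestlings=nestlings,
        adults=adults,
        config=cfg,
    )
    return bundle, truth


def simulate_binomial_dataset(
    n_individuals: int = 40,
    trips_per_individual: int = 30,
    beta: dict | None = None,
    beta0: float = 0.0,
    sigma_id: float = 0.773,
    sigma_slope: float = 0.0,
    slope_term: str = "solar",
    seed: int = 0,
) -> pd.DataFrame:
    """Model-level tactic data: standardized covariates and binomial draws.

    Bypasses the movement chain entirely; used for estimator-recovery and
    calibration experiments on the mixed models.  Covariates ``solar``,
    ``twc``, ``cwc`` are standard normal, ``rain`` and ``stage`` are
    standardized Bernoulli (rates 0.14 and 0.55).  Returns a tidy frame with
    ``individual_id``, the covariates, the latent intercept and ``df_trip``.
    """
    beta = beta if beta is not None else {"solar": 0.70, "rain": -0.12,
                                          "twc": -0.16, "cwc": 0.32, "stage": 0.53}
    rng = np.random.default_rng(seed)
    n = n_individuals * trips_per_individual
    ind = np.repeat(np.arange(n_individuals), trips_per_individual)
    b = rng.standard_normal(n_individuals) * sigma_id
    s = rng.standard_normal(n_individuals) * sigma_slope
    cols = {}
    for name, rate in (("rain", 0.14), ("stage", 0.55)):
        x = (rng.random(n) < rate).astype(float)
        cols[name] = (x - x.mean()) / max(x.std(ddof=0), 1e-12)
    for name in ("solar", "twc", "cwc"):
        x = rng.standard_normal(n)
        cols[name] = (x - x.mean()) / x.std(ddof=0)
    eta = beta0 + b[ind] + s[ind] * cols[slope_term]
    for name, val in beta.items():
        eta = eta + val * cols[name]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    out = pd.DataFrame(cols)
    out.insert(0, "individual_id", [f"I{i:03d}" for i in ind])
    out["latent_intercept"] = b[ind]
    out["df_trip"] = y
    return out


def write_study(bundle: StudyBundle, truth: SyntheticTruth, outdir) -> None:
    """Write the study tables as CSV (plus the ground truth as JSON/CSV)."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.fixes.to_csv(out / "fixes.csv", index=False)
    bundle.weather.to_csv(out / "weather.csv", index=False)
    bundle.nests.to_csv(out / "nests.csv", index=False)
    bundle.nestlings.to_csv(out / "nestlings.csv", index=False)
    bundle.adults.to_csv(out / "adults.csv", index=False)
    if bundle.acc is not None:
        bundle.acc.to_csv(out / "acc.csv", index=False)
    truth.trip_tactic.to_csv(out / "truth_trips.csv", index=False)
    truth.fix_behaviour.to_csv(out / "truth_fixes.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "true_params": truth.true_params,
                "individual_intercept": truth.individual_intercept.set_index(
                    "individual_id"
                )["intercept"].to_dict(),
            },
            fh,
            indent=2,
        )
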