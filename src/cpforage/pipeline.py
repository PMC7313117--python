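"""End-to-end analysis pipeline.

Stages: segment foraging trips -> step metrics -> behavioural-mode
clustering and smoothing -> trip profiles and SF/DF tactic assignment ->
trip ODBA -> weather covariates -> binomial GLMM of P(DF) with pruned
sex-by-weather interactions, repeatability, conditional modes and reaction
norms -> descriptor LMMs -> fitness correlates.  Every intermediate table is
derivable from the input fixes plus the configuration; when the study is
synthetic the report also scores recovery against the generator truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import embc, fitness, glmm, lmm, odba, tactics, trajectory, weather
from .simulate import AccSimulator, SimConfig, StudyBundle, SyntheticTruth

WEATHER_TERMS = ("solar", "rain", "twc", "cwc")


@dataclass
class PipelineConfig:
    buffer_m: float = 50.0
    first_fix_discard_km: float = 2.0
    tz_offset_h: float = 0.0
    acc_window_s: float = 1.0
    acc_rate_hz: int = 25
    embc_scope: str = "global"   # or "per_individual" (unstable at few trips/bird)
    embc_min_points: int = 300
    smoothing_window: int = 5
    kmeans_restarts: int = 100
    kmeans_max_iter: int = 100
    quadrature_nodes: int = 15
    wind_convention: str = "from"
    n_perm: int = 9999
    n_sim_modes: int = 10_000
    run_random_slopes: bool = True
    with_odba: bool = True
    run_select_k: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def segment_all(bundle: StudyBundle, cfg: PipelineConfig) -> list[trajectory.Trip]:
    trips = []
    nests = bundle.nests.drop_duplicates("individual_id").set_index("individual_id")
    for ind, fx in bundle.fixes.groupby("individual_id", sort=True):
        nest = (float(nests.loc[ind, "lat"]), float(nests.loc[ind, "lon"]))
        for trip in trajectory.segment_trips(
            fx,
            nest,
            buffer_m=cfg.buffer_m,
            first_fix_discard_km=cfg.first_fix_discard_km,
            tz_offset_h=cfg.tz_offset_h,
        ):
            if not trip.has_end_bound:
                continue  # device-off before return: not a complete foraging trip
            trajectory.trip_descriptors(trip, nest)
            nr = bundle.nests[bundle.nests["individual_id"] == ind]
            trip.stage = trajectory.assign_stage(trip.start_t, nr)
            trips.append(trip)
    return trips


def label_behaviours(
    trips: list[trajectory.Trip], cfg: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    """Fit the binary-clustering model and attach smoothed labels per trip.

    Returns a long table (trip_id, fix_index, speed, turn, mode,
    smoothed_mode, habitat) over the interior fixes of every trip, plus the
    fitted models keyed by scope.
    """
    per_trip_points = {}
    for trip in trips:
        m = trajectory.step_metrics(trip.fixes) if len(trip.fixes) >= 3 else None
        if m is None:
            continue
        ok = m["speed"].notna() & m["turn"].notna()
        pts = m.loc[ok, ["speed", "turn"]].to_numpy()
        per_trip_points[trip.trip_id] = (trip, m.index[ok], pts)

    by_ind: dict[str, list] = {}
    for trip_id, (trip, ix, pts) in per_trip_points.items():
        by_ind.setdefault(trip.individual_id, []).append(pts)

    all_pts = np.vstack([np.vstack(v) for v in by_ind.values()])
    global_model = embc.embc_fit(all_pts)
    models = {"__global__": global_model}
    if cfg.embc_scope == "per_individual":
        for ind, chunks in by_ind.items():
            pts = np.vstack(chunks)
            if len(pts) >= cfg.embc_min_points:
                try:
                    models[ind] = embc.embc_fit(pts)
                except ValueError:
                    pass

    rows = []
    for trip_id, (trip, ix, pts) in per_trip_points.items():
        model = models.get(trip.individual_id, global_model)
        labels, post = embc.embc_label(model, pts)
        smoothed = embc.smooth_labels(labels, post, window=cfg.smoothing_window)
        habitats = (
            trip.fixes.loc[ix, "habitat"].tolist()
            if "habitat" in trip.fixes.columns
            else [None] * len(ix)
        )
        times = trip.fixes.loc[ix, "t"].tolist()
        for k in range(len(labels)):
            rows.append(
                {
                    "trip_id": trip_id,
                    "individual_id": trip.individual_id,
                    "t": times[k],
                    "mode": labels[k],
                    "smoothed_mode": smoothed[k],
                    "habitat": habitats[k],
                }
            )
    return pd.DataFrame(rows), models


def classify_tactics(labels_df: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    trip_ids = []
    profiles = []
    for trip_id, sub in labels_df.groupby("trip_id", sort=True):
        trip_ids.append(trip_id)
        profiles.append(tactics.trip_profile(sub["smoothed_mode"]))
    profiles = np.asarray(profiles)
    assign = tactics.kmeans_tactics(
        profiles,
        k=2,
        n_restarts=cfg.kmeans_restarts,
        max_iter=cfg.kmeans_max_iter,
        seed=cfg.seed,
    )
    out = pd.DataFrame(profiles, columns=list(tactics.PROFILE_COLUMNS))
    out.insert(0, "trip_id", trip_ids)
    out["tactic"] = assign["tactic"].to_numpy()
    out["cluster_id"] = assign["cluster_id"].to_numpy()
    out.attrs["centroids"] = assign.attrs["centroids"]
    return out


def compute_trip_odba(
    trips, bundle: StudyBundle, cfg: PipelineConfig, acc_sim: AccSimulator | None
) -> pd.DataFrame:
    window = int(round(cfg.acc_window_s * cfg.acc_rate_hz))
    rows = []
    for trip in trips:
        if acc_sim is not None:
            stream = acc_sim.stream(trip.individual_id, trip.start_t, trip.end_t)
        elif bundle.acc is not None:
            a = bundle.acc
            mask = (
                (a["individual_id"] == trip.individual_id)
                & (pd.to_datetime(a["t"]) >= trip.start_t)
                & (pd.to_datetime(a["t"]) <= trip.end_t)
            )
            stream = a.loc[mask]
        else:
            continue
        if len(stream) < window:
            rows.append({"trip_id": trip.trip_id, "trip_odba_g": np.nan, "n_samples": len(stream)})
            continue
        series = odba.odba_for_stream(stream, window)
        val = odba.trip_odba(stream["t"], series, trip.start_t, trip.end_t)
        rows.append({"trip_id": trip.trip_id, "trip_odba_g": val, "n_samples": len(stream)})
    return pd.DataFrame(rows)


def compute_trip_weather(trips, bundle: StudyBundle, labels_df, cfg: PipelineConfig) -> pd.DataFrame:
    nests = bundle.nests.drop_duplicates("individual_id").set_index("individual_id")
    rows = []
    for trip in trips:
        nest = (
            float(nests.loc[trip.individual_id, "lat"]),
            float(nests.loc[trip.individual_id, "lon"]),
        )
        try:
            wc = weather.wind_components(
                trip, bundle.weather, nest, wind_convention=cfg.wind_convention
            )
        except ValueError:
            wc = None
        sub = labels_df[labels_df["trip_id"] == trip.trip_id]
        if len(sub):
            hab = trajectory.habitat_time(sub["habitat"], sub["smoothed_mode"])
            arable = hab.get("arable", np.nan)
        else:
            arable = np.nan
        rows.append(
            {
                "trip_id": trip.trip_id,
                "solar_wm2": wc.solar_at_departure if wc else np.nan,
                "rain_present": wc.rain_present if wc else np.nan,
                "twc_ms": wc.twc_ms if wc else np.nan,
                "cwc_ms": wc.cwc_ms if wc else np.nan,
                "td_deg": wc.td_deg if wc else np.nan,
                "time_arable": arable,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def build_model_table(trips, tactics_df, weather_df, bundle: StudyBundle) -> pd.DataFrame:
    base = pd.DataFrame(
        {
            "trip_id": [t.trip_id for t in trips],
            "individual_id": [t.individual_id for t in trips],
            "stage": [1 if t.stage == trajectory.STAGE_NESTLING else 0 for t in trips],
            "duration_h": [t.duration_h for t in trips],
            "length_km": [t.length_km for t in trips],
            "max_distance_km": [t.max_distance_km for t in trips],
            "tortuosity": [t.tortuosity for t in trips],
        }
    )
    adults = bundle.adults[["individual_id", "sex", "year"]]
    df = (
        base.merge(tactics_df[["trip_id", "tactic"]], on="trip_id")
        .merge(weather_df, on="trip_id")
        .merge(adults, on="individual_id", how="left")
    )
    df["df_trip"] = (df["tactic"] == "DF").astype(int)
    df = df.rename(
        columns={
            "solar_wm2": "solar",
            "rain_present": "rain",
            "twc_ms": "twc",
            "cwc_ms": "cwc",
            "time_arable": "arable",
        }
    )
    return df


def fit_final_glmm(df: pd.DataFrame, cfg: PipelineConfig):
    """Standardize predictors, drop single-trip individuals, prune weak
    sex-by-weather interactions in one step, and fit the final model."""
    data = df.dropna(subset=["solar", "rain", "twc", "cwc", "arable"]).copy()
    counts = data["individual_id"].value_counts()
    data = data[data["individual_id"].map(counts) >= 2].reset_index(drop=True)

    covars = ["solar", "rain", "twc", "cwc", "arable", "stage", "sex"]
    usable = [c for c in covars if data[c].std(ddof=0) > 0]
    data = glmm.standardize_columns(data, usable)
    year_terms = []
    for yr in sorted(data["year"].unique())[1:]:
        col = f"year_{yr}"
        data[col] = (data["year"] == yr).astype(float)
        if data[col].std(ddof=0) > 0:
            year_terms.append(col)
    base_terms = usable + year_terms
    interactions = [
        f"sex:{w}" for w in WEATHER_TERMS if "sex" in usable and w in usable
    ]
    # an interaction is only estimable when its column adds rank to the design
    # (e.g. sex x rain degenerates when rain never occurs for one sex)
    Xb, _ = glmm.build_design(data, base_terms)
    kept_int = []
    for term in interactions:
        a, b = term.split(":")
        col = (data[a] * data[b]).to_numpy(dtype=float)[:, None]
        trial = np.column_stack([Xb] + [
            (data[t.split(":")[0]] * data[t.split(":")[1]]).to_numpy(float)[:, None]
            for t in kept_int
        ] + [col])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept_int.append(term)
    interactions = kept_int
    fit, kept = glmm.backward_prune_interactions(
        data,
        "df_trip",
        base_terms,
        interactions,
        "individual_id",
        quadrature_nodes=cfg.quadrature_nodes,
        n_sim=cfg.n_sim_modes,
        seed=cfg.seed,
    )
    return fit, kept, data, base_terms


def glmm_summary(fit, kept, data, base_terms, cfg: PipelineConfig) -> dict:
    reduced = glmm.fit_glm_binomial(data["df_trip"], fit.X, names=fit.names)
    chi2, dfree, p = glmm.lrt_random_effect(fit.loglik, reduced["loglik"], df=1)
    rep = glmm.adjusted_repeatability(fit)
    rep.lrt_chi2, rep.lrt_df, rep.p = chi2, dfree, p
    r2m, r2c = glmm.r2_nakagawa(fit)
    effects = {
        t: glmm.effect_size_r(fit, t) for t in fit.names if t != "intercept"
    }
    out = {
        "coefficients": {
            name: {
                "estimate": float(fit.beta[j]),
                "se": float(fit.se[j]),
                "ci_low": float(fit.ci_low[j]),
                "ci_high": float(fit.ci_high[j]),
            }
            for j, name in enumerate(fit.names)
        },
        "retained_interactions": kept,
        "sigma2_id": fit.sigma2_id,
        "loglik": fit.loglik,
        "phi": fit.phi,
        "r_adj": rep.r_adj,
        "r_adj_lrt": {"chi2": chi2, "df": dfree, "p": p},
        "r2_marginal": r2m,
        "r2_conditional": r2c,
        "effect_size_r": effects,
        "n_obs": fit.n_obs,
        "n_individuals": fit.n_groups,
    }
    if cfg.run_random_slopes:
        slopes = {}
        for term in WEATHER_TERMS:
            if term not in base_terms:
                continue
            try:
                rs = glmm.random_slope_model(
                    data, "df_trip", base_terms, term, "individual_id"
                )
                slopes[term] = {
                    "chi2": rs.lrt_chi2,
                    "df": rs.lrt_df,
                    "p": rs.p,
                    "sigma_slope": rs.sigma_slope,
                }
            except Exception as exc:  # non-convergence: report, do not abort
                slopes[term] = {"error": str(exc)}
        out["random_slopes"] = slopes
    return out


def descriptor_lmms(df: pd.DataFrame, odba_df: pd.DataFrame | None) -> dict:
    out = {}
    data = df.copy()
    data["tactic01"] = data["df_trip"].astype(float)
    responses = ["duration_h", "length_km", "max_distance_km", "tortuosity"]
    if odba_df is not None and len(odba_df):
        data = data.merge(odba_df[["trip_id", "trip_odba_g"]], on="trip_id", how="left")
        responses.append("trip_odba_g")
    for resp in responses:
        sub = data.dropna(subset=[resp])
        if sub["individual_id"].nunique() < 2 or len(sub) < 10:
            continue
        X = np.column_stack([np.ones(len(sub)), sub["tactic01"].to_numpy()])
        fit = lmm.fit_lmm(sub[resp], X, sub["individual_id"], names=["intercept", "tactic_df"])
        j = fit.names.index("tactic_df")
        out[resp] = {
            "estimate": float(fit.beta[j]),
            "se": float(fit.se[j]),
            "f": float(fit.f_stat[j]),
            "df_denom": float(fit.df_denom[j]),
            "p": float(fit.p_values[j]),
            "r2_marginal": fit.r2_marginal,
            "r2_conditional": fit.r2_conditional,
            "mean_sf": float(sub.loc[sub["tactic01"] == 0, resp].mean()),
            "mean_df": float(sub.loc[sub["tactic01"] == 1, resp].mean()),
        }
    return out


def fitness_analysis(
    fit, bundle: StudyBundle, trips, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    adults = bundle.adults.copy()
    modes = glmm.conditional_modes(fit).rename(
        columns={"mode": "tendency", "sd": "tendency_sd"}
    )
    adults = adults.merge(modes, on="individual_id", how="inner")

    adults["smi"] = fitness.scaled_mass_index(adults["body_mass_g"], adults["keel_mm"])
    adults["residual_smi"] = fitness.residualize(adults["smi"], adults[["sex"]])

    # brood DBMI and survivor brood size
    dbmi_rows = []
    for ind, sub in bundle.nestlings.groupby("individual_id"):
        try:
            val = fitness.dbmi(sub)
        except ValueError:
            continue
        dbmi_rows.append(
            {
                "individual_id": ind,
                "dbmi": val,
                "brood_size": int(sub["bm_second"].notna().sum()),
            }
        )
    dbmi_df = pd.DataFrame(dbmi_rows, columns=["individual_id", "dbmi", "brood_size"])
    adults = adults.merge(dbmi_df, on="individual_id", how="left")
    ok = adults["dbmi"].notna()
    if ok.sum() >= 4 and adults.loc[ok, "year"].nunique() >= 1:
        preds = pd.DataFrame(
            {
                "brood_size": adults.loc[ok, "brood_size"],
            }
        )
        for yr in sorted(adults.loc[ok, "year"].unique())[1:]:
            preds[f"y{yr}"] = (adults.loc[ok, "year"] == yr).astype(float)
        preds = preds.loc[:, preds.std(ddof=0) > 0]
        adults.loc[ok, "residual_dbmi"] = fitness.residualize(adults.loc[ok, "dbmi"], preds)

    # feeding frequency: nestling-rearing birds, trips per device-on hour
    trips_by_ind = pd.Series([t.individual_id for t in trips]).value_counts()
    stage_by_ind = {
        t.individual_id: t.stage for t in trips if t.stage == trajectory.STAGE_NESTLING
    }
    hours = bundle.fixes.groupby("individual_id").size() / 60.0
    ff = {}
    for ind in adults["individual_id"]:
        if ind in stage_by_ind and ind in hours.index:
            ff[ind] = fitness.feeding_frequency(int(trips_by_ind.get(ind, 0)), float(hours[ind]))
    adults["feeding_freq"] = adults["individual_id"].map(ff)
    ok = adults["feeding_freq"].notna() & adults["brood_size"].notna()
    if ok.sum() >= 5:
        preds = pd.DataFrame(
            {"sex": adults.loc[ok, "sex"], "brood_size": adults.loc[ok, "brood_size"]}
        )
        for yr in sorted(adults.loc[ok, "year"].unique())[1:]:
            preds[f"y{yr}"] = (adults.loc[ok, "year"] == yr).astype(float)
        preds = preds.loc[:, preds.std(ddof=0) > 0]
        adults.loc[ok, "residual_feeding_freq"] = fitness.residualize(
            adults.loc[ok, "feeding_freq"], preds
        )

    corr = fitness.correlate_tendency(adults, n_perm=cfg.n_perm, seed=cfg.seed)
    return adults, corr


# ---------------------------------------------------------------------------
# Truth scoring
# ---------------------------------------------------------------------------

def score_against_truth(
    truth: SyntheticTruth, labels_df, tactics_df, trips, summary
) -> dict:
    tt = truth.trip_tactic
    # trip matching by individual + temporal containment of the trip midpoint
    tactic_map = tactics_df.set_index("trip_id")["tactic"]
    matched = 0
    correct = 0
    for trip in trips:
        if trip.trip_id not in tactic_map.index:
            continue
        mid = trip.start_t + (trip.end_t - trip.start_t) / 2
        cand = tt[
            (tt["individual_id"] == trip.individual_id)
            & (tt["dep_t"] <= mid)
            & (tt["ret_t"] >= mid)
        ]
        if len(cand) == 1:
            matched += 1
            correct += int(cand["tactic"].iloc[0] == tactic_map[trip.trip_id])
    tactic_acc = correct / matched if matched else np.nan

    fb = truth.fix_behaviour.set_index(["individual_id", "t"])["mode"]
    lab = labels_df.set_index(["individual_id", "t"])
    common = lab.index.intersection(fb.index)
    behav_acc = float(
        (lab.loc[common, "smoothed_mode"] == fb.loc[common]).mean()
    ) if len(common) else np.nan

    beta_true = truth.true_params["beta"]
    coefs = summary["coefficients"]
    beta_cmp = {
        k: {
            "true": beta_true[k],
            "estimate": coefs[k]["estimate"] if k in coefs else np.nan,
        }
        for k in beta_true
    }
    return {
        "behaviour_accuracy": behav_acc,
        "tactic_accuracy": tactic_acc,
        "n_trips_matched": matched,
        "beta": beta_cmp,
        "sigma_id_true": truth.true_params["sigma_id"],
    }


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------

def run_pipeline(
    bundle: StudyBundle,
    cfg: PipelineConfig | None = None,
    truth: SyntheticTruth | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage on a study bundle and return the report dictionary."""
    cfg = cfg or PipelineConfig()
    trips = segment_all(bundle, cfg)
    if not trips:
        raise ValueError("no foraging trips found")
    labels_df, models = label_behaviours(trips, cfg)
    tactics_df = classify_tactics(labels_df, cfg)
    profiles = tactics_df[list(tactics.PROFILE_COLUMNS)].to_numpy()
    if cfg.run_select_k and len(profiles) >= 10:
        k_star, votes = tactics.select_k(profiles, seed=cfg.seed)
    else:
        k_star, votes = 2, {}

    acc_sim = AccSimulator(truth, bundle.config) if (
        cfg.with_odba and truth is not None and bundle.acc is None
    ) else None
    odba_df = (
        compute_trip_odba(trips, bundle, cfg, acc_sim)
        if cfg.with_odba and (acc_sim is not None or bundle.acc is not None)
        else pd.DataFrame()
    )
    weather_df = compute_trip_weather(trips, bundle, labels_df, cfg)
    model_df = build_model_table(trips, tactics_df, weather_df, bundle)

    fit, kept, data, base_terms = fit_final_glmm(model_df, cfg)
    summary = glmm_summary(fit, kept, data, base_terms, cfg)
    lmms = descriptor_lmms(model_df, odba_df if len(odba_df) else None)
    adults, corr = fitness_analysis(fit, bundle, trips, cfg)

    trips_table = pd.DataFrame(
        {
            "trip_id": [t.trip_id for t in trips],
            "individual_id": [t.individual_id for t in trips],
            "stage": [t.stage for t in trips],
            "duration_h": [t.duration_h for t in trips],
            "length_km": [t.length_km for t in trips],
            "maxdist_km": [t.max_distance_km for t in trips],
            "tortuosity": [t.tortuosity for t in trips],
            "n_fixes": [t.n_fixes for t in trips],
        }
    )
    report = {
        "n_individuals": int(bundle.adults["individual_id"].nunique()),
        "n_trips": len(trips),
        "n_trips_modelled": summary["n_obs"],
        "tactic_counts": tactics_df["tactic"].value_counts().to_dict(),
        "prop_df": float((tactics_df["tactic"] == "DF").mean()),
        "consensus_k": k_star,
        "consensus_votes": votes,
        "glmm": summary,
        "descriptor_lmms": lmms,
        "fitness_correlations": corr.to_dict(orient="records"),
    }
    if truth is not None:
        report["truth_recovery"] = score_against_truth(
            truth, labels_df, tactics_df, trips, summary
        )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        trips_table.to_csv(out / "trips.csv", index=False)
        labels_df.to_csv(out / "labels.csv", index=False)
        tactics_df.to_csv(out / "tactics.csv", index=False)
        if len(odba_df):
            odba_df.to_csv(out / "odba.csv", index=False)
        weather_df.to_csv(out / "trip_weather.csv", index=False)
        corr.to_csv(out / "fitness_correlations.csv", index=False)
        with open(out / "model_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def run_synthetic(
    sim_config: SimConfig | None = None,
    cfg: PipelineConfig | None = None,
    outdir=None,
) -> tuple[dict, StudyBundle, SyntheticTruth]:
    """Simulate a study and run the full pipeline on it."""
    from .simulate import simulate_study

    sim_config = sim_config or SimConfig()
    bundle, truth = simulate_study(sim_config)
    cfg = cfg or PipelineConfig(seed=sim_config.seed)
    report = run_pipeline(bundle, cfg=cfg, truth=truth, outdir=outdir)
    return report, bundle, truth
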