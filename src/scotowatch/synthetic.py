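"""Synthetic studies: drives, collision-course pedestrians, gaze, horn responses.

The generator emulates the study design end to end so that every pipeline
stage and statistic can be exercised without any recorded data: 104
pedestrian appearances per participant, evenly split over eccentricities
-14/-4/+4/+14 deg and over city (30 mph, appearing ~220 ft away) and highway
(60 mph, ~440 ft) drives, each pedestrian on a constant-bearing collision
course reaching the lane edge in ~5 s.

Gaze is a four-state process: forward fixation with isotropic jitter,
Poisson-scheduled downward dashboard glances, occasional early attempts to
foveate a peripherally-sensed hazard (which, with an eccentric PRL, drags
the hazard into the scotoma), and a hazard-directed pursuit in the final
fraction of a second before the horn press.  Tracker imperfection is
modelled as i.i.d. per-sample dropout plus occasional multi-second gaps.

Responses follow a log-linear model: log RT = subject intercept
+ eccentricity-class effect + slope x occlusion time + Gaussian noise, made
self-consistent with the occlusion actually experienced: the press occurs at
the first instant t where exp(eta + slope x occluded-time-so-far(t)) <= t.
Occlusion experienced by the driver uses the dropout-free gaze; dropouts
only degrade what the tracker records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .occlusion import occlusion_fractions
from .scenario import ScenarioConfig, stopping_distance
from .visual_field import ScotomaPolygon, VisualField

__all__ = [
    "GazeBehaviorParams",
    "ResponseModelParams",
    "StudyData",
    "superior_scotoma_field",
    "default_response_params",
    "generate_study",
    "recover_parameters",
]


@dataclass
class GazeBehaviorParams:
    """Parameters of the synthetic gaze process.  ``seed`` is mandatory."""

    seed: int
    fixation_jitter_sd: float = 0.5  # degrees
    saccade_latency_mean: float = 0.25  # s, pursuit onset before the press
    saccade_latency_sd: float = 0.05
    dashboard_glance_rate: float = 3.0  # per minute
    glance_duration: float = 0.7  # s
    glance_duration_sd: float = 0.15
    glance_elevation: float = -12.0  # degrees (down to the dashboard)
    dropout_prob: float = 0.02  # i.i.d. per-sample tracker loss
    long_gap_rate: float = 8.0  # per minute
    long_gap_mean: float = 3.0  # s, exponential gap length
    # attempted "foveal" fixation on a peripherally-sensed hazard, which drags
    # the hazard into the scotoma (eccentric-viewing disruption); per event
    foveal_disruption_prob: float = 0.4
    foveal_start_min: float = 0.2  # s after appearance
    foveal_start_max: float = 0.5
    foveal_duration_median: float = 0.5  # s (lognormal)
    foveal_duration_sigma: float = 0.5  # log-sd

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("GazeBehaviorParams.seed is required for reproducibility")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        for name in ("fixation_jitter_sd", "dashboard_glance_rate", "glance_duration",
                     "long_gap_rate", "long_gap_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ResponseModelParams:
    """Log-linear reaction-time model.  ``seed`` is mandatory."""

    seed: int
    subject_intercepts: dict = dc_field(default_factory=dict)  # pid -> log-seconds
    ecc_effect: float = -0.12  # log-s, large (14 deg) vs small (4 deg)
    occ_slope: float = 0.3  # log-s per second of occlusion
    noise_sd: float = 0.35  # log-s
    detect_prob: float = 0.98

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("ResponseModelParams.seed is required for reproducibility")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 < self.detect_prob <= 1.0:
            raise ValueError("detect_prob must be in (0, 1]")


@dataclass
class StudyData:
    """Everything one synthetic study produced, keyed (participant, drive_type)."""

    drives: dict
    gaze: dict
    fields: dict
    configs: dict
    horn_events: dict
    truth: pd.DataFrame


def superior_scotoma_field(
    participant_id: str,
    center_elevation: float = 10.0,
    half_width: float = 8.0,
    half_height: float = 5.0,
    n_vertices: int = 16,
) -> VisualField:
    """An elliptical scotoma above the PRL (default: azimuth +-8, elevation +5..+15).

    The inferior edge sits a few degrees above the PRL so that steady forward
    gaze leaves the road scene visible; downward dashboard glances lift the
    pedestrian's image into the scotoma - the mechanism under study.
    """
    ang = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    verts = np.column_stack(
        [half_width * np.cos(ang), center_elevation + half_height * np.sin(ang)]
    )
    return VisualField(
        polygons=[ScotomaPolygon(verts)],
        participant_id=participant_id,
        prl_note="synthetic superior scotoma",
    )


def default_response_params(cfl_ids, nv_ids, seed: int) -> ResponseModelParams:
    """Subject intercepts drawn so group medians land near 2.3 s (CFL) / 1.1 s (NV)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 911]))
    intercepts = {}
    for pid in sorted(cfl_ids):
        intercepts[pid] = float(rng.normal(0.78, 0.15))
    for pid in sorted(nv_ids):
        intercepts[pid] = float(rng.normal(0.08, 0.10))
    return ResponseModelParams(seed=int(seed), subject_intercepts=intercepts)


def _event_schedule(cfg: ScenarioConfig, n_events: int, rng) -> list:
    """Eccentricity per event slot: balanced then shuffled."""
    eccs = np.asarray(cfg.eccentricities, dtype=float)
    if n_events % eccs.size:
        raise ValueError("events per drive must divide evenly among eccentricities")
    sched = np.repeat(eccs, n_events // eccs.size)
    return list(rng.permutation(sched))


def _interval_mask(t: np.ndarray, starts, durations) -> np.ndarray:
    m = np.zeros(t.shape, dtype=bool)
    for s, d in zip(starts, durations):
        m |= (t >= s) & (t < s + d)
    return m


def _poisson_starts(rate_per_min: float, total: float, rng) -> np.ndarray:
    if rate_per_min <= 0:
        return np.empty(0)
    rate = rate_per_min / 60.0
    n_max = int(total * rate * 4 + 20)
    gaps = rng.exponential(1.0 / rate, size=n_max)
    starts = np.cumsum(gaps)
    return starts[starts < total]


def _generate_drive(
    pid: str,
    field: VisualField,
    cfg: ScenarioConfig,
    gaze_p: GazeBehaviorParams,
    resp: ResponseModelParams,
    n_events: int,
    rng,
    event_spacing: float = 8.0,
    lead_in: float = 2.0,
):
    """One participant x drive-type log pair plus its ground-truth rows."""
    v = cfg.car_speed
    dt30 = cfg.dt
    window = cfg.appearance_travel_time
    total = lead_in + n_events * event_spacing
    n30 = int(round(total / dt30)) + 1
    t30 = np.arange(n30) * dt30
    n60 = 2 * (n30 - 1) + 1
    t60 = np.arange(n60) * (dt30 / 2.0)

    # --- latent gaze: forward fixation + dashboard glances -----------------
    az60 = rng.normal(0.0, gaze_p.fixation_jitter_sd, n60)
    el60 = rng.normal(0.0, gaze_p.fixation_jitter_sd, n60)
    g_starts = _poisson_starts(gaze_p.dashboard_glance_rate, total, rng)
    g_durs = np.maximum(0.2, rng.normal(gaze_p.glance_duration, gaze_p.glance_duration_sd,
                                        g_starts.size))
    glance_mask = _interval_mask(t60, g_starts, g_durs)
    el60 = np.where(glance_mask, gaze_p.glance_elevation + 0.3 * rng.standard_normal(n60), el60)

    # --- events -------------------------------------------------------------
    theta_all = _event_schedule(cfg, n_events, rng)
    d_appear = v * window

    def _event_geometry(i, ecc, t):
        """Pedestrian azimuth / elevation extent at times ``t`` for event i."""
        theta = math.radians(ecc)
        side = 1.0 if ecc > 0 else -1.0
        t_appear = lead_in + i * event_spacing
        station = v * t_appear + d_appear * math.cos(theta)
        vlat = v * abs(math.tan(theta))
        lat0 = d_appear * abs(math.sin(theta))
        lat = np.maximum(lat0 - vlat * (t - t_appear), cfg.lane_half_width)
        rng_m = np.maximum(station - v * t, 1.0)
        az = np.degrees(np.arctan2(side * lat, rng_m))
        bot = np.degrees(np.arctan2(-cfg.eye_height, rng_m))
        top = np.degrees(np.arctan2(cfg.pedestrian_height - cfg.eye_height, rng_m))
        return az, bot, top

    # eccentric-viewing disruption: early in some events the driver attempts
    # to foveate the hazard, which centres it in the scotoma for a moment
    if field.has_scotoma:
        sc_cx, sc_cy = field.polygons[0].vertices.mean(axis=0)
        for i, ecc in enumerate(theta_all):
            if rng.random() >= gaze_p.foveal_disruption_prob:
                continue
            t_appear = lead_in + i * event_spacing
            t_fix = t_appear + rng.uniform(gaze_p.foveal_start_min, gaze_p.foveal_start_max)
            dur = min(2.5, rng.lognormal(math.log(gaze_p.foveal_duration_median),
                                         gaze_p.foveal_duration_sigma))
            m = (t60 >= t_fix) & (t60 < t_fix + dur)
            if not m.any():
                continue
            az_h, bot_h, top_h = _event_geometry(i, ecc, t60[m])
            az60[m] = az_h - sc_cx + 0.2 * rng.standard_normal(int(m.sum()))
            el60[m] = 0.5 * (bot_h + top_h) - sc_cy + 0.2 * rng.standard_normal(int(m.sum()))

    # tracker validity: i.i.d. dropout plus multi-second gaps
    valid = rng.random(n60) >= gaze_p.dropout_prob
    gap_starts = _poisson_starts(gaze_p.long_gap_rate, total, rng)
    gap_durs = rng.exponential(gaze_p.long_gap_mean, gap_starts.size) if gap_starts.size else []
    valid &= ~_interval_mask(t60, gap_starts, gap_durs)

    az_final = az60.copy()
    el_final = el60.copy()
    ped_id = np.full(n30, "", dtype=object)
    ped_x = np.full(n30, np.nan)
    ped_y = np.full(n30, np.nan)
    ped_vis = np.zeros(n30, dtype=int)
    horn = np.zeros(n30, dtype=int)
    truth_rows = []

    for i, ecc in enumerate(theta_all):
        t_appear = lead_in + i * event_spacing
        k0 = int(round(t_appear / dt30))
        theta = math.radians(ecc)
        side = 1.0 if ecc > 0 else -1.0
        station = v * t_appear + d_appear * math.cos(theta)
        vlat = v * abs(math.tan(theta))
        lat0 = d_appear * abs(math.sin(theta))
        # window ends at despawn or just before the car passes the station
        t_pass = station / v
        n_ev = int(min(window, t_pass - t_appear - dt30) / dt30) + 1
        ks = k0 + np.arange(n_ev)
        te = t30[ks]
        lat = np.maximum(lat0 - vlat * (te - t_appear), cfg.lane_half_width)
        rng_m = station - v * te
        az_t = np.degrees(np.arctan2(side * lat, rng_m))
        bot_t = np.degrees(np.arctan2(-cfg.eye_height, rng_m))
        top_t = np.degrees(np.arctan2(cfg.pedestrian_height - cfg.eye_height, rng_m))

        eid = f"{pid}-{cfg.drive_type}-{i:03d}"
        ped_id[ks] = eid
        ped_x[ks] = station
        ped_y[ks] = side * lat
        ped_vis[ks] = 1

        # occlusion experienced (dropout-free gaze), on the 30 Hz grid
        g_idx = 2 * ks
        rel_az = az_t - az60[g_idx]
        rel_bot = bot_t - el60[g_idx]
        rel_top = top_t - el60[g_idx]
        frac = occlusion_fractions(field, rel_az, rel_bot, rel_top)
        occ_cum = np.cumsum(frac > 0.0) * dt30  # occluded time up to and incl. sample k

        # self-consistent press: first sample where predicted RT has elapsed
        eta = (
            resp.subject_intercepts.get(pid, 0.0)
            + resp.ecc_effect * (abs(ecc) > 9.0)
            + rng.normal(0.0, resp.noise_sd)
        )
        occ_before = np.r_[0.0, occ_cum[:-1]]
        rt_grid = np.arange(n_ev) * dt30
        pred = np.exp(eta + resp.occ_slope * occ_before)
        hit = np.nonzero((rt_grid >= pred) & (rt_grid > 0))[0]
        detected = bool(hit.size) and (rng.random() < resp.detect_prob)
        rt = float(rt_grid[hit[0]]) if detected else math.nan
        t_press = t_appear + rt if detected else math.nan

        occ_latent = float(occ_before[hit[0]]) if detected else float(occ_cum[-1])
        if detected:
            horn[k0 + hit[0]] = 1
            # hazard-directed pursuit just before the press
            latency = max(0.1, rng.normal(gaze_p.saccade_latency_mean, gaze_p.saccade_latency_sd))
            m = (t60 >= t_press - latency) & (t60 <= t_press)
            if m.any():
                rng_p = station - v * t60[m]
                rng_p = np.maximum(rng_p, 1.0)
                lat_p = np.maximum(lat0 - vlat * (t60[m] - t_appear), cfg.lane_half_width)
                az_final[m] = np.degrees(np.arctan2(side * lat_p, rng_p))
                el_final[m] = 0.5 * (
                    np.degrees(np.arctan2(-cfg.eye_height, rng_p))
                    + np.degrees(np.arctan2(cfg.pedestrian_height - cfg.eye_height, rng_p))
                )
            timely = (station - v * t_press) >= stopping_distance(v, cfg.deceleration)
        else:
            timely = math.nan

        truth_rows.append(
            {
                "participant_id": pid,
                "drive_type": cfg.drive_type,
                "event_id": eid,
                "eccentricity": float(ecc),
                "ecc_class": "large" if abs(ecc) > 9.0 else "small",
                "t_appear": t_appear,
                "detected": detected,
                "reaction_time": rt,
                "eta": eta,
                "occlusion_time": occ_latent,
                "glance_overlap": bool(glance_mask[g_idx].any()),
                "timely": timely,
                "lateral_speed": vlat,
                "station": station,
            }
        )

    # recompute ground-truth occlusion from the final (pursuit-adjusted) gaze
    for row in truth_rows:
        k0 = int(round(row["t_appear"] / dt30))
        end = row["t_appear"] + (row["reaction_time"] if row["detected"] else window)
        ks = k0 + np.arange(int(round((min(end, t30[-1]) - row["t_appear"]) / dt30)) + 1)
        ks = ks[ped_id[ks] == row["event_id"]]
        if ks.size == 0:
            continue
        te = t30[ks]
        rng_m = row["station"] - v * te
        side = 1.0 if row["eccentricity"] > 0 else -1.0
        lat = np.abs(ped_y[ks])
        az_t = np.degrees(np.arctan2(side * lat, rng_m))
        bot_t = np.degrees(np.arctan2(-cfg.eye_height, rng_m))
        top_t = np.degrees(np.arctan2(cfg.pedestrian_height - cfg.eye_height, rng_m))
        g_idx = 2 * ks
        frac = occlusion_fractions(
            field, az_t - az_final[g_idx], bot_t - el_final[g_idx], top_t - el_final[g_idx]
        )
        row["occlusion_time"] = float((frac > 0.0).sum()) * dt30

    drive = pd.DataFrame(
        {
            "t": t30,
            "car_along_track_m": v * t30,
            "car_speed_mps": np.full(n30, v),
            "car_heading_deg": np.zeros(n30),
            "ped_id": ped_id,
            "ped_x_m": ped_x,
            "ped_y_m": ped_y,
            "ped_visible": ped_vis,
            "horn": horn,
        }
    )
    gaze = pd.DataFrame(
        {
            "t": t60,
            "gaze_azimuth_deg": np.where(valid, az_final, np.nan),
            "gaze_elevation_deg": np.where(valid, el_final, np.nan),
            "valid": valid.astype(int),
        }
    )
    return drive, gaze, truth_rows


def generate_study(
    cfg: ScenarioConfig,
    gaze_params: GazeBehaviorParams,
    resp_params: ResponseModelParams,
    fields: dict,
    seed: int,
) -> StudyData:
    """Generate a complete deterministic study for the given participants.

    ``fields`` maps participant id to :class:`VisualField` (empty field =
    normal-vision control).  Each participant receives ``cfg.n_appearances``
    pedestrian events split evenly between a city and a highway drive and
    evenly over eccentricities.  Deterministic given the seeds.
    """
    if seed is None:
        raise ValueError("generate_study requires a seed")
    if cfg.n_appearances % (2 * len(cfg.eccentricities)) != 0:
        raise ValueError("n_appearances must divide evenly over drive types and eccentricities")
    n_per_drive = cfg.n_appearances // 2
    ss = np.random.SeedSequence([int(seed), int(gaze_params.seed), int(resp_params.seed)])
    pids = sorted(fields)
    children = ss.spawn(2 * len(pids))
    drives, gaze_logs, configs, horn_events = {}, {}, {}, {}
    truth_rows = []
    for i, pid in enumerate(pids):
        for j, drive_type in enumerate(("city", "highway")):
            dcfg = cfg.with_drive_type(drive_type)
            rng = np.random.default_rng(children[2 * i + j])
            drive, gaze, rows = _generate_drive(
                pid, fields[pid], dcfg, gaze_params, resp_params, n_per_drive, rng
            )
            key = (pid, drive_type)
            drives[key] = drive
            gaze_logs[key] = gaze
            configs[key] = dcfg
            horn_events[key] = drive["t"].to_numpy()[drive["horn"].to_numpy() == 1]
            truth_rows.extend(rows)
    truth = pd.DataFrame(truth_rows)
    truth["group"] = truth["participant_id"].map(
        lambda p: "CFL" if fields[p].has_scotoma else "NV"
    )
    return StudyData(drives, gaze_logs, fields, configs, horn_events, truth)


def default_study(
    n_cfl: int = 2,
    n_nv: int = 2,
    seed: int = 0,
    cfg: ScenarioConfig | None = None,
    gaze_overrides: dict | None = None,
    resp_overrides: dict | None = None,
) -> StudyData:
    """Convenience wrapper: CFL participants with superior scotomas vs controls."""
    cfg = cfg or ScenarioConfig()
    cfl_ids = [f"CFL{i+1}" for i in range(n_cfl)]
    nv_ids = [f"NV{i+1}" for i in range(n_nv)]
    fields = {pid: superior_scotoma_field(pid) for pid in cfl_ids}
    fields.update({pid: VisualField(participant_id=pid) for pid in nv_ids})
    gp = GazeBehaviorParams(seed=seed, **(gaze_overrides or {}))
    rp = default_response_params(cfl_ids, nv_ids, seed)
    for k, val in (resp_overrides or {}).items():
        setattr(rp, k, val)
    return generate_study(cfg, gp, rp, fields, seed=seed)


def recover_parameters(study: StudyData) -> dict:
    """Run the full pipeline on a synthetic study and estimate the response model.

    Scores occlusion from the recorded (dropout-afflicted) logs, builds the
    event table, and fits log RT ~ occlusion time + eccentricity class +
    subject over gaze-usable detected scotoma-group events.  Returns slope
    estimate with 95% CI, eccentricity and subject effects, residual SD, and
    the occlusion-time/RT Pearson correlation.
    """
    from .occlusion import build_event_table
    from .stats import ols_logrt, pearson_r

    table = build_event_table(study.drives, study.gaze, study.fields, study.configs)
    cfl = {p for p, f in study.fields.items() if f.has_scotoma}
    sub = table.loc[
        table["participant_id"].isin(cfl)
        & table["detected"].astype(bool)
        & table["gaze_usable"].astype(bool)
    ]
    occ = sub["occlusion_time"].to_numpy()
    out = {"n_events": int(len(sub)), "event_table": table}
    if len(sub) < 10 or np.var(occ) == 0:
        out["identifiable"] = False
        return out
    extra = pd.DataFrame({"large_ecc": (sub["ecc_class"] == "large").astype(float).to_numpy()})
    fit = ols_logrt(sub["log_rt"], occ, sub["participant_id"], extra=extra)
    out.update(
        identifiable=True,
        occ_slope=fit["occ_slope"],
        occ_slope_ci=fit["occ_slope_ci"],
        ecc_effect=fit["params"].get("large_ecc", 0.0),
        subject_effects=fit["subject_effects"],
        noise_sd=fit["resid_sd"],
        adj_r2=fit["adj_r2"],
        occlusion_rt_r=pearson_r(occ, sub["reaction_time"].to_numpy()),
    )
    return out
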