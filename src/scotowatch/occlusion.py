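"""Gaze-contingent occlusion scoring and per-appearance outcome assembly.

For each simulator sample the pedestrian is a vertical angular segment; the
momentary gaze direction places the visual field (PRL at the gaze point)
over the scene, and the fraction of the segment inside the scotoma union is
the occlusion fraction.  Samples with any part of the pedestrian inside a
scotoma are coded occluded; occlusion time is the occluded-sample count over
the simulator rate, accumulated from the appearance to the horn press (or to
disappearance when undetected).

Gaze (60 Hz) is merged onto the simulator stream (30 Hz) by nearest-neighbor
matching within half a gaze frame, which reduces to "every other gaze
sample" for phase-locked clocks.  Gaze-missing samples count as not occluded
(a conservative under-estimate of occlusion).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import (
    AngularSegment,
    CarState,
    PedestrianEvent,
    ScenarioConfig,
    is_timely,
    project_to_angles_arrays,
)
from .visual_field import VisualField

__all__ = [
    "GazeSample",
    "OcclusionTrace",
    "align_streams",
    "retinal_position",
    "occlusion_fraction",
    "occlusion_fractions",
    "occlusion_time",
    "build_event_table",
    "gaze_availability_check",
]

log = logging.getLogger(__name__)

GAZE_MATCH_TOL = 1.0 / 60.0 + 1e-9  # s; half a tracker frame each side

SMALL_LARGE_SPLIT = 9.0  # degrees; |ecc| <= split -> "small"


@dataclass
class GazeSample:
    """One tracker sample: combined head+eye gaze relative to car heading."""

    t: float
    azimuth: float = math.nan
    elevation: float = math.nan
    valid: bool = True


@dataclass
class OcclusionTrace:
    """Per-sample occlusion record for one hazard event (simulator rate)."""

    event_id: str
    samples: pd.DataFrame  # columns: t, fraction, occluded, gaze_valid
    sim_rate: float = 30.0


def align_streams(gaze: pd.DataFrame, drive: pd.DataFrame) -> pd.DataFrame:
    """Attach the nearest valid gaze sample (within +-1/60 s) to each sim sample.

    ``gaze`` columns: t, gaze_azimuth_deg, gaze_elevation_deg, valid;
    ``drive`` needs a t column.  Unmatched or invalid gaze leaves the sample
    flagged ``gaze_valid = False`` with NaN angles.
    """
    if gaze["t"].iloc[0] > drive["t"].iloc[-1] or gaze["t"].iloc[-1] < drive["t"].iloc[0]:
        raise ValueError("gaze and drive logs cover disjoint time ranges")
    g = gaze.loc[gaze["valid"].astype(bool), ["t", "gaze_azimuth_deg", "gaze_elevation_deg"]]
    g = g.sort_values("t")
    merged = pd.merge_asof(
        drive.sort_values("t"),
        g,
        on="t",
        direction="nearest",
        tolerance=GAZE_MATCH_TOL,
    )
    merged["gaze_valid"] = merged["gaze_azimuth_deg"].notna()
    return merged


def retinal_position(target: AngularSegment, gaze) -> AngularSegment:
    """Map a scene segment into visual-field coordinates for the current gaze.

    The PRL (field origin) coincides with the gaze direction, so the target's
    field position is the target angle minus the gaze angle: a downward
    dashboard glance raises the target's field elevation into any superior
    scotoma.
    """
    if isinstance(gaze, GazeSample):
        if not gaze.valid:
            raise ValueError("gaze sample invalid; retinal position undefined")
        gx, gy = gaze.azimuth, gaze.elevation
    else:
        gx, gy = float(gaze[0]), float(gaze[1])
    return AngularSegment(
        azimuth=target.azimuth - gx,
        elevation_bottom=target.elevation_bottom - gy,
        elevation_top=target.elevation_top - gy,
    )


def occlusion_fractions(field: VisualField, azimuth, bottom, top) -> np.ndarray:
    """Vectorized occluded fraction of vertical segments (visual-field coords).

    For each sample, the union over scotoma polygons of the vertical chord at
    the segment azimuth is intersected with the segment's elevation interval;
    the fraction is the covered length over the segment height.  NaN inputs
    (missing gaze) yield 0.
    """
    az = np.atleast_1d(np.asarray(azimuth, dtype=float))
    bot = np.broadcast_to(np.asarray(bottom, dtype=float), az.shape).astype(float)
    topv = np.broadcast_to(np.asarray(top, dtype=float), az.shape).astype(float)
    out = np.zeros(az.shape, dtype=float)
    if not field.polygons:
        return out
    height = topv - bot
    usable = np.isfinite(az) & np.isfinite(bot) & np.isfinite(topv) & (height > 0)
    if not usable.any():
        return out
    los, his = [], []
    for poly in field.polygons:
        lo, hi = poly.chords(np.where(usable, az, 0.0))
        lo = np.maximum(lo, bot)
        hi = np.minimum(hi, topv)
        good = usable & np.isfinite(lo) & (hi > lo)
        los.append(np.where(good, lo, np.nan))
        his.append(np.where(good, hi, np.nan))
    lo_arr = np.vstack(los)  # (P, m)
    hi_arr = np.vstack(his)
    valid = np.isfinite(lo_arr)
    nvalid = valid.sum(axis=0)
    lengths = np.where(valid, hi_arr - lo_arr, 0.0).sum(axis=0)
    covered = lengths.copy()
    # Exact union where several polygon chords overlap the same segment.
    multi = np.nonzero(nvalid > 1)[0]
    for j in multi:
        ivals = sorted(
            (lo_arr[k, j], hi_arr[k, j]) for k in range(lo_arr.shape[0]) if valid[k, j]
        )
        tot, cur_lo, cur_hi = 0.0, *ivals[0]
        for a, b in ivals[1:]:
            if a > cur_hi:
                tot += cur_hi - cur_lo
                cur_lo, cur_hi = a, b
            else:
                cur_hi = max(cur_hi, b)
        covered[j] = tot + (cur_hi - cur_lo)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(usable, covered / height, 0.0)
    return np.clip(frac, 0.0, 1.0)


def occlusion_fraction(field: VisualField, seg: AngularSegment) -> float:
    """Occluded fraction of one vertical segment in visual-field coordinates."""
    return float(
        occlusion_fractions(field, seg.azimuth, seg.elevation_bottom, seg.elevation_top)[0]
    )


def occlusion_time(trace: OcclusionTrace, analysis_end: float | None = None) -> float:
    """Seconds the pedestrian was (at least partly) occluded, up to analysis_end."""
    s = trace.samples
    if len(s) == 0:
        warnings.warn("empty occlusion trace; occlusion time 0", stacklevel=2)
        return 0.0
    occ = s["occluded"].to_numpy(dtype=bool)
    if analysis_end is not None:
        occ = occ[s["t"].to_numpy() <= analysis_end]
    return float(occ.sum()) / trace.sim_rate


def _horn_press_times(drive: pd.DataFrame) -> np.ndarray:
    horn = drive["horn"].to_numpy(dtype=int)
    rising = np.nonzero((horn == 1) & (np.r_[0, horn[:-1]] == 0))[0]
    return drive["t"].to_numpy()[rising]


def _nearest_eccentricity(value: float, cfg: ScenarioConfig) -> float:
    eccs = np.asarray(cfg.eccentricities, dtype=float)
    return float(eccs[np.argmin(np.abs(eccs - value))])


def score_drive(
    drive: pd.DataFrame,
    gaze: pd.DataFrame,
    field: VisualField,
    cfg: ScenarioConfig,
    participant_id: str = "",
    drive_id: str = "",
    horn_times=None,
) -> tuple[pd.DataFrame, dict]:
    """Score every pedestrian appearance in one drive log.

    Returns the per-appearance outcome rows and a dict of
    :class:`OcclusionTrace` by event id.
    """
    merged = align_streams(gaze, drive)
    presses = list(_horn_press_times(drive) if horn_times is None else np.asarray(horn_times))
    press_used: set = set()
    rows = []
    traces: dict = {}
    vis = merged["ped_visible"].to_numpy(dtype=bool)
    groups = merged.loc[vis].groupby("ped_id", sort=False).groups
    # presses are assigned to the earliest unanswered event, so walk events in time order
    ordered = sorted(groups.items(), key=lambda kv: merged.loc[kv[1], "t"].min())
    for event_id, idx in ordered:
        e = merged.loc[idx].sort_values("t")
        t_appear = float(e["t"].iloc[0])
        t_end = float(e["t"].iloc[-1])
        # assign the first unused press inside the window to this event
        t_press = None
        for k, p in enumerate(presses):
            if k in press_used or p <= t_appear or p > t_end:
                continue
            t_press = float(p)
            press_used.add(k)
            if any(t_appear < q <= t_end for j, q in enumerate(presses) if j not in press_used):
                log.warning("event %s window contains more than one press; using the earliest", event_id)
            break
        detected = t_press is not None
        analysis_end = t_press if detected else t_end
        car_x = e["car_along_track_m"].to_numpy()
        az, bot, top = project_to_angles_arrays(
            car_x, e["ped_x_m"].to_numpy(), e["ped_y_m"].to_numpy(), cfg
        )
        gaze_ok = e["gaze_valid"].to_numpy(dtype=bool) & np.isfinite(az)
        rel_az = az - e["gaze_azimuth_deg"].to_numpy()
        rel_bot = bot - e["gaze_elevation_deg"].to_numpy()
        rel_top = top - e["gaze_elevation_deg"].to_numpy()
        frac = np.zeros(len(e))
        if gaze_ok.any():
            frac[gaze_ok] = occlusion_fractions(
                field, rel_az[gaze_ok], rel_bot[gaze_ok], rel_top[gaze_ok]
            )
        t_arr = e["t"].to_numpy()
        # analysis span: appearance up to the press (press sample excluded;
        # it belongs to the reaction) or through disappearance if undetected
        span = (t_arr < analysis_end - 1e-9) if detected else (t_arr <= analysis_end)
        occluded = (frac > 0.0) & gaze_ok
        trace = OcclusionTrace(
            event_id=str(event_id),
            samples=pd.DataFrame(
                {"t": t_arr[span], "fraction": frac[span], "occluded": occluded[span],
                 "gaze_valid": gaze_ok[span]}
            ),
            sim_rate=cfg.sim_rate,
        )
        traces[str(event_id)] = trace
        occ_time = occlusion_time(trace) if span.any() else 0.0
        n_span = int(span.sum())
        n_valid = int(gaze_ok[span].sum())
        gaze_usable = n_span > 0 and n_valid / n_span >= 0.5
        ecc = _nearest_eccentricity(float(az[0]), cfg)
        rt = (t_press - t_appear) if detected else math.nan
        timely = math.nan
        if detected:
            tlog = drive["t"].to_numpy()
            car = CarState(
                t=t_press,
                along_track=float(np.interp(t_press, tlog, drive["car_along_track_m"])),
                speed=float(np.interp(t_press, tlog, drive["car_speed_mps"])),
            )
            ev = PedestrianEvent(
                event_id=str(event_id),
                eccentricity=ecc,
                t_appear=t_appear,
                appearance_distance=float(np.hypot(e["ped_x_m"].iloc[0] - car_x[0], e["ped_y_m"].iloc[0])),
                window=t_end - t_appear,
            )
            ev.station = float(e["ped_x_m"].iloc[0])
            timely = bool(is_timely(t_press, car, ev, cfg))
        rows.append(
            {
                "participant_id": participant_id,
                "drive_id": drive_id,
                "drive_type": cfg.drive_type,
                "event_id": str(event_id),
                "eccentricity": ecc,
                "ecc_class": "small" if abs(ecc) <= SMALL_LARGE_SPLIT else "large",
                "t_appear": t_appear,
                "detected": detected,
                "reaction_time": rt,
                "log_rt": math.log(rt) if detected else math.nan,
                "timely": timely,
                "occlusion_time": occ_time,
                "max_fraction": float(frac[span].max()) if n_span else 0.0,
                "n_samples": n_span,
                "n_gaze_valid": n_valid,
                "gaze_usable": gaze_usable,
            }
        )
    for k, p in enumerate(presses):
        if k not in press_used:
            log.debug("press at t=%.2f matched no event window", p)
    table = pd.DataFrame(rows).sort_values("t_appear").reset_index(drop=True)
    return table, traces


def build_event_table(drives, gaze_logs, fields, configs, horn_events=None) -> pd.DataFrame:
    """Assemble the study event table: one row per pedestrian appearance.

    ``drives``/``gaze_logs`` are dicts keyed ``(participant_id, drive_id)``;
    ``fields`` maps participant to :class:`VisualField`; ``configs`` maps the
    same drive keys to :class:`ScenarioConfig`.  ``horn_events`` optionally
    supplies press times per key, otherwise presses come from the drive log's
    horn column.
    """
    tables = []
    for key, drive in drives.items():
        pid, drive_id = key
        table, _ = score_drive(
            drive,
            gaze_logs[key],
            fields[pid],
            configs[key],
            participant_id=pid,
            drive_id=str(drive_id),
            horn_times=None if horn_events is None else horn_events.get(key),
        )
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def gaze_availability_check(table: pd.DataFrame, expected_weights=None) -> dict:
    """Usable-event counts per eccentricity and a goodness-of-fit chi-square.

    Expected counts are proportional to ``expected_weights`` (default: total
    appearances per eccentricity in the table, i.e. dropout-rate uniformity;
    pass equal weights to test against a flat distribution instead).
    """
    from . import stats as _stats

    per_ecc = table.groupby("eccentricity")
    totals = per_ecc.size()
    usable = per_ecc["gaze_usable"].sum().astype(int)
    weights = totals.to_numpy(dtype=float) if expected_weights is None else np.asarray(expected_weights, float)
    statistic, pvalue = _stats.chi2_gof(usable.to_numpy(dtype=float), weights)
    if usable.min() == 0 or (usable.min() / max(usable.max(), 1)) < 0.5:
        warnings.warn("gross imbalance in usable gaze data across eccentricities", stacklevel=2)
    return {
        "eccentricities": list(totals.index),
        "usable": usable.tolist(),
        "totals": totals.tolist(),
        "statistic": statistic,
        "pvalue": pvalue,
    }
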