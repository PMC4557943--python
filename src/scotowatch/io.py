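"""File formats, configuration, manifests, and the end-to-end pipeline.

Conventions: time in seconds from drive start (double precision), angles in
degrees, distances in metres internally (feet only at reporting
boundaries).  CSVs are comma-separated UTF-8 with a mandatory header row
and '.' decimal separator; floats are written with repr-precision so a
read -> write -> read round trip is exact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .occlusion import build_event_table, gaze_availability_check, score_drive
from .scenario import ScenarioConfig
from .stats import GroupSummary, median_summary, untimely_summary
from .synthetic import (
    GazeBehaviorParams,
    ResponseModelParams,
    StudyData,
    default_response_params,
    generate_study,
    superior_scotoma_field,
)
from .visual_field import VisualField

__all__ = [
    "RunManifest",
    "read_drive_log",
    "read_gaze_log",
    "read_events",
    "write_table",
    "write_study",
    "load_config",
    "run_pipeline",
]

_FLOAT_FMT = "%.12g"

DRIVE_COLUMNS = [
    "t", "car_along_track_m", "car_speed_mps", "car_heading_deg",
    "ped_id", "ped_x_m", "ped_y_m", "ped_visible", "horn",
]
GAZE_COLUMNS = ["t", "gaze_azimuth_deg", "gaze_elevation_deg", "valid"]


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    config: dict
    seed: int
    package_version: str = __version__
    timestamp: float = dc_field(default_factory=time.time)
    input_digests: dict = dc_field(default_factory=dict)
    output_digests: dict = dc_field(default_factory=dict)

    @property
    def digest(self) -> str:
        core = json.dumps(
            {"config": self.config, "seed": self.seed, "inputs": self.input_digests},
            sort_keys=True,
        )
        return hashlib.sha256(core.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        obj = asdict(self)
        obj["digest"] = self.digest
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_drive_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ped_id": str}, keep_default_na=False,
                     na_values=[""], low_memory=False)
    missing = [c for c in DRIVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"drive log {path} missing columns: {missing}")
    df["ped_id"] = df["ped_id"].fillna("")
    return df


def read_gaze_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze log {path} missing columns: {missing}")
    return df


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_study(study: StudyData, out_dir) -> dict:
    """Write a study's logs to ``out_dir``; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    horn_rows = []
    for (pid, drive_type), drive in study.drives.items():
        stem = f"{pid}_{drive_type}"
        p = out / f"drive_{stem}.csv"
        write_table(drive, p)
        paths[p.name] = p
        p = out / f"gaze_{stem}.csv"
        write_table(study.gaze[(pid, drive_type)], p)
        paths[p.name] = p
        for t in study.horn_events[(pid, drive_type)]:
            horn_rows.append({"participant_id": pid, "drive_type": drive_type, "t": t})
    for pid, field in study.fields.items():
        p = out / f"field_{pid}.json"
        field.to_json(p)
        paths[p.name] = p
    p = out / "horn_events.csv"
    write_table(pd.DataFrame(horn_rows, columns=["participant_id", "drive_type", "t"]), p)
    paths[p.name] = p
    p = out / "ground_truth.csv"
    write_table(study.truth, p)
    paths[p.name] = p
    return paths


# ---------------------------------------------------------------------------
# configuration

_TOP_KEYS = {"seed", "simulate", "inputs", "stats"}
_SIM_KEYS = {"n_cfl", "n_nv", "participants", "scenario", "gaze", "response"}


def load_config(path) -> dict:
    """Load and validate a pipeline config (YAML key-value)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' or an 'inputs' section")
    if "simulate" in cfg:
        unknown = set(cfg["simulate"] or {}) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    if "inputs" in cfg:
        for item in cfg["inputs"]:
            for req in ("participant", "drive_type", "drive", "gaze", "field"):
                if req not in item:
                    raise ValueError(f"inputs entry missing '{req}': {item}")
            for req in ("drive", "gaze", "field"):
                if not Path(item[req]).exists():
                    raise FileNotFoundError(f"input file not found: {item[req]}")
    return cfg


def _study_from_config(cfg: dict, seed: int) -> StudyData:
    sim = cfg.get("simulate") or {}
    scen = ScenarioConfig(**(sim.get("scenario") or {}))
    n_cfl = int(sim.get("n_cfl", 2))
    n_nv = int(sim.get("n_nv", 2))
    cfl_ids = [f"CFL{i+1}" for i in range(n_cfl)]
    nv_ids = [f"NV{i+1}" for i in range(n_nv)]
    fields = {pid: superior_scotoma_field(pid) for pid in cfl_ids}
    fields.update({pid: VisualField(participant_id=pid) for pid in nv_ids})
    for item in sim.get("participants") or []:
        pid = item["id"]
        fpath = item.get("field")
        fields[pid] = (
            VisualField(participant_id=pid)
            if fpath in (None, "none")
            else VisualField.from_json(fpath)
        )
    gp = GazeBehaviorParams(seed=seed, **(sim.get("gaze") or {}))
    rp = default_response_params(
        [p for p in fields if fields[p].has_scotoma],
        [p for p in fields if not fields[p].has_scotoma],
        seed,
    )
    for k, v in (sim.get("response") or {}).items():
        if not hasattr(rp, k):
            raise ValueError(f"unknown response key: {k}")
        setattr(rp, k, v)
    return generate_study(scen, gp, rp, fields, seed=seed)


def _summaries_to_json(table: pd.DataFrame, seed: int) -> dict:
    """All standard summaries of an event table, JSON-ready."""
    from .stats import ols_logrt, pearson_r

    report: dict = {"schema_version": 1, "n_events": int(len(table))}
    unt = untimely_summary(table)
    tab = unt.pop("occlusion_by_timeliness")
    unt["occlusion_by_timeliness"] = {"a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d}
    report["untimely"] = unt
    by = ["group"] if "group" in table.columns else ["participant_id"]
    report["reaction_time_medians"] = [
        asdict(s) for s in median_summary(table, by=by, seed=seed)
    ]
    report["gaze_availability"] = gaze_availability_check(table)
    usable = table.loc[
        table["detected"].astype(bool)
        & table["gaze_usable"].astype(bool)
        & (table["occlusion_time"].notna())
    ]
    if "group" in usable.columns:
        # occlusion analyses concern the scotoma group only
        usable = usable.loc[usable["group"] == "CFL"]
    if len(usable) >= 10 and usable["occlusion_time"].var() > 0:
        report["occlusion_rt_r"] = pearson_r(
            usable["occlusion_time"], usable["reaction_time"]
        )
        if usable["participant_id"].nunique() >= 1:
            fit = ols_logrt(
                usable["log_rt"], usable["occlusion_time"], usable["participant_id"]
            )
            report["log_rt_regression"] = {
                k: fit[k]
                for k in ("occ_slope", "occ_slope_ci", "f_statistic", "adj_r2", "df_resid")
            }
    return report


def run_pipeline(config_path, out_dir, seed: int | None = None) -> Path:
    """simulate (optional) -> score -> stats; idempotent given seeds.

    Writes events.csv, report.json and manifest.json under ``out_dir``.
    """
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed)

    if "simulate" in cfg:
        study = _study_from_config(cfg, seed)
        sim_paths = write_study(study, out / "simulated")
        manifest.input_digests = {n: file_digest(p) for n, p in sim_paths.items()}
        drives, gaze, fields, configs = study.drives, study.gaze, study.fields, study.configs
        group = {p: ("CFL" if f.has_scotoma else "NV") for p, f in fields.items()}
    else:
        drives, gaze, fields, configs, group = {}, {}, {}, {}, {}
        for item in cfg["inputs"]:
            key = (item["participant"], item["drive_type"])
            drives[key] = read_drive_log(item["drive"])
            gaze[key] = read_gaze_log(item["gaze"])
            fields[item["participant"]] = VisualField.from_json(item["field"])
            configs[key] = ScenarioConfig(
                drive_type=item["drive_type"], **(item.get("scenario") or {})
            )
            group[item["participant"]] = (
                "CFL" if fields[item["participant"]].has_scotoma else "NV"
            )
            for f in ("drive", "gaze", "field"):
                manifest.input_digests[Path(item[f]).name] = file_digest(item[f])

    table = build_event_table(drives, gaze, fields, configs)
    table["group"] = table["participant_id"].map(group)
    events_path = out / "events.csv"
    write_table(table, events_path)

    report = _summaries_to_json(table, seed)
    report["manifest_digest"] = manifest.digest
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True, default=float) + "\n")

    manifest.output_digests = {
        "events.csv": file_digest(events_path),
        "report.json": file_digest(report_path),
    }
    manifest.write(out / "manifest.json")
    return out
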