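"""Driving-scene geometry: car kinematics, collision-course pedestrians, timeliness.

The road is straight; the car travels along +x at (nominally) constant speed
with the driver's eye ``eye_height`` above the road.  Pedestrian hazards
appear at a fixed eccentricity relative to the car heading and walk
perpendicular to the road on a constant-bearing collision course: with the
car at speed v and the pedestrian at bearing theta, a lateral speed of
v*tan(theta) keeps the bearing constant, so the hazard stays in the same
part of the visual field under steady forward gaze.  Pedestrians stop at the
lane edge and never enter the travel lane; the collision is counterfactual.

A horn press is "timely" when braking at a fixed deceleration from the press
instant would stop the car before the pedestrian's crossing point
(stopping distance v^2 / 2a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MPS_PER_MPH",
    "FT_PER_M",
    "ScenarioConfig",
    "CarState",
    "PedestrianEvent",
    "AngularSegment",
    "appearance_distance",
    "make_trajectory",
    "project_to_angles",
    "stopping_distance",
    "is_timely",
]

MPS_PER_MPH = 0.44704
FT_PER_M = 1.0 / 0.3048

#: posted-limit speeds by drive type, m/s (30 mph city, 60 mph highway)
DRIVE_SPEEDS = {"city": 13.41, "highway": 26.82}


@dataclass
class ScenarioConfig:
    """Scene parameters; defaults reproduce the city/highway study conditions."""

    drive_type: str = "city"
    car_speed: float | None = None  # m/s; None -> posted limit for drive_type
    appearance_travel_time: float = 5.0  # s to reach the lane edge
    eccentricities: tuple = (-14.0, -4.0, 4.0, 14.0)  # degrees
    n_appearances: int = 104
    pedestrian_height: float = 2.0  # m
    deceleration: float = 5.0  # m/s^2, dry level road
    eye_height: float = 1.2  # m above road
    lane_half_width: float = 1.8  # m
    sim_rate: float = 30.0  # Hz

    def __post_init__(self) -> None:
        if self.drive_type not in DRIVE_SPEEDS:
            raise ValueError(f"drive_type must be one of {sorted(DRIVE_SPEEDS)}")
        if self.car_speed is None:
            self.car_speed = DRIVE_SPEEDS[self.drive_type]
        if not self.car_speed > 0:
            raise ValueError("car_speed must be > 0")
        if not self.deceleration > 0:
            raise ValueError("deceleration must be > 0")
        if self.n_appearances % len(self.eccentricities) != 0:
            raise ValueError(
                f"n_appearances={self.n_appearances} not divisible by "
                f"{len(self.eccentricities)} eccentricities"
            )

    def with_drive_type(self, drive_type: str) -> "ScenarioConfig":
        """Same config at the other drive type's posted speed."""
        return replace(self, drive_type=drive_type, car_speed=None)

    @property
    def dt(self) -> float:
        return 1.0 / self.sim_rate


@dataclass
class CarState:
    t: float  # s
    along_track: float  # m
    speed: float  # m/s
    heading: float = 0.0  # degrees; straight roads only

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class PedestrianEvent:
    """One scripted pedestrian appearance."""

    event_id: str
    eccentricity: float  # degrees, signed (sign = side of road)
    t_appear: float  # s
    appearance_distance: float  # m, range at appearance
    lateral_speed: float | None = None  # m/s; None -> constant-bearing value
    window: float = 5.0  # s from appearance to lane edge / despawn
    station: float = dc_field(default=math.nan)  # along-road x of the pedestrian

    def __post_init__(self) -> None:
        if not self.appearance_distance > 0:
            raise ValueError("appearance_distance must be > 0")


@dataclass
class AngularSegment:
    """The pedestrian's image: a vertical segment at one azimuth (degrees)."""

    azimuth: float
    elevation_bottom: float
    elevation_top: float

    def __post_init__(self) -> None:
        if not self.elevation_top > self.elevation_bottom:
            raise ValueError("elevation_top must exceed elevation_bottom")

    @property
    def height(self) -> float:
        return self.elevation_top - self.elevation_bottom


def appearance_distance(speed: float, travel_time: float) -> tuple[float, float]:
    """Appearance range = speed x travel time; returns ``(meters, feet)``.

    At the posted limits this puts city pedestrians 220 ft away and highway
    pedestrians 440 ft away, twice the recommended 2.5-s perception-brake
    sight distance.
    """
    if not speed > 0:
        raise ValueError("speed must be > 0")
    if not travel_time > 0:
        raise ValueError("travel_time must be > 0")
    d = speed * travel_time
    return d, d * FT_PER_M


def make_trajectory(cfg: ScenarioConfig, ev: PedestrianEvent) -> pd.DataFrame:
    """Sample one pedestrian's collision-course path at the simulator rate.

    The pedestrian appears at range D along the line of sight at the event's
    eccentricity (ahead D*cos(theta), lateral D*sin(theta)), walks toward the
    lane at ``lateral_speed`` (constant-bearing v*tan(theta) by default), and
    stops at the lane edge.  Columns: t, ped_x_m (along-road station, fixed),
    ped_y_m (lateral, right positive).
    """
    theta = math.radians(ev.eccentricity)
    if ev.eccentricity == 0.0:
        raise ValueError("eccentricity 0 has no collision-course geometry")
    side = 1.0 if ev.eccentricity > 0 else -1.0
    v = cfg.car_speed
    vlat = ev.lateral_speed if ev.lateral_speed is not None else v * abs(math.tan(theta))
    d = ev.appearance_distance
    car_x0 = v * ev.t_appear
    station = car_x0 + d * math.cos(theta)
    lat0 = d * abs(math.sin(theta))
    n = int(round(ev.window * cfg.sim_rate)) + 1
    t = ev.t_appear + np.arange(n) / cfg.sim_rate
    lat = np.maximum(lat0 - vlat * (t - ev.t_appear), cfg.lane_half_width)
    ev.station = station
    return pd.DataFrame({"t": t, "ped_x_m": np.full(n, station), "ped_y_m": side * lat})


def project_to_angles(car: CarState, ped_position, cfg: ScenarioConfig) -> AngularSegment:
    """Project a pedestrian ground position to the driver's angular coordinates.

    Azimuth is the signed bearing relative to car heading (right positive);
    the 2-m-tall pedestrian spans elevations atan(-eye_height/range) to
    atan((height - eye_height)/range).
    """
    px, py = float(ped_position[0]), float(ped_position[1])
    rng = px - car.along_track
    if rng <= 0:
        raise ValueError("pedestrian behind or abreast of the car (event closed)")
    az = math.degrees(math.atan2(py, rng))
    bottom = math.degrees(math.atan2(-cfg.eye_height, rng))
    top = math.degrees(math.atan2(cfg.pedestrian_height - cfg.eye_height, rng))
    return AngularSegment(azimuth=az, elevation_bottom=bottom, elevation_top=top)


def project_to_angles_arrays(car_x, ped_x, ped_y, cfg: ScenarioConfig):
    """Vectorized :func:`project_to_angles`; NaN where the range is non-positive."""
    rng = np.asarray(ped_x, dtype=float) - np.asarray(car_x, dtype=float)
    ok = rng > 0
    rng = np.where(ok, rng, np.nan)
    az = np.degrees(np.arctan2(ped_y, rng))
    bottom = np.degrees(np.arctan2(-cfg.eye_height, rng))
    top = np.degrees(np.arctan2(cfg.pedestrian_height - cfg.eye_height, rng))
    return az, bottom, top


def stopping_distance(speed: float, deceleration: float = 5.0) -> float:
    """Braking distance v^2 / (2 a) from the given speed, metres."""
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if not deceleration > 0:
        raise ValueError("deceleration must be > 0")
    return speed * speed / (2.0 * deceleration)


def is_timely(t_press: float, car: CarState, ev: PedestrianEvent, cfg: ScenarioConfig) -> bool:
    """Could the car stop before the pedestrian's crossing point?

    Timely iff the distance from the car at the press to the pedestrian's
    along-road station is at least the stopping distance at the instantaneous
    speed (boundary counts as timely).  Braking onset is the horn press; no
    additional brake-movement lag is assumed.
    """
    if math.isnan(ev.station):
        raise ValueError("event has no station; build its trajectory first")
    remaining = ev.station - car.along_track
    return remaining >= stopping_distance(car.speed, cfg.deceleration)
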