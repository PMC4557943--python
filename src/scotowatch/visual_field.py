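"""Binocular visual fields with central scotomas mapped by kinetic perimetry.

The visual field is a planar chart in degrees of visual angle with the
preferred retinal locus (PRL) at the origin: azimuth positive rightward,
elevation positive upward. Scotomas (regions of absent sensitivity) are
modelled as convex polygons of at most 100 vertices; a field may carry
several polygons, treated as a union (e.g. a central scotoma plus a
paracentral one from blind-spot overlap).

Degrees are treated as planar coordinates throughout (tangent-plane
small-angle convention), matching perimetric chart practice.  Points on a
polygon boundary count as inside (closed-set convention); this convention
is used everywhere downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "AngularPoint",
    "ScotomaPolygon",
    "VisualField",
    "PerimetryGeometry",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "validate_polygon",
    "vertical_chord",
    "scotoma_size",
    "fixation_stability",
    "gaze_accuracy",
]

MAX_VERTICES = 100


@dataclass(frozen=True)
class AngularPoint:
    """A direction in the visual field, in degrees (azimuth right+, elevation up+)."""

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.azimuth) and math.isfinite(self.elevation)):
            raise ValueError("angular coordinates must be finite")
        if not -180.0 <= self.azimuth <= 180.0:
            raise ValueError(f"azimuth {self.azimuth} outside [-180, 180]")
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation {self.elevation} outside [-90, 90]")


class ScotomaPolygon:
    """A convex scotoma outline with counter-clockwise vertices, in degrees.

    Construct through :func:`validate_polygon` (or the constructor, which
    validates identically): vertices are reordered CCW, convexity is
    enforced, and at most :data:`MAX_VERTICES` vertices are accepted.
    """

    def __init__(self, vertices) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (azimuth, elevation)")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        n = v.shape[0]
        if n < 3:
            raise ValueError(f"a polygon needs at least 3 vertices, got {n}")
        if n > MAX_VERTICES:
            raise ValueError(f"polygon has {n} vertices; at most {MAX_VERTICES} allowed")
        # Shoelace: negative signed area means clockwise input; reorder CCW.
        x, y = v[:, 0], v[:, 1]
        area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if area2 == 0.0:
            raise ValueError("degenerate polygon (zero area)")
        if area2 < 0.0:
            v = v[::-1].copy()
        # Convexity: every turn must be a left turn (cross product >= 0).
        a = v
        b = np.roll(v, -1, axis=0)
        c = np.roll(v, -2, axis=0)
        cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - b[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - b[:, 0])
        bad = np.nonzero(cross < -1e-12 * np.max(np.abs(v)) ** 2 - 1e-300)[0]
        if bad.size:
            i = int((bad[0] + 1) % v.shape[0])
            raise ValueError(
                f"polygon is not convex: reflex turn at vertex {i} {tuple(v[i])}"
            )
        self.vertices = v

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def __repr__(self) -> str:
        return f"ScotomaPolygon(n={len(self)})"

    def to_shapely(self):
        """The polygon as a :class:`shapely.geometry.Polygon` (for interop/plots)."""
        from shapely.geometry import Polygon

        return Polygon(self.vertices)

    # -- geometry -----------------------------------------------------------

    def chords(self, azimuths) -> tuple[np.ndarray, np.ndarray]:
        """Vertical chords at each azimuth, vectorized.

        Returns (lo, hi) elevation arrays; NaN where the vertical line misses
        the polygon.  A line through a single vertex yields lo == hi.
        """
        xs = np.atleast_1d(np.asarray(azimuths, dtype=float))[:, None]  # (m,1)
        v = self.vertices
        x1, y1 = v[:, 0], v[:, 1]
        x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
        dx = x2 - x1
        nonvert = dx != 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (xs - x1) / np.where(nonvert, dx, np.nan)
        hit = nonvert & (t >= 0.0) & (t <= 1.0)
        y = y1 + t * (y2 - y1)
        # Vertical edges lying exactly on the query line contribute both ends.
        on_vert = (~nonvert) & (xs == x1)
        lo_c = np.where(hit, y, np.inf)
        lo_c = np.where(on_vert, np.minimum(y1, y2), lo_c)
        hi_c = np.where(hit, y, -np.inf)
        hi_c = np.where(on_vert, np.maximum(y1, y2), hi_c)
        lo = lo_c.min(axis=1)
        hi = hi_c.max(axis=1)
        miss = ~np.isfinite(lo)
        lo[miss] = np.nan
        hi[miss] = np.nan
        return lo, hi

    def size(self) -> float:
        """Scotoma diameter: mean of horizontal and vertical chords through the center.

        The center is the vertex centroid.  Mirrors the clinical definition of
        averaging cardinal meridians through the scotoma center; for a convex
        outline the two full chords equal the four cardinal radii summed.
        """
        cx, cy = self.vertices.mean(axis=0)
        lo, hi = self.chords(cx)
        vlen = float(hi[0] - lo[0]) if np.isfinite(lo[0]) else 0.0
        swapped = ScotomaPolygon.__new__(ScotomaPolygon)
        swapped.vertices = self.vertices[:, ::-1][::-1].copy()  # swap axes, keep CCW
        lo, hi = swapped.chords(cy)
        hlen = float(hi[0] - lo[0]) if np.isfinite(lo[0]) else 0.0
        return 0.5 * (hlen + vlen)


@dataclass
class VisualField:
    """Per-participant binocular field: union of scotoma polygons, PRL at origin."""

    polygons: list = dc_field(default_factory=list)
    participant_id: str = ""
    prl_note: str = ""

    def __post_init__(self) -> None:
        self.polygons = [
            p if isinstance(p, ScotomaPolygon) else validate_polygon(p)
            for p in self.polygons
        ]

    @property
    def has_scotoma(self) -> bool:
        return bool(self.polygons)

    # -- JSON interchange ---------------------------------------------------

    @classmethod
    def from_json(cls, path) -> "VisualField":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            polygons=[np.asarray(p, dtype=float) for p in obj.get("polygons", [])],
            participant_id=str(obj.get("participant_id", "")),
            prl_note=str(obj.get("prl_note", "")),
        )

    def to_json(self, path) -> None:
        obj = {
            "participant_id": self.participant_id,
            "polygons": [p.vertices.tolist() for p in self.polygons],
            "prl_note": self.prl_note,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
            fh.write("\n")


@dataclass
class PerimetryGeometry:
    """Viewing geometry of the screen-based perimetry test used to map scotomas.

    Defaults match a binocular kinetic test with 0.74 deg square targets and a
    1.23 deg fixation cross viewed from 1 m.
    """

    viewing_distance: float = 1.0  # m
    pixel_pitch: float = 0.3  # mm / pixel
    screen_center_px: tuple = (512.0, 384.0)
    target_size_deg: float = 0.74
    fixation_cross_deg: float = 1.23

    def __post_init__(self) -> None:
        if not self.viewing_distance > 0:
            raise ValueError("viewing_distance must be > 0")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")


def pixels_to_degrees(p, g: PerimetryGeometry) -> AngularPoint:
    """Convert a screen pixel coordinate to visual angle by arctangent projection.

    Screen y grows downward (raster convention); elevation grows upward.
    """
    px, py = float(p[0]), float(p[1])
    if not (math.isfinite(px) and math.isfinite(py)):
        raise ValueError("pixel coordinates must be finite")
    cx, cy = g.screen_center_px
    dx_m = (px - cx) * g.pixel_pitch / 1000.0
    dy_m = (cy - py) * g.pixel_pitch / 1000.0
    return AngularPoint(
        azimuth=math.degrees(math.atan2(dx_m, g.viewing_distance)),
        elevation=math.degrees(math.atan2(dy_m, g.viewing_distance)),
    )


def degrees_to_pixels(a: AngularPoint, g: PerimetryGeometry) -> tuple[float, float]:
    """Inverse of :func:`pixels_to_degrees` (tangent projection back to the screen)."""
    cx, cy = g.screen_center_px
    dx_m = g.viewing_distance * math.tan(math.radians(a.azimuth))
    dy_m = g.viewing_distance * math.tan(math.radians(a.elevation))
    return (cx + dx_m * 1000.0 / g.pixel_pitch, cy - dy_m * 1000.0 / g.pixel_pitch)


def validate_polygon(vertices) -> ScotomaPolygon:
    """Validate a candidate vertex list into a CCW convex :class:`ScotomaPolygon`."""
    return ScotomaPolygon(vertices)


def vertical_chord(poly: ScotomaPolygon, x: float):
    """Intersection of the vertical line at azimuth ``x`` with the polygon.

    Returns an ``(elevation_lo, elevation_hi)`` tuple, or ``None`` when the
    line misses the polygon.  Endpoints are exact at vertices.
    """
    lo, hi = poly.chords(x)
    if not np.isfinite(lo[0]):
        return None
    return (float(lo[0]), float(hi[0]))


def scotoma_size(vf: VisualField) -> float:
    """Field-level scotoma size in degrees: the largest polygon's diameter.

    Per polygon the diameter is the mean of the horizontal and vertical chords
    through its vertex centroid; see :func:`scotoma_sizes` for the full list.
    """
    if not vf.polygons:
        raise ValueError("visual field has no scotoma polygons")
    return max(p.size() for p in vf.polygons)


def scotoma_sizes(vf: VisualField) -> list[float]:
    """Per-polygon diameters (degrees), in field order."""
    if not vf.polygons:
        raise ValueError("visual field has no scotoma polygons")
    return [p.size() for p in vf.polygons]


def fixation_stability(samples, diameter: float, center=None) -> float:
    """Percent of gaze samples within a circle of the given diameter.

    By default the circle is centered on the sample centroid (robust to a
    constant calibration offset); pass ``center=(az, el)`` to center on the
    fixation target instead.  NaN samples are discarded first.
    """
    if not diameter > 0:
        raise ValueError("diameter must be > 0")
    pts = np.asarray(
        [(s.azimuth, s.elevation) if isinstance(s, AngularPoint) else s for s in samples],
        dtype=float,
    )
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need at least one sample")
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] == 0:
        raise ValueError("all fixation samples invalid")
    c = pts.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    r = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    return 100.0 * float(np.mean(r <= diameter / 2.0))


def gaze_accuracy(measured, intended: AngularPoint) -> float:
    """Mean planar angular deviation (degrees) of measured gaze from the target."""
    pts = np.asarray(
        [(s.azimuth, s.elevation) if isinstance(s, AngularPoint) else s for s in measured],
        dtype=float,
    )
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need at least one sample")
    return float(np.mean(np.hypot(pts[:, 0] - intended.azimuth, pts[:, 1] - intended.elevation)))
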