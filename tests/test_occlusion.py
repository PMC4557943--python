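"""Stream alignment, occlusion scoring, and event-table assembly."""

import numpy as np
import pandas as pd
import pytest

from scotowatch.occlusion import (
    OcclusionTrace,
    align_streams,
    gaze_availability_check,
    occlusion_fraction,
    occlusion_fractions,
    occlusion_time,
    retinal_position,
    score_drive,
)
from scotowatch.scenario import AngularSegment, ScenarioConfig
from scotowatch.visual_field import VisualField
from conftest import random_convex_polygon, raster_fraction

SQUARE_FIELD = VisualField(polygons=[[(-5, -5), (5, -5), (5, 5), (-5, 5)]])


def _gaze_df(t, az=0.0, el=0.0, valid=1):
    n = len(t)
    return pd.DataFrame(
        {
            "t": t,
            "gaze_azimuth_deg": np.broadcast_to(az, n).astype(float),
            "gaze_elevation_deg": np.broadcast_to(el, n).astype(float),
            "valid": np.broadcast_to(valid, n).astype(int),
        }
    )


class TestAlignment:
    def test_phase_locked_uses_every_other_sample(self):
        t60 = np.arange(120) / 60.0
        gaze = _gaze_df(t60, az=np.arange(120, dtype=float))
        drive = pd.DataFrame({"t": np.arange(60) / 30.0})
        merged = align_streams(gaze, drive)
        assert merged["gaze_valid"].all()
        # azimuth encodes the gaze sample index: every other one is used
        assert np.array_equal(merged["gaze_azimuth_deg"].to_numpy(), np.arange(0, 120, 2))

    def test_small_clock_offset_drops_nothing(self):
        gaze = _gaze_df(np.arange(120) / 60.0 + 0.005)
        drive = pd.DataFrame({"t": np.arange(59) / 30.0 + 0.01})
        merged = align_streams(gaze, drive)
        assert merged["gaze_valid"].all()

    def test_all_invalid_gaze_flags_missing(self):
        gaze = _gaze_df(np.arange(120) / 60.0, valid=0)
        drive = pd.DataFrame({"t": np.arange(60) / 30.0})
        merged = align_streams(gaze, drive)
        assert not merged["gaze_valid"].any()

    def test_disjoint_ranges_error(self):
        gaze = _gaze_df(np.arange(60) / 60.0 + 100.0)
        drive = pd.DataFrame({"t": np.arange(60) / 30.0})
        with pytest.raises(ValueError, match="disjoint"):
            align_streams(gaze, drive)


class TestRetinalPosition:
    def test_forward_gaze_identity(self):
        seg = AngularSegment(14.0, -1.0, 1.0)
        out = retinal_position(seg, (0.0, 0.0))
        assert out.azimuth == 14.0

    def test_fixating_the_target(self):
        seg = AngularSegment(14.0, -1.0, 1.0)
        assert retinal_position(seg, (14.0, 0.0)).azimuth == 0.0

    def test_dashboard_glance_raises_field_elevation(self):
        # gaze 10 deg down puts a horizon-level target 10 deg up in the field
        seg = AngularSegment(4.0, -1.0, 1.0)
        out = retinal_position(seg, (0.0, -10.0))
        assert out.elevation_bottom == pytest.approx(9.0)
        assert out.elevation_top == pytest.approx(11.0)


class TestOcclusionFraction:
    @pytest.mark.parametrize(
        "seg,expected",
        [
            (AngularSegment(0.0, -2.0, 2.0), 1.0),
            (AngularSegment(10.0, -2.0, 2.0), 0.0),
            (AngularSegment(0.0, -10.0, 0.0), 0.5),
        ],
    )
    def test_square_scotoma(self, seg, expected):
        assert occlusion_fraction(SQUARE_FIELD, seg) == pytest.approx(expected)

    def test_empty_field_never_occludes(self, rng):
        vf = VisualField()
        az = rng.uniform(-30, 30, 100)
        assert np.all(occlusion_fractions(vf, az, -1.0, 1.0) == 0.0)

    def test_translation_equivariance(self, rng):
        seg = AngularSegment(2.0, -3.0, 1.0)
        base = occlusion_fraction(SQUARE_FIELD, seg)
        for _ in range(10):
            dx, dy = rng.uniform(-5, 5, 2)
            shifted = retinal_position(
                AngularSegment(seg.azimuth + dx, seg.elevation_bottom + dy, seg.elevation_top + dy),
                (dx, dy),
            )
            assert occlusion_fraction(SQUARE_FIELD, shifted) == pytest.approx(base)

    def test_union_bounds_with_two_polygons(self, rng):
        a = [(-5, -5), (0, -5), (0, 5), (-5, 5)]
        b = [(-2, -5), (3, -5), (3, 5), (-2, 5)]  # overlaps a
        both = VisualField(polygons=[a, b])
        fa = VisualField(polygons=[a])
        fb = VisualField(polygons=[b])
        for _ in range(50):
            seg = AngularSegment(rng.uniform(-7, 7), -4.0, 4.0)
            u = occlusion_fraction(both, seg)
            s1, s2 = occlusion_fraction(fa, seg), occlusion_fraction(fb, seg)
            assert u >= max(s1, s2) - 1e-12
            assert u <= min(1.0, s1 + s2) + 1e-12

    def test_matches_rasterized_oracle(self, rng):
        # spot check here; the full 1000-case sweep runs in the acceptance suite
        for _ in range(10):
            vf = VisualField(polygons=[random_convex_polygon(rng)])
            for _ in range(10):
                az = rng.uniform(-12, 12)
                bot = rng.uniform(-12, 8)
                top = bot + rng.uniform(0.5, 6)
                got = occlusion_fractions(vf, az, bot, top)[0]
                assert got == pytest.approx(raster_fraction(vf, az, bot, top), abs=0.02)


class TestOcclusionTime:
    def _trace(self, occluded):
        n = len(occluded)
        return OcclusionTrace(
            "e",
            pd.DataFrame(
                {
                    "t": np.arange(n) / 30.0,
                    "fraction": np.where(occluded, 1.0, 0.0),
                    "occluded": occluded,
                    "gaze_valid": True,
                }
            ),
            sim_rate=30.0,
        )

    def test_no_occlusion(self):
        assert occlusion_time(self._trace(np.zeros(30, dtype=bool))) == 0.0

    def test_fifteen_samples_is_half_second(self):
        occ = np.zeros(60, dtype=bool)
        occ[10:25] = True
        assert occlusion_time(self._trace(occ)) == pytest.approx(0.5)

    def test_monotone_in_analysis_end(self):
        occ = np.zeros(90, dtype=bool)
        occ[::3] = True
        tr = self._trace(occ)
        vals = [occlusion_time(tr, e) for e in (0.5, 1.0, 2.0, 3.0)]
        assert vals == sorted(vals)

    def test_empty_trace_warns(self):
        tr = OcclusionTrace("e", pd.DataFrame(columns=["t", "fraction", "occluded", "gaze_valid"]))
        with pytest.warns(UserWarning):
            assert occlusion_time(tr) == 0.0


def _scripted_drive(cfg, t_appear=1.0, press_after=None, window=4.0):
    """Minimal one-pedestrian city drive with forward gaze."""
    v = cfg.car_speed
    total = t_appear + window + 1.0
    n = int(round(total * cfg.sim_rate)) + 1
    t = np.arange(n) / cfg.sim_rate
    d = v * cfg.appearance_travel_time
    station = v * t_appear + d * np.cos(np.radians(14.0))
    in_win = (t >= t_appear) & (t <= t_appear + window)
    lat = np.maximum(
        d * np.sin(np.radians(14.0)) - v * np.tan(np.radians(14.0)) * (t - t_appear),
        cfg.lane_half_width,
    )
    drive = pd.DataFrame(
        {
            "t": t,
            "car_along_track_m": v * t,
            "car_speed_mps": v,
            "car_heading_deg": 0.0,
            "ped_id": np.where(in_win, "ped1", ""),
            "ped_x_m": np.where(in_win, station, np.nan),
            "ped_y_m": np.where(in_win, lat, np.nan),
            "ped_visible": in_win.astype(int),
            "horn": 0,
        }
    )
    if press_after is not None:
        k = int(round((t_appear + press_after) * cfg.sim_rate))
        drive.loc[k, "horn"] = 1
    gaze = _gaze_df(np.arange(2 * (n - 1) + 1) / (2 * cfg.sim_rate))
    return drive, gaze


class TestEventTable:
    def test_single_event_reaction_time(self):
        cfg = ScenarioConfig(drive_type="city")
        drive, gaze = _scripted_drive(cfg, press_after=1.0)
        table, _ = score_drive(drive, gaze, VisualField(), cfg, "P1", "d1")
        assert len(table) == 1
        row = table.iloc[0]
        assert row["detected"]
        assert row["reaction_time"] == pytest.approx(1.0, abs=1e-9)
        assert row["eccentricity"] == 14.0
        assert bool(row["timely"])
        assert row["occlusion_time"] == 0.0

    def test_no_press_is_undetected(self):
        cfg = ScenarioConfig(drive_type="city")
        drive, gaze = _scripted_drive(cfg, press_after=None)
        table, _ = score_drive(drive, gaze, VisualField(), cfg, "P1", "d1")
        assert not table.iloc[0]["detected"]
        assert np.isnan(table.iloc[0]["reaction_time"])

    def test_scripted_full_occlusion_time(self):
        # an all-covering scotoma occludes from appearance to the 1.2-s press
        cfg = ScenarioConfig(drive_type="city")
        drive, gaze = _scripted_drive(cfg, press_after=1.2)
        big = VisualField(polygons=[[(-60, -60), (60, -60), (60, 60), (-60, 60)]])
        table, traces = score_drive(drive, gaze, big, cfg, "P1", "d1")
        assert table.iloc[0]["occlusion_time"] == pytest.approx(1.2, abs=1 / 30)
        assert table.iloc[0]["max_fraction"] == 1.0

    def test_balanced_design_counts(self):
        from scotowatch.synthetic import default_study
        from scotowatch.occlusion import build_event_table

        s = default_study(n_cfl=1, n_nv=0, seed=2)
        table = build_event_table(s.drives, s.gaze, s.fields, s.configs)
        counts = table.groupby("eccentricity").size()
        assert set(counts.index) == {-14.0, -4.0, 4.0, 14.0}
        assert (counts == 26).all()


class TestAvailability:
    def _table(self, usable_per_ecc, totals_per_ecc):
        rows = []
        for ecc, (u, tot) in zip((-14, -4, 4, 14), zip(usable_per_ecc, totals_per_ecc)):
            for i in range(tot):
                rows.append({"eccentricity": float(ecc), "gaze_usable": i < u})
        return pd.DataFrame(rows)

    def test_balanced_fully_usable_is_zero(self):
        out = gaze_availability_check(self._table([10] * 4, [10] * 4))
        assert out["statistic"] == pytest.approx(0.0)

    def test_study_counts_reproduced(self):
        out = gaze_availability_check(self._table([66, 67, 62, 65], [178, 179, 175, 173]))
        assert out["usable"] == [66, 67, 62, 65]
        assert out["statistic"] == pytest.approx(0.139, abs=0.001)

    def test_dropped_eccentricity_warns(self):
        with pytest.warns(UserWarning, match="imbalance"):
            out = gaze_availability_check(self._table([20, 20, 20, 0], [20] * 4))
        assert out["statistic"] > 10
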