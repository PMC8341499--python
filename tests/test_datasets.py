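"""Dataset assembly: segment rules, nearest-turbine pairing, drop accounting,
descriptive summaries against independent oracles."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from windshy import (
    StatusTable,
    Turbine,
    build_after_records,
    build_before_after_records,
    build_segments,
    proportion_within_diameters,
    quantile_by_group,
    summarize_distances,
)
from windshy.geometry import closest_approach_2d, distance_3d, fix_to_hub_3d


def _fixes(rows):
    return pd.DataFrame(
        rows,
        columns=["bird_id", "timestamp", "easting", "northing", "altitude_asl"],
    ).assign(timestamp=lambda d: pd.to_datetime(d["timestamp"]))


def test_build_segments_gap_rule():
    t0 = pd.Timestamp("2018-06-01 10:00:00")
    fx = _fixes(
        [
            ("B1", t0, 0, 0, 700),
            ("B1", t0 + pd.Timedelta(seconds=120), 100, 0, 710),
            ("B1", t0 + pd.Timedelta(seconds=400), 200, 0, 720),  # gap 280 s, kept
            ("B1", t0 + pd.Timedelta(seconds=702), 300, 0, 730),  # gap 302 s, dropped
        ]
    )
    seg = build_segments(fx, max_gap=300)
    assert len(seg) == 2
    assert list(seg["duration_s"]) == [120.0, 280.0]


def test_build_segments_single_fix_and_bird_boundary():
    t0 = pd.Timestamp("2018-06-01 10:00:00")
    fx = _fixes([("B1", t0, 0, 0, 700), ("B2", t0 + pd.Timedelta(seconds=60), 1, 1, 700)])
    assert len(build_segments(fx)) == 0  # never joins across birds


@pytest.fixture()
def world():
    turbines = [
        Turbine("T1", "F1", 0.0, 0.0, 620.0, 80.0, 40.0, operation_date=date(2017, 1, 1)),
        Turbine("T2", "F1", 800.0, 0.0, 620.0, 80.0, 40.0, operation_date=date(2017, 1, 1)),
        Turbine("T3", "F2", 5000.0, 5000.0, 600.0, 73.0, 57.5, operation_date=date(2018, 6, 1)),
    ]
    from windshy.habitat import GETRaster

    rng = np.random.default_rng(5)
    data = rng.integers(1, 11, size=(160, 160))
    raster = GETRaster(data=data, xll=-2000.0, yll=-2000.0, cellsize=50.0)
    return turbines, raster


def test_before_after_worked_example(world):
    turbines, raster = world
    # two fixes near T1 with hand-computable geometry: hub alt = 700
    fx = pd.DataFrame(
        {
            "bird_id": ["B1", "B1"],
            "timestamp": pd.to_datetime(["2016-06-01 12:00", "2018-06-01 12:00"]),
            "easting": [300.0, 0.0],
            "northing": [0.0, 400.0],
            "altitude_asl": [1100.0, 1000.0],
        }
    )
    rec, drops = build_before_after_records(fx, turbines, raster)
    assert len(rec) == 2
    assert rec["d3d"].tolist() == pytest.approx([500.0, 500.0])  # 3-4-5 triangles
    assert rec["phase"].tolist() == ["before", "after"]
    assert rec["turbine_id"].tolist() == ["T1", "T1"]


def test_before_after_buffer_rule(world):
    turbines, raster = world
    fx = pd.DataFrame(
        {
            "bird_id": ["B1"],
            "timestamp": pd.to_datetime(["2018-06-01 12:00"]),
            "easting": [2000.0],   # 1200 m from T2, further from others
            "northing": [0.0],
            "altitude_asl": [700.0],
        }
    )
    rec, drops = build_before_after_records(fx, turbines, raster)
    assert len(rec) == 0
    assert drops["outside_buffer"] == 1


def test_before_after_matches_brute_force_pairing(world):
    turbines, raster = world
    rng = np.random.default_rng(9)
    n = 400
    fx = pd.DataFrame(
        {
            "bird_id": "B1",
            "timestamp": pd.Timestamp("2018-01-01 12:00"),
            "easting": rng.uniform(-1500, 6000, n),
            "northing": rng.uniform(-1500, 6000, n),
            "altitude_asl": rng.uniform(500, 1200, n),
        }
    )
    rec, drops = build_before_after_records(fx, turbines, raster)
    # exhaustive all-pairs oracle
    expected = []
    for i in range(n):
        best = min(
            turbines,
            key=lambda t: np.hypot(fx.easting[i] - t.easting, fx.northing[i] - t.northing),
        )
        d2 = np.hypot(fx.easting[i] - best.easting, fx.northing[i] - best.northing)
        if d2 <= 1000.0:
            expected.append((i, best.turbine_id, fix_to_hub_3d(
                fx.easting[i], fx.northing[i], fx.altitude_asl[i], best).d3d))
    assert len(rec) == len(expected)
    assert rec["turbine_id"].tolist() == [e[1] for e in expected]
    assert rec["d3d"].to_numpy() == pytest.approx([e[2] for e in expected])
    assert drops["outside_buffer"] + len(rec) + drops["raster_miss"] == n


def test_buffer_shrinking_never_adds_records(world):
    turbines, raster = world
    rng = np.random.default_rng(10)
    fx = pd.DataFrame(
        {
            "bird_id": "B1",
            "timestamp": pd.Timestamp("2018-01-01 12:00"),
            "easting": rng.uniform(-1500, 6000, 300),
            "northing": rng.uniform(-1500, 6000, 300),
            "altitude_asl": 800.0,
        }
    )
    sizes = [
        len(build_before_after_records(fx, turbines, raster, buffer=b)[0])
        for b in (1500.0, 1000.0, 500.0, 100.0)
    ]
    assert sizes == sorted(sizes, reverse=True)


@pytest.fixture()
def scada(world):
    turbines, _ = world
    times = pd.date_range("2018-06-01", "2018-06-03", freq="3h")
    rows = []
    for t in turbines:
        for ts in times:
            rows.append((t.turbine_id, ts, 8.0, 10.0))
    return StatusTable(pd.DataFrame(rows, columns=["turbine_id", "timestamp", "wind_speed", "rotor_speed"]))


def test_after_records_rounding_chain(world, scada):
    turbines, raster = world
    # segment passing 300 m from T1 at fraction 0.5 of 240 s starting 11:58
    seg = pd.DataFrame(
        {
            "bird_id": ["B1"],
            "t_start": pd.to_datetime(["2018-06-02 11:58:00"]),
            "t_end": pd.to_datetime(["2018-06-02 12:02:00"]),
            "duration_s": [240.0],
            "x0": [-100.0], "y0": [300.0], "alt0": [720.0],
            "x1": [100.0], "y1": [300.0], "alt1": [680.0],
        }
    )
    rec, drops = build_after_records(seg, turbines, raster, scada)
    assert len(rec) == 1
    assert rec["timestamp"].iloc[0] == pd.Timestamp("2018-06-02 12:00:00")
    assert rec["wind_speed"].iloc[0] == 8.0
    assert rec["blade_status"].iloc[0] == "moving"
    assert rec["d2d"].iloc[0] == pytest.approx(300.0)


def test_after_records_missing_scada_dropped_and_counted(world, scada):
    turbines, raster = world
    seg = pd.DataFrame(
        {
            "bird_id": ["B1"],
            "t_start": pd.to_datetime(["2019-01-01 12:00:00"]),  # outside SCADA period
            "t_end": pd.to_datetime(["2019-01-01 12:02:00"]),
            "duration_s": [120.0],
            "x0": [-100.0], "y0": [300.0], "alt0": [700.0],
            "x1": [100.0], "y1": [300.0], "alt1": [700.0],
        }
    )
    rec, drops = build_after_records(seg, turbines, raster, scada)
    assert len(rec) == 0
    assert drops["scada_missing"] == 1


def test_after_records_recount_oracle(small_world, qc_fixes):
    raster, turbines, status, _ = small_world
    seg = build_segments(qc_fixes[qc_fixes["tag_type"] == "GSM"])
    rec, drops = build_after_records(seg, turbines, raster, StatusTable(status))
    total = len(rec) + sum(drops.values())
    assert total == len(seg)
    assert rec["d3d"].ge(rec["d2d"] - 1e-9).all()
    assert set(rec["blade_status"]) <= {"still", "moving"}


# -- descriptive summaries ------------------------------------------------

def test_summarize_distances_basic():
    rec = pd.DataFrame({"d3d": [100.0, 200.0, 300.0], "g": "a"})
    s = summarize_distances(rec, keys=["g"])
    assert s.loc["a", "mean"] == pytest.approx(200.0)
    assert s.loc["a", "n"] == 3
    const = summarize_distances(pd.DataFrame({"d3d": [5.0, 5.0]}))
    assert const["sd"].iloc[0] == 0.0


def test_summarize_percentiles_match_sorting_oracle():
    rng = np.random.default_rng(2)
    v = rng.lognormal(6.0, 0.5, 5000)
    s = summarize_distances(pd.DataFrame({"d3d": v}))
    sv = np.sort(v)
    # order-statistics oracle with linear interpolation
    def q(p):
        h = (len(sv) - 1) * p
        lo = int(np.floor(h))
        return sv[lo] + (h - lo) * (sv[min(lo + 1, len(sv) - 1)] - sv[lo])
    assert s["range95_lo"].iloc[0] == pytest.approx(q(0.025))
    assert s["range95_hi"].iloc[0] == pytest.approx(q(0.975))


def test_proportion_within_diameters_boundaries():
    rec = pd.DataFrame({"d3d": [79.0, 80.0, 81.0], "rotor_diameter": 80.0})
    cnt, prop = proportion_within_diameters(rec, k=1)
    assert cnt == 1 and prop == pytest.approx(1 / 3)  # strict <: 80.0 not counted
    cnt2, _ = proportion_within_diameters(rec, k=2)
    assert cnt2 == 3


def test_quantile_by_group_rules():
    rec = pd.DataFrame(
        {"d3d": np.arange(100.0, 1100.0, 100.0), "farm_id": "f", "blade_status": "still"}
    )
    q = quantile_by_group(rec, q=0.1)
    # linear interpolation between order statistics: index 0.9 -> 190
    assert q[("f", "still")] == pytest.approx(190.0)
    q0 = quantile_by_group(rec, q=0.0)
    assert q0[("f", "still")] == 100.0


def test_quantile_matches_distribution():
    rng = np.random.default_rng(12)
    v = rng.normal(500, 100, 40000)
    rec = pd.DataFrame({"d3d": v, "farm_id": "f", "blade_status": "x"})
    q = quantile_by_group(rec, q=0.025)
    from scipy import stats

    assert q.iloc[0] == pytest.approx(stats.norm.ppf(0.025, 500, 100), abs=5.0)
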