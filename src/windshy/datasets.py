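"""Assembly of the two modelling datasets and descriptive summaries.

Two analysis tables are built from QC-passed telemetry:

* **before/after (fix-based)** — every fix whose nearest turbine (2-D
  planar distance) lies within a 1-km buffer becomes one row: 3-D distance
  to that turbine's hub, BEFORE/AFTER phase relative to the turbine's
  operation date, and GET habitat scores at the turbine and at the fix.

* **after-operation (flight-line based)** — consecutive GSM fixes no more
  than 5 min apart are joined into straight flight segments; each segment
  within the buffer of its nearest turbine (by 2-D closest approach)
  becomes one row carrying the 3-D closest-pass distance, the GET score
  under the pass location, and the turbine's wind speed and blade-motion
  status at the pass time rounded to the SCADA 3-h grid.

Each fix/segment contributes at most one row (its nearest turbine), and
all drops (outside buffer, nodata raster, missing SCADA, pre-operation)
are counted so the report reconciles with the input exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geometry import closest_approach_2d, distance_3d, hub_altitude
from .habitat import GETRaster, turbine_get_score
from .turbines import Phase, StatusTable, Turbine, round_to_3h_array

log = logging.getLogger(__name__)

BUFFER_M = 1000.0
MAX_SEGMENT_GAP_S = 300.0


def build_segments(fixes: pd.DataFrame, max_gap: float = MAX_SEGMENT_GAP_S) -> pd.DataFrame:
    """Flight segments between consecutive fixes of the same bird.

    Pairs more than ``max_gap`` seconds apart are excluded (the straight
    line approximation degrades with gap length).  Returns one row per
    retained pair with start/end coordinates, altitudes and times.
    """
    f = fixes.sort_values(["bird_id", "timestamp"], kind="mergesort")
    g = f.groupby("bird_id", sort=False)
    nxt = g.shift(-1)
    same = nxt["timestamp"].notna()
    gap = (nxt["timestamp"] - f["timestamp"]).dt.total_seconds()
    keep = same & (gap > 0) & (gap <= max_gap)
    seg = pd.DataFrame(
        {
            "bird_id": f["bird_id"][keep],
            "t_start": f["timestamp"][keep],
            "t_end": nxt["timestamp"][keep],
            "duration_s": gap[keep],
            "x0": f["easting"][keep],
            "y0": f["northing"][keep],
            "alt0": f["altitude_asl"][keep],
            "x1": nxt["easting"][keep],
            "y1": nxt["northing"][keep],
            "alt1": nxt["altitude_asl"][keep],
        }
    ).reset_index(drop=True)
    return seg


def _turbine_arrays(turbines: list[Turbine]):
    tx = np.array([t.easting for t in turbines])
    ty = np.array([t.northing for t in turbines])
    hub_alt = np.array([hub_altitude(t) for t in turbines])
    return tx, ty, hub_alt


def _phase_after(ts: np.ndarray, turbines: list[Turbine], idx: np.ndarray) -> np.ndarray:
    """Boolean AFTER mask for timestamps paired with turbines[idx]."""
    op = np.array(
        [
            np.datetime64(t.operation_date, "s") if t.operation_date is not None
            else np.datetime64("9999-01-01", "s")
            for t in turbines
        ]
    )
    return np.asarray(ts, dtype="datetime64[s]") >= op[idx]


def build_before_after_records(
    fixes: pd.DataFrame,
    turbines: list[Turbine],
    raster: GETRaster,
    buffer: float = BUFFER_M,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One proximity row per fix whose nearest turbine lies within the buffer.

    Returns ``(records, drops)`` with drops counted by reason
    (``outside_buffer``, ``raster_miss``); counts reconcile with the input.
    """
    tx, ty, hub_alt = _turbine_arrays(turbines)
    x = fixes["easting"].to_numpy(float)
    y = fixes["northing"].to_numpy(float)
    d2 = np.hypot(x[:, None] - tx[None, :], y[:, None] - ty[None, :])
    nearest = d2.argmin(axis=1)
    d2d = d2[np.arange(len(x)), nearest]

    in_buf = d2d <= buffer
    drops = {"outside_buffer": int((~in_buf).sum()), "raster_miss": 0}

    get_loc = raster.values_at(x[in_buf], y[in_buf])
    ok = get_loc > 0
    drops["raster_miss"] = int((~ok).sum())

    sel = np.flatnonzero(in_buf)[ok]
    ni = nearest[sel]
    alt = fixes["altitude_asl"].to_numpy(float)[sel]
    d3d = distance_3d(d2d[sel], alt, hub_alt[ni])
    turb_get = {t.turbine_id: turbine_get_score(raster, t) for t in turbines}
    ts = fixes["timestamp"].to_numpy()[sel]
    after = _phase_after(ts, turbines, ni)

    records = pd.DataFrame(
        {
            "bird_id": fixes["bird_id"].to_numpy()[sel],
            "farm_id": [turbines[i].farm_id for i in ni],
            "turbine_id": [turbines[i].turbine_id for i in ni],
            "phase": np.where(after, Phase.AFTER.value, Phase.BEFORE.value),
            "postop": after.astype(int),
            "d2d": d2d[sel],
            "d3d": d3d,
            "get_turbine": [turb_get[turbines[i].turbine_id] for i in ni],
            "get_location": get_loc[ok],
            "rotor_diameter": [turbines[i].rotor_diameter for i in ni],
            "timestamp": ts,
        }
    )
    return records, drops


def build_after_records(
    segments: pd.DataFrame,
    turbines: list[Turbine],
    raster: GETRaster,
    status: StatusTable,
    buffer: float = BUFFER_M,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One proximity row per flight segment within the buffer of its nearest
    turbine, with SCADA wind/blade state joined at the 3-h-rounded pass time.

    Segments are paired with the turbine of smallest 2-D closest-approach
    distance.  Rows are dropped (and counted) when the pass is outside the
    buffer, the turbine is not yet operational at the pass time, SCADA is
    missing for the rounded instant, or the raster has no data under the
    pass point.
    """
    tx, ty, hub_alt = _turbine_arrays(turbines)
    n = len(segments)
    ax = segments["x0"].to_numpy(float)
    ay = segments["y0"].to_numpy(float)
    bx = segments["x1"].to_numpy(float)
    by = segments["y1"].to_numpy(float)

    frac = np.empty((n, len(turbines)))
    d2 = np.empty((n, len(turbines)))
    for j in range(len(turbines)):
        frac[:, j], d2[:, j] = closest_approach_2d(tx[j], ty[j], ax, ay, bx, by)
    nearest = d2.argmin(axis=1)
    rows = np.arange(n)
    d2d = d2[rows, nearest]
    fr = frac[rows, nearest]

    in_buf = d2d <= buffer
    drops = {
        "outside_buffer": int((~in_buf).sum()),
        "pre_operational": 0,
        "scada_missing": 0,
        "raster_miss": 0,
    }

    sel = np.flatnonzero(in_buf)
    ni = nearest[sel]
    alt0 = segments["alt0"].to_numpy(float)[sel]
    alt1 = segments["alt1"].to_numpy(float)[sel]
    alt_pass = alt0 + fr[sel] * (alt1 - alt0)
    d3d = distance_3d(d2d[sel], alt_pass, hub_alt[ni])

    t0 = segments["t_start"].to_numpy()[sel].astype("datetime64[s]")
    dur = segments["duration_s"].to_numpy(float)[sel]
    t_pass = t0 + (fr[sel] * dur).round().astype("timedelta64[s]")
    t_key = round_to_3h_array(t_pass)

    after = _phase_after(t_pass, turbines, ni)
    px = ax[sel] + fr[sel] * (bx[sel] - ax[sel])
    py = ay[sel] + fr[sel] * (by[sel] - ay[sel])
    get_loc = raster.values_at(px, py)
    turb_get = {t.turbine_id: turbine_get_score(raster, t) for t in turbines}

    out = []
    for k in range(len(sel)):
        if not after[k]:
            drops["pre_operational"] += 1
            continue
        if get_loc[k] < 1:
            drops["raster_miss"] += 1
            continue
        turb = turbines[ni[k]]
        rec = status.lookup(turb.turbine_id, pd.Timestamp(t_key[k]).to_pydatetime())
        if rec is None or rec.blade_status is None:
            drops["scada_missing"] += 1
            continue
        out.append(
            (
                segments["bird_id"].to_numpy()[sel][k],
                turb.farm_id,
                turb.turbine_id,
                float(d2d[sel[k]]),
                float(d3d[k]),
                turb_get[turb.turbine_id],
                int(get_loc[k]),
                rec.wind_speed,
                rec.blade_status.value,
                int(rec.blade_status.value == "moving"),
                turb.rotor_diameter,
                pd.Timestamp(t_key[k]),
            )
        )
    records = pd.DataFrame(
        out,
        columns=[
            "bird_id", "farm_id", "turbine_id", "d2d", "d3d",
            "get_turbine", "get_location", "wind_speed", "blade_status",
            "turning", "rotor_diameter", "timestamp",
        ],
    )
    return records, drops


def summarize_distances(
    records: pd.DataFrame, keys: list[str] | None = None, value: str = "d3d"
) -> pd.DataFrame:
    """Per-group mean, sample sd, empirical 2.5-97.5% range and count.

    The "range95" is the empirical 2.5th/97.5th percentile of the data —
    a descriptive spread, not a standard error band.  Empty inputs yield
    an empty frame; empty groups are simply absent.
    """
    def agg(g: pd.Series) -> pd.Series:
        v = g.to_numpy(float)
        return pd.Series(
            {
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "range95_lo": np.quantile(v, 0.025),
                "range95_hi": np.quantile(v, 0.975),
                "n": len(v),
            }
        )

    if len(records) == 0:
        return pd.DataFrame(columns=["mean", "sd", "range95_lo", "range95_hi", "n"])
    if keys:
        out = records.groupby(keys)[value].apply(agg).unstack()
    else:
        out = agg(records[value]).to_frame().T
    out["n"] = out["n"].astype(int)
    return out


def proportion_within_diameters(
    records: pd.DataFrame, k: float = 1.0, value: str = "d3d"
) -> tuple[int, float]:
    """Count and proportion of records closer than k rotor diameters
    (strict ``<``) to their paired turbine's hub."""
    if len(records) == 0:
        return 0, float("nan")
    within = records[value].to_numpy(float) < k * records["rotor_diameter"].to_numpy(float)
    return int(within.sum()), float(within.mean())


def quantile_by_group(
    records: pd.DataFrame,
    q: float = 0.025,
    keys: list[str] = ("farm_id", "blade_status"),
    value: str = "d3d",
) -> pd.Series:
    """Empirical q-quantile of distance per group (linear interpolation
    between order statistics, the numpy default)."""
    return records.groupby(list(keys))[value].quantile(q)
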