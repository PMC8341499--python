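"""Synthetic landscapes, wind farms, SCADA series and eagle telemetry.

The generator emulates the four input streams of the analysis — a
spatially autocorrelated 1-10 habitat-preference raster at 50-m pixels,
two wind-farm layouts, 3-hourly per-turbine wind/rotor records with
cut-in-driven blade stoppage, and GPS telemetry from tagged eagles — with
the statistical structure the pipeline assumes, so every stage and the
model layer's recovery properties are testable without any field data.

Movement is a biased correlated random walk run in independent "bouts"
(visits to the study area scattered over the simulated period): at each
step, candidate headings are weighted by

    exp( kappa*cos(dh) + alpha*GET(x) - penalty(x, t) - centre pull )

where ``penalty = beta * exp(-d_op / rho)`` repels from the nearest
*operational* turbine (distance d_op, decay range rho), applies only after
that turbine's operation date, and is scaled down at high wind speed by
``(1 - wind_coupling * wind/12)``.  This is the simplest mechanism that
produces the qualitative structure the analysis targets — displacement
after operation, weakened in preferred habitat and at higher wind — and is
a modelling convenience, not a claim about eagle cognition.

True positions are kept alongside the HDOP-degraded observed ones so
pipeline estimates can be checked against simulated truth.  Everything is
deterministic for a given seed (one ``numpy.random.default_rng`` stream
consumed in a fixed order).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .habitat import GETRaster, write_ascii_grid
from .turbines import Turbine

# mock affine "projection" anchoring planar metres to WGS84 degrees so the
# daylight filter is exercisable; documented, not a real map projection
LAT0, LON0 = 57.15, -4.35
M_PER_DEG_LAT = 111320.0


@dataclass(frozen=True)
class FarmSpec:
    """Layout and milestone dates for one simulated wind farm."""

    farm_id: str
    n_turbines: int
    hub_height_agl: float
    blade_length: float
    erection_date: date
    operation_date: date | None
    centre: tuple[float, float]
    spacing_m: float = 350.0
    base_elev_range: tuple[float, float] = (650.0, 750.0)


def study_farms() -> list[FarmSpec]:
    """Presets shaped like the study system: a 33-turbine farm (80 m hubs,
    40 m blades) and a 66-turbine farm (73 m hubs, 57.5 m blades)."""
    return [
        FarmSpec("dunmaglass", 33, 80.0, 40.0, date(2016, 5, 1), date(2016, 11, 7),
                 centre=(3200.0, 4000.0)),
        FarmSpec("stronelairg", 66, 73.0, 57.5, date(2017, 9, 21), date(2018, 6, 1),
                 centre=(8800.0, 4000.0)),
    ]


def scaled_farms(n1: int = 10, n2: int = 16) -> list[FarmSpec]:
    """Reduced-turbine-count variants of the study layouts for fast runs."""
    f1, f2 = study_farms()
    return [
        dataclasses.replace(f1, n_turbines=n1),
        dataclasses.replace(f2, n_turbines=n2),
    ]


@dataclass
class SimConfig:
    """All generator knobs; defaults mirror the study conditions."""

    seed: int = 0
    # landscape: 12 x 8 km at 50-m pixels
    nx: int = 240
    ny: int = 160
    cellsize: float = 50.0
    origin: tuple[float, float] = (0.0, 0.0)
    autocorr_length_m: float = 400.0
    score_freqs: tuple[float, ...] = (
        0.10, 0.14, 0.16, 0.15, 0.13, 0.10, 0.08, 0.06, 0.05, 0.03,
    )
    farms: list[FarmSpec] = field(default_factory=study_farms)
    # wind: Weibull marginal with AR(1) persistence on the 3-h grid
    weibull_scale: float = 8.0
    weibull_shape: float = 2.0
    wind_ar1: float = 0.7
    cut_in_speed: float = 3.5
    maintenance_stop_prob: float = 0.02
    # movement
    step_scale_m: float = 500.0
    turning_kappa: float = 0.5
    n_heading_candidates: int = 16
    alpha_get: float = 0.25
    beta_avoid: float = 4.0
    rho_avoid_m: float = 300.0
    wind_coupling: float = 0.5
    centre_pull: float = 1.0
    bout_steps: int = 60
    # altitude (asl, metres)
    alt_mean_asl: float = 780.0
    alt_sd: float = 60.0
    alt_ar1: float = 0.3
    alt_wind_coupling: float = 3.0
    # sampling
    n_gsm_birds: int = 9
    n_argos_birds: int = 14
    gsm_interval_s: int = 60
    argos_interval_s: int = 3600
    fixes_per_gsm_bird: int = 1500
    fixes_per_argos_bird: int = 400
    period_start: date = date(2016, 6, 1)
    period_end: date = date(2019, 6, 1)
    # observation model
    hdop_log_mu: float = 0.45
    hdop_log_sigma: float = 0.35
    hdop_high_frac: float = 0.08  # fraction of fixes with HDOP >= 3.5
    gps_noise_per_hdop_m: float = 6.0
    alt_noise_m: float = 15.0
    alt_missing_frac: float = 0.02

    def __post_init__(self):
        if abs(sum(self.score_freqs) - 1.0) > 1e-9 or len(self.score_freqs) != 10:
            raise ValueError("score_freqs must be 10 frequencies summing to 1")
        for name in ("step_scale_m", "rho_avoid_m", "weibull_scale", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("maintenance_stop_prob", "hdop_high_frac", "alt_missing_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# -- landscape ------------------------------------------------------------

def gen_landscape(config: SimConfig, rng: np.random.Generator) -> GETRaster:
    """Smoothed Gaussian random field quantised to GET scores 1-10.

    White noise is smoothed with a Gaussian kernel of the configured
    autocorrelation length, rank-transformed to uniform, and cut at the
    cumulative configured score frequencies.
    """
    z = rng.standard_normal((config.ny, config.nx))
    sigma_px = config.autocorr_length_m / config.cellsize
    if sigma_px > 1e-9:
        z = ndimage.gaussian_filter(z, sigma=sigma_px, mode="reflect")
    ranks = stats.rankdata(z.ravel(), method="average") / (z.size + 1)
    cuts = np.cumsum(config.score_freqs)[:-1]
    scores = (np.searchsorted(cuts, ranks, side="left") + 1).reshape(z.shape)
    return GETRaster(
        data=scores.astype(int),
        xll=config.origin[0],
        yll=config.origin[1],
        cellsize=config.cellsize,
    )


# -- wind farm layouts ----------------------------------------------------

def gen_windfarm(
    config: SimConfig, raster: GETRaster, rng: np.random.Generator
) -> list[Turbine]:
    """Jittered grid layouts per farm spec; outer-ring turbines labelled in
    the id suffix so layout-sensitivity checks can distinguish them."""
    xmin, ymin, xmax, ymax = raster.extent
    turbines: list[Turbine] = []
    for farm in config.farms:
        ncol = int(np.ceil(np.sqrt(farm.n_turbines * 1.8)))
        nrow = int(np.ceil(farm.n_turbines / ncol))
        cx, cy = farm.centre
        k = 0
        for r in range(nrow):
            for c in range(ncol):
                if k >= farm.n_turbines:
                    break
                x = cx + (c - (ncol - 1) / 2) * farm.spacing_m
                y = cy + (r - (nrow - 1) / 2) * farm.spacing_m
                x += rng.uniform(-0.15, 0.15) * farm.spacing_m
                y += rng.uniform(-0.15, 0.15) * farm.spacing_m
                if not (xmin + 2 * raster.cellsize < x < xmax - 2 * raster.cellsize
                        and ymin + 2 * raster.cellsize < y < ymax - 2 * raster.cellsize):
                    raise ValueError(f"farm {farm.farm_id} layout leaves the raster")
                outer = r in (0, nrow - 1) or c in (0, ncol - 1)
                tid = f"{farm.farm_id[:4].upper()}_{'O' if outer else 'I'}{k + 1:02d}"
                turbines.append(
                    Turbine(
                        turbine_id=tid,
                        farm_id=farm.farm_id,
                        easting=float(x),
                        northing=float(y),
                        base_elevation_asl=float(rng.uniform(*farm.base_elev_range)),
                        hub_height_agl=farm.hub_height_agl,
                        blade_length=farm.blade_length,
                        erection_date=farm.erection_date,
                        operation_date=farm.operation_date,
                    )
                )
                k += 1
    return turbines


# -- SCADA ----------------------------------------------------------------

def gen_weather_status(
    config: SimConfig,
    turbines: list[Turbine],
    period: tuple[date, date] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """3-hourly wind/rotor records per turbine over the period.

    One AR(1) Gaussian series per farm drives a Weibull-marginal wind
    speed (hub anemometers within a farm are strongly correlated; a small
    per-turbine jitter is added).  Rotor speed is 0 below the cut-in wind
    speed or during randomly sampled maintenance records, else increases
    with wind.  Columns: turbine_id, timestamp, wind_speed, rotor_speed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    start, end = period or (config.period_start, config.period_end)
    t0 = datetime(start.year, start.month, start.day, tzinfo=timezone.utc)
    n_steps = int((datetime(end.year, end.month, end.day, tzinfo=timezone.utc) - t0)
                  / timedelta(hours=3))
    times = pd.date_range(t0, periods=n_steps, freq="3h").tz_localize(None)

    phi = config.wind_ar1
    frames = []
    farms = sorted({t.farm_id for t in turbines})
    for farm in farms:
        z = np.empty(n_steps)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(n_steps - 1) * np.sqrt(1 - phi**2)
        for i in range(1, n_steps):
            z[i] = phi * z[i - 1] + eps[i - 1]
        u = stats.norm.cdf(z)
        wind_farm = stats.weibull_min.ppf(u, c=config.weibull_shape,
                                          scale=config.weibull_scale)
        for t in [tt for tt in turbines if tt.farm_id == farm]:
            wind = np.clip(wind_farm + rng.normal(0.0, 0.3, n_steps), 0.0, None)
            # classify against the value as reported (2 dp) so the stored
            # wind/rotor pair is always internally consistent
            wind = wind.round(2)
            maint = rng.random(n_steps) < config.maintenance_stop_prob
            still = (wind < config.cut_in_speed) | maint
            rotor = np.where(still, 0.0, np.clip(5.0 + 0.8 * wind, 0.0, 14.0))
            # operational turbines only report from their operation date
            frames.append(
                pd.DataFrame(
                    {
                        "turbine_id": t.turbine_id,
                        "timestamp": times,
                        "wind_speed": wind,
                        "rotor_speed": rotor.round(2),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out


# -- telemetry ------------------------------------------------------------

def _daylightish_start(rng: np.random.Generator, day: date) -> datetime:
    """Bout start within the broad local activity window 05-17 UTC (some
    winter starts fall before sunrise, exercising the night filter)."""
    hour = rng.uniform(5.0, 17.0)
    return datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(hours=hour)


def simulate_tracks(
    config: SimConfig,
    raster: GETRaster,
    turbines: list[Turbine],
    status: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Biased correlated-random-walk telemetry for all simulated birds.

    Returns the canonical telemetry frame (see :mod:`windshy.telemetry`)
    plus ``x_true``/``y_true``/``alt_true`` columns carrying the
    noise-free simulated state.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    xmin, ymin, xmax, ymax = raster.extent
    margin = 2 * config.cellsize
    tx = np.array([t.easting for t in turbines])
    ty = np.array([t.northing for t in turbines])
    t_op = np.array(
        [
            np.datetime64(t.operation_date, "s") if t.operation_date else np.datetime64("9999-01-01", "s")
            for t in turbines
        ]
    )
    farm_of = np.array([t.farm_id for t in turbines])
    farms = sorted(set(farm_of))
    centres = {f.farm_id: f.centre for f in config.farms}

    # farm-level mean wind by 3-h key, for the wind/avoidance coupling
    st = status.copy()
    st["farm_id"] = st["turbine_id"].map({t.turbine_id: t.farm_id for t in turbines})
    farm_wind = st.groupby(["farm_id", "timestamp"])["wind_speed"].mean()

    n_days = (config.period_end - config.period_start).days
    headings = np.arange(config.n_heading_candidates) / config.n_heading_candidates * 2 * np.pi

    rows = []
    bird_plans = [("GSM", f"G{i+1:02d}", config.fixes_per_gsm_bird, config.gsm_interval_s)
                  for i in range(config.n_gsm_birds)]
    bird_plans += [("ARGOS", f"A{i+1:02d}", config.fixes_per_argos_bird, config.argos_interval_s)
                   for i in range(config.n_argos_birds)]

    for tag_type, bird_id, n_fixes, interval in bird_plans:
        made = 0
        while made < n_fixes:
            day = config.period_start + timedelta(days=int(rng.integers(0, n_days)))
            t = _daylightish_start(rng, day)
            farm_pick = farms[int(rng.integers(0, len(farms)))]
            cx, cy = centres[farm_pick]
            x = float(np.clip(cx + rng.uniform(-2500, 2500), xmin + margin, xmax - margin))
            y = float(np.clip(cy + rng.uniform(-2500, 2500), ymin + margin, ymax - margin))
            alt = rng.normal(config.alt_mean_asl, config.alt_sd)
            heading = rng.uniform(0, 2 * np.pi)
            t3 = pd.Timestamp(t).tz_localize(None).floor("3h")
            wind_here = float(farm_wind.get((farm_pick, t3), config.weibull_scale * 0.886))
            windfac = max(0.0, 1.0 - config.wind_coupling * min(wind_here, 12.0) / 12.0)

            steps = min(config.bout_steps, n_fixes - made)
            for _ in range(steps):
                L = rng.gamma(2.0, config.step_scale_m / 2.0)
                # rotate the candidate fan randomly each step so the walk is
                # not confined to a fixed set of absolute directions
                cand = headings + rng.uniform(0, 2 * np.pi / len(headings))
                cxs = x + L * np.cos(cand)
                cys = y + L * np.sin(cand)
                inside = (cxs > xmin + margin) & (cxs < xmax - margin) & \
                         (cys > ymin + margin) & (cys < ymax - margin)
                get = raster.values_at(cxs, cys).astype(float)
                w = config.turning_kappa * np.cos(cand - heading) + config.alpha_get * get
                now64 = np.datetime64(t.replace(tzinfo=None), "s")
                op = t_op <= now64
                if op.any() and config.beta_avoid != 0.0:
                    d_op = np.min(
                        np.hypot(cxs[:, None] - tx[None, op], cys[:, None] - ty[None, op]),
                        axis=1,
                    )
                    w = w - config.beta_avoid * windfac * np.exp(-d_op / config.rho_avoid_m)
                dc = np.hypot(cxs - cx, cys - cy)
                w = w - config.centre_pull * (dc / 3000.0) ** 2
                w[~inside] = -np.inf
                p = np.exp(w - w.max())
                p /= p.sum()
                pick = int(rng.choice(len(cand), p=p))
                x, y, heading = float(cxs[pick]), float(cys[pick]), float(cand[pick])
                alt = (
                    config.alt_mean_asl
                    + config.alt_wind_coupling * (wind_here - config.weibull_scale * 0.886)
                    + config.alt_ar1 * (alt - config.alt_mean_asl)
                    + rng.normal(0.0, config.alt_sd * np.sqrt(1 - config.alt_ar1**2))
                )

                hdop = (
                    rng.uniform(3.5, 8.0)
                    if rng.random() < config.hdop_high_frac
                    else float(np.exp(rng.normal(config.hdop_log_mu, config.hdop_log_sigma)))
                )
                noise = config.gps_noise_per_hdop_m * hdop
                x_obs = x + rng.normal(0.0, noise)
                y_obs = y + rng.normal(0.0, noise)
                alt_obs = alt + rng.normal(0.0, config.alt_noise_m)
                if rng.random() < config.alt_missing_frac:
                    alt_obs = np.nan
                lat = LAT0 + (y_obs - config.origin[1]) / M_PER_DEG_LAT
                lon = LON0 + (x_obs - config.origin[0]) / (
                    M_PER_DEG_LAT * np.cos(np.deg2rad(LAT0))
                )
                rows.append(
                    (
                        bird_id, t.replace(tzinfo=None), x_obs, y_obs, lat, lon,
                        alt_obs, round(hdop, 2), tag_type, x, y, alt,
                    )
                )
                made += 1
                t = t + timedelta(seconds=interval)

    df = pd.DataFrame(
        rows,
        columns=[
            "bird_id", "timestamp", "easting", "northing", "lat", "lon",
            "altitude_asl", "hdop", "tag_type", "x_true", "y_true", "alt_true",
        ],
    )
    df = df.sort_values(["bird_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return df


# -- bundles --------------------------------------------------------------

def _config_to_jsonable(config: SimConfig) -> dict:
    def conv(v):
        if isinstance(v, date):
            return v.isoformat()
        if isinstance(v, tuple):
            return list(v)
        return v

    d = dataclasses.asdict(config)
    out = {}
    for k, v in d.items():
        if k == "farms":
            out[k] = [
                {kk: conv(vv) for kk, vv in farm.items()} for farm in v
            ]
        else:
            out[k] = conv(v)
    return out


def generate_all(config: SimConfig):
    """Run the full generator chain from one seed lineage.

    Returns ``(raster, turbines, status_frame, telemetry_frame)``.
    """
    rng = np.random.default_rng(config.seed)
    raster = gen_landscape(config, rng)
    turbines = gen_windfarm(config, raster, rng)
    status = gen_weather_status(config, turbines, rng=rng)
    fixes = simulate_tracks(config, raster, turbines, status, rng=rng)
    return raster, turbines, status, fixes


def write_fixture_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete input bundle to ``outdir``.

    Files: telemetry.csv, turbines.csv, scada.csv, get_raster.asc and
    manifest.json (seed and full parameter echo).  Byte-identical for a
    given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raster, turbines, status, fixes = generate_all(config)

    paths = {
        "telemetry": outdir / "telemetry.csv",
        "turbines": outdir / "turbines.csv",
        "scada": outdir / "scada.csv",
        "raster": outdir / "get_raster.asc",
        "manifest": outdir / "manifest.json",
    }
    fixes.to_csv(paths["telemetry"], index=False, float_format="%.3f")
    pd.DataFrame(
        [
            {
                "turbine_id": t.turbine_id,
                "farm_id": t.farm_id,
                "easting": round(t.easting, 2),
                "northing": round(t.northing, 2),
                "base_elevation_asl": round(t.base_elevation_asl, 1),
                "hub_height_agl": t.hub_height_agl,
                "blade_length": t.blade_length,
                "erection_date": t.erection_date.isoformat() if t.erection_date else "",
                "operation_date": t.operation_date.isoformat() if t.operation_date else "",
            }
            for t in turbines
        ]
    ).to_csv(paths["turbines"], index=False)
    status.to_csv(paths["scada"], index=False)
    write_ascii_grid(raster, paths["raster"])
    manifest = {"seed": config.seed, "config": _config_to_jsonable(config)}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
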