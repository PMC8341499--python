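"""Turbine metadata, 3-hourly SCADA state, and before/after phase logic.

Turbines carry static geometry (position, base elevation asl, hub height
agl, blade length) and two milestone dates: erection and first operation.
Telemetry records are classified BEFORE operation (which includes the
construction period — a conservative choice for displacement tests, since
construction disturbance can only shrink the before/after contrast) or
AFTER, relative to each turbine's own operation date.

SCADA wind speed and rotor speed arrive on a 3-hour grid; record times are
rounded to the nearest grid instant (ties, exactly 90 min, round up) and
joined by exact key.  Rotor speed is binarised to STILL/MOVING at a
configurable threshold (default: any positive rotation counts as moving).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

THREE_HOURS_S = 3 * 3600


class Phase(enum.Enum):
    BEFORE = "before"
    AFTER = "after"


class BladeStatus(enum.Enum):
    STILL = "still"
    MOVING = "moving"


@dataclass(frozen=True)
class Turbine:
    turbine_id: str
    farm_id: str
    easting: float
    northing: float
    base_elevation_asl: float
    hub_height_agl: float
    blade_length: float
    erection_date: date | None = None
    operation_date: date | None = None

    def __post_init__(self):
        if self.blade_length <= 0:
            raise ValueError(f"turbine {self.turbine_id}: blade_length must be > 0")
        if (
            self.erection_date is not None
            and self.operation_date is not None
            and self.operation_date < self.erection_date
        ):
            raise ValueError(f"turbine {self.turbine_id}: operation before erection")

    @property
    def rotor_diameter(self) -> float:
        return 2.0 * self.blade_length


@dataclass(frozen=True)
class StatusRecord:
    turbine_id: str
    timestamp: datetime
    wind_speed: float
    rotor_speed: float | None
    blade_status: BladeStatus | None


def _as_utc(t: datetime) -> datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def classify_phase(t: datetime, turbine: Turbine) -> Phase:
    """BEFORE iff t is strictly earlier than the operation instant.

    The operation date is promoted to midnight UTC.  A turbine with no
    operation date (never operational) classifies every instant BEFORE.
    The boundary instant itself is AFTER.
    """
    if turbine.operation_date is None:
        return Phase.BEFORE
    op = datetime(
        turbine.operation_date.year,
        turbine.operation_date.month,
        turbine.operation_date.day,
        tzinfo=timezone.utc,
    )
    return Phase.BEFORE if _as_utc(t) < op else Phase.AFTER


def round_to_3h(t: datetime) -> datetime:
    """Round an instant to the nearest 3-h UTC grid point; 90-min ties go up."""
    tu = _as_utc(t)
    secs = tu.timestamp()
    rounded = np.floor((secs + THREE_HOURS_S / 2) / THREE_HOURS_S) * THREE_HOURS_S
    return datetime.fromtimestamp(rounded, tz=timezone.utc)


def round_to_3h_array(ts: pd.Series | np.ndarray) -> np.ndarray:
    """Vectorised :func:`round_to_3h` for datetime64 arrays (UTC)."""
    s = np.asarray(pd.to_datetime(ts).values, dtype="datetime64[s]").astype("int64")
    rounded = (s + THREE_HOURS_S // 2) // THREE_HOURS_S * THREE_HOURS_S
    return rounded.astype("datetime64[s]")


def blade_status_from_rotor(
    rotor_speed: float | None, still_threshold_rpm: float = 0.0
) -> BladeStatus | None:
    """Binarise rotor speed: STILL iff speed <= threshold; None if missing."""
    if rotor_speed is None or (isinstance(rotor_speed, float) and np.isnan(rotor_speed)):
        return None
    if rotor_speed < 0:
        raise ValueError("rotor speed cannot be negative")
    return BladeStatus.STILL if rotor_speed <= still_threshold_rpm else BladeStatus.MOVING


class StatusTable:
    """3-hourly SCADA state keyed by (turbine_id, grid instant)."""

    def __init__(self, frame: pd.DataFrame, still_threshold_rpm: float = 0.0):
        """``frame`` columns: turbine_id, timestamp, wind_speed, rotor_speed."""
        f = frame.copy()
        f["timestamp"] = pd.to_datetime(f["timestamp"])
        if f["timestamp"].dt.tz is not None:
            f["timestamp"] = f["timestamp"].dt.tz_convert("UTC").dt.tz_localize(None)
        secs = f["timestamp"].astype("int64") // 10**9
        if not np.all(secs % THREE_HOURS_S == 0):
            raise ValueError("SCADA timestamps must lie on the 3-hour UTC grid")
        if np.any(f["wind_speed"] < 0):
            raise ValueError("wind speed cannot be negative")
        self.still_threshold_rpm = still_threshold_rpm
        self.frame = f
        self._index = {
            (tid, ts): (w, r)
            for tid, ts, w, r in zip(
                f["turbine_id"], f["timestamp"], f["wind_speed"], f["rotor_speed"]
            )
        }

    def lookup(self, turbine_id: str, t: datetime) -> StatusRecord | None:
        """Exact-key lookup; ``t`` must already be 3-h grid aligned."""
        tu = _as_utc(t).replace(tzinfo=None)
        if (tu - datetime(1970, 1, 1)).total_seconds() % THREE_HOURS_S != 0:
            raise ValueError(f"lookup time {t} is not 3-h grid aligned; round first")
        key = (turbine_id, pd.Timestamp(tu))
        if key not in self._index:
            return None
        wind, rotor = self._index[key]
        rotor_val = None if pd.isna(rotor) else float(rotor)
        return StatusRecord(
            turbine_id=turbine_id,
            timestamp=tu.replace(tzinfo=timezone.utc),
            wind_speed=float(wind),
            rotor_speed=rotor_val,
            blade_status=blade_status_from_rotor(rotor_val, self.still_threshold_rpm),
        )


def read_turbines(path: str | Path) -> list[Turbine]:
    """Read turbine metadata from delimited text.

    Expected columns: turbine_id, farm_id, easting, northing,
    base_elevation_asl, hub_height_agl, blade_length, erection_date,
    operation_date (dates ISO-8601, blank for none).
    """
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        def _d(v):
            return None if pd.isna(v) or v == "" else pd.Timestamp(v).date()
        out.append(
            Turbine(
                turbine_id=str(row.turbine_id),
                farm_id=str(row.farm_id),
                easting=float(row.easting),
                northing=float(row.northing),
                base_elevation_asl=float(row.base_elevation_asl),
                hub_height_agl=float(row.hub_height_agl),
                blade_length=float(row.blade_length),
                erection_date=_d(getattr(row, "erection_date", None)),
                operation_date=_d(getattr(row, "operation_date", None)),
            )
        )
    return out


def read_status_table(path: str | Path, still_threshold_rpm: float = 0.0) -> StatusTable:
    """Read a 3-hourly SCADA table (turbine_id, timestamp, wind_speed, rotor_speed)."""
    return StatusTable(pd.read_csv(path), still_threshold_rpm=still_threshold_rpm)
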