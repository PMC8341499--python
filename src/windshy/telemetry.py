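"""Reading and quality-controlling GPS tag fixes.

In-memory container is a pandas DataFrame with the canonical columns

    bird_id, timestamp (UTC), easting, northing (planar metres),
    lat, lon (WGS84 degrees), altitude_asl (m, NaN if missing),
    hdop, tag_type ("GSM" | "ARGOS")

plus optional ``vdop`` (read, never filtered on) and ``dispersal``
(boolean, honoured when present — records outside natal dispersal are
dropped at read time; determining dispersal is upstream of this package).

Quality control applies the fix-level rules in a fixed order so every
excluded record is attributed to exactly one reason, making the QC report
reproducible: (1) HDOP at or above the cut-off (strict ``hdop < 3.5``
retains), (2) altitude missing, (3) altitude above the plausibility
ceiling (6 km), (4) fix between local sunset and sunrise (birds roost at
night; turbine interactions are implausible).  Sunrise/sunset are computed
per fix at its own lat/lon/date; fixes exactly at the rise/set instants
are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .solar import is_daylight

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "bird_id", "timestamp", "easting", "northing",
    "lat", "lon", "altitude_asl", "hdop", "tag_type",
]
OPTIONAL_COLUMNS = ["vdop", "dispersal"]

#: default fix-level QC thresholds
MAX_HDOP = 3.5
MAX_ALTITUDE_ASL = 6000.0


@dataclass
class QCReport:
    """Counts of retained fixes and of exclusions by (single) reason."""

    input_count: int = 0
    retained: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {
            "hdop": 0, "missing_altitude": 0, "altitude_gt_max": 0, "night": 0, "other": 0,
        }
    )

    def conserves_counts(self) -> bool:
        return self.retained + sum(self.excluded.values()) == self.input_count

    def to_json(self) -> str:
        return json.dumps(
            {"input": self.input_count, "retained": self.retained, "excluded": self.excluded},
            indent=2,
        )


def read_fixes(
    path: str | Path,
    dialect: dict | None = None,
) -> pd.DataFrame:
    """Read raw tag records from delimited text into the canonical frame.

    ``dialect`` may carry ``columns`` (mapping canonical name -> file
    column) and ``sep`` (delimiter; autodetected when omitted).  Rows that
    fail to parse are collected and logged, not fatal.  Duplicate
    (bird_id, timestamp) rows collapse to the first occurrence, logged.
    Output is sorted by (bird_id, timestamp).
    """
    dialect = dialect or {}
    colmap: dict[str, str] = dialect.get("columns", {})
    sep = dialect.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")

    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(
            f"telemetry file {path} lacks required columns {missing}; "
            "map them via the dialect column config"
        )

    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = ts.isna() | ~np.isfinite(df["easting"]) | ~np.isfinite(df["northing"])
    if bad.any():
        log.warning("dropped %d unparseable telemetry rows from %s", int(bad.sum()), path)
        df = df[~bad]
        ts = ts[~bad]
    df["timestamp"] = ts.dt.tz_convert("UTC").dt.tz_localize(None)

    for col in ("easting", "northing", "lat", "lon", "altitude_asl", "hdop"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["hdop"] < 0).any():
        raise ValueError("negative HDOP encountered; corrupt input")

    if "dispersal" in df.columns:
        n0 = len(df)
        df = df[df["dispersal"].astype(bool)]
        if len(df) < n0:
            log.info("dropped %d non-dispersal records", n0 - len(df))

    df = df.sort_values(["bird_id", "timestamp"], kind="mergesort")
    dups = df.duplicated(subset=["bird_id", "timestamp"], keep="first")
    if dups.any():
        log.info("collapsed %d duplicate (bird, timestamp) rows", int(dups.sum()))
        df = df[~dups]
    return df.reset_index(drop=True)


def qc_filter(
    fixes: pd.DataFrame,
    max_hdop: float = MAX_HDOP,
    max_alt: float = MAX_ALTITUDE_ASL,
    daylight_only: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply fix-level QC; returns (retained fixes, QCReport).

    Retains fixes with ``hdop < max_hdop`` (strict), altitude present and
    ``<= max_alt``, and — when ``daylight_only`` — timestamp within
    [sunrise, sunset] at the fix's own location and date (closed interval).
    Each excluded fix is counted under the first failing rule.
    """
    report = QCReport(input_count=len(fixes))
    if len(fixes) == 0:
        return fixes.copy(), report

    reason = np.full(len(fixes), "", dtype=object)
    hdop_bad = ~(fixes["hdop"].to_numpy() < max_hdop)  # NaN hdop fails too
    reason[hdop_bad] = "hdop"

    alt = fixes["altitude_asl"].to_numpy(dtype=float)
    m = (reason == "") & np.isnan(alt)
    reason[m] = "missing_altitude"
    m = (reason == "") & (alt > max_alt)
    reason[m] = "altitude_gt_max"

    if daylight_only:
        undecided = reason == ""
        if undecided.any():
            lat = fixes["lat"].to_numpy(dtype=float)[undecided]
            lon = fixes["lon"].to_numpy(dtype=float)[undecided]
            if np.any(np.isnan(lat) | np.isnan(lon)):
                raise ValueError("daylight filtering requires lat/lon on every fix")
            ts = fixes["timestamp"].to_numpy()[undecided]
            day = is_daylight(lat, lon, ts)
            idx = np.flatnonzero(undecided)[~day]
            reason[idx] = "night"

    retained = fixes[reason == ""].copy()
    for r in reason[reason != ""]:
        report.excluded[r] += 1
    report.retained = len(retained)
    return retained, report


def filter_min_records_per_bird(
    records: pd.DataFrame, phase: str, min_n: int = 10, phase_column: str = "phase"
) -> pd.DataFrame:
    """Drop birds with fewer than ``min_n`` records in the named phase.

    A bird with exactly ``min_n`` records is retained (strict less-than).
    Birds failing the rule are removed from the whole analysis set, not
    just from that phase.
    """
    if len(records) == 0:
        return records.copy()
    counts = records[records[phase_column] == phase].groupby("bird_id").size()
    bad = set(counts[counts < min_n].index)
    # birds with zero records in the phase also fail the rule
    all_birds = set(records["bird_id"].unique())
    bad |= all_birds - set(counts.index)
    kept = records[~records["bird_id"].isin(bad)].copy()
    if bad:
        log.info("dropped %d birds with < %d %s-phase records", len(bad), min_n, phase)
    return kept
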