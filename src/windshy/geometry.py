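"""Closest-approach geometry between eagle fixes/flight lines and turbine hubs.

The convention throughout is *2-D first*: the closest pass of a flight line
to a hub is located in the horizontal plane, the flight altitude is linearly
interpolated at that pass fraction, and the 3-D distance follows by
trigonometry from the horizontal separation and the altitude difference to
the hub.  This is deliberately not the true 3-D minimum over the segment;
it is the conservative convention used in displacement analyses of this
kind (the resulting distances are, if anything, slightly low).

Altitude datum: tag altitudes are metres above sea level (asl); turbine hub
height is above ground level (agl) and is converted to asl via the tower
base elevation before differencing (see :func:`hub_altitude`).

All planar coordinates are metric (projected easting/northing in metres).
Functions are numpy-vectorised; scalars work too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .turbines import Turbine


@dataclass(frozen=True)
class ApproachResult:
    """Closest pass of a fix or flight segment to one turbine hub.

    Attributes
    ----------
    d2d : float
        Horizontal (2-D) distance at the closest pass, metres.
    fraction : float
        Position of the closest 2-D pass along the segment, in [0, 1]
        (0 for point fixes).
    alt_at_pass : float
        Interpolated flight altitude asl at the pass, metres.
    d3d : float
        3-D distance: sqrt(d2d^2 + (alt_at_pass - hub_alt)^2), metres.
    hub_alt : float
        Hub altitude asl, metres.
    """

    d2d: float
    fraction: float
    alt_at_pass: float
    d3d: float
    hub_alt: float


def closest_approach_2d(px, py, ax, ay, bx, by):
    """Closest point on segment a-b to point p, in the plane.

    Returns ``(fraction, d2d)`` where ``fraction`` is the clamped
    orthogonal-foot parameter in [0, 1] along a->b and ``d2d`` the planar
    distance from p to that point.  A degenerate segment (a == b) yields
    fraction 0 and the point-to-point distance.
    """
    px, py, ax, ay, bx, by = (np.asarray(v, dtype=float) for v in (px, py, ax, ay, bx, by))
    if not all(np.all(np.isfinite(v)) for v in (px, py, ax, ay, bx, by)):
        raise ValueError("closest_approach_2d requires finite coordinates")
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(L2 > 0.0, ((px - ax) * dx + (py - ay) * dy) / np.where(L2 > 0, L2, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    cx, cy = ax + t * dx, ay + t * dy
    d2d = np.hypot(px - cx, py - cy)
    return t, d2d


def interpolate_altitude(alt_start, alt_end, fraction):
    """Linear altitude at ``fraction`` of the way from start to end fix."""
    alt_start = np.asarray(alt_start, dtype=float)
    alt_end = np.asarray(alt_end, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    if np.any(np.isnan(alt_start)) or np.any(np.isnan(alt_end)):
        raise ValueError("both fix altitudes must be present to interpolate")
    if np.any((fraction < 0) | (fraction > 1)):
        raise ValueError("fraction must lie in [0, 1]")
    return alt_start + fraction * (alt_end - alt_start)


def hub_altitude(turbine: "Turbine") -> float:
    """Hub altitude asl = tower base elevation asl + hub height agl."""
    base = turbine.base_elevation_asl
    hub = turbine.hub_height_agl
    if base is None or hub is None or np.isnan(base) or np.isnan(hub):
        raise ValueError(f"turbine {turbine.turbine_id}: base elevation and hub height required")
    if hub < 0:
        raise ValueError(f"turbine {turbine.turbine_id}: negative hub height")
    return float(base + hub)


def distance_3d(d2d, alt_asl, hub_alt_asl):
    """3-D distance from horizontal separation and altitude difference."""
    d2d = np.asarray(d2d, dtype=float)
    return np.hypot(d2d, np.asarray(alt_asl, dtype=float) - np.asarray(hub_alt_asl, dtype=float))


def fix_to_hub_3d(x, y, alt_asl, turbine: "Turbine") -> ApproachResult:
    """Closest 2-D/3-D distance from a single tag fix to a turbine hub."""
    if alt_asl is None or np.isnan(alt_asl):
        raise ValueError("fix altitude missing; cannot compute 3-D distance")
    hub_alt = hub_altitude(turbine)
    d2d = float(np.hypot(x - turbine.easting, y - turbine.northing))
    d3d = float(distance_3d(d2d, alt_asl, hub_alt))
    return ApproachResult(d2d=d2d, fraction=0.0, alt_at_pass=float(alt_asl), d3d=d3d, hub_alt=hub_alt)


def segment_to_hub(ax, ay, alt_a, bx, by, alt_b, turbine: "Turbine") -> ApproachResult:
    """Closest pass of the flight line a->b to a turbine hub (2-D-first)."""
    frac, d2d = closest_approach_2d(turbine.easting, turbine.northing, ax, ay, bx, by)
    alt = interpolate_altitude(alt_a, alt_b, frac)
    hub_alt = hub_altitude(turbine)
    d3d = distance_3d(d2d, alt, hub_alt)
    return ApproachResult(
        d2d=float(d2d), fraction=float(frac), alt_at_pass=float(alt),
        d3d=float(d3d), hub_alt=hub_alt,
    )
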