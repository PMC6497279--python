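"""Tow geometry: layback correction of sled positions and swept-area accounting.

A towed sled trails behind the vessel by the horizontal *layback*
``L = sqrt(R**2 - D**2)`` for cable out ``R`` and water depth ``D``, treating
the cable as a straight line (no catenary).  For tows run due north or due
south the correction is applied to latitude only: the sled sits ``L`` metres
behind the vessel along the track, so layback is subtracted from the vessel
latitude on a northward tow and added on a southward one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TowFix", "METERS_PER_DEGREE_LAT", "layback", "correct_position", "swept_area"]

#: Metres per degree of latitude: 1 nautical mile (1852 m) per arc-minute.
METERS_PER_DEGREE_LAT = 1852.0 * 60.0


@dataclass(frozen=True)
class TowFix:
    """One vessel position fix with cable and depth at that moment."""

    vessel_lat: float
    vessel_lon: float
    cable_out_m: float
    depth_m: float
    heading: str

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth_m}")
        if self.cable_out_m < self.depth_m:
            raise ValueError(
                f"cable out ({self.cable_out_m} m) is shorter than depth "
                f"({self.depth_m} m); layback undefined"
            )
        if self.heading not in ("north", "south"):
            raise ValueError(f"heading must be 'north' or 'south', got {self.heading!r}")


def layback(cable_out_m: float, depth_m: float) -> float:
    """Horizontal vessel-to-sled distance ``sqrt(R^2 - D^2)`` in metres."""
    if depth_m < 0:
        raise ValueError(f"depth must be >= 0, got {depth_m}")
    if cable_out_m < depth_m:
        raise ValueError(
            f"cable out ({cable_out_m} m) shorter than depth ({depth_m} m)"
        )
    return math.sqrt(cable_out_m**2 - depth_m**2)


def correct_position(
    fix: TowFix, meters_per_degree: float = METERS_PER_DEGREE_LAT
) -> tuple[float, float]:
    """Sled (lat, lon) from a vessel fix: latitude shifted by the layback.

    Northward tow: the sled trails south of the vessel, so layback is
    subtracted from the latitude; southward tow: added.  Longitude is
    unchanged (tracks are meridional).
    """
    L = layback(fix.cable_out_m, fix.depth_m)
    dlat = L / meters_per_degree
    if fix.heading == "north":
        return fix.vessel_lat - dlat, fix.vessel_lon
    return fix.vessel_lat + dlat, fix.vessel_lon


def swept_area(width_m: float, speed_ms: float, duration_s: float) -> float:
    """Seafloor area covered by a tow: gear width x speed x duration (m^2)."""
    if width_m <= 0 or speed_ms <= 0 or duration_s <= 0:
        raise ValueError("width, speed and duration must all be positive")
    return width_m * speed_ms * duration_s
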