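"""Cheek mass point location and its position relative to the cornea.

The cheek mass (Ck) point is the most anterior point of the soft-tissue
profile cut by the mid-pupillary plane (the parasagittal plane through the
corneal apex), within the vertical window between the subnasale level and the
infraorbital (Or) level.  Its signed anterior distance to the cornea
perpendicular plane (the coronal plane through the corneal apex) is the cheek
mass position: positive when the cheek projects in front of the cornea,
negative for a deficient (retruded) cheek contour.

The published normative value for balanced adult faces, consumed here as a
constant, is 2.145 ± 1.201 mm (n = 60 individuals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh

from .anatomy import LandmarkSet, PlaneSet, ReferenceFrame, construct_planes
from .errors import MeasurementError

#: Normative cheek mass position: mean (mm), SD (mm), cohort size.
NORM_MEAN_MM = 2.145
NORM_SD_MM = 1.201
NORM_N = 60


@dataclass(frozen=True)
class CheekMassResult:
    side: str
    ck_point: np.ndarray   # world coordinates, mm
    position: float        # signed mm anterior of the CPP


def cheek_mass_position(soft: trimesh.Trimesh, frame: ReferenceFrame,
                        lm: LandmarkSet, side: str,
                        planes: Optional[PlaneSet] = None) -> CheekMassResult:
    """Locate the Ck point on one side and measure its position.

    Intersects the soft-tissue surface with the mid-pupillary plane, keeps
    the profile between the subnasale and infraorbital levels, and returns
    the most anterior profile point with its signed distance to the cornea
    perpendicular plane.
    """
    if planes is None:
        planes = construct_planes(frame, lm)
    mpp = planes.sided("MPP", side)
    segments = trimesh.intersections.mesh_plane(
        soft, plane_normal=mpp.normal, plane_origin=mpp.normal * mpp.offset)
    if len(segments) == 0:
        raise MeasurementError(f"cheek profile not found: MPP misses mesh "
                               f"(side {side})")
    pts = segments.reshape(-1, 3)
    local = frame.to_frame(pts)
    z_lo = frame.to_frame(lm["Sn"])[2]
    z_hi = frame.to_frame(lm.sided("Or", side))[2]
    if z_hi <= z_lo:
        raise MeasurementError("cheek profile not found: empty vertical window")
    in_window = (local[:, 2] > z_lo) & (local[:, 2] < z_hi)
    if not np.any(in_window):
        raise MeasurementError(f"cheek profile not found: no profile points in "
                               f"window (side {side})")
    idx = np.argmax(local[in_window, 1])
    ck = pts[in_window][idx]
    position = planes.sided("CPP", side).signed_distance(ck)
    return CheekMassResult(side=side, ck_point=ck, position=float(position))
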