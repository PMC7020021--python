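"""Anteromedial cheek ROI clipping, volumetric subtraction and movement.

The cheek region of interest is the surface patch bounded laterally by the
lateral cheek plane (through the exocanthion), medially by the medial cheek
plane (through the alare), inferiorly by the inferior cheek plane (through
the subnasale) and superiorly by the Frankfort horizontal plane; only the
anterior-facing sheet is kept.

The average sagittal movement of a region is its signed post-minus-pre
volume (mm³) divided by its pre-operative surface area (mm²).  The volume
between the two surfaces is integrated as an anterior height-field
difference: both surfaces are sampled by parallel rays along +y on a regular
x–z grid over the ROI footprint (default cell 0.4 mm, matching the scan
voxel), keeping the outermost hit, and ``Σ (y_post − y_pre) · cell_area`` is
accumulated.  Anterior displacement is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import trimesh

from ._surface import sample_heightfield
from .anatomy import Plane, PlaneSet, ReferenceFrame
from .errors import MeasurementError

#: Default sampling cell (mm); matches the 0.4 mm CBCT voxel.
DEFAULT_GRID_MM = 0.4

#: Advancement strata (mm): [1,2), [2,3), [3,4), [4, inf); < 1 mm is flagged.
STRATUM_LABELS = ("1-2 mm", "2-3 mm", "3-4 mm", ">4 mm")
BELOW_RANGE = "below-range"


@dataclass(frozen=True)
class ROIPatch:
    """Clipped anterior-facing cheek patch of one mesh."""

    side: str                 # "L" | "R"
    tissue: str               # "bone" | "soft"
    epoch: str                # "pre" | "post"
    mesh: trimesh.Trimesh     # triangles inside the four half-spaces
    surface_area: float       # mm², sum of retained triangle areas

    @property
    def bounds_xz(self) -> Tuple[float, float, float, float]:
        v = self.mesh.vertices
        return (float(v[:, 0].min()), float(v[:, 0].max()),
                float(v[:, 2].min()), float(v[:, 2].max()))


@dataclass(frozen=True)
class RegionMeasurement:
    """Per-side, per-tissue volumetric result."""

    side: str
    tissue: str
    delta_volume: float       # mm³, anterior-positive
    pre_area: float           # mm²
    movement: float           # mm = delta_volume / pre_area
    rotation_change: Optional[float] = None  # degrees, clockwise-positive


def roi_half_spaces(planes: PlaneSet, side: str) -> Tuple[Plane, ...]:
    """Inward-oriented half-space planes of the cheek ROI for one side.

    A point is inside the ROI iff its signed distance to every returned plane
    is non-negative.
    """
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    lcp = planes.sided("LCP", side)
    mcp = planes.sided("MCP", side)
    icp = planes["ICP"]
    fh = planes["FH"]
    # medial boundary: keep the side away from the midline; lateral: toward it.
    # Plane normals point along +x; the Ex (lateral) offset exceeds the Al
    # (medial) offset on the right side and vice versa on the left.
    if lcp.offset >= mcp.offset:      # right side (x positive)
        lateral, medial = lcp.flipped(), mcp
    else:                             # left side
        lateral, medial = lcp, mcp.flipped()
    return (lateral, medial, icp, fh.flipped())


def clip_mesh_to_roi(mesh: trimesh.Trimesh, planes: PlaneSet, side: str,
                     tissue: str = "", epoch: str = "") -> ROIPatch:
    """Clip a surface to the cheek ROI, splitting boundary triangles.

    Retains only the anterior-facing sheet (face normals with a positive
    component along the anterior axis, taken from the CO plane normal).
    """
    clipped = mesh
    for plane in roi_half_spaces(planes, side):
        if len(clipped.faces) == 0:
            break
        clipped = trimesh.intersections.slice_mesh_plane(
            clipped, plane_normal=plane.normal,
            plane_origin=plane.normal * plane.offset)
    if len(clipped.faces) == 0:
        raise MeasurementError(f"ROI does not intersect mesh (side {side})")
    anterior = planes["CO"].normal
    keep = clipped.face_normals @ anterior > 0
    if not np.any(keep):
        raise MeasurementError(
            f"ROI does not intersect mesh: no anterior-facing triangles "
            f"(side {side})")
    patch = clipped.submesh([np.nonzero(keep)[0]], append=True)
    return ROIPatch(side=side, tissue=tissue, epoch=epoch, mesh=patch,
                    surface_area=float(patch.area))


def volumetric_change(pre: ROIPatch, post_mesh: trimesh.Trimesh,
                      frame: ReferenceFrame, grid_mm: float = DEFAULT_GRID_MM,
                      max_miss_fraction: float = 0.01) -> float:
    """Signed volume (mm³) between the pre patch and the post surface.

    Both surfaces are expressed in the anatomical frame and sampled as
    anterior height fields on a ``grid_mm`` grid over the pre patch's x–z
    footprint.  Cells the pre patch does not cover are outside the footprint;
    if the post surface misses more than ``max_miss_fraction`` of footprint
    cells the measurement aborts.
    """
    if grid_mm <= 0:
        raise ValueError("grid_mm must be positive")
    pre_v = frame.to_frame(pre.mesh.vertices)
    post_v = frame.to_frame(post_mesh.vertices)
    x0, x1 = pre_v[:, 0].min(), pre_v[:, 0].max()
    z0, z1 = pre_v[:, 2].min(), pre_v[:, 2].max()
    # cell centers
    xs = np.arange(x0 + grid_mm / 2, x1, grid_mm)
    zs = np.arange(z0 + grid_mm / 2, z1, grid_mm)
    if len(xs) == 0 or len(zs) == 0:
        raise MeasurementError("ROI footprint smaller than one grid cell")
    h_pre = sample_heightfield(pre_v, pre.mesh.faces, xs, zs)
    h_post = sample_heightfield(post_v, post_mesh.faces, xs, zs)
    footprint = ~np.isnan(h_pre)
    n_fp = int(footprint.sum())
    if n_fp == 0:
        raise MeasurementError("ROI footprint empty after sampling")
    missed = footprint & np.isnan(h_post)
    if missed.sum() > max_miss_fraction * n_fp:
        raise MeasurementError(
            f"surface coverage insufficient: post surface misses "
            f"{missed.sum()}/{n_fp} footprint cells")
    both = footprint & ~np.isnan(h_post)
    return float(np.sum(h_post[both] - h_pre[both]) * grid_mm * grid_mm)


def average_sagittal_movement(delta_volume: float, pre_area: float) -> float:
    """Volumetric change (mm³) over pre-operative surface area (mm²) -> mm."""
    if pre_area <= 0:
        raise MeasurementError("pre-operative area must be positive")
    return float(delta_volume) / float(pre_area)


def rotation_change(pre_angle: float, post_angle: float) -> float:
    """Post-minus-pre FH–occlusal angle; positive = clockwise rotation."""
    return float(post_angle) - float(pre_angle)


def stratify_advancement(movement_mm: float) -> str:
    """Bin a bone advancement into the four half-open strata.

    [1, 2) → "1-2 mm", [2, 3) → "2-3 mm", [3, 4) → "3-4 mm", [4, ∞) →
    ">4 mm"; values below 1 mm return the ``below-range`` flag.
    """
    m = float(movement_mm)
    if m < 0:
        raise ValueError("advancement must be non-negative")
    if m < 1:
        return BELOW_RANGE
    if m < 2:
        return STRATUM_LABELS[0]
    if m < 3:
        return STRATUM_LABELS[1]
    if m < 4:
        return STRATUM_LABELS[2]
    return STRATUM_LABELS[3]


def measure_region(pre_mesh: trimesh.Trimesh, post_mesh: trimesh.Trimesh,
                   planes: PlaneSet, frame: ReferenceFrame, side: str,
                   tissue: str, grid_mm: float = DEFAULT_GRID_MM,
                   rotation_delta: Optional[float] = None) -> RegionMeasurement:
    """Clip the pre mesh to the ROI and measure ΔV, area and movement."""
    pre_patch = clip_mesh_to_roi(pre_mesh, planes, side, tissue=tissue, epoch="pre")
    dv = volumetric_change(pre_patch, post_mesh, frame, grid_mm=grid_mm)
    movement = average_sagittal_movement(dv, pre_patch.surface_area)
    return RegionMeasurement(side=side, tissue=tissue, delta_volume=dv,
                             pre_area=pre_patch.surface_area, movement=movement,
                             rotation_change=rotation_delta)
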