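"""Craniofacial coordinate frame, reference planes and angular measurements.

Everything downstream of raw surface scans is expressed in a landmark-derived
anatomical frame: the Frankfort horizontal (FH) plane through both porions and
the mid-infraorbital point supplies the vertical axis, the midsagittal plane
(MSP) through sella and nasion (constrained perpendicular to FH) supplies the
lateral axis, and their intersection logic fixes a right-handed system with

* ``x`` lateral, positive toward the patient's right,
* ``y`` anteroposterior, positive anterior,
* ``z`` vertical, positive superior,

with the sella (S) as origin.  All coordinates are millimetres.

The reference planes are the standard cephalometric set: FH, MSP, the coronal
plane (CO) through S, the occlusal plane (OP) through the upper-incisor
midpoint and both first-molar cusps, and per-side planes bounding the
anteromedial cheek region (lateral cheek plane LCP through the exocanthion,
medial cheek plane MCP through the alare, inferior cheek plane ICP through the
subnasale) plus the mid-pupillary (MPP) and cornea-perpendicular (CPP) planes
through the corneal apex.

The maxillary rotational angle is the FH–OP dihedral measured on the
midsagittal trace, reported as a magnitude in [0, 90] degrees; the clockwise /
counterclockwise direction is carried by the sign of the post-minus-pre
difference downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

from .errors import DegenerateGeometryError, MissingLandmarkError

#: Landmark names expected in every landmark file (lateral pairs carry _L/_R).
REQUIRED_LANDMARKS: Tuple[str, ...] = (
    "Ex_L", "Ex_R", "C_L", "C_R", "Al_L", "Al_R", "Sn",
    "Or_L", "Or_R", "Po_L", "Po_R", "N", "S", "Ba",
    "U1", "U6_L", "U6_R",
)

#: Plane tags, sided planes expand to e.g. ``LCP_L`` / ``LCP_R``.
PLANE_NAMES: Tuple[str, ...] = (
    "FH", "MSP", "CO", "OP",
    "MPP_L", "MPP_R", "CPP_L", "CPP_R",
    "LCP_L", "LCP_R", "MCP_L", "MCP_R", "ICP",
)

_EPS_UNIT = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("degenerate frame: zero-length axis")
    return v / n


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D points (mm) in scanner space.

    Extra landmarks beyond the required set are allowed and preserved.
    """

    points: Dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            a = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(a)):
                raise MissingLandmarkError(
                    f"incomplete landmark set: {name} is not finite"
                )
            clean[name] = a
        missing = [n for n in REQUIRED_LANDMARKS if n not in clean]
        if missing:
            raise MissingLandmarkError(
                "incomplete landmark set: missing " + ", ".join(missing)
            )
        object.__setattr__(self, "points", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(f"incomplete landmark set: missing {name}")

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> Iterable[str]:
        return self.points.keys()

    def sided(self, name: str, side: str) -> np.ndarray:
        """Look up a lateral landmark, ``side`` in {"L", "R"}."""
        if side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {side!r}")
        return self[f"{name}_{side}"]

    def array(self, names: Iterable[str]) -> np.ndarray:
        return np.stack([self[n] for n in names])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply the rigid map ``p -> R p + t`` to every landmark."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float).reshape(3)
        return LandmarkSet({n: R @ p + t for n, p in self.points.items()})


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``{p : n·p = offset}`` with unit normal ``n`` (mm)."""

    normal: np.ndarray
    offset: float
    name: str = ""

    def __post_init__(self):
        n = np.asarray(self.normal, float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            n = _unit(n)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    @classmethod
    def from_point_normal(cls, point, normal, name: str = "") -> "Plane":
        n = _unit(np.asarray(normal, float).reshape(3))
        p = np.asarray(point, float).reshape(3)
        return cls(normal=n, offset=float(n @ p), name=name)

    @classmethod
    def from_points(cls, a, b, c, name: str = "") -> "Plane":
        a, b, c = (np.asarray(p, float).reshape(3) for p in (a, b, c))
        n = np.cross(b - a, c - a)
        if np.linalg.norm(n) < 1e-9:
            raise DegenerateGeometryError(
                f"degenerate frame: collinear points defining plane {name or '?'}"
            )
        return cls.from_point_normal(a, n, name=name)

    def signed_distance(self, p) -> np.ndarray | float:
        """``n·p − offset`` (mm); positive on the normal side.

        Accepts a single point ``(3,)`` or an array ``(n, 3)``.
        """
        a = np.asarray(p, float)
        d = a @ self.normal - self.offset
        return float(d) if a.ndim == 1 else d

    def flipped(self) -> "Plane":
        return Plane(normal=-self.normal, offset=-self.offset, name=self.name)


def signed_distance(plane: Plane, p) -> np.ndarray | float:
    """Module-level alias for :meth:`Plane.signed_distance`."""
    return plane.signed_distance(p)


@dataclass(frozen=True)
class ReferenceFrame:
    """Right-handed anatomical frame: origin at S, axes (x lateral-right,
    y anterior, z superior), all unit and mutually orthogonal."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    def __post_init__(self):
        for name in ("origin", "axis_x", "axis_y", "axis_z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation; columns are the frame axes."""
        return np.column_stack([self.axis_x, self.axis_y, self.axis_z])

    def to_frame(self, p) -> np.ndarray:
        """World coordinates -> frame coordinates."""
        a = np.asarray(p, float)
        return (a - self.origin) @ self.rotation

    def to_world(self, p) -> np.ndarray:
        a = np.asarray(p, float)
        return a @ self.rotation.T + self.origin


def build_reference_frame(lm: LandmarkSet) -> ReferenceFrame:
    """Construct the anatomical frame from a landmark set.

    FH is the plane through Po_L, Po_R and the infraorbital midpoint; its
    normal, oriented so that N is superior to Ba, is the z axis.  The MSP
    contains S and N and is perpendicular to FH; the anterior axis y is the
    in-FH component of S→N, and x = y × z completes the right-handed system.
    """
    po_l, po_r = lm["Po_L"], lm["Po_R"]
    mid_or = 0.5 * (lm["Or_L"] + lm["Or_R"])
    n_fh = np.cross(po_r - po_l, mid_or - po_l)
    if np.linalg.norm(n_fh) < 1e-9:
        raise DegenerateGeometryError(
            "degenerate frame: Po_L, Po_R and mid-Or are collinear"
        )
    z = _unit(n_fh)
    if z @ (lm["N"] - lm["Ba"]) < 0:  # orient superior
        z = -z
    sn = lm["N"] - lm["S"]
    y_raw = sn - (sn @ z) * z  # project S->N into FH
    if np.linalg.norm(y_raw) < 1e-9:
        raise DegenerateGeometryError("degenerate frame: S and N vertically aligned")
    y = _unit(y_raw)
    x = np.cross(y, z)
    return ReferenceFrame(origin=lm["S"], axis_x=x, axis_y=y, axis_z=z)


@dataclass(frozen=True)
class PlaneSet:
    """All reference planes, keyed by tag (sided tags carry ``_L``/``_R``)."""

    planes: Dict[str, Plane] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Plane:
        return self.planes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.planes

    def sided(self, base: str, side: str) -> Plane:
        if side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {side!r}")
        return self.planes[f"{base}_{side}"]


def construct_planes(frame: ReferenceFrame, lm: LandmarkSet) -> PlaneSet:
    """Build every reference plane from the frame and landmark set.

    Plane normals are oriented along the positive frame axes: FH/ICP along +z,
    MSP and all parasagittal planes (MPP, LCP, MCP) along +x, CO/CPP along +y.
    The occlusal plane passes through U1, U6_L and U6_R with its normal
    oriented superiorly.
    """
    x, y, z = frame.axis_x, frame.axis_y, frame.axis_z
    planes: Dict[str, Plane] = {}
    mid_or = 0.5 * (lm["Or_L"] + lm["Or_R"])
    planes["FH"] = Plane.from_point_normal(mid_or, z, name="FH")
    planes["MSP"] = Plane.from_point_normal(lm["S"], x, name="MSP")
    planes["CO"] = Plane.from_point_normal(lm["S"], y, name="CO")

    u1, u6_l, u6_r = lm["U1"], lm["U6_L"], lm["U6_R"]
    mid_u6 = 0.5 * (u6_l + u6_r)
    if np.linalg.norm(u1 - mid_u6) < 1e-9:
        raise DegenerateGeometryError("degenerate occlusal plane: U1 equals mid-U6")
    try:
        op = Plane.from_points(u1, u6_l, u6_r, name="OP")
    except DegenerateGeometryError:
        raise DegenerateGeometryError("degenerate occlusal plane: U1, U6 collinear")
    if op.normal @ z < 0:
        op = op.flipped()
    planes["OP"] = Plane(op.normal, op.offset, name="OP")

    planes["ICP"] = Plane.from_point_normal(lm["Sn"], z, name="ICP")
    for side in ("L", "R"):
        planes[f"MPP_{side}"] = Plane.from_point_normal(
            lm.sided("C", side), x, name=f"MPP_{side}")
        planes[f"CPP_{side}"] = Plane.from_point_normal(
            lm.sided("C", side), y, name=f"CPP_{side}")
        planes[f"LCP_{side}"] = Plane.from_point_normal(
            lm.sided("Ex", side), x, name=f"LCP_{side}")
        planes[f"MCP_{side}"] = Plane.from_point_normal(
            lm.sided("Al", side), x, name=f"MCP_{side}")
    return PlaneSet(planes=planes)


def maxillary_rotation_angle(frame: ReferenceFrame, lm: LandmarkSet) -> float:
    """FH–OP dihedral angle (degrees, in [0, 90]) on the midsagittal trace.

    The occlusal plane's trace in the MSP is ``n_OP × n_MSP``; the angle is
    the inclination of that trace relative to FH.  Magnitude only: the
    clockwise sign convention is applied by the post-minus-pre difference.
    """
    planes = construct_planes(frame, lm)
    trace = np.cross(planes["OP"].normal, planes["MSP"].normal)
    norm = np.linalg.norm(trace)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "degenerate occlusal plane: OP parallel to MSP")
    trace = trace / norm
    s = np.clip(abs(trace @ frame.axis_z), 0.0, 1.0)
    return float(np.degrees(np.arcsin(s)))


def validate_plane_incidence(planes: PlaneSet, lm: LandmarkSet,
                             tol: float = 1e-6) -> Mapping[str, float]:
    """Signed distance of each defining landmark to its own plane.

    Returns the per-plane residuals; raises ``AssertionError`` if any exceeds
    ``tol`` (used by the phantom generator's self-checks and the test suite).
    """
    pairs = [("ICP", lm["Sn"])]
    for side in ("L", "R"):
        pairs += [
            (f"LCP_{side}", lm.sided("Ex", side)),
            (f"MCP_{side}", lm.sided("Al", side)),
            (f"MPP_{side}", lm.sided("C", side)),
            (f"CPP_{side}", lm.sided("C", side)),
        ]
    out = {}
    for name, p in pairs:
        d = abs(planes[name].signed_distance(p))
        out[name] = d
        if d > tol:
            raise AssertionError(f"landmark off its plane {name}: {d:.3g} mm")
    return out
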