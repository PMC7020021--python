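"""Anatomical frame, plane construction and angle measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cheekmorph.anatomy import (LandmarkSet, Plane, build_reference_frame,
                                construct_planes, maxillary_rotation_angle,
                                signed_distance, validate_plane_incidence)
from cheekmorph.errors import DegenerateGeometryError, MissingLandmarkError
from cheekmorph.phantom import canonical_landmarks, PhantomSpec

from conftest import random_rigid


@pytest.fixture(scope="module")
def landmarks():
    return canonical_landmarks(PhantomSpec())


def test_fh_normal_from_symmetric_landmarks(landmarks):
    """Symmetric Po/Or constructions give an exactly vertical FH normal."""
    pts = dict(landmarks.points)
    pts.update({"Po_L": [-60, 0, 0], "Po_R": [60, 0, 0],
                "Or_L": [-30, 70, 2], "Or_R": [30, 70, -2],
                "N": [0, 80, 10], "S": [0, 0, 0], "Ba": [0, -10, -20]})
    frame = build_reference_frame(LandmarkSet(pts))
    assert np.allclose(frame.axis_z, [0, 0, 1], atol=1e-12)
    assert np.allclose(frame.axis_y, [0, 1, 0], atol=1e-12)
    assert np.allclose(frame.axis_x, [1, 0, 0], atol=1e-12)


def test_frame_axes_orthonormal_right_handed(landmarks):
    frame = build_reference_frame(landmarks)
    R = frame.rotation
    assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
    assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)
    # N anterior of S, superior of Ba in frame coordinates
    assert frame.to_frame(landmarks["N"])[1] > 0
    assert frame.to_frame(landmarks["N"])[2] > frame.to_frame(landmarks["Ba"])[2]


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    axis=st.tuples(*[st.floats(-1, 1) for _ in range(3)]).filter(
        lambda a: np.linalg.norm(a) > 0.1),
    angle=st.floats(-np.pi, np.pi),
    t=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
)
def test_frame_rigid_motion_equivariance(axis, angle, t):
    """Frame coordinates of every landmark are rigid-motion invariant."""
    landmarks = canonical_landmarks(PhantomSpec())
    frame = build_reference_frame(landmarks)
    base = {n: frame.to_frame(landmarks[n]) for n in landmarks.names()}
    R = Rotation.from_rotvec(angle * np.asarray(axis)
                             / np.linalg.norm(axis)).as_matrix()
    moved = landmarks.transformed(R, np.asarray(t))
    frame2 = build_reference_frame(moved)
    for n in landmarks.names():
        assert np.allclose(frame2.to_frame(moved[n]), base[n], atol=1e-8)


def test_missing_landmark_raises(landmarks):
    pts = dict(landmarks.points)
    del pts["Sn"]
    with pytest.raises(MissingLandmarkError, match="incomplete landmark set"):
        LandmarkSet(pts)


def test_collinear_fh_points_raise(landmarks):
    pts = dict(landmarks.points)
    pts.update({"Po_L": [-60, 0, 0], "Po_R": [60, 0, 0],
                "Or_L": [0, 0, 0], "Or_R": [0, 0, 0]})
    with pytest.raises(DegenerateGeometryError):
        build_reference_frame(LandmarkSet(pts))


def test_plane_orthogonality_and_incidence(landmarks):
    frame = build_reference_frame(landmarks)
    planes = construct_planes(frame, landmarks)
    for a, b in (("FH", "MSP"), ("FH", "CO"), ("MSP", "CO")):
        assert abs(planes[a].normal @ planes[b].normal) < 1e-9
    # every defining landmark on its own plane
    validate_plane_incidence(planes, landmarks, tol=1e-6)
    # sided sanity: left/right pairs straddle the midsagittal plane
    for name in ("Ex", "Al", "C", "Po", "Or", "U6"):
        dl = planes["MSP"].signed_distance(landmarks.sided(name, "L"))
        dr = planes["MSP"].signed_distance(landmarks.sided(name, "R"))
        assert dl * dr < 0


def test_icp_plane_parallel_to_fh(landmarks):
    """The inferior cheek plane is FH-parallel through the subnasale."""
    frame = build_reference_frame(landmarks)
    planes = construct_planes(frame, landmarks)
    assert np.allclose(planes["ICP"].normal, planes["FH"].normal, atol=1e-12)
    assert abs(planes["ICP"].signed_distance(landmarks["Sn"])) < 1e-9


def test_mcp_is_parasagittal_through_alare(landmarks):
    frame = build_reference_frame(landmarks)
    planes = construct_planes(frame, landmarks)
    mcp = planes.sided("MCP", "R")
    assert np.allclose(np.abs(mcp.normal), np.abs(frame.axis_x), atol=1e-12)
    assert abs(mcp.signed_distance(landmarks["Al_R"])) < 1e-9


def test_signed_distance_trivial_and_oracle():
    plane = Plane(normal=[0, 0, 1], offset=0.0, name="z0")
    assert signed_distance(plane, [1, 2, 3]) == pytest.approx(3.0)
    assert signed_distance(plane, [5, -2, 0]) == pytest.approx(0.0)
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        p0 = rng.uniform(-50, 50, 3)
        plane = Plane.from_point_normal(p0, n)
        q = rng.uniform(-50, 50, 3)
        # oracle: distance via explicit projection onto the plane
        proj = q - ((q - p0) @ n) * n
        expected = np.sign((q - p0) @ n) * np.linalg.norm(q - proj)
        assert signed_distance(plane, q) == pytest.approx(expected, abs=1e-12)


def _dentition(landmarks, u1, u6_mid, half_span=23.0):
    pts = dict(landmarks.points)
    pts["U1"] = np.asarray(u1, float)
    pts["U6_L"] = np.asarray(u6_mid, float) + [-half_span, 0, 0]
    pts["U6_R"] = np.asarray(u6_mid, float) + [half_span, 0, 0]
    return LandmarkSet(pts)


def test_rotation_angle_parallel_and_sloped(landmarks):
    frame = build_reference_frame(landmarks)
    flat = _dentition(landmarks, [0, 70, -25], [0, 40, -25])
    assert maxillary_rotation_angle(frame, flat) == pytest.approx(0.0, abs=1e-9)
    # analytic slope: drop the molars so the OP trace has slope tan(10 deg)
    dy = 30.0
    dz = dy * np.tan(np.radians(10.0))
    sloped = _dentition(landmarks, [0, 70, -25], [0, 70 - dy, -25 - dz])
    assert maxillary_rotation_angle(frame, sloped) == pytest.approx(10.0, abs=1e-9)


def test_rotation_angle_invariances(landmarks):
    frame = build_reference_frame(landmarks)
    base = maxillary_rotation_angle(frame, landmarks)
    rng = np.random.default_rng(11)
    R, t = random_rigid(rng)
    moved = landmarks.transformed(R, t)
    assert maxillary_rotation_angle(build_reference_frame(moved), moved) == \
        pytest.approx(base, abs=1e-8)
    # uniform anterior translation of the dentition leaves the angle unchanged
    pts = dict(landmarks.points)
    for n in ("U1", "U6_L", "U6_R"):
        pts[n] = pts[n] + np.array([0.0, 7.5, 0.0])
    assert maxillary_rotation_angle(frame, LandmarkSet(pts)) == \
        pytest.approx(base, abs=1e-9)


def test_degenerate_occlusal_plane_raises(landmarks):
    frame = build_reference_frame(landmarks)
    bad = _dentition(landmarks, [0, 40, -25], [0, 40, -25], half_span=0.0)
    with pytest.raises(DegenerateGeometryError, match="degenerate occlusal"):
        maxillary_rotation_angle(frame, bad)
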