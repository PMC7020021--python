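"""ROI clipping, height-field volumetric subtraction and stratification."""

import numpy as np
import pytest
import trimesh

from cheekmorph._surface import structured_grid_mesh
from cheekmorph.errors import MeasurementError
from cheekmorph.phantom import (PhantomSpec, SurgeryParams, apply_surgery,
                                make_phantom, soft_height)
from cheekmorph.volumetrics import (average_sagittal_movement,
                                    clip_mesh_to_roi, measure_region,
                                    roi_half_spaces, rotation_change,
                                    stratify_advancement, volumetric_change)

from conftest import brute_force_heights, flat_patch, transformed_mesh


def test_clip_keeps_full_anterior_mesh_when_roi_contains_it(phantom, planes):
    """A patch strictly inside all four half-spaces is retained entirely."""
    patch = flat_patch(size=10, res=1.0, y=60.0, x0=25.0, z0=-20.0)
    clipped = clip_mesh_to_roi(patch, planes, "R")
    assert clipped.surface_area == pytest.approx(100.0, rel=1e-9)
    assert clipped.surface_area == pytest.approx(
        sum(clipped.mesh.area_faces), abs=1e-6)


def test_clip_splits_triangles_at_boundaries(phantom, planes):
    """Clipping the full soft surface gives exactly the in-ROI area."""
    roi = clip_mesh_to_roi(phantom.soft, planes, "R")
    hs = roi_half_spaces(planes, "R")
    centroids = roi.mesh.triangles_center
    for plane in hs:
        assert (plane.signed_distance(centroids) >= -1e-6).all()
    # brute-force per-vertex classification of the source mesh agrees with
    # the retained patch up to boundary splits
    v = phantom.soft.vertices
    inside = np.ones(len(v), bool)
    for plane in hs:
        inside &= plane.signed_distance(v) >= -1e-9
    strict = v[inside]
    lo, hi = strict.min(axis=0), strict.max(axis=0)
    rv = roi.mesh.vertices
    assert (rv.min(axis=0) >= lo - 1e-6).all()
    assert (rv.max(axis=0) <= hi + 1e-6).all()


def test_flat_patch_volume_and_movement(frame, planes):
    """ΔV = A·d for a flat patch: 10×10 mm advanced 3 mm → 300 mm³."""
    pre_mesh = flat_patch(size=10, res=0.5, y=60.0, x0=25.0, z0=-20.0)
    post = transformed_mesh(pre_mesh, np.eye(3), [0, 3.0, 0])
    pre = clip_mesh_to_roi(pre_mesh, planes, "R")
    dv = volumetric_change(pre, post, frame, grid_mm=0.4)
    assert dv == pytest.approx(300.0, rel=0.005)
    move = average_sagittal_movement(dv, pre.surface_area)
    assert move == pytest.approx(3.0, rel=0.005)


def test_identical_surfaces_give_zero_change(frame, planes, phantom):
    pre = clip_mesh_to_roi(phantom.soft, planes, "L")
    assert volumetric_change(pre, phantom.soft, frame) == pytest.approx(
        0.0, abs=1e-9)


def test_heightfield_matches_voxel_counting_oracle(frame, planes):
    """Gaussian-bump patch displaced 2 mm: height-field ΔV vs an
    independent voxel-column counting oracle at 0.2 mm, within 2 %."""
    spec = PhantomSpec(resolution=1.0)
    xs = np.arange(22.0, 38.0 + 0.5, 1.0)
    zs = np.arange(-24.0, -8.0 + 0.5, 1.0)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    pre_mesh = structured_grid_mesh(xs, zs, soft_height(spec, X, Z))
    post_mesh = transformed_mesh(pre_mesh, np.eye(3), [0, 2.0, 0])
    pre = clip_mesh_to_roi(pre_mesh, planes, "R")
    dv = volumetric_change(pre, post_mesh, frame, grid_mm=0.4)

    vox = 0.2
    gx = np.arange(pre.mesh.vertices[:, 0].min() + vox / 2,
                   pre.mesh.vertices[:, 0].max(), vox)
    gz = np.arange(pre.mesh.vertices[:, 2].min() + vox / 2,
                   pre.mesh.vertices[:, 2].max(), vox)
    h_pre = brute_force_heights(pre.mesh, gx, gz)
    h_post = brute_force_heights(post_mesh, gx, gz)
    both = ~np.isnan(h_pre) & ~np.isnan(h_post)
    # boolean voxel counting: number of voxel centres between the surfaces
    n_between = (np.floor(h_post[both] / vox) - np.floor(h_pre[both] / vox))
    dv_oracle = float(n_between.sum()) * vox ** 3
    assert dv == pytest.approx(dv_oracle, rel=0.02)


def test_curved_patch_movement_bounded_by_translation(frame, planes, phantom):
    """|ΔV/A| ≤ |d| for a pure +y translation of a curved patch."""
    d = 2.5
    post = transformed_mesh(phantom.soft, np.eye(3), [0, d, 0])
    pre = clip_mesh_to_roi(phantom.soft, planes, "R")
    move = average_sagittal_movement(
        volumetric_change(pre, post, frame), pre.surface_area)
    assert 0 < move <= d
    assert move == pytest.approx(d, rel=0.02)


@pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 5.0])
def test_bone_movement_recovers_pure_translation(phantom, frame, planes, d):
    """End-to-end: an applied pure advancement is recovered within 0.05 mm."""
    post, _ = apply_surgery(
        phantom, SurgeryParams(advancement=d, pose_translation_mm=0.0,
                               pose_rotation_deg=0.0))
    m = measure_region(phantom.bone, post.bone, planes, frame, "R", "bone")
    assert m.movement == pytest.approx(d, abs=0.05)
    assert m.movement * m.pre_area == pytest.approx(m.delta_volume, abs=1e-9)


def test_average_movement_formula_and_errors():
    assert average_sagittal_movement(10.0, 5.0) == pytest.approx(2.0)
    assert average_sagittal_movement(0.0, 123.0) == 0.0
    with pytest.raises(MeasurementError):
        average_sagittal_movement(10.0, 0.0)


def test_rotation_change_is_post_minus_pre():
    assert rotation_change(8.3, 11.1) == pytest.approx(2.8)
    assert rotation_change(4.4, 4.4) == 0.0


def test_stratification_boundaries():
    assert stratify_advancement(2.0) == "2-3 mm"     # left-closed bins
    assert stratify_advancement(4.01) == ">4 mm"
    assert stratify_advancement(4.0) == ">4 mm"
    assert stratify_advancement(1.0) == "1-2 mm"
    assert stratify_advancement(0.5) == "below-range"
    with pytest.raises(ValueError):
        stratify_advancement(-0.1)


def test_roi_missing_surface_raises(frame, planes):
    patch = flat_patch(size=4, res=0.5, y=60.0, x0=25.0, z0=-20.0)
    pre = clip_mesh_to_roi(patch, planes, "R")
    elsewhere = flat_patch(size=4, res=0.5, y=60.0, x0=-40.0, z0=-20.0)
    with pytest.raises(MeasurementError, match="coverage"):
        volumetric_change(pre, elsewhere, frame)
    far_patch = flat_patch(size=4, res=0.5, y=60.0, x0=-40.0, z0=-20.0)
    with pytest.raises(MeasurementError, match="ROI does not intersect"):
        clip_mesh_to_roi(far_patch, planes, "R")
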