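"""Surface meshes, rigid registration, deviation maps."""

import numpy as np
import pytest

from graftvol import (
    RigidTransform,
    VoxelGrid,
    deviation_map,
    extract_surface,
    mesh_volume,
    point_based_register,
)
from graftvol.errors import DegenerateLandmarksError, EmptyMaskError
from graftvol.surface_eval import SurfaceMesh, face_normals, is_closed, load_stl, save_stl


def sphere_grid(radius_mm, spacing=0.25, pad=2.0, center=(0.0, 0.0, 0.0)):
    lim = radius_mm + pad
    n = int(2 * lim / spacing)
    coords = -lim + (np.arange(n) + 0.5) * spacing
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    mask = (
        (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        < radius_mm**2
    )
    return VoxelGrid(mask.astype(np.uint8), spacing, np.full(3, coords[0]))


def test_single_voxel_gives_closed_octahedron():
    """The 0.5 iso-surface of one voxel is a closed octahedron through the
    cell-edge midpoints, enclosing spacing^3 / 6."""
    data = np.zeros((5, 5, 5), dtype=np.uint8)
    data[2, 2, 2] = 1
    mesh = extract_surface(VoxelGrid(data, 0.25))
    assert is_closed(mesh)
    assert mesh_volume(mesh) == pytest.approx(0.25**3 / 6.0, rel=1e-6)


def test_voxel_block_volume_approaches_nominal():
    data = np.zeros((8, 8, 8), dtype=np.uint8)
    data[2:6, 2:6, 2:6] = 1
    mesh = extract_surface(VoxelGrid(data, 0.25))
    assert is_closed(mesh)
    assert mesh_volume(mesh) == pytest.approx(64 * 0.25**3, rel=0.25)


def test_sphere_mesh_volume_matches_analytic_within_three_percent():
    grid = sphere_grid(3.0)
    mesh = extract_surface(grid)
    analytic = 4.0 / 3.0 * np.pi * 3.0**3
    assert mesh_volume(mesh) == pytest.approx(analytic, rel=0.03)
    # cross-check the divergence-theorem volume with an independent library
    import trimesh

    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    assert mesh_volume(mesh) == pytest.approx(abs(tm.volume), rel=1e-9)


def test_padded_mask_yields_translated_congruent_mesh():
    data = np.zeros((6, 6, 6), dtype=np.uint8)
    data[2:4, 2:4, 2:4] = 1
    a = extract_surface(VoxelGrid(data, 0.25))
    padded = np.pad(data, ((3, 0), (0, 0), (0, 0)))
    b = extract_surface(VoxelGrid(padded, 0.25, origin=(-3 * 0.25, 0, 0)))
    order_a = np.lexsort(a.vertices.T)
    order_b = np.lexsort(b.vertices.T)
    assert np.allclose(a.vertices[order_a], b.vertices[order_b], atol=1e-9)


def test_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        extract_surface(VoxelGrid(np.zeros((4, 4, 4)), 0.25))


# ---------------------------------------------------------------------------
# Registration


def random_landmarks(rng, n=6):
    return rng.uniform(-10, 10, size=(n, 3))


def test_identity_registration_has_zero_residual():
    rng = np.random.default_rng(0)
    p = random_landmarks(rng)
    t = point_based_register(None, None, (p, p))
    assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(t.translation, 0, atol=1e-12)
    assert t.residual_rms == pytest.approx(0.0, abs=1e-12)


def test_known_rigid_motion_is_recovered_to_micron_precision():
    rng = np.random.default_rng(1)
    p = random_landmarks(rng)
    angle = np.deg2rad(30)
    R = np.array(
        [
            [np.cos(angle), -np.sin(angle), 0],
            [np.sin(angle), np.cos(angle), 0],
            [0, 0, 1],
        ]
    )
    shift = np.array([3.0, -2.0, 5.0])
    q = p @ R.T + shift
    t = point_based_register(None, None, (p, q))
    assert np.allclose(t.rotation, R, atol=1e-6)
    assert np.allclose(t.translation, shift, atol=1e-6)
    assert np.allclose(t.apply(p), q, atol=1e-6)


def test_noisy_landmarks_leave_residual_at_noise_scale():
    rng = np.random.default_rng(2)
    residuals = []
    sigma = 0.1
    for _ in range(20):
        p = random_landmarks(rng, n=8)
        q = p + rng.normal(0, sigma, p.shape)
        residuals.append(point_based_register(None, None, (p, q)).residual_rms)
    mean_res = np.mean(residuals)
    assert 0.3 * sigma < mean_res < 3 * sigma


def test_collinear_landmarks_rejected():
    p = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    with pytest.raises(DegenerateLandmarksError):
        point_based_register(None, None, (p, p))
    with pytest.raises(DegenerateLandmarksError):
        point_based_register(None, None, (p[:2], p[:2]))


# ---------------------------------------------------------------------------
# Deviation maps


def test_self_deviation_is_zero():
    mesh = extract_surface(sphere_grid(3.0))
    dev = deviation_map(mesh, mesh)
    assert dev.max_abs == pytest.approx(0.0, abs=1e-9)


def test_concentric_spheres_have_half_millimetre_mean_deviation():
    ref = extract_surface(sphere_grid(5.0))
    test = extract_surface(sphere_grid(5.5))
    dev = deviation_map(test, ref)
    assert dev.mean == pytest.approx(0.5, abs=0.1)
    inner = deviation_map(ref, test)
    assert inner.mean == pytest.approx(-0.5, abs=0.1)


def test_deviation_summary_invariant_to_common_rigid_motion():
    """Moving test and reference by the same rigid transform, then
    registering through equally-moved landmarks, leaves the summary
    unchanged."""
    ref = extract_surface(sphere_grid(4.0))
    test = extract_surface(sphere_grid(4.5))
    rng = np.random.default_rng(3)
    landmarks = rng.uniform(-4, 4, size=(4, 3))
    base = deviation_map(
        test, ref, point_based_register(test, ref, (landmarks, landmarks))
    )

    angle = np.deg2rad(20)
    R = np.array(
        [
            [1, 0, 0],
            [0, np.cos(angle), -np.sin(angle)],
            [0, np.sin(angle), np.cos(angle)],
        ]
    )
    shift = np.array([1.0, 2.0, -3.0])
    moved_ref = SurfaceMesh(ref.vertices @ R.T + shift, ref.triangles)
    moved_test = SurfaceMesh(test.vertices @ R.T + shift, test.triangles)
    moved_marks = landmarks @ R.T + shift
    moved = deviation_map(
        moved_test,
        moved_ref,
        point_based_register(moved_test, moved_ref, (moved_marks, moved_marks)),
    )
    assert moved.mean == pytest.approx(base.mean, abs=1e-6)
    assert moved.rms == pytest.approx(base.rms, abs=1e-6)


def test_symmetric_deviation_sanity():
    """mean|d|(A->B) and mean|d|(B->A) agree within a mean edge length."""
    a = extract_surface(sphere_grid(4.0))
    b = extract_surface(sphere_grid(4.4))
    d_ab = deviation_map(a, b).mean_abs
    d_ba = deviation_map(b, a).mean_abs
    edges = a.vertices[a.triangles[:, 0]] - a.vertices[a.triangles[:, 1]]
    mean_edge = np.linalg.norm(edges, axis=1).mean()
    assert abs(d_ab - d_ba) < mean_edge


def test_outward_normals_point_away_from_center():
    mesh = extract_surface(sphere_grid(3.0))
    normals = face_normals(mesh)
    centroids = mesh.vertices[mesh.triangles].mean(axis=1)
    assert (np.einsum("ij,ij->i", normals, centroids) > 0).mean() > 0.99


def test_stl_round_trip(tmp_path):
    mesh = extract_surface(sphere_grid(2.0, spacing=0.5))
    path = tmp_path / "sphere.stl"
    save_stl(mesh, path)
    back = load_stl(path)
    assert len(back.triangles) == len(mesh.triangles)
    assert mesh_volume(back) == pytest.approx(abs(mesh_volume(mesh)), rel=1e-6)
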