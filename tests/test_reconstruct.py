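"""Volume assembly, volume measurement, meshing, cleanup and export."""

import math

import numpy as np
import pytest
import trimesh

import palate3d as p3
from palate3d.errors import EmptyStructureError
from palate3d.reconstruct import (
    LabeledVolume,
    SurfaceMesh,
    load_mesh,
    volume_report,
)
from palate3d.register import AlignedStack, RigidTransform2D
from palate3d.segment import CavityMask


def _aligned_from_planes(planes):
    masks = [CavityMask(pl.astype(np.uint8)) for pl in planes]
    return AlignedStack(
        masks=masks,
        transforms=[RigidTransform2D.identity()] * len(masks),
        reference_index=0,
    )


def test_assemble_identical_squares_gives_cuboid():
    sq = np.zeros((12, 16), np.uint8)
    sq[3:9, 4:12] = 1
    vol = p3.assemble_volume(_aligned_from_planes([sq] * 10), (2.0, 2.0, 7.0))
    assert vol.voxels.shape == (10, 12, 16)
    assert np.count_nonzero(vol.voxels) == 10 * 6 * 8
    assert p3.measure_volume(vol, 1) == pytest.approx(10 * 6 * 8 * 2 * 2 * 7)


def test_assemble_fills_degenerate_plane_from_nearest_neighbor():
    a = np.zeros((8, 8), np.uint8); a[2:6, 2:6] = 1
    b = np.zeros((8, 8), np.uint8)  # degenerate
    c = np.zeros((8, 8), np.uint8); c[3:7, 3:7] = 1
    vol = p3.assemble_volume(_aligned_from_planes([a, b, c]), (1, 1, 7))
    np.testing.assert_array_equal(vol.voxels[1], vol.voxels[0])


def test_measure_volume_arithmetic_and_absent_label():
    # 1000 voxels at (2, 2, 7) um spacing -> 28 000 um^3
    vol = LabeledVolume(np.ones((10, 10, 10), np.int16), (2.0, 2.0, 7.0))
    assert p3.measure_volume(vol, 1) == pytest.approx(28000.0)
    assert p3.measure_volume(vol, 5) == 0.0


def test_measure_volume_additive_and_permutation_invariant():
    rng = np.random.default_rng(1)
    vox = rng.integers(0, 3, (6, 7, 8)).astype(np.int16)
    vol = LabeledVolume(vox, (1.5, 2.0, 7.0))
    total = p3.measure_volume(vol, 1) + p3.measure_volume(vol, 2)
    assert total == pytest.approx(np.count_nonzero(vox) * vol.voxel_volume_um3)
    # axis permutation with correspondingly permuted spacing
    perm = LabeledVolume(np.transpose(vox, (2, 0, 1)), (7.0, 1.5, 2.0))
    assert p3.measure_volume(perm, 1) == pytest.approx(p3.measure_volume(vol, 1))


def test_voxelized_ellipsoid_volume_close_to_closed_form():
    spec = p3.PhantomSpec(
        image_size=(120, 80), n_slices=50, pixel_size=1.0,
        thickness=1.0, shapes=(
            p3.phantom.Ellipsoid(1, (60.0, 40.0, 25.0), (50.0, 30.0, 20.0)),
        ),
        noise_sd=0.0, jitter_sd=(0.0, 0.0),
    )
    truth = p3.build_truth(spec)
    analytic = 4 / 3 * math.pi * 50 * 30 * 20
    assert truth.volumes_um3[1] == pytest.approx(analytic, rel=0.03)


def test_extract_surface_single_voxel_closed_positive():
    """Marching cubes on one voxel yields the octahedron through the cell
    edge midpoints: closed, outward-wound, volume 1/6."""
    vol = LabeledVolume(np.ones((1, 1, 1), np.int16), (1.0, 1.0, 1.0))
    mesh = p3.extract_surface(vol, 1)
    tm = mesh.to_trimesh()
    assert tm.is_watertight
    assert tm.volume > 0
    assert tm.volume == pytest.approx(1 / 6, rel=1e-6)


def test_extract_surface_cuboid_volume():
    vol = LabeledVolume(np.ones((10, 10, 10), np.int16), (1.0, 1.0, 1.0))
    mesh = p3.extract_surface(vol, 1)
    assert mesh.to_trimesh().is_watertight
    assert mesh.enclosed_volume_um3 == pytest.approx(1000.0, rel=0.10)


def test_extract_surface_empty_label_rejected():
    vol = LabeledVolume(np.zeros((3, 3, 3), np.int16), (1, 1, 1))
    with pytest.raises(EmptyStructureError):
        p3.extract_surface(vol, 1)


def test_mesh_volume_agrees_with_voxel_count_on_phantom(desk_truth):
    vol = desk_truth.volume
    union = LabeledVolume((vol.voxels > 0).astype(np.int16), vol.spacing)
    mesh = p3.extract_surface(union, 1)
    vox_v = p3.measure_volume(union, 1)
    assert mesh.enclosed_volume_um3 == pytest.approx(vox_v, rel=0.05)


def test_surface_volume_converges_with_resolution():
    """Mesh/voxel volume error strictly decreases as the sampling of a fixed
    ellipsoid is refined across three resolutions."""
    errs = []
    for px in (4.0, 2.0, 1.0):
        n = int(64 / px)
        spec = p3.PhantomSpec(
            image_size=(n, n), n_slices=n, pixel_size=px, thickness=px,
            shapes=(p3.phantom.Ellipsoid(
                1, (32.0, 32.0, 32.0), (24.0, 18.0, 14.0)),),
            noise_sd=0.0, jitter_sd=(0.0, 0.0),
        )
        truth = p3.build_truth(spec)
        mesh = p3.extract_surface(truth.volume, 1)
        v_vox = p3.measure_volume(truth.volume, 1)
        errs.append(abs(mesh.enclosed_volume_um3 - v_vox) / v_vox)
    assert errs[0] > errs[1] > errs[2]


def _noisy_sphere(seed=0, radius=10.0, noise=0.5):
    sph = trimesh.creation.icosphere(subdivisions=3, radius=radius)
    rng = np.random.default_rng(seed)
    rad = np.linalg.norm(sph.vertices, axis=1)
    v = sph.vertices * (1 + rng.normal(0, noise, len(rad)) / rad)[:, None]
    return SurfaceMesh(v, sph.faces), sph


def test_remove_spikes_leaves_clean_sphere_untouched():
    sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    mesh = SurfaceMesh(sph.vertices.copy(), sph.faces)
    out = p3.remove_spikes(mesh)
    np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-9)
    np.testing.assert_array_equal(out.faces, mesh.faces)


def test_remove_spikes_snaps_displaced_vertex_back():
    sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    mesh = SurfaceMesh(sph.vertices.copy(), sph.faces)
    mesh.vertices[7] *= 11.0  # 10 radii outward
    out = p3.remove_spikes(mesh)
    assert abs(np.linalg.norm(out.vertices[7]) - 10.0) < 1.0
    np.testing.assert_array_equal(out.faces, mesh.faces)


def test_remove_spikes_tiny_mesh_unchanged():
    tri = SurfaceMesh(np.eye(3), np.array([[0, 1, 2]]))
    out = p3.remove_spikes(tri)
    np.testing.assert_array_equal(out.vertices, tri.vertices)


def test_smoothing_zero_iterations_is_identity():
    mesh, _ = _noisy_sphere()
    out = p3.smooth_mesh(mesh, iterations=0)
    np.testing.assert_array_equal(out.vertices, mesh.vertices)


def test_smoothing_reduces_noise_and_preserves_volume():
    """10 Taubin iterations halve the RMS radial noise of a perturbed sphere
    while changing the enclosed volume by <= 5%."""
    mesh, _ = _noisy_sphere(seed=0)
    rms0 = np.sqrt(np.mean((np.linalg.norm(mesh.vertices, axis=1) - 10) ** 2))
    out = p3.smooth_mesh(mesh, iterations=10)
    rms1 = np.sqrt(np.mean((np.linalg.norm(out.vertices, axis=1) - 10) ** 2))
    assert rms1 <= 0.5 * rms0
    v0, v1 = mesh.enclosed_volume_um3, out.enclosed_volume_um3
    assert abs(v1 - v0) / v0 <= 0.05


def test_export_unit_cube_stl_has_12_triangles(tmp_path):
    box = trimesh.creation.box(extents=(1, 1, 1))
    mesh = SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
    path = p3.export_mesh(mesh, tmp_path / "cube.stl")
    again = load_mesh(path)
    assert len(again.faces) == 12


def test_export_ply_carries_structure_color(tmp_path):
    box = trimesh.creation.box(extents=(2, 1, 1))
    mesh = SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces),
                       label=3, color="orange")
    path = p3.export_mesh(mesh, tmp_path / "shelf.ply")
    tm = trimesh.load(path, process=False)
    np.testing.assert_array_equal(tm.visual.vertex_colors[0][:3], (255, 165, 0))


def test_export_import_round_trip(tmp_path, desk_truth):
    vol = desk_truth.volume
    mesh = p3.extract_surface(
        LabeledVolume((vol.voxels > 0).astype(np.int16), vol.spacing), 1)
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.vertices)
    for fmt in ("stl", "ply"):
        path = p3.export_mesh(mesh, tmp_path / f"cavity.{fmt}")
        again = load_mesh(path)
        assert len(again.faces) == len(mesh.faces)
        # STL stores per-triangle float32 vertices; every re-imported point
        # must coincide with an original vertex to float32 precision
        d, _ = tree.query(again.vertices)
        assert d.max() <= 1e-3


def test_volume_report_lists_all_labels(tmp_path, desk_truth):
    path = volume_report(desk_truth.volume, tmp_path / "report.csv")
    rows = path.read_text().strip().splitlines()
    assert rows[0] == "label,voxels,volume_um3"
    labels = [int(r.split(",")[0]) for r in rows[1:]]
    assert labels == desk_truth.volume.labels()
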