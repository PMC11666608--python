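"""Mesh substrate: I/O, normals, mirroring, plane cutting."""

import numpy as np
import pytest

from bisym import (
    EmptyMeshError,
    MeshFormatError,
    TriSurface,
    closest_points_on_surface,
    compute_vertex_normals,
    cut_at_height,
    cut_below_plane,
    load_mesh,
    mirror_sagittal,
    save_mesh,
)
from bisym.anatomy import AnatomicalFrame
from bisym.mesh import merge_duplicate_vertices

from conftest import open_cylinder

FRAME = AnatomicalFrame.canonical()


# -- loading -------------------------------------------------------------------

TETRA_PLY = """ply
format ascii 1.0
element vertex 4
property float x
property float y
property float z
element face 4
property list uchar int vertex_indices
end_header
0 0 0
1 0 0
0 1 0
0 0 1
3 0 2 1
3 0 1 3
3 0 3 2
3 1 2 3
"""


def test_load_ply_tetrahedron(tmp_path):
    p = tmp_path / "tetra.ply"
    p.write_text(TETRA_PLY)
    mesh = load_mesh(p)
    assert mesh.n_vertices == 4 and mesh.n_faces == 4
    assert mesh.signed_volume() == pytest.approx(1.0 / 6.0, abs=1e-12)


def test_load_stl_merges_duplicated_vertices(tmp_path, tetra):
    p = tmp_path / "tetra.stl"
    save_mesh(tetra, p)
    mesh = load_mesh(p)
    assert mesh.n_vertices == 4  # STL stores 12 per-facet corner records
    assert mesh.n_faces == 4
    assert abs(mesh.signed_volume()) == pytest.approx(1.0 / 6.0, abs=1e-9)


def test_load_truncated_ply_raises(tmp_path):
    # header declares 8 vertices, file carries 4
    p = tmp_path / "bad.ply"
    p.write_text(TETRA_PLY.replace("element vertex 4", "element vertex 8"))
    with pytest.raises((MeshFormatError, EmptyMeshError)):
        load_mesh(p)


def test_empty_mesh_rejected():
    with pytest.raises(EmptyMeshError):
        TriSurface(np.zeros((3, 3)), np.empty((0, 3), dtype=int))


def test_degenerate_face_rejected():
    v = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])  # collinear
    with pytest.raises(ValueError):
        TriSurface(v, np.array([[0, 1, 2]]))


# -- normals -------------------------------------------------------------------

def _symmetric_cube() -> TriSurface:
    """Cube triangulated with face diagonals through the even-parity corners,
    so every corner has equal incident area on its three faces."""
    v = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)], float)
    even = [(c < 0).sum() % 2 == 0 for c in v]
    faces = []
    for axis in range(3):
        for s in (-1, 1):
            quad = [i for i in range(8) if v[i][axis] == s]
            u, w = [a for a in range(3) if a != axis]
            # order CCW viewed from outside: (u, w, axis) is right-handed for
            # axis 0 and 2, left-handed for axis 1
            handed = 1 if axis != 1 else -1
            ang = np.arctan2(v[quad, w], v[quad, u])
            quad = [quad[i] for i in np.argsort(ang if s * handed > 0 else -ang)]
            while not even[quad[0]]:
                quad = quad[1:] + quad[:1]
            faces += [[quad[0], quad[1], quad[2]], [quad[0], quad[2], quad[3]]]
    return TriSurface(v, np.array(faces))


def test_cube_corner_normals_symmetric_and_outward():
    cube = _symmetric_cube()
    assert cube.signed_volume() == pytest.approx(8.0, abs=1e-12)
    n = compute_vertex_normals(cube).vertex_normals
    assert cube.n_vertices == 8
    # corner symmetry: all components equal in magnitude
    assert np.allclose(np.abs(n), 1 / np.sqrt(3), atol=1e-12)
    # outward: aligned with the corner direction from the centre
    assert (np.einsum("ij,ij->i", n, cube.vertices) > 0).all()


def test_sphere_normals_radial_within_2_degrees(icosphere):
    n = icosphere.vertex_normals
    radial = icosphere.vertices / np.linalg.norm(icosphere.vertices, axis=1, keepdims=True)
    cos = np.einsum("ij,ij->i", n, radial)
    assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() < 2.0


def test_flat_square_normals_point_up():
    v = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
    f = np.array([[0, 1, 2], [0, 2, 3]])  # CCW seen from +z
    n = TriSurface(v, f).vertex_normals
    assert np.allclose(n, [0, 0, 1], atol=1e-12)


def test_vertex_normals_unit_length(tibia_default):
    n = tibia_default.vertex_normals
    assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)


def test_outward_orientation_of_closed_mesh(tibia_default):
    c = tibia_default.vertices.mean(axis=0)
    dots = np.einsum("ij,ij->i", tibia_default.vertex_normals, tibia_default.vertices - c)
    assert dots.mean() > 0


# -- mirroring -----------------------------------------------------------------

def test_mirror_is_involution(tetra):
    twice = mirror_sagittal(mirror_sagittal(tetra, FRAME), FRAME)
    assert (twice.vertices == tetra.vertices).all()
    assert (twice.faces == tetra.faces).all()


def test_mirror_preserves_signed_volume(tetra):
    assert mirror_sagittal(tetra, FRAME).signed_volume() == pytest.approx(1.0 / 6.0, abs=1e-15)


def test_mirror_of_symmetric_mesh_is_identity_up_to_reindexing(icosphere):
    mirrored = mirror_sagittal(icosphere, FRAME)
    # brute-force nearest-vertex Hausdorff distance
    d2 = ((mirrored.vertices[:, None, :] - icosphere.vertices[None, :, :]) ** 2).sum(-1)
    assert np.sqrt(d2.min(axis=1)).max() < 1e-9
    assert np.sqrt(d2.min(axis=0)).max() < 1e-9


# -- cutting -------------------------------------------------------------------

def test_cut_cylinder_lateral_area():
    cyl = open_cylinder(radius=10.0, height=100.0, n_seg=192, n_ring=41)
    cut = cut_at_height(cyl, FRAME, 30.0)
    expected = 2 * np.pi * 10.0 * 30.0
    assert cut.distal_part.area() == pytest.approx(expected, rel=0.005)


def test_cut_above_mesh_is_noop(icosphere):
    cut = cut_at_height(icosphere, FRAME, 200.0)
    assert cut.distal_part.n_vertices == icosphere.n_vertices
    assert len(cut.boundary_loop) == 0


def test_cut_below_mesh_raises(icosphere):
    with pytest.raises(EmptyMeshError):
        cut_below_plane(icosphere, [0, 0, -5.0], [0, 0, 1.0])


def test_cut_through_vertex_ring_keeps_on_plane_vertices():
    cyl = open_cylinder(radius=5.0, height=60.0, n_seg=48, n_ring=7)  # rings every 10 mm
    cut = cut_at_height(cyl, FRAME, 30.0)
    z = cut.distal_part.vertices[:, 2]
    assert z.max() <= 30.0 + 1e-9
    # the full ring at z=30 is retained (tie toward inclusion)
    assert (np.abs(z - 30.0) < 1e-9).sum() >= 48


def test_cut_new_vertices_lie_on_plane(icosphere):
    cut = cut_at_height(icosphere, FRAME, 1.3)
    z = cut.distal_part.vertices[:, 2]
    plane = icosphere.vertices[:, 2].min() + 1.3
    assert z.max() <= plane + 1e-9
    on_plane = cut.boundary_vertex_mask
    assert on_plane.any()
    assert np.abs(z[on_plane] - plane).max() <= 1e-9
    assert np.abs(cut.boundary_loop[:, 2] - plane).max() <= 1e-9


@pytest.mark.parametrize("height", [0.4, 1.0, 1.7])
def test_cut_conserves_area(icosphere, height):
    plane_z = icosphere.vertices[:, 2].min() + height
    distal = cut_below_plane(icosphere, [0, 0, plane_z], [0, 0, 1.0])
    proximal = cut_below_plane(icosphere, [0, 0, plane_z], [0, 0, -1.0])
    total = distal.distal_part.area() + proximal.distal_part.area()
    assert total == pytest.approx(icosphere.area(), rel=1e-6)


# -- saving --------------------------------------------------------------------

def test_ply_roundtrip_double_precision(tmp_path, icosphere):
    big = TriSurface(icosphere.vertices * 100.0, icosphere.faces)
    p = tmp_path / "sphere.ply"
    save_mesh(big, p)
    back = load_mesh(p)
    assert back.n_vertices == big.n_vertices
    assert np.abs(back.vertices - big.vertices).max() < 1e-6
    assert (back.faces == big.faces).all()


def test_ply_carries_quality_scalar(tmp_path, tetra):
    import trimesh

    p = tmp_path / "q.ply"
    scalar = np.array([0.0, 1.0, 2.0, 5.0])
    save_mesh(tetra, p, per_vertex_scalar=scalar)
    raw = trimesh.load(str(p), process=False).metadata["_ply_raw"]
    assert np.allclose(raw["vertex"]["data"]["quality"], scalar)


def test_scalar_length_mismatch_raises(tmp_path, tetra):
    with pytest.raises(ValueError):
        save_mesh(tetra, tmp_path / "x.ply", per_vertex_scalar=np.zeros(3))


def test_stl_drops_scalars_with_warning(tmp_path, tetra):
    with pytest.warns(UserWarning, match="cannot store per-vertex scalars"):
        save_mesh(tetra, tmp_path / "x.stl", per_vertex_scalar=np.zeros(4))
    assert load_mesh(tmp_path / "x.stl").n_faces == 4


def test_obj_roundtrip(tmp_path, tetra):
    p = tmp_path / "t.obj"
    save_mesh(tetra, p)
    back = load_mesh(p)
    assert back.n_vertices == 4 and back.n_faces == 4


# -- closest point -------------------------------------------------------------

def test_closest_point_matches_bruteforce(icosphere):
    import trimesh.triangles as tt

    rng = np.random.default_rng(0)
    queries = rng.normal(size=(40, 3)) * 1.3
    fast = closest_points_on_surface(icosphere, queries)
    tris = icosphere.triangles()
    for q, f in zip(queries, fast):
        pts = tt.closest_point(tris, np.repeat(q[None], len(tris), axis=0))
        d = np.linalg.norm(pts - q, axis=1)
        assert np.linalg.norm(f - q) == pytest.approx(d.min(), abs=1e-9)
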