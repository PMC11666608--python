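"""Rigid and nonrigid CPD registration: recovery, invariants, correspondences."""

import hypothesis as hyp
import hypothesis.strategies as st
import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from bisym import (
    CPDParams,
    DegenerateInputError,
    NonRigidWarp,
    RigidTransform,
    TriSurface,
    correspondence_from_warp,
    farthest_point_sample,
    nonrigid_cpd,
    rigid_cpd,
)
from bisym.cpd import cpd_posteriors

from conftest import open_cylinder


def bone_cloud(n=500, seed=0):
    rng = np.random.default_rng(seed)
    # elongated anisotropic cloud, same aspect as a long-bone sample
    pts = rng.normal(size=(n, 3)) * np.array([8.0, 10.0, 40.0])
    return pts


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(rng.uniform(0, 30)) * axis).as_matrix()
    return RigidTransform(R, rng.uniform(-20, 20, 3))


# -- RigidTransform group structure --------------------------------------------

@hyp.given(st.integers(0, 10_000), st.integers(0, 10_000))
@hyp.settings(deadline=None, derandomize=True, max_examples=40)
def test_rigid_transform_group_axioms(seed_a, seed_b):
    a, b = random_rigid(seed_a), random_rigid(seed_b)
    pts = bone_cloud(50, seed_a)
    assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9)
    ident = a.compose(a.inverse())
    assert np.allclose(ident.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(ident.translation, 0, atol=1e-9)


def test_reflection_rejected():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))


# -- rigid CPD -----------------------------------------------------------------

def test_rigid_self_registration_is_identity():
    pts = bone_cloud(200)
    T, report = rigid_cpd(pts, pts, CPDParams(outlier_weight_w=0.0))
    assert np.abs(T.rotation - np.eye(3)).max() < 1e-6
    assert np.abs(T.translation).max() < 1e-6
    assert report.final_sigma2 < 1e-6


def test_rigid_recovers_known_transform():
    pts = bone_cloud(500)
    R = Rotation.from_rotvec(np.radians(10.0) * np.array([0, 0, 1.0])).as_matrix()
    applied = RigidTransform(R, [1.0, 2.0, 3.0])
    T, _ = rigid_cpd(applied.apply(pts), pts)
    residual = T.compose(applied)
    assert residual.rotation_angle_deg() < np.degrees(1e-4)
    assert np.linalg.norm(residual.translation) < 1e-4


def test_rigid_robust_to_outliers():
    rng = np.random.default_rng(3)
    pts = bone_cloud(500, 3)
    applied = random_rigid(7)
    moving = applied.apply(pts)
    k = 25  # 5% outliers
    lo, hi = moving.min(axis=0), moving.max(axis=0)
    moving[rng.choice(len(moving), k, replace=False)] = rng.uniform(lo, hi, (k, 3))
    T, _ = rigid_cpd(moving, pts, CPDParams(outlier_weight_w=0.1))
    residual = T.compose(applied)
    assert np.linalg.norm(residual.translation) < 0.1


def test_rigid_equivariance_under_pre_transform():
    pts = bone_cloud(300)
    moving = pts + np.random.default_rng(1).normal(0, 0.05, pts.shape)
    base, _ = rigid_cpd(moving, pts)
    for seed in range(3):
        pre = random_rigid(seed + 50)
        T, _ = rigid_cpd(pre.apply(moving), pts)
        combined = T.compose(pre)
        assert np.abs(combined.rotation - base.rotation).max() < 1e-4
        assert np.abs(combined.translation - base.translation).max() < 1e-4


def test_rigid_objective_non_increasing():
    pts = bone_cloud(400, 5)
    moving = random_rigid(5).apply(pts)
    _, report = rigid_cpd(moving, pts)
    trace = np.asarray(report.objective_trace)
    assert (np.diff(trace) <= 1e-8 * np.abs(trace[:-1]) + 1e-12).all()


def test_posterior_columns_sum_to_one():
    pts = bone_cloud(80, 2)
    P, p_out, _ = cpd_posteriors(pts, pts + 0.5, sigma2=4.0, w=0.1)
    assert np.abs(P.sum(axis=0) + p_out - 1.0).max() < 1e-10


@pytest.mark.parametrize("bad", [
    np.zeros((3, 3)),                              # too few points
    np.c_[np.arange(10.0), np.arange(10.0), np.zeros(10)],  # rank-deficient
])
def test_rigid_degenerate_inputs_rejected(bad):
    good = bone_cloud(50)
    with pytest.raises(DegenerateInputError):
        rigid_cpd(bad, good)


def test_nonfinite_coordinates_rejected():
    pts = bone_cloud(50)
    bad = pts.copy()
    bad[0, 0] = np.nan
    with pytest.raises(DegenerateInputError):
        rigid_cpd(bad, pts)


# -- nonrigid CPD --------------------------------------------------------------

def grid_plate(half=20.0, n=41):
    g = np.linspace(-half, half, n)
    X, Y = np.meshgrid(g, g)
    return np.c_[X.ravel(), Y.ravel(), np.zeros(X.size)]


def test_nonrigid_self_registration_is_identity():
    pts = grid_plate(10.0, 15)
    warp, _ = nonrigid_cpd(pts, pts)
    assert np.abs(warp.coefficients).max() < 1e-6
    assert np.abs(warp.displaced_points - pts).max() < 1e-6


def test_zero_coefficient_warp_is_exact_identity():
    pts = grid_plate(10.0, 9)
    warp = NonRigidWarp(pts, kernel_width_beta=3.0, coefficients=np.zeros_like(pts))
    assert (warp.transform(pts) == pts).all()


def test_nonrigid_tracks_smooth_bump():
    moving = grid_plate(20.0, 41)
    bump = 1.0 * np.exp(-(moving[:, 0] ** 2 + moving[:, 1] ** 2) / (2 * 5.0**2))
    fixed = moving + np.c_[np.zeros((len(moving), 2)), bump]
    warp, _ = nonrigid_cpd(moving, fixed, CPDParams(outlier_weight_w=0.0))
    d, _ = cKDTree(fixed).query(warp.displaced_points)
    assert d.mean() < 0.05


def test_lambda_increases_smoothness():
    rng = np.random.default_rng(0)
    moving = grid_plate(20.0, 29)
    fixed = moving + rng.normal(0, 0.5, moving.shape)

    def roughness(lam):
        warp, _ = nonrigid_cpd(moving, fixed, CPDParams(nonrigid_lambda=lam))
        disp = warp.displaced_points - moving
        # mean squared displacement difference between grid neighbours
        d = disp.reshape(29, 29, 3)
        return float(((d[1:] - d[:-1]) ** 2).sum() + ((d[:, 1:] - d[:, :-1]) ** 2).sum())

    assert roughness(1e6) < roughness(10.0) < roughness(0.1)


def test_lambda_zero_warns():
    pts = grid_plate(5.0, 5)
    with pytest.warns(UserWarning, match="ill-posed"):
        nonrigid_cpd(pts, pts, CPDParams(nonrigid_lambda=0.0))


# -- correspondences -----------------------------------------------------------

def test_coincident_surfaces_give_zero_distances():
    surf = open_cylinder(10.0, 30.0, 48, 7)
    warp = NonRigidWarp(surf.vertices, 3.0, np.zeros_like(surf.vertices))
    corr = correspondence_from_warp(surf.vertices, warp, surf)
    assert corr.distances_mm.max() < 1e-9


def test_parallel_plates_distance():
    lower = grid_plate(10.0, 21)
    upper = lower + [0.0, 0.0, 2.0]
    # triangulate the upper plate
    idx = np.arange(21 * 21).reshape(21, 21)
    faces = []
    for i in range(20):
        for j in range(20):
            faces += [[idx[i, j], idx[i + 1, j], idx[i, j + 1]],
                      [idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]]]
    plate = TriSurface(upper, np.array(faces))
    warp, _ = nonrigid_cpd(lower, upper, CPDParams(outlier_weight_w=0.0))
    corr = correspondence_from_warp(lower, warp, plate)
    assert np.abs(corr.distances_mm - 2.0).max() < 1e-3


def test_offset_surface_median_distance(icosphere):
    # fixed surface is the moving sphere offset 0.5 mm along the normal
    r = 20.0
    moving = icosphere.vertices * r
    fixed = TriSurface(icosphere.vertices * (r + 0.5), icosphere.faces)
    warp, _ = nonrigid_cpd(moving, fixed.vertices, CPDParams(outlier_weight_w=0.0))
    corr = correspondence_from_warp(moving, warp, fixed)
    assert np.median(corr.distances_mm) == pytest.approx(0.5, rel=0.05)


def test_correspondence_distance_definition():
    surf = open_cylinder(10.0, 30.0, 48, 7)
    warp = NonRigidWarp(surf.vertices, 3.0, np.zeros_like(surf.vertices))
    corr = correspondence_from_warp(surf.vertices + [0.3, 0, 0], warp, surf)
    recomputed = np.linalg.norm(corr.right_points - corr.left_points, axis=1)
    assert np.abs(recomputed - corr.distances_mm).max() <= 1e-12


# -- subsampling ---------------------------------------------------------------

def test_farthest_point_sampling_is_deterministic_and_spreading():
    pts = bone_cloud(400, 9)
    a = farthest_point_sample(pts, 50, seed=4)
    b = farthest_point_sample(pts, 50, seed=4)
    assert (a == b).all()
    assert len(np.unique(a)) == 50
    # max-min spread beats random thinning
    rng = np.random.default_rng(4)
    rand = rng.choice(len(pts), 50, replace=False)

    def min_gap(idx):
        sub = pts[idx]
        d = np.linalg.norm(sub[:, None] - sub[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        return d.min()

    assert min_gap(a) > min_gap(rand)
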