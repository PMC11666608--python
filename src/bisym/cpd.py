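"""Coherent Point Drift (CPD) point-set registration, rigid and nonrigid.

The moving point set is treated as the centroids of an isotropic Gaussian
mixture fitted to the fixed set by expectation-maximisation, with a uniform
component of weight ``w`` absorbing outliers. The rigid variant solves the
M-step in closed form (SVD of the weighted cross-covariance with determinant
correction; scale fixed at 1, so genuine size differences between the two
surfaces are *not* absorbed by the registration). The nonrigid variant
parameterises the displacement field as a Gaussian-kernel expansion over the
moving points with motion-coherence (kernel-norm) regularisation.

Implementation notes
--------------------
* ``sigma2`` is initialised to the mean pairwise squared distance between the
  two sets divided by the dimension, the standard CPD choice.
* The objective traced per iteration is the negative log-likelihood of the
  fixed points under the mixture (including the uniform component); EM makes
  it non-increasing up to floating point.
* The uniform outlier density is taken as ``1/V`` with ``V`` the volume of
  the fixed set's axis-aligned bounding box (inflated slightly to avoid a
  degenerate flat box).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .mesh import TriSurface, closest_points_on_surface


class DegenerateInputError(ValueError):
    """Point set too small or degenerate (coplanar/collinear) for registration."""


@dataclass
class CPDParams:
    """Hyperparameters of the CPD expectation-maximisation.

    outlier_weight_w:
        Mixture weight of the uniform outlier component, in [0, 1).
    tolerance:
        Relative change of the EM negative log-likelihood at which to stop.
    nonrigid_beta:
        Width (mm) of the Gaussian kernel carrying the nonrigid displacement
        field; larger values force longer-range coherent motion.
    nonrigid_lambda:
        Weight of the motion-coherence regulariser; larger values yield
        smoother (ultimately near-rigid) displacement fields.
    subsample_count:
        Maximum number of points fed to EM (farthest-point subsampling);
        ``"all"`` disables subsampling.
    """

    outlier_weight_w: float = 0.1
    max_iterations: int = 150
    tolerance: float = 1e-8
    nonrigid_beta: float = 6.0
    nonrigid_lambda: float = 10.0
    subsample_count: int | str = 5000

    def __post_init__(self):
        if not (0.0 <= self.outlier_weight_w < 1.0):
            raise ValueError("outlier_weight_w must be in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.nonrigid_beta <= 0:
            raise ValueError("nonrigid_beta must be positive")
        if self.nonrigid_lambda < 0:
            raise ValueError("nonrigid_lambda must be non-negative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal within 1e-9")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 (reflection or scale)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriSurface) -> TriSurface:
        return mesh.transformed(self.rotation, self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}


@dataclass
class NonRigidWarp:
    """Gaussian-kernel displacement field fitted by nonrigid CPD.

    The warp of an arbitrary point p is ``p + sum_j G(p, y_j) w_j`` where the
    ``y_j`` are the source (moving) points used in the fit, ``G`` the Gaussian
    kernel of width ``kernel_width_beta`` and ``w_j`` the fitted coefficient
    vectors. With all coefficients zero the warp is exactly the identity.
    """

    source_points: np.ndarray
    kernel_width_beta: float
    coefficients: np.ndarray

    def __post_init__(self):
        self.source_points = np.asarray(self.source_points, dtype=np.float64)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != self.source_points.shape:
            raise ValueError("coefficients must be one 3-vector per source point")

    def kernel(self, points: np.ndarray) -> np.ndarray:
        d2 = cdist(np.asarray(points, dtype=np.float64), self.source_points, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.kernel_width_beta**2))

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        if not self.coefficients.any():
            return points.copy()
        return points + self.kernel(points) @ self.coefficients

    @property
    def displaced_points(self) -> np.ndarray:
        return self.transform(self.source_points)


@dataclass
class RegistrationReport:
    """Diagnostics of one EM run (serialisable to a JSON run record)."""

    iterations_run: int = 0
    final_sigma2: float = np.nan
    objective_trace: list = field(default_factory=list)
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "iterations_run": self.iterations_run,
            "final_sigma2": self.final_sigma2,
            "objective_first": self.objective_trace[0] if self.objective_trace else None,
            "objective_final": self.objective_trace[-1] if self.objective_trace else None,
            "converged": self.converged,
        }


@dataclass
class CorrespondenceSet:
    """Paired points on the right surface and the superimposed mirrored-left
    surface, with their Euclidean separations in mm — the primary measurement
    of left-right asymmetry."""

    right_points: np.ndarray
    left_points: np.ndarray
    distances_mm: np.ndarray
    articular_mask: np.ndarray = None

    def __post_init__(self):
        self.right_points = np.asarray(self.right_points, dtype=np.float64)
        self.left_points = np.asarray(self.left_points, dtype=np.float64)
        self.distances_mm = np.asarray(self.distances_mm, dtype=np.float64)
        if self.articular_mask is None:
            self.articular_mask = np.ones(len(self.right_points), dtype=bool)
        self.articular_mask = np.asarray(self.articular_mask, dtype=bool)
        d = np.linalg.norm(self.right_points - self.left_points, axis=1)
        if not np.allclose(d, self.distances_mm, atol=1e-12, rtol=0):
            raise ValueError("stored distances disagree with stored point pairs")

    def __len__(self) -> int:
        return len(self.distances_mm)


# -- shared EM machinery -------------------------------------------------------


def _validate_cloud(points: np.ndarray, minimum: int, require_rank3: bool) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateInputError(f"expected (n, 3) point set, got {pts.shape}")
    if not np.isfinite(pts).all():
        raise DegenerateInputError("non-finite coordinates in point set")
    if len(pts) < minimum:
        raise DegenerateInputError(f"need at least {minimum} points, got {len(pts)}")
    if require_rank3:
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3:
            raise DegenerateInputError("point set is coplanar/collinear (rank < 3)")
    return pts


def _init_sigma2(X: np.ndarray, TY: np.ndarray) -> float:
    n, m = len(X), len(TY)
    sx = X.sum(axis=0)
    sy = TY.sum(axis=0)
    total = m * (X**2).sum() + n * (TY**2).sum() - 2.0 * sx @ sy
    return float(total / (3.0 * n * m))


def _uniform_density(X: np.ndarray) -> float:
    extent = X.max(axis=0) - X.min(axis=0)
    extent = np.maximum(extent, 1e-3)
    return float(1.0 / np.prod(extent))


def cpd_posteriors(X: np.ndarray, TY: np.ndarray, sigma2: float, w: float,
                   uniform_density: float | None = None):
    """E-step of CPD: posterior responsibilities and negative log-likelihood.

    Returns ``(P, p_outlier, nll)`` where ``P[m, n]`` is the posterior that
    fixed point ``n`` was generated by moving centroid ``m`` and ``p_outlier[n]``
    the posterior of the uniform component; each column of ``P`` plus its
    outlier posterior sums to one.
    """
    X = np.asarray(X, dtype=np.float64)
    TY = np.asarray(TY, dtype=np.float64)
    n, m = len(X), len(TY)
    if uniform_density is None:
        uniform_density = _uniform_density(X)
    K = np.exp(-cdist(TY, X, "sqeuclidean") / (2.0 * sigma2))
    gauss_norm = (2.0 * np.pi * sigma2) ** 1.5
    # p(x_n) = (1-w)/M * sum_m N(x_n; T y_m, sigma2 I) + w * u
    c = gauss_norm * (w / max(1.0 - w, 1e-300)) * m * uniform_density
    denom = K.sum(axis=0) + c
    denom = np.maximum(denom, 1e-300)
    P = K / denom
    p_out = c / denom
    nll = float(-(np.log(denom).sum() + n * (np.log1p(-w) - np.log(m) - np.log(gauss_norm))))
    return P, p_out, nll


def _converged(trace: list, tol: float) -> bool:
    if len(trace) < 2:
        return False
    prev, cur = trace[-2], trace[-1]
    return abs(prev - cur) <= tol * (abs(prev) + 1e-12)


# -- rigid CPD -----------------------------------------------------------------


def rigid_cpd(moving: np.ndarray, fixed: np.ndarray,
              params: CPDParams | None = None) -> tuple[RigidTransform, RegistrationReport]:
    """Register ``moving`` onto ``fixed`` by a proper rigid transform.

    EM over the CPD Gaussian mixture; M-step rotation from the SVD of the
    weighted cross-covariance with determinant correction, scale fixed at 1.
    Returns the transform mapping moving points onto the fixed set and a
    report with the objective trace.
    """
    params = params or CPDParams()
    Y = _validate_cloud(moving, 4, require_rank3=True)
    X = _validate_cloud(fixed, 4, require_rank3=True)
    w = params.outlier_weight_w
    u_density = _uniform_density(X)

    R = np.eye(3)
    t = np.zeros(3)
    TY = Y
    sigma2 = _init_sigma2(X, TY)
    report = RegistrationReport()

    for it in range(params.max_iterations):
        P, _, nll = cpd_posteriors(X, TY, sigma2, w, u_density)
        report.objective_trace.append(nll)
        report.iterations_run = it + 1

        P1 = P.sum(axis=1)          # (M,)
        Pt1 = P.sum(axis=0)         # (N,)
        Np = P1.sum()
        if Np <= 0 or not np.isfinite(Np):
            break
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y) / Np
        Xc = X - mu_x
        Yc = Y - mu_y
        A = (P @ Xc).T @ Yc         # cross-covariance, (3, 3)
        U, S, Vt = np.linalg.svd(A)
        C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ C @ Vt
        t = mu_x - R @ mu_y
        TY = Y @ R.T + t
        trAR = np.trace(A.T @ R)
        sigma2 = (
            (Pt1 * (Xc**2).sum(axis=1)).sum()
            - 2.0 * trAR
            + (P1 * (Yc**2).sum(axis=1)).sum()
        ) / (3.0 * Np)
        sigma2 = max(float(sigma2), 1e-12)

        if _converged(report.objective_trace, params.tolerance):
            report.converged = True
            break

    report.final_sigma2 = float(sigma2)
    return RigidTransform(R, t), report


# -- nonrigid CPD --------------------------------------------------------------


def nonrigid_cpd(moving: np.ndarray, fixed: np.ndarray,
                 params: CPDParams | None = None) -> tuple[NonRigidWarp, RegistrationReport]:
    """Fit a coherent Gaussian-kernel displacement field moving -> fixed.

    Solves, each M-step, the regularised linear system
    ``(diag(P1) G + lambda sigma2 I) W = P X - diag(P1) Y`` where ``G`` is the
    Gaussian kernel Gram matrix over the moving points.
    """
    params = params or CPDParams()
    Y = _validate_cloud(moving, 10, require_rank3=False)
    X = _validate_cloud(fixed, 10, require_rank3=False)
    if params.nonrigid_lambda == 0:
        warnings.warn("nonrigid_lambda = 0: unregularised displacement field is ill-posed")
    beta = params.nonrigid_beta
    lam = params.nonrigid_lambda
    w = params.outlier_weight_w
    u_density = _uniform_density(X)
    m = len(Y)

    G = np.exp(-cdist(Y, Y, "sqeuclidean") / (2.0 * beta**2))
    W = np.zeros_like(Y)
    TY = Y
    sigma2 = _init_sigma2(X, TY)
    report = RegistrationReport()

    for it in range(params.max_iterations):
        P, _, nll = cpd_posteriors(X, TY, sigma2, w, u_density)
        report.objective_trace.append(nll)
        report.iterations_run = it + 1

        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = P1.sum()
        if Np <= 0 or not np.isfinite(Np):
            break
        lhs = G * P1[:, None] + lam * sigma2 * np.eye(m)
        rhs = P @ X - P1[:, None] * Y
        W = np.linalg.solve(lhs, rhs)
        TY = Y + G @ W
        sigma2 = (
            (Pt1 * (X**2).sum(axis=1)).sum()
            - 2.0 * np.einsum("md,md->", P @ X, TY)
            + (P1 * (TY**2).sum(axis=1)).sum()
        ) / (3.0 * Np)
        sigma2 = max(float(sigma2), 1e-12)

        if _converged(report.objective_trace, params.tolerance):
            report.converged = True
            break

    report.final_sigma2 = float(sigma2)
    return NonRigidWarp(Y, beta, W), report


# -- correspondences -----------------------------------------------------------


def correspondence_from_warp(moving: np.ndarray, warp: NonRigidWarp,
                             fixed_surface: TriSurface) -> CorrespondenceSet:
    """Build correspondence pairs from a fitted warp.

    Each moving point is carried by the warp toward the fixed surface; its
    correspondence point is the closest point on the fixed surface to the
    warped position. The recorded distance is the Euclidean distance between
    the *original* (unwarped) moving point and that correspondence point, so
    it measures the separation of the two surfaces, not the warp residual.
    """
    from .mesh import EmptyMeshError

    moving = np.asarray(moving, dtype=np.float64)
    if fixed_surface.n_faces == 0:
        raise EmptyMeshError("fixed surface has no faces")
    warped = warp.transform(moving)
    matched = closest_points_on_surface(fixed_surface, warped)
    distances = np.linalg.norm(moving - matched, axis=1)
    return CorrespondenceSet(moving, matched, distances)


# -- subsampling ---------------------------------------------------------------


def farthest_point_sample(points: np.ndarray, count: int, seed: int = 0) -> np.ndarray:
    """Seeded farthest-point subsampling; returns sorted indices into ``points``.

    Greedy max-min: start from a seeded random point, repeatedly add the point
    farthest from the selected set. Gives near-uniform coverage of a surface
    sampling, which the CPD mixture prefers over uniform-random thinning.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if count >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    chosen = np.empty(count, dtype=np.int64)
    chosen[0] = rng.integers(n)
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    for i in range(1, count):
        chosen[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(points - points[chosen[i]], axis=1))
    return np.sort(chosen)


def subsample(points: np.ndarray, params: CPDParams, seed: int = 0) -> np.ndarray:
    """Apply the params' subsampling policy; returns the selected points."""
    if params.subsample_count == "all":
        return np.asarray(points, dtype=np.float64)
    return np.asarray(points, dtype=np.float64)[
        farthest_point_sample(points, int(params.subsample_count), seed)
    ]
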