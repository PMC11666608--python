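"""Synthetic distal-tibia pair generator with ground-truth asymmetry.

Serves as the statistical stand-in for a bilateral CT cohort: each specimen
is a pair of closed triangulated surfaces (left and right) whose true
left-right asymmetry is known exactly, enabling parameter-recovery tests of
the whole symmetry pipeline.

The canonical right bone is a smooth implicit surface — a tapered shaft
sweeping into a flared distal epiphysis, a concave plafond patch, a medial
malleolus prominence reaching below the plafond rim, and an anterolateral
tubercle bump — triangulated by marching cubes at a configurable voxel
pitch. Canonical axes: +x lateral, +y anterior, +z proximal; the plafond rim
sits at z = 0 and the malleolus tip at z = -malleolus_height_mm (the globally
most distal point, as in the real bone).

The left bone is the mirror image of the right with asymmetry applied as
truncated Gaussian bumps along the outward vertex normals at nameable sites
(medial malleolus, anterior tubercle, plafond centre — where the largest
left-right differences are seen clinically). Both bones then receive
independent Gaussian surface noise along their normals (segmentation noise at
sub-voxel scale) and an independent random rigid pose. Noise is applied
before the pose so it models surface/segmentation error, not motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.measure import marching_cubes
import trimesh

from .anatomy import AnatomicalFrame
from .cpd import RigidTransform
from .mesh import TriSurface

SITE_LABELS = ("medial_malleolus", "anterior_tubercle", "plafond_centre")


class ResolutionError(ValueError):
    """Mesh resolution too coarse to resolve the smallest asymmetry site."""


@dataclass
class AsymmetrySite:
    """One localised left-right asymmetry: a Gaussian bump of the given
    amplitude (mm, along the outward normal) and kernel width (mm), truncated
    to zero beyond three kernel widths."""

    site: str
    amplitude_mm: float
    width_mm: float

    def __post_init__(self):
        if self.site not in SITE_LABELS:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITE_LABELS}")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be >= 0")
        if self.width_mm <= 0:
            raise ValueError("width_mm must be > 0")


@dataclass
class PoseBounds:
    """Bounds of the random rigid pose applied independently to each bone."""

    max_rotation_deg: float = 20.0
    max_translation_mm: float = 20.0


@dataclass
class SyntheticPairSpec:
    """Full parameterisation of one synthetic left/right pair.

    Geometry defaults give a distal tibia of realistic adult proportions
    (shaft radius 12 mm flaring 1.5x at the epiphysis, 4 mm plafond
    concavity, 12 mm malleolus). ``noise_sd_mm`` defaults to 0.1 mm,
    sub-voxel for clinical CT voxels of ~0.8 mm. ``mesh_resolution`` is the
    marching-cubes voxel pitch in mm (approximate mesh edge length).
    The same spec and seed always regenerate byte-identical meshes.
    """

    shaft_radius_mm: float = 12.0
    flare_scale: float = 1.5
    plafond_concavity_depth_mm: float = 4.0
    malleolus_height_mm: float = 12.0
    malleolus_width_mm: float = 8.0
    tubercle_prominence_mm: float = 3.0
    shaft_length_mm: float = 100.0
    shaft_triangularity: float = 0.12
    asymmetry_sites: list = field(default_factory=lambda: [
        AsymmetrySite("medial_malleolus", 0.7, 6.0),
        AsymmetrySite("anterior_tubercle", 0.5, 6.0),
    ])
    noise_sd_mm: float = 0.1
    pose: PoseBounds = field(default_factory=PoseBounds)
    mesh_resolution: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in ("shaft_radius_mm", "flare_scale", "plafond_concavity_depth_mm",
                     "malleolus_height_mm", "malleolus_width_mm", "tubercle_prominence_mm",
                     "shaft_length_mm", "mesh_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if not (0.0 <= self.shaft_triangularity < 0.5):
            raise ValueError("shaft_triangularity must be in [0, 0.5)")
        self.asymmetry_sites = [
            s if isinstance(s, AsymmetrySite) else AsymmetrySite(*s)
            for s in self.asymmetry_sites
        ]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Exact generator state for one pair, the oracle for recovery tests.

    ``displacement_mm`` gives the true per-vertex asymmetry magnitude on the
    canonical right mesh (identically indexed on the mirrored left);
    ``site_footprints`` mark each bump's core (kernel weight >= 0.8), within
    which the mean true displacement is close to the site amplitude.
    """

    canonical_right: TriSurface
    displacement_mm: np.ndarray
    site_footprints: dict
    site_centres: dict
    frame: AnatomicalFrame
    malleolus_tip: np.ndarray
    plafond_mask: np.ndarray
    shaft_mask: np.ndarray
    right_pose: RigidTransform
    left_pose: RigidTransform
    spec: SyntheticPairSpec

    def prenoise_left(self) -> TriSurface:
        """Reconstruct the pre-noise, pre-pose left bone: the mirrored
        canonical right displaced by the recorded asymmetry magnitudes along
        its outward vertex normals."""
        from .mesh import mirror_sagittal

        mirrored = mirror_sagittal(self.canonical_right, frame=AnatomicalFrame.canonical())
        v = mirrored.vertices + self.displacement_mm[:, None] * mirrored.vertex_normals
        return TriSurface(v, mirrored.faces, validate=False)


# -- implicit shape ------------------------------------------------------------


def _smin(a, b, k):
    """Polynomial smooth minimum (smooth union of implicit shapes)."""
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b * (1.0 - h) + a * h - k * h * (1.0 - h)


def _tibia_field(x, y, z, spec: SyntheticPairSpec):
    """Implicit field of the canonical right distal tibia (negative inside)."""
    r_shaft = spec.shaft_radius_mm
    r_epi = r_shaft * spec.flare_scale
    top = spec.shaft_length_mm - spec.malleolus_height_mm
    flare_len = 2.0 * r_shaft

    rho = np.sqrt(x**2 + y**2)
    zc = np.clip(z, 0.0, top)
    t = np.clip((flare_len - zc) / flare_len, 0.0, 1.0)
    smooth = t * t * (3.0 - 2.0 * t)
    r_prof = r_shaft * (1.0 + (spec.flare_scale - 1.0) * smooth)
    # the tibial shaft is a rounded triangular prism with an anterior crest;
    # the cross-section blends to near-circular at the epiphysis
    theta = np.arctan2(y, x)
    tri = spec.shaft_triangularity * (1.0 - smooth)
    r_prof = r_prof * (1.0 + tri * np.cos(3.0 * (theta - 0.5 * np.pi)))
    f_side = rho - r_prof
    # concave plafond: centre domed proximally by the concavity depth
    z_bottom = spec.plafond_concavity_depth_mm * (1.0 - (rho / r_epi) ** 2)
    f_bottom = z_bottom - z
    f_top = z - top
    f_body = np.maximum(np.maximum(f_side, f_bottom), f_top)

    # medial malleolus: ellipsoid reaching down to z = -malleolus_height
    ax = 0.6 * spec.malleolus_width_mm
    ay = 0.75 * spec.malleolus_width_mm
    az = 0.95 * spec.malleolus_height_mm
    cx = -(r_epi - 0.25 * spec.malleolus_width_mm)
    cz = az - spec.malleolus_height_mm
    f_mall = (np.sqrt(((x - cx) / ax) ** 2 + (y / ay) ** 2 + ((z - cz) / az) ** 2) - 1.0) * min(ax, ay, az)

    # anterolateral tubercle: sphere protruding by tubercle_prominence
    d = np.array([0.5, np.sqrt(1 - 0.25), 0.0])
    r_t = max(2.5, 1.3 * spec.tubercle_prominence_mm)
    centre = d * (r_epi - r_t + spec.tubercle_prominence_mm)
    cz_t = 4.0
    f_tub = np.sqrt((x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - cz_t) ** 2) - r_t

    k = 2.5
    return _smin(_smin(f_body, f_mall, k), f_tub, k)


def _tubercle_apex(spec: SyntheticPairSpec) -> np.ndarray:
    d = np.array([0.5, np.sqrt(1 - 0.25), 0.0])
    r_epi = spec.shaft_radius_mm * spec.flare_scale
    r_t = max(2.5, 1.3 * spec.tubercle_prominence_mm)
    centre = d * (r_epi - r_t + spec.tubercle_prominence_mm) + np.array([0.0, 0.0, 4.0])
    return centre + d * r_t


def canonical_right_tibia(spec: SyntheticPairSpec) -> TriSurface:
    """Triangulate the canonical-pose right bone by marching cubes."""
    res = spec.mesh_resolution
    r_epi = spec.shaft_radius_mm * spec.flare_scale
    reach = r_epi + spec.malleolus_width_mm + spec.tubercle_prominence_mm
    margin = 2.0 * res + 2.0
    x = np.arange(-reach - margin, reach + margin, res)
    y = np.arange(-reach - margin, reach + margin, res)
    z = np.arange(-spec.malleolus_height_mm - margin,
                  spec.shaft_length_mm - spec.malleolus_height_mm + margin, res)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    F = _tibia_field(X, Y, Z, spec)
    verts, faces, _, _ = marching_cubes(F, level=0.0, spacing=(res, res, res))
    verts += np.array([x[0], y[0], z[0]])
    tm = trimesh.Trimesh(verts, faces, process=True)
    tm.update_faces(tm.area_faces > 1e-10)
    tm.remove_unreferenced_vertices()
    mesh = TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces), validate=False)
    if mesh.signed_volume() < 0:
        mesh = TriSurface(mesh.vertices, mesh.faces[:, [0, 2, 1]], validate=False)
    return mesh


# -- pair generation -----------------------------------------------------------


def _random_pose(rng: np.random.Generator, bounds: PoseBounds) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, bounds.max_rotation_deg))
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, bounds.max_translation_mm)
    return RigidTransform(R, t)


def _site_centre(label: str, mesh: TriSurface, spec: SyntheticPairSpec) -> np.ndarray:
    v = mesh.vertices
    if label == "medial_malleolus":
        return v[int(np.argmin(v[:, 2]))]
    if label == "anterior_tubercle":
        return v[int(np.argmin(np.linalg.norm(v - _tubercle_apex(spec), axis=1)))]
    # plafond centre: deepest point of the concave dome
    target = np.array([0.0, 0.0, spec.plafond_concavity_depth_mm])
    return v[int(np.argmin(np.linalg.norm(v - target, axis=1)))]


def generate_pair(spec: SyntheticPairSpec):
    """Generate one (left, right, truth) specimen.

    The right bone is the canonical shape with surface noise under a random
    pose; the left bone is its mirror image with the spec's asymmetry bumps
    applied along outward normals, independent noise, and an independent
    random pose. Raises :class:`ResolutionError` when a site footprint is
    resolved by fewer than 16 vertices.
    """
    from .mesh import mirror_sagittal

    rng = np.random.default_rng(spec.seed)
    canonical = canonical_right_tibia(spec)
    n = canonical.n_vertices
    v = canonical.vertices

    displacement = np.zeros(n)
    footprints: dict[str, np.ndarray] = {}
    centres: dict[str, np.ndarray] = {}
    for site in spec.asymmetry_sites:
        centre = _site_centre(site.site, canonical, spec)
        r = np.linalg.norm(v - centre, axis=1)
        kernel = np.exp(-(r**2) / (2.0 * site.width_mm**2))
        kernel[r > 3.0 * site.width_mm] = 0.0
        footprint = kernel >= 0.8
        if footprint.sum() < 16:
            raise ResolutionError(
                f"site {site.site!r}: footprint resolved by only {int(footprint.sum())} "
                f"vertices; refine mesh_resolution or widen the site"
            )
        displacement += site.amplitude_mm * kernel
        footprints[site.site] = footprint
        centres[site.site] = centre

    mirrored = mirror_sagittal(canonical, frame=AnatomicalFrame.canonical())
    left_v = mirrored.vertices + displacement[:, None] * mirrored.vertex_normals

    noise_r = rng.normal(0.0, spec.noise_sd_mm, n) if spec.noise_sd_mm > 0 else np.zeros(n)
    noise_l = rng.normal(0.0, spec.noise_sd_mm, n) if spec.noise_sd_mm > 0 else np.zeros(n)
    right_pose = _random_pose(rng, spec.pose)
    left_pose = _random_pose(rng, spec.pose)

    right_v = v + noise_r[:, None] * canonical.vertex_normals
    left_v = left_v + noise_l[:, None] * mirrored.vertex_normals

    right = TriSurface(right_pose.apply(right_v), canonical.faces, validate=False)
    left = TriSurface(left_pose.apply(left_v), mirrored.faces, validate=False)

    normals_z = canonical.vertex_normals[:, 2]
    rho = np.linalg.norm(v[:, :2], axis=1)
    r_epi = spec.shaft_radius_mm * spec.flare_scale
    plafond = (normals_z < -0.3) & (v[:, 2] < spec.plafond_concavity_depth_mm + 2.0) & (rho < 0.9 * r_epi)
    shaft = (v[:, 2] > 2.0 * spec.shaft_radius_mm) & (np.abs(normals_z) < 0.3)

    truth = GroundTruth(
        canonical_right=canonical,
        displacement_mm=displacement,
        site_footprints=footprints,
        site_centres=centres,
        frame=AnatomicalFrame.canonical(origin=v.mean(axis=0)),
        malleolus_tip=v[int(np.argmin(v[:, 2]))].copy(),
        plafond_mask=plafond,
        shaft_mask=shaft,
        right_pose=right_pose,
        left_pose=left_pose,
        spec=spec,
    )
    return left, right, truth


def generate_cohort(n: int, base_spec: SyntheticPairSpec | None = None,
                    amplitude_range: tuple[float, float] = (0.3, 0.9),
                    master_seed: int = 0):
    """Generate ``n`` reproducible specimens emulating inter-subject variation.

    Per specimen, site amplitudes are drawn uniformly from
    ``amplitude_range`` and the geometric shape parameters are jittered by
    +/-10 percent. Returns a list of ``(left, right, truth)`` tuples; each
    truth carries its fully resolved spec for provenance.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lo, hi = amplitude_range
    if lo > hi or lo < 0:
        raise ValueError("invalid amplitude_range")
    base = base_spec or SyntheticPairSpec()
    rng = np.random.default_rng(master_seed)
    out = []
    for _ in range(n):
        jit = lambda val: float(val * rng.uniform(0.9, 1.1))  # noqa: E731
        sites = [
            AsymmetrySite(s.site, float(rng.uniform(lo, hi)), s.width_mm)
            for s in base.asymmetry_sites
        ]
        spec = replace(
            base,
            shaft_radius_mm=jit(base.shaft_radius_mm),
            flare_scale=jit(base.flare_scale),
            plafond_concavity_depth_mm=jit(base.plafond_concavity_depth_mm),
            malleolus_height_mm=jit(base.malleolus_height_mm),
            malleolus_width_mm=jit(base.malleolus_width_mm),
            tubercle_prominence_mm=jit(base.tubercle_prominence_mm),
            asymmetry_sites=sites,
            seed=int(rng.integers(2**31)),
        )
        out.append(generate_pair(spec))
    return out
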