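"""Anatomical coordinate frame, distal landmark, reference point, and the
articulating-surface selection rule.

Frame convention (right-bone handedness): ``axis_ml`` points lateral (+x),
``axis_ap`` anterior (+y), ``axis_si`` proximal (+z); the triad is
right-handed. The frame is recovered from mesh geometry alone: the
longitudinal axis from the principal inertia axis of the vertices (signed so
the flared epiphyseal end is distal), and the mediolateral axis from the
transverse offset of the malleolus tip — which sits medially, i.e. at -x for
a right bone and +x for an (unmirrored) left bone. Using the landmark offset
rather than the transverse inertia axes keeps the frame well-defined for the
nearly circular shaft cross-sections of long bones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .mesh import TriSurface


class FrameDegeneracyError(ValueError):
    """The mesh has no dominant long axis; supply a frame manually."""


@dataclass
class AnatomicalFrame:
    """Origin plus right-handed orthonormal mediolateral / anteroposterior /
    longitudinal axes (mm)."""

    origin: np.ndarray
    axis_ml: np.ndarray
    axis_ap: np.ndarray
    axis_si: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.axis_ml = np.asarray(self.axis_ml, dtype=np.float64)
        self.axis_ap = np.asarray(self.axis_ap, dtype=np.float64)
        self.axis_si = np.asarray(self.axis_si, dtype=np.float64)
        B = self.basis()
        if not np.allclose(B @ B.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal within 1e-9")
        if abs(np.linalg.det(B) - 1.0) > 1e-9:
            raise ValueError("frame axes are not right-handed")

    def basis(self) -> np.ndarray:
        """Rows are (ml, ap, si)."""
        return np.vstack([self.axis_ml, self.axis_ap, self.axis_si])

    def coords(self, points: np.ndarray) -> np.ndarray:
        """Express world points in frame coordinates (ml, ap, si)."""
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.basis().T

    def point(self, coords) -> np.ndarray:
        """Map frame coordinates back to world space."""
        return self.origin + np.asarray(coords, dtype=np.float64) @ self.basis()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnatomicalFrame":
        R = np.asarray(rotation, dtype=np.float64)
        return AnatomicalFrame(
            R @ self.origin + np.asarray(translation, dtype=np.float64),
            R @ self.axis_ml, R @ self.axis_ap, R @ self.axis_si,
        )

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axis_ml": self.axis_ml.tolist(),
            "axis_ap": self.axis_ap.tolist(),
            "axis_si": self.axis_si.tolist(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomicalFrame":
        return cls(np.array(d["origin"]), np.array(d["axis_ml"]),
                   np.array(d["axis_ap"]), np.array(d["axis_si"]))

    @classmethod
    def canonical(cls, origin=(0.0, 0.0, 0.0)) -> "AnatomicalFrame":
        return cls(np.asarray(origin, float), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])


@dataclass
class ReferencePoint:
    """Centre of the distal tibia at the height of the most distal point of
    the medial malleolus; the anchor of the articular-surface angle rule."""

    point: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=np.float64)


@dataclass
class SurfaceMask:
    """Per-vertex boolean selection on a mesh (here: the articulating surface)."""

    mesh: TriSurface
    selected: np.ndarray

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.shape != (self.mesh.n_vertices,):
            raise ValueError("mask length must equal vertex count")


def fit_anatomical_frame(mesh: TriSurface, side: str) -> AnatomicalFrame:
    """Recover the anatomical frame of a (full or distal) tibia mesh.

    The longitudinal axis is the principal axis with the largest vertex
    extent, signed so the wider (epiphyseal) end is distal. The mediolateral
    axis is the transverse direction of the most distal vertex (the malleolus
    tip) relative to the bone axis, signed so the malleolus lies medial:
    -ml for a right bone, +ml for a left bone before mirroring.

    Raises :class:`FrameDegeneracyError` when the largest principal extent is
    less than twice the next (no dominant long axis).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    V = mesh.vertices
    centroid = V.mean(axis=0)
    Vc = V - centroid
    _, _, axes = np.linalg.svd(Vc, full_matrices=False)
    proj = Vc @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = np.argsort(extents)[::-1]
    axes, extents = axes[order], extents[order]
    if extents[0] < 2.0 * extents[1]:
        raise FrameDegeneracyError(
            "no dominant long axis (extent ratio "
            f"{extents[0] / extents[1]:.2f} < 2); supply an AnatomicalFrame manually"
        )
    si = axes[0]

    # orient si proximal: the flared epiphysis (wider end) is distal
    s = Vc @ si
    radial = np.linalg.norm(Vc - np.outer(s, si), axis=1)
    lo, hi = np.quantile(s, [0.2, 0.8])
    if radial[s <= lo].mean() < radial[s >= hi].mean():
        si = -si
        s = -s

    # mediolateral from the malleolus-tip transverse offset
    tip = V[int(np.argmin(s))]
    d = (tip - centroid) - ((tip - centroid) @ si) * si
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        raise FrameDegeneracyError("most distal point lies on the bone axis; cannot fix ml")
    medial = d / nd
    ml = -medial if side == "right" else medial
    # re-orthogonalise against si and complete the right-handed triad
    ml = ml - (ml @ si) * si
    ml /= np.linalg.norm(ml)
    ap = np.cross(si, ml)
    return AnatomicalFrame(centroid, ml, ap, si)


def most_distal_point(mesh: TriSurface, frame: AnatomicalFrame) -> np.ndarray:
    """Vertex with minimal longitudinal coordinate (the malleolus tip for a
    tibia); ties broken toward the smallest vertex index."""
    s = mesh.vertices @ frame.axis_si
    return mesh.vertices[int(np.argmin(s))].copy()


def reference_point(distal_mesh: TriSurface, frame: AnatomicalFrame) -> ReferencePoint:
    """Centre of the distal tibia: mean mediolateral and anteroposterior
    coordinate over all vertices of the distal mesh, at the longitudinal
    height of its most distal point."""
    c = frame.coords(distal_mesh.vertices)
    return ReferencePoint(frame.point([c[:, 0].mean(), c[:, 1].mean(), c[:, 2].min()]))


def select_articulating_surface(distal_mesh: TriSurface, ref: ReferencePoint,
                                exclude: np.ndarray | None = None,
                                angle_deg: float = 90.0) -> SurfaceMask:
    """Select the articulating surface as all vertices facing the reference
    point: the angle between the outward vertex normal and the line from the
    vertex to the reference point is strictly less than ``angle_deg``
    (default 90 degrees, i.e. a strictly positive dot product).

    ``exclude`` marks vertices to reject regardless (cut-boundary vertices,
    whose normals are clipping artefacts). Vertices with a zero normal
    (isolated) are never selected.
    """
    normals = distal_mesh.vertex_normals
    to_ref = ref.point - distal_mesh.vertices
    dist = np.linalg.norm(to_ref, axis=1)
    dot = np.einsum("ij,ij->i", normals, to_ref)
    if angle_deg == 90.0:
        selected = dot > 0.0  # exact threshold, no trigonometric round-off
    else:
        cos = dot / np.maximum(dist, 1e-300)
        selected = cos > np.cos(np.radians(angle_deg))
    selected &= np.linalg.norm(normals, axis=1) > 0.5  # zero-normal vertices out
    if exclude is not None:
        selected &= ~np.asarray(exclude, dtype=bool)
    return SurfaceMask(distal_mesh, selected)
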