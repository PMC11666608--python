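"""End-to-end bilateral symmetry pipeline for distal tibia pairs.

Protocol per pair: mirror the left bone in the sagittal plane; superimpose it
onto the right by rigid CPD; cut both bones 50 mm above the right bone's most
distal point (the malleolus tip) and re-superimpose; cut at 30 mm and
re-superimpose, yielding two equally sized tibial plafonds; fit a nonrigid
CPD warp of the right plafond onto the superimposed mirrored left over the
most distal 25 mm; take each right vertex's correspondence point as the
closest point on the left surface to its warped position, and record the
Euclidean distance between the original right vertex and that point. The
articulating surface (region of interest) is the subset of right vertices
whose outward normal makes an angle of less than 90 degrees with the line to
the reference point at the centre of the distal tibia. Distances are
summarised by median / IQR / 1st-99th percentile whiskers / max and rendered
as a heatmap on the right plafond, capped at 2 mm (dark red above).

The incremental cutting ensures the final registration is driven by the
plafond geometry alone rather than the shaft.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import Normalize  # noqa: E402

from . import __version__ as _pkg_version
from .anatomy import AnatomicalFrame, fit_anatomical_frame, reference_point, select_articulating_surface
from .cpd import (
    CPDParams,
    CorrespondenceSet,
    RegistrationReport,
    correspondence_from_warp,
    farthest_point_sample,
    nonrigid_cpd,
    rigid_cpd,
)
from .mesh import TriSurface, cut_below_plane, mirror_sagittal, save_mesh

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Registration diverged; carries the offending report."""

    def __init__(self, message: str, report: RegistrationReport | None = None):
        super().__init__(message)
        self.report = report


@dataclass
class PipelineConfig:
    """Protocol parameters: cut heights (mm above the most distal point),
    correspondence region height, ROI angle threshold, heatmap cap and
    whisker percentiles, plus the CPD hyperparameters and master seed."""

    cut1_height_mm: float = 50.0
    cut2_height_mm: float = 30.0
    correspondence_height_mm: float = 25.0
    roi_angle_deg: float = 90.0
    heatmap_cap_mm: float = 2.0
    whisker_percentiles: tuple = (1.0, 99.0)
    cpd: CPDParams = field(default_factory=lambda: CPDParams(subsample_count=1500))
    seed: int = 0

    def __post_init__(self):
        if not (self.cut1_height_mm > self.cut2_height_mm > self.correspondence_height_mm > 0):
            raise ValueError("require cut1 > cut2 > correspondence_height > 0")
        if self.heatmap_cap_mm <= 0:
            raise ValueError("heatmap_cap_mm must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["whisker_percentiles"] = list(self.whisker_percentiles)
        return d


@dataclass
class DistanceSummary:
    """Descriptive statistics of correspondence distances (mm)."""

    median_mm: float
    iqr_mm: tuple
    p1_mm: float
    p99_mm: float
    max_mm: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "median_mm": self.median_mm,
            "q1_mm": self.iqr_mm[0],
            "q3_mm": self.iqr_mm[1],
            "p1_mm": self.p1_mm,
            "p99_mm": self.p99_mm,
            "max_mm": self.max_mm,
            "n_points": self.n_points,
        }


@dataclass
class PairResult:
    """One specimen's result: the correspondence set, the heatmap carrier
    mesh (the right plafond) with its per-vertex distance field, and the two
    summaries (entire plafond; articulating surface only), both derived from
    the same correspondence set."""

    specimen_id: str
    correspondences: CorrespondenceSet
    summary_full: DistanceSummary
    summary_articular: DistanceSummary
    heatmap_mesh: TriSurface
    heatmap_distances: np.ndarray
    frame: AnatomicalFrame
    reports: dict
    run_record: dict
    heatmap_mesh_path: str | None = None


def summarize_distances(distances, whisker_percentiles=(1.0, 99.0)) -> DistanceSummary:
    """Median, quartiles (linear interpolation between closest ranks),
    whisker percentiles and maximum of a non-empty distance list."""
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValueError("cannot summarise an empty distance list")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    lo, hi = whisker_percentiles
    q1, med, q3 = np.percentile(d, [25.0, 50.0, 75.0])
    p_lo, p_hi = np.percentile(d, [lo, hi])
    return DistanceSummary(
        median_mm=float(med),
        iqr_mm=(float(q1), float(q3)),
        p1_mm=float(p_lo),
        p99_mm=float(p_hi),
        max_mm=float(d.max()),
        n_points=int(d.size),
    )


def _check_report(stage: str, report: RegistrationReport) -> None:
    if not np.isfinite(report.final_sigma2):
        raise PipelineError(f"{stage}: registration diverged (sigma2 not finite)", report)
    trace = np.asarray(report.objective_trace)
    if len(trace) >= 3:
        rises = np.diff(trace) > 1e-6 * np.abs(trace[:-1])
        if rises[-3:].all():
            raise PipelineError(f"{stage}: objective increased persistently", report)


def _rigid_step(stage: str, moving: TriSurface, fixed: TriSurface,
                cpd: CPDParams, seed: int, reports: dict) -> TriSurface:
    msub = moving.vertices[farthest_point_sample(moving.vertices, _count(cpd, moving), seed)]
    fsub = fixed.vertices[farthest_point_sample(fixed.vertices, _count(cpd, fixed), seed + 1)]
    transform, report = rigid_cpd(msub, fsub, cpd)
    _check_report(stage, report)
    reports[stage] = report
    log.info("%s: %d iterations, sigma2=%.3g", stage, report.iterations_run, report.final_sigma2)
    return transform.apply_mesh(moving)


def _count(cpd: CPDParams, mesh: TriSurface) -> int:
    if cpd.subsample_count == "all":
        return mesh.n_vertices
    return min(int(cpd.subsample_count), mesh.n_vertices)


def run_pair(left_mesh: TriSurface, right_mesh: TriSurface,
             config: PipelineConfig | None = None,
             specimen_id: str = "pair",
             out_dir: str | Path | None = None) -> PairResult:
    """Run the full mirror / superimpose / cut / correspond protocol on one
    left-right pair and summarise the per-correspondence distances.

    The right bone is the fixed template throughout; both cut planes are
    anchored to the right bone's most distal point, so left and right are cut
    by the same world-space plane. When ``out_dir`` is given, the heatmap PLY
    (distance stored as the ``quality`` vertex property), an axial-view PNG
    and a JSON run record are written there.
    """
    config = config or PipelineConfig()
    cpd = config.cpd
    seed = config.seed
    reports: dict = {}

    frame = fit_anatomical_frame(right_mesh, side="right")
    # reflection plane is immaterial before registration (the left pose is
    # arbitrary); mirror across the global x=0 plane
    mirrored = mirror_sagittal(left_mesh, frame=AnatomicalFrame.canonical())
    # stage 1: whole-bone superposition of the mirrored left onto the right
    moved = _rigid_step("rigid_full", mirrored, right_mesh, cpd, seed, reports)

    si = frame.axis_si
    s_right = right_mesh.vertices @ si
    tip = right_mesh.vertices[int(np.argmin(s_right))]

    # stage 2: cut both at cut1 above the right tip, re-superimpose
    plane1 = tip + config.cut1_height_mm * si
    right1 = cut_below_plane(right_mesh, plane1, si)
    left1 = cut_below_plane(moved, plane1, si)
    moved1 = _rigid_step("rigid_cut1", left1.distal_part, right1.distal_part, cpd, seed + 10, reports)

    # stage 3: cut at cut2 (the 30 mm plafond), re-superimpose
    plane2 = tip + config.cut2_height_mm * si
    right2 = cut_below_plane(right_mesh, plane2, si)
    left2 = cut_below_plane(moved1, plane2, si)
    moved2 = _rigid_step("rigid_cut2", left2.distal_part, right2.distal_part, cpd, seed + 20, reports)

    # stage 4: correspondence over the most distal correspondence_height mm
    plane3 = tip + config.correspondence_height_mm * si
    right3 = cut_below_plane(right_mesh, plane3, si)
    left3 = cut_below_plane(moved2, plane3, si)
    interior = ~right3.boundary_vertex_mask
    l_interior = ~left3.boundary_vertex_mask

    moving_all = right3.distal_part.vertices[interior]
    m_idx = farthest_point_sample(moving_all, min(_count(cpd, right3.distal_part), len(moving_all)), seed + 30)
    fixed_pts = left3.distal_part.vertices[l_interior]
    f_idx = farthest_point_sample(fixed_pts, min(_count(cpd, left3.distal_part), len(fixed_pts)), seed + 31)
    warp, report = nonrigid_cpd(moving_all[m_idx], fixed_pts[f_idx], cpd)
    _check_report("nonrigid", report)
    reports["nonrigid"] = report

    # correspondences for every vertex of the right plafond (heatmap field),
    # statistics over the interior (non-boundary) vertices only
    corr_all = correspondence_from_warp(right3.distal_part.vertices, warp, left3.distal_part)
    distances_all = corr_all.distances_mm

    # region of interest: articulating surface of the right plafond
    ref = reference_point(right2.distal_part, frame)
    roi = select_articulating_surface(right3.distal_part, ref,
                                      exclude=right3.boundary_vertex_mask,
                                      angle_deg=config.roi_angle_deg)

    corr = CorrespondenceSet(
        right_points=corr_all.right_points[interior],
        left_points=corr_all.left_points[interior],
        distances_mm=distances_all[interior],
        articular_mask=roi.selected[interior],
    )
    summary_full = summarize_distances(corr.distances_mm, config.whisker_percentiles)
    if corr.articular_mask.any():
        summary_articular = summarize_distances(
            corr.distances_mm[corr.articular_mask], config.whisker_percentiles
        )
    else:
        raise PipelineError("articulating-surface selection is empty")

    run_record = {
        "specimen_id": specimen_id,
        "config": config.to_dict(),
        "versions": {"bisym": _pkg_version, "numpy": np.__version__},
        "registration": {k: r.to_dict() for k, r in reports.items()},
        "summary_full": summary_full.to_dict(),
        "summary_articular": summary_articular.to_dict(),
    }

    result = PairResult(
        specimen_id=specimen_id,
        correspondences=corr,
        summary_full=summary_full,
        summary_articular=summary_articular,
        heatmap_mesh=right3.distal_part,
        heatmap_distances=distances_all,
        frame=frame,
        reports=reports,
        run_record=run_record,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ply = out_dir / f"{specimen_id}_heatmap.ply"
        save_mesh(result.heatmap_mesh, ply, per_vertex_scalar=distances_all)
        result.heatmap_mesh_path = str(ply)
        run_record["heatmap_mesh_path"] = str(ply)
        render_heatmap(result, path=out_dir / f"{specimen_id}_heatmap.png",
                       cap_mm=config.heatmap_cap_mm)
        with open(out_dir / f"{specimen_id}_run.json", "w") as fh:
            json.dump(run_record, fh, indent=1)
    return result


# -- heatmap rendering ---------------------------------------------------------


def distance_colormap(cap_mm: float = 2.0):
    """Colormap + normalisation used for distance heatmaps: a perceptually
    ordered map over [0, cap] with values above the cap clipped to dark red."""
    cmap = plt.get_cmap("turbo").copy()
    cmap.set_over("darkred")
    return cmap, Normalize(vmin=0.0, vmax=cap_mm, clip=False)


def distances_to_colors(distances, cap_mm: float = 2.0) -> np.ndarray:
    """Per-vertex RGBA colours for a distance field under the heatmap rule."""
    cmap, norm = distance_colormap(cap_mm)
    d = np.asarray(distances, dtype=np.float64)
    return cmap(np.where(d > cap_mm, np.inf, norm(d)))


def render_heatmap(result: PairResult, path=None, cap_mm: float = 2.0, view: str = "axial"):
    """Render the per-vertex distance field on the right plafond.

    ``axial`` projects along the longitudinal axis looking proximally at the
    plafond (the surgeon's view of the joint surface); ``custom`` projects on
    the mediolateral-longitudinal plane. Returns ``(figure, rgba_colors)``
    and writes a PNG when ``path`` is given.
    """
    mesh = result.heatmap_mesh
    d = result.heatmap_distances
    cmap, norm = distance_colormap(cap_mm)
    colors = distances_to_colors(d, cap_mm)

    c = result.frame.coords(mesh.vertices)
    if view == "axial":
        u, v = c[:, 0], c[:, 1]
        xlabel, ylabel = "mediolateral (mm)", "anteroposterior (mm)"
    else:
        u, v = c[:, 0], c[:, 2]
        xlabel, ylabel = "mediolateral (mm)", "longitudinal (mm)"

    fig, axm = plt.subplots(figsize=(6, 5))
    capped = np.minimum(d, cap_mm)
    tri = axm.tripcolor(u, v, mesh.faces, capped, cmap=cmap, norm=norm, shading="gouraud")
    over = d > cap_mm
    if over.any():
        axm.scatter(u[over], v[over], s=4, color="darkred", zorder=3)
    axm.set_aspect("equal")
    axm.set_xlabel(xlabel)
    axm.set_ylabel(ylabel)
    cb = fig.colorbar(tri, ax=axm, extend="max")
    cb.set_label("left-right distance (mm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, colors


# -- cohort --------------------------------------------------------------------


def run_cohort(pairs, config: PipelineConfig | None = None,
               out_dir: str | Path | None = None):
    """Run the pipeline over a cohort of (left, right) mesh pairs.

    ``pairs`` is an iterable of ``(specimen_id, left, right)``. Individual
    failures are logged and skipped. Returns ``(results, table, pooled)``
    where ``table`` is a per-specimen pandas DataFrame (medians, IQRs,
    maxima for both regions) and ``pooled`` maps the two boxplot groups
    (``full_plafond``, ``articular``) to pooled distance arrays across
    specimens. When ``out_dir`` is given, writes the cohort TSV, a JSON run
    record and per-specimen outputs.
    """
    import pandas as pd

    config = config or PipelineConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty cohort")

    results: list[PairResult] = []
    failures: list[str] = []
    for specimen_id, left, right in pairs:
        try:
            results.append(run_pair(left, right, config, specimen_id=specimen_id,
                                    out_dir=out_dir))
        except Exception as exc:  # record and continue
            log.warning("specimen %s failed: %s", specimen_id, exc)
            failures.append(specimen_id)
    if not results:
        raise PipelineError(f"all {len(pairs)} specimens failed")

    rows = []
    for r in results:
        rows.append({
            "specimen_id": r.specimen_id,
            "n_points": r.summary_full.n_points,
            "median_full_mm": r.summary_full.median_mm,
            "q1_full_mm": r.summary_full.iqr_mm[0],
            "q3_full_mm": r.summary_full.iqr_mm[1],
            "max_full_mm": r.summary_full.max_mm,
            "n_articular": r.summary_articular.n_points,
            "median_articular_mm": r.summary_articular.median_mm,
            "q1_articular_mm": r.summary_articular.iqr_mm[0],
            "q3_articular_mm": r.summary_articular.iqr_mm[1],
            "max_articular_mm": r.summary_articular.max_mm,
        })
    table = pd.DataFrame(rows)
    pooled = {
        "full_plafond": np.concatenate([r.correspondences.distances_mm for r in results]),
        "articular": np.concatenate([
            r.correspondences.distances_mm[r.correspondences.articular_mask] for r in results
        ]),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cohort.tsv", sep="\t", index=False, float_format="%.6f")
        record = {
            "config": config.to_dict(),
            "versions": {"bisym": _pkg_version, "numpy": np.__version__},
            "n_specimens": len(results),
            "failed_specimens": failures,
            "pooled_summary_full": summarize_distances(
                pooled["full_plafond"], config.whisker_percentiles).to_dict(),
            "pooled_summary_articular": summarize_distances(
                pooled["articular"], config.whisker_percentiles).to_dict(),
        }
        with open(out_dir / "cohort_run.json", "w") as fh:
            json.dump(record, fh, indent=1)
        _cohort_boxplot(pooled, config, out_dir / "cohort_boxplot.png")
    return results, table, pooled


def _cohort_boxplot(pooled: dict, config: PipelineConfig, path) -> None:
    """Two-group boxplot (entire plafond vs articulating surface) with
    whiskers at the configured percentiles."""
    lo, hi = config.whisker_percentiles
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(
        [pooled["full_plafond"], pooled["articular"]],
        tick_labels=["entire plafond", "articulating surface"],
        whis=(lo, hi),
        showfliers=False,
    )
    ax.set_ylabel("left-right correspondence distance (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
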