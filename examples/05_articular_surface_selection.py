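"""Select the articulating surface of a distal tibia by the angle rule.

The articulating surface is the part of the plafond facing the talus: every
vertex whose outward normal makes an angle of less than 90 degrees with the
line from the vertex to a reference point at the centre of the distal tibia
(at the height of the malleolus tip).
"""

from bisym import (
    cut_at_height,
    fit_anatomical_frame,
    most_distal_point,
    reference_point,
    select_articulating_surface,
)
from bisym.synthetic import SyntheticPairSpec, canonical_right_tibia

bone = canonical_right_tibia(SyntheticPairSpec())
frame = fit_anatomical_frame(bone, side="right")
tip = most_distal_point(bone, frame)

plafond = cut_at_height(bone, frame, 30.0)  # the 30 mm distal tibia
ref = reference_point(plafond.distal_part, frame)
mask = select_articulating_surface(plafond.distal_part, ref,
                                   exclude=plafond.boundary_vertex_mask)

n = plafond.distal_part.n_vertices
print(f"malleolus tip: {tip.round(1)} mm; reference point: {ref.point.round(1)} mm")
print(f"30 mm plafond: {n} vertices, {plafond.boundary_vertex_mask.sum()} on the cut boundary")
print(f"articulating surface: {mask.selected.sum()} vertices "
      f"({100 * mask.selected.mean():.0f}% of the plafond mesh)")
# Downward-facing joint-surface vertices are selected; shaft walls (normals
# perpendicular to the line toward the reference point) are excluded, as are
# cut-boundary vertices whose normals are clipping artefacts.
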