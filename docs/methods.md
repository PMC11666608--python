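# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## The measurement model

The quantity reported everywhere is the per-correspondence Euclidean
distance between the right tibial plafond and the superimposed mirrored left
plafond. Correspondences are directed: the right bone is the template; a
nonrigid warp carries each right vertex toward the left surface, the
correspondence point is the closest point *on the left surface* (triangle-
projected, not nearest vertex) to the warped position, and the distance is
measured from the original unwarped right vertex. Under a perfect warp this
is the local surface-to-surface separation; under an imperfect warp it adds
a tangential mismatch component, which is why the registration design below
matters.

Statistics are computed twice from the same correspondence set: over the
whole 25 mm plafond region, and over the articulating-surface subset.
Quantiles use linear interpolation between closest ranks (the convention is
stated because IQR values depend on it); boxplot whiskers span the 1st–99th
percentiles. Cut-boundary vertices are excluded from correspondences and
from the articular mask: their positions and normals are artefacts of plane
clipping, not anatomy.

## Rigid CPD

Rigid registration is expectation–maximisation over a Gaussian mixture whose
centroids are the (transformed) moving points, plus a uniform outlier
component of weight `w = 0.1`. The uniform density is `1/V` with `V` the
fixed set's bounding-box volume. `sigma²` is initialised to the mean pairwise
squared distance over the dimension; the M-step solves rotation by SVD of
the weighted cross-covariance with determinant correction and updates
`sigma²` in closed form. **Scale is fixed at 1**: allowing scale would
absorb true left–right size asymmetry, the very quantity being measured.
Initialisation is the identity — mirroring already provides gross
pre-alignment in the pipeline — and EM stops when the relative change of the
negative log-likelihood falls below `1e-8` or after 150 iterations. The
objective trace is recorded per run and is non-increasing up to floating
point (EM guarantee); a persistently increasing trace aborts the pipeline
with the report attached.

Surfaces are subsampled before EM by seeded farthest-point sampling
(default cap 5000 points in the library, 1500 in the pipeline
configuration), giving near-uniform coverage; the fitted transform or warp
is then applied to all vertices.

## Nonrigid CPD

The displacement field is a Gaussian-kernel expansion over the moving
points, `T(p) = p + Σ_j G(p, y_j) w_j`, with motion-coherence regularisation
`lambda · sigma² · tr(WᵀGW)`; each M-step solves
`(diag(P1) G + lambda sigma² I) W = P X − diag(P1) Y`.

Kernel width `beta` and weight `lambda` control the stiffness of the field.
The widely quoted default ranges for these parameters assume point sets
normalised to zero mean and unit variance; this package deliberately works
in millimetres without normalisation, so the defaults are scale-adjusted:
**beta = 6 mm, lambda = 10**. Rationale: `beta` must be several mesh edge
lengths (1.5–2 mm here) so the warp averages over, rather than chases,
per-vertex surface noise, and no smaller than the anatomical feature scale
it must track (malleolar/tubercle prominences, ~6 mm). At `beta = 2 mm` the
background correspondence error on noisy-but-symmetric pairs is ~0.27 mm —
well above the ~0.11 mm floor implied by two independent 0.1 mm noise
fields — while at 6 mm it sits at ~0.13–0.15 mm and still tracks 1–2 mm
bumps of 6 mm width with <20 % attenuation. Both parameters remain
configurable per run.

## Anatomical frame and landmarks

The longitudinal axis is the principal vertex axis with the largest extent
(a dominant axis, extent ratio ≥ 2, is required; otherwise the fit refuses
and a user-supplied frame must be passed). Its sign is set so the flared
(epiphyseal) end — identified by the larger mean radial distance of the
extreme 20 % of vertices — is distal. The mediolateral axis is taken from
the transverse offset of the most distal vertex (the malleolus tip, which is
medial: −ml for a right bone, +ml for a left bone before mirroring) rather
than from the two remaining inertia axes: long-bone shaft cross-sections
are nearly circular, so the transverse inertia axes are ill-conditioned
while the landmark offset is stable. The anteroposterior axis completes a
right-handed triad. Accuracy on synthetic bones is ~1–3°, and the two uses
of the frame (cut heights along the axis, the reference point of the ROI
rule) are first-order insensitive to rotations of this size.

The "most distal point of the medial malleolus" is implemented as the
globally most distal vertex: the malleolus tip is the tibia's most distal
point. Ties break to the lowest vertex index. The reference point takes the
mean mediolateral/anteroposterior coordinates over *all* vertices of the
30 mm plafond mesh (not only articular candidates) at the height of the most
distal point. The articular rule is strict: a dot product of exactly zero
(angle exactly 90°) is not selected.

## Pipeline anchoring choices

Both cut planes are anchored to the right (template) bone's most distal
point after each superposition, so left and right are always cut by the same
world-space plane and the two plafonds have identical heights. The 25 mm
correspondence restriction is likewise applied to both point sets at the
right bone's landmark height. Cut boundaries are left open (no cap);
boundary vertices are flagged and excluded as described above. Cohort
outputs include both per-specimen summaries and pooled distances; the pooled
table is the primary one, with the per-specimen table available for
median-of-medians reporting.

## Synthetic data: what it emulates and what it does not

The generator emulates a bilateral CT cohort at the mesh level:

- **Shape**: an implicit surface — a tapered shaft of rounded-triangular
  cross-section (anterior crest) sweeping into a 1.5× flared epiphysis, a
  concave plafond (4 mm dome), a medial malleolus reaching 12 mm below the
  plafond rim, and an anterolateral tubercle — triangulated by marching
  cubes at a 1.5 mm pitch (≈5000 vertices per bone). The triangular shaft
  section matters: a circular shaft is nearly rotation-symmetric about its
  long axis and admits spurious registration minima that real tibiae do not.
- **Asymmetry**: truncated Gaussian bumps (zero beyond 3 kernel widths)
  applied to the mirrored bone along outward vertex normals at the sites
  where clinical heatmaps localise differences (medial malleolus, anterior
  tubercle, optionally the plafond centre). Default amplitudes 0.5–0.7 mm,
  width 6 mm; cohort generation draws amplitudes per specimen from
  0.3–0.9 mm and jitters shape parameters by ±10 %.
- **Noise**: independent per-vertex Gaussian offsets along normals
  (sd 0.1 mm, sub-voxel for ~0.8 mm CT voxels), applied to both bones
  *before* posing, so it models segmentation noise rather than motion.
- **Pose**: independent random rigid transforms (≤20°, ≤20 mm by default).

Ground truth records the exact per-vertex displacement magnitudes, the bump
cores (kernel weight ≥ 0.8, over which the mean true displacement is ≈0.9×
the amplitude), landmark coordinates, region labels, and both poses.

Not emulated: real population shape variation (no statistical shape model),
spatially correlated segmentation error, CT partial-volume artefacts at the
malleolus and tubercle, cartilage, and pathology. Passing the synthetic
validation therefore shows the *measurement machinery* is unbiased and
precise at clinically relevant scales; it does not certify accuracy on any
particular scanner/segmentation combination.

## Problem sizes and numerical choices

Validation runs use deliberately modest sizes chosen as the package's own
test conditions: 2.0 mm generator pitch (~2900 vertices) with 800-point CPD
subsampling for cohort-scale sweeps, the default 1.5 mm pitch with
1200-point subsampling for amplitude-recovery runs, and 500-point clouds
for transform-recovery sweeps. Duplicate vertices merge within 1e-6 mm on
load; cut clipping is exact with on-plane vertices (±1e-9 mm) kept distal;
degenerate faces (area ≤ 1e-12 mm²) are rejected; `sigma²` is floored at
1e-12 mm² to avoid division blow-ups on exact self-registration; PLY output
is double precision (the package writes its own PLY so round trips hold to
<1e-6 mm at 100 mm coordinate scale). All stochastic steps (sampling,
generator, poses) take explicit seeds; identical configuration and seed
reproduce cohort tables byte for byte.

## Known limitations

- The nonrigid correspondence conflates normal separation with residual
  tangential mismatch; on noisy symmetric pairs this inflates the background
  median to ~1.3–1.5× the pure noise floor. Reported asymmetries below
  ~0.15 mm at 0.1 mm surface noise should be read as "at measurement
  precision".
- The anatomical frame assumes a dominant long axis and a malleolus-like
  most-distal landmark; it is not meaningful for bones cut below ~2:1
  aspect, where a frame must be supplied explicitly.
- Rigid CPD with default settings has a wide but not unlimited capture
  range; poses beyond ~30° of rotation may need a coarse pre-alignment.
- STL output cannot carry per-vertex scalars (format limitation); heatmap
  payloads require PLY.
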