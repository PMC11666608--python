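"""Full bilateral symmetry analysis of one left/right pair.

Mirror -> rigid superposition -> 50 mm cut -> 30 mm cut (re-superimposing
after each) -> nonrigid correspondence over the distal 25 mm -> articular
region of interest -> distance statistics and heatmap.
"""

from pathlib import Path

from bisym import CPDParams, PipelineConfig, run_pair
from bisym.synthetic import AsymmetrySite, SyntheticPairSpec, generate_pair

spec = SyntheticPairSpec(seed=11, noise_sd_mm=0.1, asymmetry_sites=[
    AsymmetrySite("medial_malleolus", 1.0, 6.0)])
left, right, truth = generate_pair(spec)

config = PipelineConfig(cpd=CPDParams(subsample_count=1200), seed=2)
out = Path("scratch_example_outputs")
result = run_pair(left, right, config, specimen_id="demo", out_dir=out)

f, a = result.summary_full, result.summary_articular
print(f"entire plafond   : median {f.median_mm:.2f} mm "
      f"(IQR {f.iqr_mm[0]:.2f}-{f.iqr_mm[1]:.2f}), max {f.max_mm:.2f} mm, n={f.n_points}")
print(f"articular surface: median {a.median_mm:.2f} mm "
      f"(IQR {a.iqr_mm[0]:.2f}-{a.iqr_mm[1]:.2f}), max {a.max_mm:.2f} mm, n={a.n_points}")
print(f"heatmap: {result.heatmap_mesh_path} (+ PNG axial view)")
# The medians sit near the 0.1 mm noise floor because only the malleolus is
# truly asymmetric here; the heatmap's hot spot marks the injected 1 mm bump,
# the same qualitative picture the method gives on real bilateral CT pairs.
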