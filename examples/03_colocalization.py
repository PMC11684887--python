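"""Quantify transporter-lysosome colocalization over five ROIs.

Plants a known 40% overlap of the transporter's intensity inside lysosomal
puncta, then measures Pearson and Manders coefficients in five vertical ROI
strips and averages them — the same contract as averaging five
representative images per animal. At threshold 0 the M1 coefficient recovers
the planted overlap directly.
"""

from epiquant import TissueConfig, average_sample, coloc_pair, generate_tissue, grid_rois

cfg = TissueConfig(
    image_height_px=400, image_width_px=400, pixel_size_um=1.0, n_cells=250,
    membrane_fraction_per_cell=0.5, n_lysosome_puncta_per_cell=3,
    coloc_overlap_fraction=0.4, seed=2,
)
image, truth = generate_tissue(cfg)

rois = grid_rois(image.shape, 5)
results = [
    coloc_pair(image.get("target"), image.get("lysosome"),
               roi_mask=m, threshold_method="none", roi_id=str(i))
    for i, m in enumerate(rois)
]
sample = average_sample(results, sample_id="mouse-1", expected_n=5)

print(f"planted overlap: {truth.planted_overlap_fraction:.2f}")
for r in results:
    print(f"  ROI {r.roi_id}: pearson={r.pearson_r:+.3f} "
          f"M1={r.manders_m1:.3f} M2={r.manders_m2:.3f}")
print(f"sample average: pearson={sample.pearson_r:+.3f} "
      f"M1={sample.manders_m1:.3f} M2={sample.manders_m2:.3f}")
print("M1 is the fraction of transporter intensity inside lysosome-positive "
      "pixels; it matches the planted overlap.")
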