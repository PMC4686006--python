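"""Segment the synthetic fetal-arm phantom end to end.

Builds the phantom (bright adipose ring, dark muscle, bright bone with its
acoustic shadow), trains the object phase statistics on a clean fat sector,
runs the full pipeline from a single seed in the fat layer, and evaluates
the final mask against the known gap-free fat annulus.
"""

import numpy as np

from fcseg import PipelineConfig, run_pipeline
from fcseg.metrics import area_overlap, contour_distances
from fcseg.phantom import PhantomSpec, fat_sector_roi, make_phantom

spec = PhantomSpec(seed=7)
image, labels, truth = make_phantom(spec)

# one seed at mid-thickness of the fat ring, top of the arm
seed = (int(spec.centre[0] - spec.arm_radius + spec.fat_thickness / 2), int(spec.centre[1]))
roi = fat_sector_roi(spec)  # training region: fat sector opposite the shadow

result = run_pipeline(image, [seed], PipelineConfig(), train_roi=roi)

overlap = area_overlap(result.mask, truth)
distances = contour_distances(result.mask, truth, spacing=1.0)
print(f"seed: {seed}  (trained m_o={result.params.m_o:.3f}, sigma_o={result.params.sigma_o:.3f})")
print(f"fuzzy-connectedness mask: {int(result.fc_mask.sum())} px")
print(f"after completion + smoothing: {int(result.mask.sum())} px (truth {int(truth.sum())} px)")
print(f"Dice {overlap['dice']:.3f}  sensitivity {overlap['sensitivity']:.3f}  "
      f"specificity {overlap['specificity']:.3f}")
print(f"ASD {distances['asd']:.2f} px  MSD {distances['msd']:.2f} px")
# Dice near 0.9 means the pipeline recovers the adipose ring, including the
# part hidden by the bone shadow, almost exactly; specificity near 1 means
# essentially nothing outside the true ring is segmented.
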