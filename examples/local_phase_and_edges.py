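"""Local phase, feature asymmetry and the thinned edge map.

Shows the contrast invariance that motivates phase-based processing of
B-mode ultrasound: a gain/offset change leaves the phase map untouched,
while the feature-asymmetry edge map highlights the tissue boundaries.
"""

import numpy as np

from fcseg.features import feature_asymmetry, modified_nms
from fcseg.monogenic import BandpassSpec, monogenic_signal, phase_maps
from fcseg.phantom import PhantomSpec, contrast_transform, make_phantom

image, labels, _ = make_phantom(PhantomSpec(seed=7))

maps = phase_maps(monogenic_signal(image, BandpassSpec(27.0)))
print(f"local phase: fat {maps.phase[labels == 2].mean():.2f} rad, "
      f"muscle {maps.phase[labels == 3].mean():.2f} rad, "
      f"background {maps.phase[labels == 1].mean():.2f} rad")
# the bright fat ring and the dark regions sit at clearly different phases,
# which is what the object term of the affinity exploits

dimmed = contrast_transform(image, a=0.6, c=0.2)  # no clipping at these settings
maps_dimmed = phase_maps(monogenic_signal(dimmed, BandpassSpec(27.0)))
print(f"max phase change after gain/offset transform: "
      f"{np.abs(maps.phase - maps_dimmed.phase).max():.2e} rad")

fa = feature_asymmetry(image)  # default: scales 23/25/27, Ts=0.155
edge = modified_nms(fa)
print(f"feature asymmetry: max {fa.max():.2f}, "
      f"mean in homogeneous fat {fa[labels == 2].mean():.3f}")
print(f"edge map: {int((edge > 0.2).sum())} strong edge pixels "
      f"({(edge > 0).mean():.1%} of the image survives thinning)")
# high FA concentrates on the ring boundaries; non-maximal suppression in
# all directions thins the thick FA ridges to one-pixel crests
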