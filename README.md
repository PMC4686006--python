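# fcseg — feature-based fuzzy connectedness segmentation of B-mode ultrasound

`fcseg` segments soft-tissue structures in 2D B-mode ultrasound — its model
case is the adipose (fat) layer of a fetal arm cross-section — using fuzzy
connectedness driven by **local phase** features instead of intensities.
Ultrasound intensities are unreliable: contrast varies between acquisitions,
tissue regions are inhomogeneous, and acoustic shadows remove parts of the
object outright.  The package addresses all three: phase features are
contrast-invariant, fuzzy connectedness tolerates fuzzy boundaries, and a
shape-based completion step closes shadow gaps.  It is aimed at researchers
building quantitative image-analysis pipelines for ultrasound (or anyone who
needs a well-tested max-min connectivity, c-scale boundary descriptor, or
curvature-flow smoother on binary masks).

## The method

**Local phase and feature asymmetry.** The monogenic signal extends the
analytic signal to 2D: an isotropic DC-free bandpass `B(u) = |u| e^{-|u|² σ²}`
produces the even response, the Riesz transform (`H₁ = u/|u|`, `H₂ = v/|u|`)
the odd pair. Local phase `φ = atan2(|odd|, even) ∈ [0, π]` encodes structure
independently of contrast.  Step edges are detected by multi-scale feature
asymmetry

    FA = (1/N) Σ_s  ⌊|odd_s| − |even_s| − T_s⌋ / √(even_s² + odd_s² + ε)

(⌊·⌋ clamps negatives to zero), thinned by non-maximal suppression evaluated
in *all* quantised directions, giving the edge map `E`.

**Affinity and connectedness.** For 4-adjacent pixels c, d the affinity is

    μ(c,d) = ω₁ (1 − E(c,d)) + ω₂ exp(−max(|φ(c)−m_o|, |φ(d)−m_o|)² / 2σ_o²)

with `m_o`, `σ_o` the object's trained phase statistics and ω₁ + ω₂ = 1.
The connectivity of a pixel to the seed set is the max over paths of the min
affinity along the path (strongest weakest link), computed exactly by a
best-first label-setting sweep; thresholding at `T_FC` yields the object.

**Completion and regularisation.** Gaps left by acoustic shadows are found
from the convex hull of the segmentation: at each hull boundary element a
local chord (the c-scale descriptor with flatness threshold `t`) defines an
inward normal, object thickness is measured along it, and maximal
zero-thickness runs are bridged by polygons anchored `D` elements outside
each gap.  The boundary is finally smoothed by mean curvature flow
(`φ_t = κ|∇φ|` on a signed-distance embedding).

**Evaluation and image quality.** The package ships the standard agreement
metrics (TPAF sensitivity, 1−FPAF specificity, Dice, symmetric contour
distances MSD/ASD/RMSD, two-run precision) and entropy-based regional image
quality scores `S_ab = H(adipose) − H(background)`,
`S_am = H(adipose) − H(muscle)`.

Since no clinical data ship with the package, a deterministic synthetic
fetal-arm phantom (bright adipose ring, dark muscle, bright bone casting a
shadow wedge, multiplicative Rayleigh speckle, smooth inhomogeneity)
exercises every stage end to end.

## Worked example

```bash
python examples/segment_phantom.py
```

```
seed: (47, 128)  (trained m_o=0.391, sigma_o=0.761)
fuzzy-connectedness mask: 10140 px
after completion + smoothing: 11011 px (truth 14272 px)
Dice 0.871  sensitivity 0.772  specificity 1.000
ASD 3.11 px  MSD 13.15 px
```

One seed inside the fat ring suffices: the fuzzy-connectedness stage
recovers the visible ring, the completion step closes the bone-shadow gap,
and the final mask overlaps the true (gap-free) annulus with Dice 0.87 while
segmenting essentially nothing outside it (specificity 1.0).  Different seed
placements inside the ring give bit-identical masks.  The other examples
show the contrast invariance of the phase features
(`local_phase_and_edges.py`), multi-gap completion (`gap_completion.py`) and
the quality scores under a contrast sweep (`image_quality.py`).

The same pipeline is available from the shell:

```bash
fcseg phantom --seed 7 --out img.png --labels labels.png --truth truth.png
fcseg segment --image img.png --seeds seeds.json --out mask.png
fcseg eval --test mask.png --ref truth.png --spacing 0.2 --out metrics.csv
```

with `seeds.json` a list of 0-based `{"row": r, "col": c}` coordinates
(row 0 at the top).  `fcseg features | complete | smooth | quality` expose
the individual stages; `--preset under30|over30` switches the filter-scale
presets for smaller or larger anatomy.

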