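# Methods

This note documents the models implemented in `fcseg`, the parameter
conventions, the numerical choices that were genuinely open, and what the
synthetic phantom does and does not establish.

## Monogenic signal and phase convention

The image is filtered with the radial Gaussian-derivative bandpass
`B(u) = |u| exp(−|u|² σ²)` on a frequency grid in cycles/pixel (`|u| ≤ ~0.7`
at the grid corners); the two Riesz components are computed in quadrature so
that a pure cosine mode maps to its sine.  Two conventions deserve
explanation:

- **Scale and gain.** `σ` is dimensionless on the cycles/pixel grid; the
  continuous profile peaks at `|u| = 1/(σ√2)`, i.e. σ = 27 selects
  structures of roughly 38 px wavelength.  The response is normalised to
  unit peak gain on the realised grid.  Without this, the raw profile's peak
  gain (≈ `e^{−1/2}/(σ√2)`, under 2 % at the scales used here) would make
  the filter responses of a [0, 1]-normalised image orders of magnitude
  smaller than the feature-asymmetry noise threshold `T_s = 0.155`, reducing
  FA to zero everywhere.  Unit peak gain makes response magnitudes
  commensurate with image contrast at every scale, so one `T_s` works across
  scales.  `make_bandpass(..., normalise=False)` returns the raw profile.
- **Folded phase.** Phase is `atan2(|odd|, even) ∈ [0, π]`: 0 at a bright
  ridge (strong positive even response), π at a dark ridge, π/2 at a pure
  step edge.  The fold is what makes a *phase mean* of an object region
  meaningful — the unfolded arctan convention is discontinuous across edge
  polarity and its regional averages are not.  The raw convention remains
  available (`phase.convention: raw`).

Images are normalised by the dtype maximum, not min-max stretched, so the
contrast invariance of phase and (threshold-free) FA is preserved exactly.
Filtering uses mirror padding by half the image size to suppress FFT
wrap-around; `phase.padding: wrap` disables it.

## Feature asymmetry and thinning

FA averages, over scales, the clamped odd-dominance
`⌊|odd| − |even| − T_s⌋ / √(even² + odd² + ε)`.  The square root spans the
whole denominator (including ε), which guarantees FA ∈ [0, 1).  Defaults:
`T_s = 0.155` applied identically at every scale, `ε = 0.01`, three scales —
23/25/27 for smaller anatomy ("under30" preset) or 27/30/35 for larger
("over30").  `estimate_Ts` offers a data-driven alternative (histogram mode
of the local energy, Freedman–Diaconis bins) but the fixed default is the
documented pathway.  Note that `T_s` and ε both break exact contrast
invariance; invariance holds in the limit `T_s = 0, ε → 0`, which is what
the invariance tests check.

Thinning evaluates classical two-neighbour suppression in 8 directions at
22.5° steps (bilinear-interpolated neighbours at unit distance) and keeps a
pixel that wins in *any* direction — this retains junctions and curved
crests that single-orientation suppression drops.  Ties are broken
asymmetrically (≥ against the up/left neighbour, > against the down/right
one): a perfectly flat plateau then keeps exactly one crest line rather than
surviving wholesale, and the operation is idempotent.  A 1e-9 guard absorbs
interpolation round-off in the comparisons.

## Affinity and connectivity

The affinity combines the edge (homogeneity) term `1 − E(c,d)` and the
object phase term with weights ω₁ = ω₂ = 0.5.  `E(c,d)` is the max of the
two endpoint edge values — an edge crest at either pixel should cut the
pair — with the mean as a config alternative.  Adjacency is 4-connected.
The object statistics default to `m_o = 2.44` rad, `σ_o = 3 × 0.086` rad,
values appropriate to fetal-arm fat at the display conventions those were
trained under; `fit_object_stats` refits them from any user ROI as
`mean(φ)` and `3 × std(φ)`, which is the recommended route for new data
(and is what the phantom workflow uses — see below).

Connectivity is computed by a label-setting best-first sweep (the
widest-path variant of Dijkstra): pixels are finalised in decreasing
strength order, so each value is exactly the max over paths of the min
affinity, independent of heap tie order.  The test suite checks exactness
against brute-force enumeration of all simple paths on 4×4 grids.
Thresholding the map at `T_FC = 0.85` yields the segmentation; superlevel
sets are nested in the threshold and every component contains a seed.

## Object completion

The convex hull of the (possibly multi-component) segmentation is densified
to unit-spaced boundary elements.  At each element the c-scale descriptor
grows a symmetric window while all window points stay within `t = 5` px of
the chord joining the window ends; the chord direction defines the inward
normal (sign chosen by a 2 px inside-the-hull probe — unambiguous on a
convex polygon).  Thickness is the length of the first foreground run along
the normal, **provided the run starts within `contact_tol = 3` px of the
hull**.  The tolerance is load-bearing: on a ring-shaped object a mid-gap
normal eventually crosses the *far side* of the ring, so a plain
first-run reading would report a bogus positive thickness inside every gap;
requiring first contact near the hull is what makes "gap ⇔ zero thickness"
true.  The tolerance also absorbs small hull-to-object offsets at shallow
concavities.

Gaps are maximal circular zero-thickness runs of at least 3 elements
(shorter runs are rasterisation dropouts).  Each gap is filled by a polygon
whose outer side follows the hull arc between two anchors placed `D = 5`
elements outside the run (widened outward if an anchor itself reads zero),
and whose inner side follows the object's inner boundary — the far end of
the thickness run — where the object exists, bridging the void with straight
edges.  Polygon interiors *and* perimeter pixels are added to the mask; the
perimeter pixels close the diagonal cracks that even-odd rasterisation can
leave against the existing mask.  `D` has no canonical value; 5 elements is
of the same order as `t` and is exposed as `completion.D`.  The composed
operation is a superset of its input and idempotent: after filling, the
object touches the hull across every former gap, so a second pass finds no
zeros.

Completion is equivariant under 90° rotations only up to discretisation
(hull densification, ray sampling and polygon rasterisation are not exactly
grid-symmetric); on the wedge fixtures the rotated results agree to Jaccard
≥ 0.995.

## Mean curvature flow

The mask is embedded as a signed distance function (positive inside) and
`φ_t = κ|∇φ|` is stepped explicitly with central differences (κ clipped to
±1 for stability at single-pixel features), `dt = 0.2 ≤ 0.25` (CFL), 25
iterations by default — enough to round the polygonal completion artefacts
without visibly shrinking the object (total smoothing time τ = 5 px²).
Every 10 steps the embedding is reconditioned by Sussman PDE
reinitialisation (`φ_τ = S(φ₀)(1 − |∇φ|)`, Godunov upwinding), which
restores `|∇φ| ≈ 1` *without moving the zero level*.  Rebuilding the
distance function from the thresholded mask instead would snap the interface
back to pixel centres each time and stall any flow slower than one pixel per
reinitialisation interval.  The implementation reproduces the shrinking
circle law `r(τ) = √(r² − 2τ)` to well under a pixel and keeps the perimeter
non-increasing; it raises (with the step index) if the object vanishes.
Level-set evolution can merge or split components; the flow itself does not
guard topology.

## Quality scores and metrics

Regional entropies are Shannon entropies (bits) of the 256-level gray
histogram inside each region, computed on 8-bit levels (floats in [0, 1] are
quantised uniformly), with `S_ab = H(adipose) − H(background)` and
`S_am = H(adipose) − H(muscle)`.  Overlap metrics follow the delineation
framework with the *reference area* as the FPAF denominator (the image-area
alternative would make specificity trivially high).  Contour distances pool
symmetric nearest-neighbour distances between 4-connected inner-boundary
pixel centres, scaled by the pixel spacing.

## The phantom, and what passing tests show

The phantom emulates the appearance the method was designed for: a bright
adipose ring (default mean 0.75) around dark muscle (0.22) with bright bone
(0.92) casting a 40° shadow wedge (0.04) that interrupts the ring, on a 0.10
background, at 256×256 px with a 95 px arm radius and 28 px ring thickness —
proportions of a mid-gestation arm cross-section at a scale where the σ = 27
filters resolve the ring.  Speckle is Rayleigh-distributed multiplicative
noise (square root of exponential intensity, unit mean) blended at scale
0.1, plus a smooth multiplicative inhomogeneity field (±8 %).  Object phase
statistics are trained once per phantom on a 90° fat sector opposite the
shadow, mirroring the method's one-off training stage on clean fat regions.

This is an appearance model, not an acoustic simulation: no beam geometry,
attenuation, frequency-dependent PSF, refraction or reverberation, and its
region boundaries are geometrically clean circles.  Passing the end-to-end
test (Dice ≈ 0.85–0.90 against the true annulus, identical masks from
different seeds) therefore demonstrates the *mechanics* — contrast-invariant
features, exact connectivity, gap closure, stable smoothing — under
controlled speckle, not clinical performance, which depends on tissue
variability no phantom of this kind reproduces.

## Degenerate inputs and edge cases

Empty images/masks/ROIs/seed lists raise; collinear masks have no 2D hull
and raise; an all-zero thickness profile raises "object vanished"; pixels
with numerically zero amplitude get phase π/2 and orientation 0; constant
response maps make `estimate_Ts` return 0.  Seeds beyond 5 are accepted with
a warning (typical usage is 1–5).  Configs reject unknown keys and
out-of-range values at load time.
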