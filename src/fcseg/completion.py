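"""Shape-based object completion: detect and fill shadow gaps in a mask.

Acoustic shadows leave the segmented object with one or more missing arcs.
The completion walks the boundary of the convex hull of the segmentation,
estimates a local tangent chord at every boundary element with the c-scale
descriptor, casts the inward normal, and measures the thickness of the
object along it.  Maximal runs of zero thickness are gaps; each gap is
closed by a polygon bounded by the hull arc on the outside, the object
boundary (where present) on the inside, and the two anchor normals picked a
fixed distance outside the gap — mirroring the straight-line bridging
clinicians use across bone shadows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

__all__ = [
    "BoundaryChain",
    "Gap",
    "convex_hull_boundary",
    "cscale",
    "inward_normals",
    "thickness_profile",
    "detect_gaps",
    "fill_gaps",
    "complete_object",
]

#: default c-scale flatness threshold (px)
DEFAULT_T = 5.0
#: default anchor distance outside a gap (boundary elements)
DEFAULT_D = 5
#: default minimum gap length (boundary elements); shorter zero-runs are
#: rasterisation dropouts, not shadows
DEFAULT_MIN_GAP = 3
#: a hull element "touches" the object if foreground starts within this many
#: px along its inward normal; deeper first contact counts as zero thickness
DEFAULT_CONTACT_TOL = 3.0


@dataclass
class BoundaryChain:
    """Closed, counter-clockwise chain of convex-hull boundary points.

    ``points`` has shape (N, 2) in (row, col) coordinates at roughly unit
    spacing; the chain is circular (``points[0]`` follows ``points[-1]``).
    The c-scale / normal / thickness annotations are filled in by the
    corresponding pipeline steps and are ``None`` until then.
    """

    points: np.ndarray
    hull_polygon: Polygon
    chord_lengths: np.ndarray | None = None
    chords: np.ndarray | None = None  # (N, 2) unit tangent (chord) directions
    normals: np.ndarray | None = None  # (N, 2) inward unit normals
    thickness: np.ndarray | None = None
    depth_far: np.ndarray | None = None  # distance to far edge of first run

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Gap:
    """Maximal circular run of zero-thickness boundary elements."""

    start_index: int  # first element of the zero run
    end_index: int  # last element of the zero run (inclusive, circular)
    length: int


def _ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Orient a closed chain counter-clockwise in (row, col) axes."""
    r, c = points[:, 0], points[:, 1]
    signed_area = 0.5 * np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c)
    return points if signed_area > 0 else points[::-1]


def convex_hull_boundary(mask: np.ndarray) -> BoundaryChain:
    """Densified boundary chain of the convex hull of a binary mask.

    The hull is taken over all foreground pixel centres (covering every
    connected component); each hull edge is resampled at unit spacing so the
    chain consists of boundary elements rather than sparse vertices.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("empty mask")
    try:
        hull = ConvexHull(coords.astype(float))
    except QhullError as exc:
        raise ValueError("degenerate hull: mask pixels are collinear") from exc

    vertices = coords[hull.vertices].astype(float)
    vertices = _ensure_ccw(vertices)

    segments = []
    n = len(vertices)
    for i in range(n):
        a = vertices[i]
        b = vertices[(i + 1) % n]
        length = float(np.linalg.norm(b - a))
        steps = max(1, int(np.ceil(length)))
        ts = np.arange(steps) / steps
        segments.append(a[None, :] + ts[:, None] * (b - a)[None, :])
    points = np.vstack(segments)

    polygon = Polygon([(v[0], v[1]) for v in vertices])
    return BoundaryChain(points=points, hull_polygon=polygon)


def cscale(chain: BoundaryChain, p: int, t: float = DEFAULT_T) -> tuple[tuple[int, int], float]:
    """c-scale segment and chord length at boundary element `p`.

    The symmetric window around `p` grows while every point in it stays
    within distance `t` of the chord joining the window's end points.
    Returns ``((start, end), chord_length)`` with circular indices of the
    maximal window.  Long chords mean locally flat boundary, short chords
    high curvature.
    """
    if not t > 0:
        raise ValueError(f"t must be > 0, got {t}")
    points = chain.points
    n = len(points)
    max_k = max(1, n // 2 - 1)
    best_k = 1
    for k in range(1, max_k + 1):
        a = points[(p - k) % n]
        b = points[(p + k) % n]
        chord = b - a
        norm = np.linalg.norm(chord)
        if norm == 0:
            break
        idx = (np.arange(p - k, p + k + 1)) % n
        window = points[idx]
        # perpendicular distance of each window point to the chord line
        rel = window - a
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
        if dist.max() >= t:
            break
        best_k = k
    a = points[(p - best_k) % n]
    b = points[(p + best_k) % n]
    return ((p - best_k) % n, (p + best_k) % n), float(np.linalg.norm(b - a))


def _annotate_cscale(chain: BoundaryChain, t: float = DEFAULT_T) -> None:
    """Fill per-point chord lengths and unit chord (tangent) directions."""
    points = chain.points
    n = len(points)
    chord_lengths = np.empty(n)
    chords = np.empty((n, 2))
    for p in range(n):
        (i, j), length = cscale(chain, p, t)
        vec = points[j] - points[i]
        norm = np.linalg.norm(vec)
        chords[p] = vec / norm if norm > 0 else (1.0, 0.0)
        chord_lengths[p] = length
    chain.chord_lengths = chord_lengths
    chain.chords = chords


def inward_normals(chain: BoundaryChain, mask: np.ndarray | None = None) -> BoundaryChain:
    """Unit normals to the c-scale chords, signed to point into the hull.

    A candidate normal is kept if the probe point two pixels along it lies
    inside the hull polygon; convexity makes the choice unambiguous.
    """
    if chain.chords is None:
        raise ValueError("c-scale chords not computed; run the c-scale step first")
    points = chain.points
    normals = np.empty_like(chain.chords)
    hull = chain.hull_polygon
    for p in range(len(points)):
        tangent = chain.chords[p]
        candidate = np.array([-tangent[1], tangent[0]])
        probe = points[p] + 2.0 * candidate
        if not hull.contains(Point(probe[0], probe[1])):
            candidate = -candidate
        normals[p] = candidate
    chain.normals = normals
    return chain


def thickness_profile(
    chain: BoundaryChain,
    mask: np.ndarray,
    *,
    step: float = 0.5,
    contact_tol: float = DEFAULT_CONTACT_TOL,
) -> np.ndarray:
    """Object thickness along the inward normal at every boundary element.

    Each ray is sampled at `step` px up to the hull diameter; the first
    connected foreground run along the ray is the object slab belonging to
    this boundary element and its length is the thickness.  If the first
    contact lies deeper than `contact_tol` px the element does not touch the
    object at all (the normal crosses a shadow gap before meeting the far
    side of the object) and the thickness is 0.
    """
    if chain.normals is None:
        raise ValueError("normals not computed; run inward_normals first")
    mask = np.asarray(mask, dtype=bool)
    points = chain.points
    bounds = chain.hull_polygon.bounds
    diameter = float(np.hypot(bounds[2] - bounds[0], bounds[3] - bounds[1]))
    distances = np.arange(0.0, diameter + step, step)

    n = len(points)
    thickness = np.zeros(n)
    depth_far = np.zeros(n)
    for p in range(n):
        ray = points[p][None, :] + distances[:, None] * chain.normals[p][None, :]
        samples = ndimage.map_coordinates(
            mask.astype(np.uint8), ray.T, order=0, cval=0
        ).astype(bool)
        hits = np.flatnonzero(samples)
        if hits.size == 0:
            continue
        first = hits[0]
        if distances[first] > contact_tol:
            continue  # gap: nearest object along the normal is too deep
        run_end = first
        while run_end + 1 < len(samples) and samples[run_end + 1]:
            run_end += 1
        thickness[p] = (run_end - first + 1) * step
        depth_far[p] = distances[run_end]
    chain.thickness = thickness
    chain.depth_far = depth_far
    return thickness


def detect_gaps(thickness: np.ndarray, min_length: int = DEFAULT_MIN_GAP) -> list[Gap]:
    """Maximal circular runs of zero thickness, shortest runs discarded."""
    thickness = np.asarray(thickness, dtype=float)
    n = len(thickness)
    zero = thickness == 0
    if zero.all():
        raise ValueError("object vanished: zero thickness along the whole boundary")
    if not zero.any():
        return []

    # rotate so the profile starts on a non-zero element, then runs are linear
    start = int(np.flatnonzero(~zero)[0])
    rotated = np.roll(zero, -start)
    gaps: list[Gap] = []
    i = 0
    while i < n:
        if rotated[i]:
            j = i
            while j + 1 < n and rotated[j + 1]:
                j += 1
            length = j - i + 1
            if length >= min_length:
                gaps.append(
                    Gap(start_index=(i + start) % n, end_index=(j + start) % n, length=length)
                )
            i = j + 1
        else:
            i += 1
    return gaps


def _find_anchor(chain: BoundaryChain, index: int, direction: int, D: int) -> int:
    """Anchor element at chain distance D outside a gap end, widening past
    any still-empty elements."""
    n = len(chain)
    candidate = (index + direction * D) % n
    widened = 0
    while chain.thickness[candidate] <= 0 and widened < n:
        candidate = (candidate + direction) % n
        widened += 1
    if widened:
        warnings.warn(
            f"anchor at distance {D} had zero thickness; widened by {widened} elements",
            stacklevel=2,
        )
    if chain.thickness[candidate] <= 0:
        raise ValueError("no anchor with positive thickness found")
    return candidate


def fill_gaps(
    mask: np.ndarray,
    chain: BoundaryChain,
    gaps: list[Gap],
    D: int = DEFAULT_D,
) -> np.ndarray:
    """Close every gap with a polygon and union it with the mask.

    For each gap the two anchors sit `D` boundary elements outside the zero
    run.  The polygon follows the hull boundary from anchor to anchor across
    the gap on the outside and the object's inner boundary (the far edge of
    the thickness run, where present) on the inside; across the empty
    stretch the inner side is bridged by straight edges.  The output is a
    superset of the input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not gaps:
        return mask.copy()
    if chain.thickness is None or chain.depth_far is None or chain.normals is None:
        raise ValueError("thickness profile not computed")

    out = mask.copy()
    n = len(chain)
    for gap in gaps:
        a1 = _find_anchor(chain, gap.start_index, -1, D)
        a2 = _find_anchor(chain, gap.end_index, +1, D)
        if a1 == a2:
            continue  # gap spans (almost) the whole boundary; nothing sensible
        span = (a2 - a1) % n
        idx = [(a1 + k) % n for k in range(span + 1)]

        outer = chain.points[idx]
        inner = []
        for i in reversed(idx):
            if chain.thickness[i] > 0:
                inner.append(chain.points[i] + chain.depth_far[i] * chain.normals[i])
        vertices = np.vstack([outer, np.array(inner)])
        rr, cc = draw_polygon(vertices[:, 0], vertices[:, 1], shape=mask.shape)
        out[rr, cc] = True
        # interior fill alone can leave diagonal cracks against the mask;
        # drawing the perimeter pixels keeps the union 4-connected
        rr, cc = polygon_perimeter(vertices[:, 0], vertices[:, 1], shape=mask.shape)
        out[rr, cc] = True
    return out


def complete_object(
    mask: np.ndarray,
    *,
    t: float = DEFAULT_T,
    D: int = DEFAULT_D,
    min_gap_length: int = DEFAULT_MIN_GAP,
    contact_tol: float = DEFAULT_CONTACT_TOL,
) -> np.ndarray:
    """Full completion pipeline: hull, c-scale, normals, thickness, fill.

    Deterministic composition of the five steps; a mask whose boundary shows
    no zero-thickness run is returned unchanged.  The output is always a
    superset of the input and the operation is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    chain = convex_hull_boundary(mask)
    _annotate_cscale(chain, t)
    inward_normals(chain, mask)
    thickness_profile(chain, mask, contact_tol=contact_tol)
    gaps = detect_gaps(chain.thickness, min_length=min_gap_length)
    return fill_gaps(mask, chain, gaps, D=D)
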