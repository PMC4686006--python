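"""Multi-scale feature asymmetry edge detection and all-direction thinning.

Feature asymmetry (FA) measures how much the odd (Riesz) response dominates
the even response at each pixel, averaged over scales: close to 1 on step
edges, close to 0 in homogeneous regions, and — up to the noise threshold —
invariant to image contrast.  The FA image has thick edges; a modified
non-maximal suppression that keeps a pixel if it is a directional maximum in
*any* quantised direction thins them while retaining junctions and curved
structure that single-orientation suppression would drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .monogenic import BandpassSpec, MonogenicResponse, monogenic_signal

__all__ = ["FAParams", "feature_asymmetry", "modified_nms", "estimate_Ts"]

#: default noise threshold (applies identically at every scale)
DEFAULT_TS = 0.155
#: default regulariser in the FA denominator
DEFAULT_EPSILON = 0.01
#: default scale triplets: smaller structures vs larger structures
SCALES_UNDER30 = (23.0, 25.0, 27.0)
SCALES_OVER30 = (27.0, 30.0, 35.0)


@dataclass(frozen=True)
class FAParams:
    """Parameters of the multi-scale feature-asymmetry measure.

    ``scales`` lists the bandpass scales averaged over; ``Ts`` suppresses
    spurious responses to noise (a single value is applied at every scale);
    ``epsilon`` keeps the denominator away from zero.
    """

    scales: tuple[BandpassSpec, ...] = field(
        default_factory=lambda: tuple(BandpassSpec(s) for s in SCALES_UNDER30)
    )
    Ts: float = DEFAULT_TS
    epsilon: float = DEFAULT_EPSILON
    padding: str = "mirror"

    def __post_init__(self) -> None:
        if len(self.scales) < 1:
            raise ValueError("at least one scale is required")
        if self.Ts < 0:
            raise ValueError(f"Ts must be >= 0, got {self.Ts}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


def feature_asymmetry(
    image: np.ndarray,
    params: FAParams | None = None,
    *,
    responses: list[MonogenicResponse] | None = None,
) -> np.ndarray:
    """Multi-scale feature asymmetry map in ``[0, 1)``.

    Per scale the contribution is::

        max(|odd| - |even| - Ts, 0) / sqrt(even^2 + odd^2 + epsilon)

    averaged over scales.  The clamped numerator is strictly below the
    denominator, so FA < 1 everywhere.  Pre-computed monogenic `responses`
    may be passed to avoid re-filtering (they must match ``params.scales``).
    """
    if params is None:
        params = FAParams()
    image = np.asarray(image, dtype=float)
    if responses is None:
        responses = [
            monogenic_signal(image, spec, padding=params.padding)
            for spec in params.scales
        ]
    if len(responses) != len(params.scales):
        raise ValueError("one monogenic response per scale is required")

    fa = np.zeros(image.shape, dtype=float)
    for resp in responses:
        even = resp.even
        odd = resp.odd_norm
        numerator = np.maximum(np.abs(odd) - np.abs(even) - params.Ts, 0.0)
        denominator = np.sqrt(even**2 + odd**2 + params.epsilon)
        fa += numerator / denominator
    fa /= len(responses)
    return fa


def _direction_offsets(n_directions: int) -> np.ndarray:
    """Unit offsets (drow, dcol) for half-turn directions at equal steps."""
    angles = np.arange(n_directions) * (np.pi / n_directions)
    return np.stack([np.sin(angles), np.cos(angles)], axis=1)


def modified_nms(fa: np.ndarray, n_directions: int = 8) -> np.ndarray:
    """All-direction non-maximal suppression of an FA map.

    Classical two-neighbour suppression is evaluated in each of
    `n_directions` quantised directions (22.5 degree steps by default, both
    neighbours sampled by bilinear interpolation at unit distance); a pixel
    survives if it is a directional maximum in at least one direction, and
    then keeps its original FA value.  Ties are broken asymmetrically — >=
    against the up/left neighbour, strict > against the down/right one — so
    a perfectly flat plateau keeps a single one-pixel-wide crest (its
    row-major-last line) instead of surviving wholesale.  Output <= input
    pointwise; the operation is idempotent on its own output.
    """
    fa = np.asarray(fa, dtype=float)
    rows, cols = fa.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    survives = np.zeros(fa.shape, dtype=bool)
    # offsets all point down/right (row >= 0), giving the canonical tie side
    for drow, dcol in _direction_offsets(n_directions):
        coords_fwd = np.stack([rr + drow, cc + dcol])
        coords_bwd = np.stack([rr - drow, cc - dcol])
        # out-of-grid neighbours read as 0 (cval), so border crests survive
        fwd = ndimage.map_coordinates(fa, coords_fwd, order=1, cval=0.0)
        bwd = ndimage.map_coordinates(fa, coords_bwd, order=1, cval=0.0)
        # 1e-9 guard: bilinear interpolation of exactly equal neighbours can
        # differ from them in the last float bits, which must still count as
        # a tie for the plateau rule to work
        survives |= (fa > fwd + 1e-9) & (fa >= bwd - 1e-9)
    out = np.where(survives, fa, 0.0)
    return out


def estimate_Ts(even: np.ndarray, odd_norm: np.ndarray) -> float:
    """Data-driven noise threshold from the local-energy distribution.

    Approximates the statistical mode of ``sqrt(even^2 + odd^2)`` with a
    histogram using Freedman-Diaconis bins.  Offered as an alternative to the
    fixed default threshold; the default pipeline does not call this.
    Returns 0 for degenerate (constant) response maps.
    """
    energy = np.sqrt(np.asarray(even, dtype=float) ** 2 + np.asarray(odd_norm, dtype=float) ** 2)
    energy = energy.ravel()
    q75, q25 = np.percentile(energy, [75, 25])
    iqr = q75 - q25
    if iqr <= 0 or energy.max() == energy.min():
        return 0.0
    bin_width = 2 * iqr / len(energy) ** (1 / 3)
    n_bins = max(1, int(np.ceil((energy.max() - energy.min()) / bin_width)))
    counts, edges = np.histogram(energy, bins=n_bins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))
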