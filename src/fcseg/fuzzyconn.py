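"""Absolute fuzzy connectedness with a local-phase / edge-map affinity.

Affinity is a fuzzy relation on 4-adjacent pixel pairs combining a
homogeneity term (1 minus the thinned edge strength between the pair) and an
object-feature term (a Gaussian membership of the local phase around the
trained object mean).  Fuzzy connectedness of a pixel to the seed set is the
max over paths of the min affinity along the path (strongest weakest link),
computed exactly by a best-first label-setting sweep; thresholding the
connectivity map yields the segmentation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffinityParams",
    "AffinityField",
    "ConnectivityMap",
    "pair_edge",
    "affinity",
    "intensity_affinity",
    "afc_connectivity",
    "threshold_segmentation",
    "fit_object_stats",
]

#: default affinity weights (homogeneity, object feature)
DEFAULT_OMEGA1 = 0.5
DEFAULT_OMEGA2 = 0.5
#: default trained local-phase statistics of the adipose (fat) layer
DEFAULT_M_O = 2.44
DEFAULT_SIGMA_O = 3 * 0.086
#: default connectivity threshold
DEFAULT_T_FC = 0.85


@dataclass(frozen=True)
class AffinityParams:
    """Weights and object statistics of the pairwise affinity.

    ``omega1`` weighs the homogeneity (edge) term, ``omega2`` the object
    feature term; they must sum to 1.  ``m_o``/``sigma_o`` are the mean and
    spread of the object's local phase (radians) from a training stage.
    ``pair_edge`` selects how the two endpoint edge values combine
    ("max" or "mean").
    """

    omega1: float = DEFAULT_OMEGA1
    omega2: float = DEFAULT_OMEGA2
    m_o: float = DEFAULT_M_O
    sigma_o: float = DEFAULT_SIGMA_O
    pair_edge: str = "max"

    def __post_init__(self) -> None:
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.omega1 + self.omega2 - 1.0) > 1e-9:
            raise ValueError(
                f"omega1 + omega2 must equal 1, got {self.omega1 + self.omega2}"
            )
        if not self.sigma_o > 0:
            raise ValueError(f"sigma_o must be > 0, got {self.sigma_o}")
        if self.pair_edge not in ("max", "mean"):
            raise ValueError(f"pair_edge must be 'max' or 'mean', got {self.pair_edge!r}")


@dataclass
class AffinityField:
    """Affinities of 4-adjacent pixel pairs on a grid of a given shape.

    ``horizontal[r, c]`` is the affinity between pixels (r, c) and (r, c+1);
    ``vertical[r, c]`` between (r, c) and (r+1, c).  Stored once per
    unordered pair, so symmetry holds by construction.
    """

    horizontal: np.ndarray  # shape (rows, cols-1)
    vertical: np.ndarray  # shape (rows-1, cols)
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if self.horizontal.shape != (rows, max(cols - 1, 0)):
            raise ValueError("horizontal affinity map has wrong shape")
        if self.vertical.shape != (max(rows - 1, 0), cols):
            raise ValueError("vertical affinity map has wrong shape")


@dataclass
class ConnectivityMap:
    """Fuzzy connectedness of every pixel to a seed set, values in [0, 1]."""

    values: np.ndarray
    seeds: list[tuple[int, int]]


def pair_edge(edge: np.ndarray, c: tuple[int, int], d: tuple[int, int], mode: str = "max") -> float:
    """Edge strength assigned to the adjacent pair (c, d).

    An edge crest at either endpoint should cut the pair's affinity, hence
    the default is the max of the two endpoint values; "mean" averages them.
    Symmetric in (c, d) either way.
    """
    if abs(c[0] - d[0]) + abs(c[1] - d[1]) != 1:
        raise ValueError(f"pixels {c} and {d} are not 4-adjacent")
    ec, ed = float(edge[c]), float(edge[d])
    if mode == "max":
        return max(ec, ed)
    if mode == "mean":
        return 0.5 * (ec + ed)
    raise ValueError(f"unknown pair_edge mode {mode!r}")


def _combine_pairs(a: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    if mode == "max":
        return np.maximum(a, b)
    return 0.5 * (a + b)


def _gaussian_object_term(feat: np.ndarray, m_o: float, sigma_o: float) -> np.ndarray:
    return np.exp(-((feat - m_o) ** 2) / (2 * sigma_o**2))


def affinity(phase: np.ndarray, edge: np.ndarray, params: AffinityParams | None = None) -> AffinityField:
    """Feature-based affinity field from a local-phase map and an edge map.

    For 4-adjacent pixels c, d::

        mu(c, d) = omega1 * (1 - E(c, d))
                 + omega2 * exp(-max(|phi(c)-m_o|, |phi(d)-m_o|)^2 / (2 sigma_o^2))

    where ``E(c, d)`` combines the endpoint edge values (see `pair_edge`).
    Values lie in [0, 1]; the field is symmetric by construction.
    """
    if params is None:
        params = AffinityParams()
    phase = np.asarray(phase, dtype=float)
    edge = np.asarray(edge, dtype=float)
    if phase.shape != edge.shape:
        raise ValueError(f"shape mismatch: phase {phase.shape} vs edge {edge.shape}")

    dev = np.abs(phase - params.m_o)

    def pair_affinity(sl_a, sl_b):
        e_pair = _combine_pairs(edge[sl_a], edge[sl_b], params.pair_edge)
        worst_dev = np.maximum(dev[sl_a], dev[sl_b])
        g4 = np.exp(-(worst_dev**2) / (2 * params.sigma_o**2))
        return params.omega1 * (1.0 - e_pair) + params.omega2 * g4

    horizontal = pair_affinity((slice(None), slice(None, -1)), (slice(None), slice(1, None)))
    vertical = pair_affinity((slice(None, -1), slice(None)), (slice(1, None), slice(None)))
    return AffinityField(horizontal=horizontal, vertical=vertical, shape=phase.shape)


def intensity_affinity(image: np.ndarray, params: AffinityParams | None = None) -> AffinityField:
    """Classical intensity-based affinity (baseline).

    Homogeneity term ``1 - |I(c) - I(d)|`` (intensities in [0, 1]) and a
    Gaussian object term on the intensities with the same ``m_o``/``sigma_o``
    role as the feature-based variant.  Provided for qualitative comparison
    with the local-phase affinity.
    """
    if params is None:
        params = AffinityParams()
    image = np.asarray(image, dtype=float)
    dev = np.abs(image - params.m_o)

    def pair_affinity(sl_a, sl_b):
        grad = np.abs(image[sl_a] - image[sl_b])
        g1 = 1.0 - np.clip(grad, 0.0, 1.0)
        worst_dev = np.maximum(dev[sl_a], dev[sl_b])
        g2 = np.exp(-(worst_dev**2) / (2 * params.sigma_o**2))
        return params.omega1 * g1 + params.omega2 * g2

    horizontal = pair_affinity((slice(None), slice(None, -1)), (slice(None), slice(1, None)))
    vertical = pair_affinity((slice(None, -1), slice(None)), (slice(1, None), slice(None)))
    return AffinityField(horizontal=horizontal, vertical=vertical, shape=image.shape)


def afc_connectivity(field: AffinityField, seeds: list[tuple[int, int]]) -> ConnectivityMap:
    """Exact max-min path-strength connectivity from a seed set.

    Best-first label-setting sweep (the widest-path variant of Dijkstra):
    pixels are finalised in decreasing connectivity order, so each pixel's
    value is the max over paths from any seed of the min affinity along the
    path.  Seeds have connectivity 1.  The result does not depend on seed
    ordering or heap tie-breaking.
    """
    rows, cols = field.shape
    if not seeds:
        raise ValueError("at least one seed is required")
    for seed in seeds:
        r, c = seed
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"seed {seed} outside image of shape {field.shape}")

    conn = np.zeros((rows, cols), dtype=float)
    done = np.zeros((rows, cols), dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r, c in seeds:
        conn[r, c] = 1.0
        heapq.heappush(heap, (-1.0, r, c))

    horizontal, vertical = field.horizontal, field.vertical
    while heap:
        neg, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        strength = -neg
        # relax the 4 neighbours through the stored pair affinities
        if c + 1 < cols and not done[r, c + 1]:
            cand = min(strength, horizontal[r, c])
            if cand > conn[r, c + 1]:
                conn[r, c + 1] = cand
                heapq.heappush(heap, (-cand, r, c + 1))
        if c - 1 >= 0 and not done[r, c - 1]:
            cand = min(strength, horizontal[r, c - 1])
            if cand > conn[r, c - 1]:
                conn[r, c - 1] = cand
                heapq.heappush(heap, (-cand, r, c - 1))
        if r + 1 < rows and not done[r + 1, c]:
            cand = min(strength, vertical[r, c])
            if cand > conn[r + 1, c]:
                conn[r + 1, c] = cand
                heapq.heappush(heap, (-cand, r + 1, c))
        if r - 1 >= 0 and not done[r - 1, c]:
            cand = min(strength, vertical[r - 1, c])
            if cand > conn[r - 1, c]:
                conn[r - 1, c] = cand
                heapq.heappush(heap, (-cand, r - 1, c))

    return ConnectivityMap(values=conn, seeds=list(seeds))


def threshold_segmentation(conn: ConnectivityMap, T_FC: float = DEFAULT_T_FC) -> np.ndarray:
    """Superlevel set of the connectivity map at threshold `T_FC`.

    The mask always contains the seeds; by the max-min construction every
    retained pixel is reachable from a seed through pixels of connectivity
    >= T_FC, so the mask is a union of seed-containing components.
    """
    if not 0.0 <= T_FC <= 1.0:
        raise ValueError(f"T_FC must be in [0, 1], got {T_FC}")
    return conn.values >= T_FC


def fit_object_stats(phase: np.ndarray, roi: np.ndarray, *, spread_factor: float = 3.0) -> tuple[float, float]:
    """Train (m_o, sigma_o) from the local phase inside an object ROI.

    Mirrors the method's training stage: the mean of the phase inside the
    ROI and its standard deviation inflated by `spread_factor` (default 3)
    to tolerate within-object variability.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty training ROI")
    values = np.asarray(phase, dtype=float)[roi]
    m_o = float(values.mean())
    sigma_o = float(spread_factor * values.std())
    if sigma_o == 0:
        raise ValueError("degenerate ROI: zero phase spread")
    return m_o, sigma_o
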