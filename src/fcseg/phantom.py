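"""Synthetic fetal-arm phantom and geometric fixtures.

The phantom emulates the appearance of an axial B-mode cross-section of a
fetal arm at mid-humeral level: a bright (echodense) adipose ring around a
dark (hypoechoic) muscle core, a small bright humerus bone inside the
muscle, and the characteristic acoustic shadow — a dark wedge cast distally
by the bone that interrupts the adipose ring.  Multiplicative speckle and a
smooth intensity inhomogeneity complete the picture.  Everything is
generated deterministically from a single seed, so phantoms double as
reproducible test fixtures.  This is an appearance model, not a physical
ultrasound simulation: there is no beam geometry, attenuation law or
frequency-dependent point-spread function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "REGION_LEGEND",
    "make_phantom",
    "make_gap_fixture",
    "fat_sector_roi",
    "contrast_transform",
]

#: label values of the phantom region map
REGION_LEGEND = {1: "background", 2: "adipose", 3: "muscle", 4: "bone", 5: "shadow"}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, echogenicity and texture of the synthetic arm cross-section.

    All lengths in pixels; intensities are region means in [0, 1].  The
    shadow wedge opens downward from the bone centre and overrides every
    tissue it crosses (including the adipose ring).  The same seed and spec
    always produce bit-identical images.
    """

    size: tuple[int, int] = (256, 256)
    centre: tuple[float, float] = (128.0, 128.0)
    arm_radius: float = 95.0
    fat_thickness: float = 28.0
    bone_centre: tuple[float, float] = (128.0, 128.0)
    bone_radius: float = 14.0
    shadow_deg: float = 40.0
    # region mean intensities
    background_intensity: float = 0.10
    fat_intensity: float = 0.75
    muscle_intensity: float = 0.22
    bone_intensity: float = 0.92
    shadow_intensity: float = 0.04
    speckle_scale: float = 0.10
    inhomogeneity_amplitude: float = 0.08
    edge_softness: float = 1.5
    seed: int = 7

    def __post_init__(self) -> None:
        if self.arm_radius <= 0 or self.fat_thickness <= 0 or self.bone_radius <= 0:
            raise ValueError("radii and thickness must be positive")
        if self.fat_thickness >= self.arm_radius:
            raise ValueError("fat ring thicker than the arm radius")
        muscle_radius = self.arm_radius - self.fat_thickness
        br, bc = self.bone_centre
        cr, cc = self.centre
        if np.hypot(br - cr, bc - cc) + self.bone_radius >= muscle_radius:
            raise ValueError("bone must sit strictly inside the muscle core")
        for name in (
            "background_intensity",
            "fat_intensity",
            "muscle_intensity",
            "bone_intensity",
            "shadow_intensity",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.speckle_scale < 1.0:
            raise ValueError("speckle_scale must be in [0, 1)")


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.size
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    radius = np.hypot(rr - spec.centre[0], cc - spec.centre[1])
    bone_radius_map = np.hypot(rr - spec.bone_centre[0], cc - spec.bone_centre[1])

    labels = np.ones(spec.size, dtype=np.uint8)  # background
    labels[radius <= spec.arm_radius] = 2  # adipose ring (outer disk first)
    labels[radius <= spec.arm_radius - spec.fat_thickness] = 3  # muscle core
    labels[bone_radius_map <= spec.bone_radius] = 4  # bone

    # acoustic shadow: wedge opening downward (increasing row) from the bone,
    # starting distal to the bone so the bone itself stays bright
    half = np.deg2rad(spec.shadow_deg) / 2.0
    drow = rr - spec.bone_centre[0]
    dcol = cc - spec.bone_centre[1]
    angle = np.arctan2(np.abs(dcol), drow)  # 0 along +row (downwards)
    in_wedge = (angle <= half) & (drow > 0) & (bone_radius_map > spec.bone_radius)
    labels[in_wedge & (labels != 1)] = 5
    return labels


def make_phantom(spec: PhantomSpec | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the phantom image, its region label map and the true fat mask.

    Returns ``(image, labels, fat_truth)`` where `image` is float in [0, 1],
    `labels` follows `REGION_LEGEND`, and `fat_truth` is the gap-free
    adipose annulus (including the part hidden by the shadow) — the ground
    truth a segmentation plus shadow completion should recover.

    The image is a blurred region template modulated by a smooth
    multiplicative inhomogeneity field and multiplicative speckle.  Speckle
    is Rayleigh distributed (the square root of exponential intensity, as in
    fully developed interference after amplitude detection), normalised to
    unit mean and blended in by ``speckle_scale``, so region means are
    preserved.
    """
    if spec is None:
        spec = PhantomSpec()
    labels = _region_labels(spec)

    means = {
        1: spec.background_intensity,
        2: spec.fat_intensity,
        3: spec.muscle_intensity,
        4: spec.bone_intensity,
        5: spec.shadow_intensity,
    }
    template = np.zeros(spec.size, dtype=float)
    for value, intensity in means.items():
        template[labels == value] = intensity
    if spec.edge_softness > 0:
        template = ndimage.gaussian_filter(template, spec.edge_softness)

    rng = np.random.default_rng(spec.seed)

    # smooth multiplicative inhomogeneity: low-pass filtered white noise
    field_sigma = max(spec.size) / 6.0
    rough = rng.standard_normal(spec.size)
    smooth = ndimage.gaussian_filter(rough, field_sigma)
    std = smooth.std()
    if std > 0:
        smooth = smooth / std
    inhomogeneity = 1.0 + spec.inhomogeneity_amplitude * smooth

    # Rayleigh speckle with unit mean, blended by the speckle scale
    rayleigh = np.sqrt(rng.exponential(1.0, size=spec.size))
    rayleigh /= np.sqrt(np.pi) / 2.0
    speckle = 1.0 + spec.speckle_scale * (rayleigh - 1.0)

    image = np.clip(template * inhomogeneity * speckle, 0.0, 1.0)

    rows, cols = spec.size
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    radius = np.hypot(rr - spec.centre[0], cc - spec.centre[1])
    fat_truth = (radius <= spec.arm_radius) & (
        radius > spec.arm_radius - spec.fat_thickness
    )
    return image, labels, fat_truth


def make_gap_fixture(
    k: int,
    wedge_deg: float = 40.0,
    r_outer: float = 80.0,
    r_inner: float = 55.0,
    size: tuple[int, int] = (200, 200),
    start_deg: float = 90.0,
) -> np.ndarray:
    """Binary annulus with `k` equally spaced wedges removed.

    Wedges are centred at ``start_deg + i * 360/k`` and must not overlap
    (``k * wedge_deg < 360``).  Used as a deterministic test bed for gap
    detection and completion.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > 0 and k * wedge_deg >= 360.0:
        raise ValueError(f"{k} wedges of {wedge_deg} deg overlap")
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    rows, cols = size
    centre = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    radius = np.hypot(rr - centre[0], cc - centre[1])
    mask = (radius <= r_outer) & (radius > r_inner)

    theta = np.degrees(np.arctan2(rr - centre[0], cc - centre[1]))  # (-180, 180]
    for i in range(k):
        centre_deg = start_deg + i * 360.0 / k
        delta = (theta - centre_deg + 180.0) % 360.0 - 180.0
        mask &= ~(np.abs(delta) <= wedge_deg / 2.0)
    return mask


def fat_sector_roi(
    spec: PhantomSpec,
    centre_deg: float = 180.0,
    width_deg: float = 90.0,
    margin: float = 4.0,
) -> np.ndarray:
    """Angular sector of the true fat annulus, for training object statistics.

    Mirrors the method's one-off training stage: a clean region of fat, away
    from the acoustic shadow (which opens at 90 degrees, straight down from
    the bone).  `margin` shrinks the annulus radially so the ROI stays clear
    of the boundaries; angles are measured from the +col axis with +row
    (downwards) at +90 degrees.
    """
    rows, cols = spec.size
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    radius = np.hypot(rr - spec.centre[0], cc - spec.centre[1])
    ring = (radius <= spec.arm_radius - margin) & (
        radius > spec.arm_radius - spec.fat_thickness + margin
    )
    theta = np.degrees(np.arctan2(rr - spec.centre[0], cc - spec.centre[1]))
    delta = (theta - centre_deg + 180.0) % 360.0 - 180.0
    roi = ring & (np.abs(delta) <= width_deg / 2.0)
    if not roi.any():
        raise ValueError("empty training sector; widen the sector or reduce margin")
    return roi


def contrast_transform(image: np.ndarray, a: float = 1.0, c: float = 0.0, gamma: float = 1.0) -> np.ndarray:
    """Gain/offset/gamma transform ``clip(a * image**gamma + c, 0, 1)``.

    Used to exercise the contrast invariance of local phase and feature
    asymmetry: with gamma = 1 and no clipping the phase maps of the
    transformed and original images coincide.
    """
    if not a > 0:
        raise ValueError(f"gain a must be > 0, got {a}")
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    image = np.asarray(image, dtype=float)
    return np.clip(a * image**gamma + c, 0.0, 1.0)
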