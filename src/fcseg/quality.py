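"""Entropy-based regional image-quality scores for B-mode ultrasound.

Each anatomical region of an image (background, adipose layer, muscle,
bone) gets the Shannon entropy of its gray-level histogram — a measure of
the information content of its speckle pattern that depends on appearance
complexity rather than contrast or absolute intensity.  The interface
scores ``S_ab = H(adipose) - H(background)`` and
``S_am = H(adipose) - H(muscle)`` quantify how distinguishable the two
interfaces that matter for adipose segmentation are: low (or negative)
scores flag images where adjacent regions look alike, i.e. lower quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QualityScores", "region_entropy", "quality_scores"]

#: gray levels used for the histograms (8-bit images)
DEFAULT_LEVELS = 256

#: region names required by the interface scores
REQUIRED_REGIONS = ("background", "adipose", "muscle", "bone")


@dataclass(frozen=True)
class QualityScores:
    """Per-region entropies (bits) and the two interface scores."""

    entropies: dict[str, float]
    S_ab: float
    S_am: float


def _as_levels(image: np.ndarray, levels: int) -> np.ndarray:
    """Map an image to integer gray levels 0..levels-1.

    Integer images are used as-is (they must already fit the level range);
    float images in [0, 1] are quantised uniformly.
    """
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        if image.min() < 0 or image.max() >= levels:
            raise ValueError(f"integer image values must lie in [0, {levels - 1}]")
        return image.astype(np.int64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("float images must be normalised to [0, 1]")
    return np.minimum((image * levels).astype(np.int64), levels - 1)


def region_entropy(image: np.ndarray, region: np.ndarray, levels: int = DEFAULT_LEVELS) -> float:
    """Shannon entropy (bits) of the gray-level histogram inside `region`.

    ``H = -sum_k p_k log2 p_k`` over the `levels` histogram bins, with the
    usual convention ``0 * log 0 = 0``.  Ranges from 0 (constant region) to
    ``log2(levels)`` (all levels equally likely).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    values = _as_levels(image, levels)[region]
    counts = np.bincount(values, minlength=levels)
    p = counts / counts.sum()
    nonzero = p[p > 0]
    return float(-(nonzero * np.log2(nonzero)).sum())


def quality_scores(
    image: np.ndarray,
    labels: np.ndarray,
    legend: dict[int, str],
    levels: int = DEFAULT_LEVELS,
) -> QualityScores:
    """Per-region entropies and the two interface quality scores.

    `legend` maps label values to region names and must cover background,
    adipose, muscle and bone; extra labelled regions (e.g. shadow) get an
    entropy too but do not enter the scores.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs labels {labels.shape}")

    name_to_label = {name: value for value, name in legend.items()}
    for name in REQUIRED_REGIONS:
        if name not in name_to_label:
            raise ValueError(f"missing region {name!r} in the label legend")
        if not (labels == name_to_label[name]).any():
            raise ValueError(f"region {name!r} has no pixels in the label map")

    entropies = {
        name: region_entropy(image, labels == value, levels)
        for value, name in legend.items()
        if (labels == value).any()
    }
    return QualityScores(
        entropies=entropies,
        S_ab=entropies["adipose"] - entropies["background"],
        S_am=entropies["adipose"] - entropies["muscle"],
    )
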