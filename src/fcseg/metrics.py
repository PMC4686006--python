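"""Segmentation agreement metrics: area overlaps and contour distances.

Region-based metrics follow the standard delineation-evaluation framework:
sensitivity is the true-positive area fraction TPAF = |T & R| / |R|,
specificity is 1 - FPAF with the false-positive area fraction
FPAF = |T - R| / |R|, and precision (repeatability of a method across two
runs) is the Jaccard overlap of the two runs.  Distance-based metrics pool
symmetric nearest-boundary distances from both masks: MSD is their maximum,
ASD their mean and RMSD their root mean square, scaled by the pixel spacing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["area_overlap", "precision_overlap", "contour_distances"]


def area_overlap(test: np.ndarray, reference: np.ndarray) -> dict[str, float]:
    """TPAF sensitivity, 1-FPAF specificity and Dice of `test` vs `reference`."""
    test = np.asarray(test, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if test.shape != reference.shape:
        raise ValueError("mask shapes differ")
    ref_area = int(reference.sum())
    if ref_area == 0:
        raise ValueError("empty reference mask")
    tp = int((test & reference).sum())
    fp = int((test & ~reference).sum())
    sensitivity = tp / ref_area
    specificity = 1.0 - fp / ref_area
    denom = int(test.sum()) + ref_area
    dice = 2.0 * tp / denom if denom else 0.0
    return {"sensitivity": sensitivity, "specificity": specificity, "dice": dice}


def precision_overlap(run1: np.ndarray, run2: np.ndarray) -> float:
    """Repeatability of two runs of a method: |T1 & T2| / |T1 | T2|."""
    run1 = np.asarray(run1, dtype=bool)
    run2 = np.asarray(run2, dtype=bool)
    if run1.shape != run2.shape:
        raise ValueError("mask shapes differ")
    union = int((run1 | run2).sum())
    if union == 0:
        raise ValueError("both masks are empty")
    return int((run1 & run2).sum()) / union


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Inner boundary pixel centres (4-connected erosion residue)."""
    structure = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~eroded).astype(float)


def contour_distances(
    test: np.ndarray,
    reference: np.ndarray,
    spacing: float = 1.0,
) -> dict[str, float]:
    """Symmetric contour distances MSD, ASD and RMSD (in spacing units).

    Nearest-neighbour distances from every boundary pixel of each mask to
    the other mask's boundary are pooled from both directions; MSD is their
    max, ASD their mean, RMSD their root mean square.  Symmetric in the two
    masks by construction, and ASD <= RMSD <= MSD always.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    test = np.asarray(test, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if test.shape != reference.shape:
        raise ValueError("mask shapes differ")
    if not test.any() or not reference.any():
        raise ValueError("empty mask")

    boundary_t = _boundary_points(test)
    boundary_r = _boundary_points(reference)
    d_tr, _ = cKDTree(boundary_r).query(boundary_t)
    d_rt, _ = cKDTree(boundary_t).query(boundary_r)
    pooled = np.concatenate([d_tr, d_rt]) * spacing
    return {
        "msd": float(pooled.max()),
        "asd": float(pooled.mean()),
        "rmsd": float(np.sqrt((pooled**2).mean())),
    }
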