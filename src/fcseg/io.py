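"""Image, mask, seed and label-map readers/writers.

Grayscale images come from 8/16-bit PNG or TIFF (via Pillow) or single-frame
DICOM (pixel data only, via pydicom) and are normalised to [0, 1] by
dividing by the dtype maximum — not by min-max stretching, which would break
the contrast invariance the local-phase machinery is built on.  Masks are
8-bit 0/255 PNGs; seeds are JSON lists of 0-based {"row": r, "col": c}
objects with row 0 at the top.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_seeds",
    "write_seeds",
    "read_labels",
    "write_labels",
]


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float in [0, 1] (dtype-max normalisation)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        dataset = pydicom.dcmread(path)
        arr = dataset.pixel_array
        if arr.ndim == 3:  # colour-encoded B-mode frame
            arr = arr.mean(axis=-1).astype(arr.dtype)
        if arr.ndim != 2:
            raise ValueError(f"expected a single-frame 2D DICOM, got shape {arr.shape}")
    else:
        with Image.open(path) as img:
            if img.mode not in ("L", "I", "I;16", "F"):
                img = img.convert("L")
            # 16-bit PNGs arrive as mode "I" (int32 array): the stored data
            # is still 16-bit, so dtype max would over-normalise
            divisor = {"L": 255.0, "I": 65535.0, "I;16": 65535.0, "F": 1.0}[img.mode]
            arr = np.asarray(img)
        return arr.astype(float) / divisor
    return arr.astype(float) / _dtype_max(arr)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0, 1] as 8-bit grayscale (PNG/TIFF by suffix)."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel is foreground)."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 0/255 8-bit PNG."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_seeds(path: str | Path) -> list[tuple[int, int]]:
    """Read seeds from a JSON list of {"row": r, "col": c} (0-based)."""
    with open(path) as handle:
        data = json.load(handle)
    if not isinstance(data, list) or not data:
        raise ValueError("seeds file must hold a non-empty JSON list")
    seeds = []
    for entry in data:
        try:
            seeds.append((int(entry["row"]), int(entry["col"])))
        except (TypeError, KeyError) as exc:
            raise ValueError(f"malformed seed entry {entry!r}") from exc
    return seeds


def write_seeds(seeds: list[tuple[int, int]], path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump([{"row": int(r), "col": int(c)} for r, c in seeds], handle, indent=2)


def read_labels(path: str | Path) -> tuple[np.ndarray, dict[int, str]]:
    """Read an integer label map (PNG) and its JSON legend sidecar.

    The sidecar lives next to the image as ``<name>.legend.json`` and maps
    label values to region names.
    """
    path = Path(path)
    with Image.open(path) as img:
        labels = np.asarray(img).astype(np.int64)
    legend_path = path.with_suffix(".legend.json")
    if not legend_path.exists():
        raise FileNotFoundError(f"label legend sidecar not found: {legend_path}")
    with open(legend_path) as handle:
        raw = json.load(handle)
    legend = {int(k): str(v) for k, v in raw.items()}
    return labels, legend


def write_labels(labels: np.ndarray, legend: dict[int, str], path: str | Path) -> None:
    path = Path(path)
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("label values must fit 8 bits")
    Image.fromarray(arr.astype(np.uint8)).save(path)
    with open(path.with_suffix(".legend.json"), "w") as handle:
        json.dump({str(k): v for k, v in legend.items()}, handle, indent=2)
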