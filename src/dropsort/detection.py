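"""Feature-based single-cell gate for nozzle-camera frames.

Before any learned classification, the dispenser only accepts a droplet when a
conventional object-detection pass finds exactly one plausible cell in the
nozzle region: background subtraction, thresholding, connected components, and
filters on object count, size and roundness.  The winning object's centroid
then anchors a 55 x 55 crop that downstream classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "DetectedObject",
    "DetectionResult",
    "DetectionParams",
    "subtract_background",
    "segment_objects",
    "is_single_cell",
    "crop_cell",
]


@dataclass(frozen=True)
class DetectedObject:
    centroid: tuple[float, float]  # (row, col), px
    area: float  # px^2
    perimeter: float  # px
    roundness: float  # 4*pi*A/P^2, clipped to (0, 1]


@dataclass(frozen=True)
class DetectionResult:
    objects: list
    is_single_cell: bool
    selected: int | None  # index into objects when is_single_cell


@dataclass(frozen=True)
class DetectionParams:
    """Gate thresholds; defaults are exposed placeholders, not instrument values."""

    area_min: float = 20.0
    area_max: float = 2000.0
    roundness_min: float = 0.5
    segmentation_threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 20.0
    smoothing_sigma: float = 1.5  # Gaussian presmoothing of |diff|; 0 disables
    crop_size: int = 55

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be < area_max")
        if not 0.0 <= self.roundness_min <= 1.0:
            raise ValueError("roundness_min must be in [0, 1]")
        if self.segmentation_threshold_mode not in ("otsu", "fixed"):
            raise ValueError("segmentation_threshold_mode must be 'otsu' or 'fixed'")


def subtract_background(frame: np.ndarray, empty: np.ndarray) -> np.ndarray:
    """Signed pixelwise difference ``frame - empty`` (no clipping).

    The sign is preserved: cells may be darker or brighter than the nozzle
    background, and the classifier's normalization handles both.
    """
    frame = np.asarray(frame, dtype=float)
    empty = np.asarray(empty, dtype=float)
    if frame.shape != empty.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs empty {empty.shape}")
    return frame - empty


def _roundness(area: float, perimeter: float) -> float:
    # isoperimetric ratio; degenerate (point-like) contours count as round
    if perimeter <= 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / perimeter**2))


def segment_objects(diff: np.ndarray, params: DetectionParams) -> list[DetectedObject]:
    """Binarize |diff|, label 8-connected components, measure each object.

    Otsu's threshold is the default; a fixed gray-value threshold is available
    for reproducibility.  Objects are returned sorted by area, largest first.
    An all-zero difference image yields an empty list.
    """
    diff = np.asarray(diff, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("difference image contains non-finite values")
    mag = np.abs(diff)
    if mag.max() == 0:
        return []
    if params.smoothing_sigma > 0:
        # suppress per-pixel camera noise before thresholding; the cell body
        # (radius >> sigma) is essentially unaffected
        mag = gaussian_filter(mag, params.smoothing_sigma)
    if params.segmentation_threshold_mode == "otsu":
        thr = threshold_otsu(mag)
    else:
        thr = params.fixed_threshold
    mask = mag > thr
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    objects = [
        DetectedObject(
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            area=float(p.area),
            perimeter=max(float(p.perimeter), 1e-9),
            roundness=_roundness(float(p.area), float(p.perimeter)),
        )
        for p in measure.regionprops(labels)
    ]
    objects.sort(key=lambda o: o.area, reverse=True)
    return objects


def is_single_cell(objects: list[DetectedObject], params: DetectionParams) -> DetectionResult:
    """Single-cell verdict: exactly one object passes all gates.

    True iff exactly one object satisfies area_min <= area <= area_max and
    roundness >= roundness_min, and no *second* object of at least area_min
    exists anywhere in the frame — two cell-sized objects mean ambiguous
    droplet occupancy and must never be dispensed as a single cell.
    """
    passing = [
        i
        for i, o in enumerate(objects)
        if params.area_min <= o.area <= params.area_max
        and o.roundness >= params.roundness_min
    ]
    big = [i for i, o in enumerate(objects) if o.area >= params.area_min]
    ok = len(passing) == 1 and len(big) == 1
    return DetectionResult(
        objects=list(objects), is_single_cell=ok, selected=passing[0] if ok else None
    )


def crop_cell(
    frame: np.ndarray, centroid: tuple[float, float], crop_size: int = 55
) -> np.ndarray:
    """Extract a ``crop_size`` square centered on ``centroid``.

    The centroid is rounded to the nearest pixel, which maps to the central
    pixel of the crop (floor convention: a 55 px window spans [c-27, c+27]).
    Windows that overrun the frame are padded with the frame's median value so
    border crops carry no artificial dark edge.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    half = crop_size // 2
    cr, cc = int(round(centroid[0])), int(round(centroid[1]))
    r0, c0 = cr - half, cc - half
    r1, c1 = r0 + crop_size, c0 + crop_size
    out = np.full((crop_size, crop_size), float(np.median(frame)))
    rr0, cc0 = max(0, r0), max(0, c0)
    rr1, cc1 = min(h, r1), min(w, c1)
    if rr0 < rr1 and cc0 < cc1:
        out[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = frame[rr0:rr1, cc0:cc1]
    return out
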