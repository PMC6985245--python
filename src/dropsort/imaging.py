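"""Synthetic nozzle-camera imagery for single-cell dispensing.

Emulates the image stream of a drop-on-demand single-cell printer: for every
dispense event the instrument stores a frame of the nozzle region together with
an ``empty`` frame captured just before the cell arrived, so the background can
be removed a posteriori.  Two morphological classes are rendered:

* ``viable`` — a single smooth, roughly circular cell body (Gaussian radial
  intensity profile), high contrast against the background;
* ``dead``   — a damaged cell, either fragmented into several sub-blobs or a
  single blob with a strongly perturbed, irregular boundary, at reduced
  contrast.

The morphology model is deliberately minimal: it is the simplest construction
under which object size and roundness — and hence a learned image classifier —
carry information about viability.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "ImagingParams",
    "LabeledFramePair",
    "make_background",
    "render_cell",
    "generate_frame_pair",
    "generate_dataset",
]

#: growth probabilities conditional on morphological class; a visually intact
#: ("viable") cell grows with high probability, a damaged one almost never
DEFAULT_GROWTH_PROBABILITY = {"viable": 0.95, "dead": 0.02}


@dataclass(frozen=True)
class ImagingParams:
    """Parameters of the synthetic nozzle-camera image generator.

    All geometric quantities are in pixels and all intensities in gray values
    of an unsigned image at ``bit_depth`` bits (clipped, never wrapped).
    """

    frame_size: tuple[int, int] = (300, 300)
    bit_depth: int = 8
    background_level: float = 120.0
    background_noise_sd: float = 3.0
    illumination_gradient: float = 0.05  # max fractional deviation across frame
    cell_radius_px: float = 8.0
    cell_radius_sd: float = 1.0
    viable_contrast: float = 60.0  # signed intensity offset of the cell body
    dead_contrast_factor: float = 0.6  # dead cells image at reduced contrast
    # dead-cell morphology: 1 = single boundary-perturbed blob (default; such
    # cells still pass a size/roundness single-cell gate, which is exactly why
    # a learned classifier is needed); >1 = fragmented into that many sub-blobs
    dead_fragmentation: int = 1
    dead_irregularity: float = 0.5  # boundary perturbation amplitude (fraction of r)
    growth_probability: dict = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_PROBABILITY)
    )

    def __post_init__(self) -> None:
        h, w = self.frame_size
        if h <= 0 or w <= 0:
            raise ValueError(f"frame_size must be positive, got {self.frame_size}")
        if h < 55 or w < 55:
            raise ValueError("frame_size must be at least the 55 px crop size")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be positive")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")
        if self.dead_fragmentation < 1:
            raise ValueError("dead_fragmentation must be >= 1")

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)

    def replace(self, **kw) -> "ImagingParams":
        return dataclasses.replace(self, **kw)


@dataclass
class LabeledFramePair:
    """An (empty frame, cell frame) pair sharing one background realization.

    The two frames differ by the rendered cell sprite and by independent
    per-pixel camera noise, so background subtraction is effective but not
    perfect — as with the stored ``empty`` images on the real instrument.
    """

    empty_frame: np.ndarray
    cell_frame: np.ndarray
    true_centroid: tuple[float, float]  # (row, col)
    true_label: str  # "viable" | "dead"
    growth_probability: float


def _background_base(params: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    """Deterministic-given-rng background structure (level + illumination ramp)."""
    h, w = params.frame_size
    rows = np.linspace(-0.5, 0.5, h)[:, None]
    cols = np.linspace(-0.5, 0.5, w)[None, :]
    # randomly oriented linear illumination ramp across the frame
    theta = rng.uniform(0, 2 * np.pi)
    ramp = rows * np.cos(theta) + cols * np.sin(theta)
    base = params.background_level * (1.0 + 2.0 * params.illumination_gradient * ramp)
    return base


def make_background(params: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    """Render one background frame: level + illumination ramp + pixel noise.

    Returns a float array of shape ``frame_size`` clipped to the representable
    intensity range at ``bit_depth``.
    """
    base = _background_base(params, rng)
    noise = rng.normal(0.0, params.background_noise_sd, size=params.frame_size)
    return np.clip(base + noise, 0.0, params.full_scale)


def _disk_profile(
    size: int, radius: float, contrast: float, softness: float = 0.35
) -> np.ndarray:
    """Gaussian-edged disk: full contrast inside, smooth roll-off at the rim."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    edge = softness * radius
    return contrast * (1.0 / (1.0 + np.exp((r - radius) / max(edge, 0.5))))


def _irregular_blob(
    size: int,
    radius: float,
    contrast: float,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single blob whose boundary radius is modulated by random low-order harmonics."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    phi = np.arctan2(yy - c, xx - c)
    r_mod = np.zeros_like(phi)
    # low-order angular harmonics give lobed, star-like outlines
    for k in range(2, 7):
        a = rng.uniform(-1.0, 1.0)
        p = rng.uniform(0, 2 * np.pi)
        r_mod += a * np.cos(k * phi + p)
    local_radius = radius * (1.0 + amplitude * r_mod / 3.0)
    local_radius = np.maximum(local_radius, 1.0)
    edge = 0.25 * radius
    return contrast * (1.0 / (1.0 + np.exp((r - local_radius) / max(edge, 0.5))))


def _sprite_metrics(sprite: np.ndarray, contrast: float) -> tuple[float, float, int]:
    """Area, perimeter and component count of the sprite binarized at half contrast."""
    mask = np.abs(sprite) > (abs(contrast) / 2.0)
    labels = measure.label(mask, connectivity=2)
    n_components = int(labels.max())
    area = float(mask.sum())
    perimeter = 0.0
    for prop in measure.regionprops(labels):
        perimeter += float(prop.perimeter)
    return area, perimeter, n_components


def render_cell(
    label: str, params: ImagingParams, rng: np.random.Generator
) -> tuple[np.ndarray, float, float]:
    """Render one cell sprite (signed intensity offset patch).

    Returns ``(sprite, area_px2, perimeter_px)`` where area and perimeter are
    measured on the sprite binarized at half its peak contrast.  A viable cell
    is a single smooth disk; a dead cell is either ``dead_fragmentation``
    sub-blobs (if that parameter exceeds 1) or one boundary-perturbed blob, at
    ``dead_contrast_factor`` of the viable contrast.
    """
    if label not in ("viable", "dead"):
        raise ValueError(f"label must be 'viable' or 'dead', got {label!r}")
    radius = max(2.0, rng.normal(params.cell_radius_px, params.cell_radius_sd))
    size = int(np.ceil(radius * 6)) | 1  # odd patch comfortably containing the cell

    if label == "viable":
        contrast = params.viable_contrast
        sprite = _disk_profile(size, radius, contrast)
    else:
        contrast = params.viable_contrast * params.dead_contrast_factor
        if params.dead_fragmentation > 1:
            sprite = np.zeros((size, size))
            k = params.dead_fragmentation
            c = (size - 1) / 2.0
            # scatter sub-blobs around the nominal cell position, kept disjoint
            # by angular placement on a ring
            angles = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, k, endpoint=False)
            ring = radius * 1.35
            sub_r = radius / np.sqrt(k) * rng.uniform(0.8, 1.1, size=k)
            for ang, sr in zip(angles, sub_r):
                dy, dx = ring * np.sin(ang), ring * np.cos(ang)
                blob = _disk_profile(size, max(sr, 1.5), contrast, softness=0.3)
                shifted = np.zeros_like(sprite)
                sy, sx = int(round(dy)), int(round(dx))
                src = blob[
                    max(0, -sy) : size - max(0, sy), max(0, -sx) : size - max(0, sx)
                ]
                shifted[
                    max(0, sy) : size - max(0, -sy), max(0, sx) : size - max(0, -sx)
                ] = src
                sprite = np.maximum(sprite, shifted)
        else:
            sprite = _irregular_blob(size, radius, contrast, params.dead_irregularity, rng)

    area, perimeter, _ = _sprite_metrics(sprite, contrast)
    return sprite, area, perimeter


def generate_frame_pair(
    label: str, params: ImagingParams, rng: np.random.Generator
) -> LabeledFramePair:
    """Generate one (empty, cell) frame pair with a shared background.

    The cell is placed uniformly inside the central region of the frame (at
    least one crop half-width from every border, mimicking a nozzle ROI).  The
    growth probability is the class-conditional default unless overridden in
    ``params.growth_probability``.
    """
    base = _background_base(params, rng)
    h, w = params.frame_size
    margin = 28  # half the 55 px crop, so crops of interior cells need no padding
    row = float(rng.integers(margin, h - margin))
    col = float(rng.integers(margin, w - margin))

    sprite, _, _ = render_cell(label, params, rng)
    s = sprite.shape[0]
    half = s // 2
    canvas = np.zeros_like(base)
    r0, c0 = int(row) - half, int(col) - half
    rr0, cc0 = max(0, r0), max(0, c0)
    rr1, cc1 = min(h, r0 + s), min(w, c0 + s)
    canvas[rr0:rr1, cc0:cc1] = sprite[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]

    full = params.full_scale
    noise_e = rng.normal(0.0, params.background_noise_sd, size=(h, w))
    noise_c = rng.normal(0.0, params.background_noise_sd, size=(h, w))
    empty = np.clip(base + noise_e, 0.0, full)
    cell = np.clip(base + canvas + noise_c, 0.0, full)

    p_grow = float(params.growth_probability[label])
    return LabeledFramePair(
        empty_frame=empty,
        cell_frame=cell,
        true_centroid=(row, col),
        true_label=label,
        growth_probability=p_grow,
    )


def _well_id(i: int) -> tuple[str, str]:
    """Map a running dispense index to (plate_id, well_id) on 96-well plates.

    Wells fill in column-major order A1, B1, ... H1, A2, ... H12.
    """
    plate, pos = divmod(i, 96)
    col_idx, row_idx = divmod(pos, 8)
    return f"P{plate + 1}", f"{chr(ord('A') + row_idx)}{col_idx + 1}"


def generate_dataset(
    n: int,
    c_v: float,
    params: ImagingParams | None = None,
    seed: int = 0,
    out_dir=None,
    val_fraction: float = 0.2,
):
    """Generate a labeled crop dataset emulating one dispensing campaign.

    Exactly ``round(n * c_v)`` cells are labeled viable; labels are shuffled
    over dispense order.  Every crop is produced through the detection module's
    background-subtract → segment → crop pipeline (falling back to a crop at
    the true centroid when segmentation misses), so synthetic and real data
    share one code path.

    Returns ``(manifest, crops)`` where ``manifest`` is a DataFrame with
    columns image_path, empty_path, well_id, plate_id, label,
    growth_probability, split, and ``crops`` is a float array of shape
    (n, 55, 55) of signed background-subtracted crops.  When ``out_dir`` is
    given, 8-bit PNG crops plus empties and a ``manifest.csv`` are written
    there and the path columns point at them.
    """
    from . import detection  # deferred import; detection also imports nothing from here

    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= c_v <= 1.0:
        raise ValueError("c_v must be in [0, 1]")
    params = params or ImagingParams()
    rng = np.random.default_rng(seed)

    n_viable = int(round(n * c_v))
    labels = np.array(["viable"] * n_viable + ["dead"] * (n - n_viable))
    rng.shuffle(labels)

    det_params = detection.DetectionParams()
    crops = np.empty((n, det_params.crop_size, det_params.crop_size))
    rows = []
    n_val = int(round(n * val_fraction))
    split = np.array(["val"] * n_val + ["train"] * (n - n_val))
    rng.shuffle(split)

    write = out_dir is not None
    if write:
        import os

        from PIL import Image

        os.makedirs(out_dir, exist_ok=True)

    for i, label in enumerate(labels):
        pair = generate_frame_pair(label, params, rng)
        diff = detection.subtract_background(pair.cell_frame, pair.empty_frame)
        objs = detection.segment_objects(diff, det_params)
        result = detection.is_single_cell(objs, det_params)
        centroid = (
            objs[result.selected].centroid if result.is_single_cell else pair.true_centroid
        )
        crops[i] = detection.crop_cell(diff, centroid, det_params.crop_size)

        plate_id, well_id = _well_id(i)
        img_path, empty_path = f"crop_{i:05d}.png", f"empty_{i:05d}.png"
        if write:
            import os

            # store the signed difference mapped to [0, full] so PNG round-trips
            full = params.full_scale
            u8 = np.clip((crops[i] + full) / 2.0, 0, full).astype(np.uint8)
            Image.fromarray(u8, mode="L").save(os.path.join(out_dir, img_path))
            e8 = np.clip(pair.empty_frame, 0, full).astype(np.uint8)
            Image.fromarray(e8, mode="L").save(os.path.join(out_dir, empty_path))
        rows.append(
            {
                "image_path": img_path,
                "empty_path": empty_path,
                "well_id": well_id,
                "plate_id": plate_id,
                "label": label,
                "growth_probability": pair.growth_probability,
                "split": split[i],
            }
        )

    manifest = pd.DataFrame(rows)
    if write:
        import os

        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest, crops
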