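"""Segmentation and particle counting on difference images.

Per frame the pipeline is: scene-model subtraction, 8-bit conversion,
thresholding (Otsu by default), one binary opening followed by one closing
to consolidate blobs, then 8-connected component labelling with an
inclusive pixel-area gate (default 150-950 px) that separates fly-sized
particles from noise specks and large artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .background import build_background, rolling_backgrounds, subtract
from .types import DetectionRecord, ImageStack, RegionOfInterest

__all__ = [
    "BinaryMask",
    "DetectionConfig",
    "to_8bit",
    "threshold",
    "open_close",
    "label_and_filter",
    "detect_stack",
    "count_flies",
]


@dataclass
class BinaryMask:
    """Boolean foreground mask with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    method: str
    degenerate: bool = False


@dataclass
class DetectionConfig:
    """Settings of the full per-frame detection pipeline."""

    window: int = 50
    scheme: str = "linear"
    rolling: bool = False
    threshold_method: str = "otsu"
    fixed_value: int | None = None
    radius: int = 1
    min_area: int = 150
    max_area: int = 950
    roi: RegionOfInterest | None = None
    # which image is converted to 8-bit and thresholded: the difference
    # image (default) or the raw frame before subtraction
    convert_source: str = "difference"

    def __post_init__(self) -> None:
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        if self.convert_source not in ("difference", "raw"):
            raise ValueError("convert_source must be 'difference' or 'raw'")


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linearly rescale an image's [min, max] onto [0, 255].

    Rounding is half-up; a constant image maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = 255.0 * (image - lo) / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)


def threshold(
    image: np.ndarray, method: str = "otsu", fixed_value: int | None = None
) -> BinaryMask:
    """Binarise an 8-bit image; foreground is ``image >= threshold``.

    ``otsu`` picks the threshold maximising between-class variance.  A
    constant image has no between-class split; it yields an empty mask
    flagged ``degenerate`` rather than an error.
    """
    image = np.asarray(image)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed thresholding requires fixed_value")
        if not 0 <= fixed_value <= 255:
            raise ValueError("fixed_value must lie in [0, 255]")
        return BinaryMask(image >= fixed_value, float(fixed_value), "fixed")
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if image.min() == image.max():
        return BinaryMask(
            np.zeros(image.shape, dtype=bool), float(image.max()) + 1, "otsu",
            degenerate=True,
        )
    # threshold_otsu returns t with foreground > t; shift to the >= convention
    t = threshold_otsu(image, nbins=256) + 1
    return BinaryMask(image >= t, float(t), "otsu")


def open_close(mask: np.ndarray | BinaryMask, radius: int = 1) -> np.ndarray:
    """Binary opening then closing with a (2r+1) square structuring element.

    Opening removes specks smaller than the element; closing bridges
    sub-element gaps so one fly does not split into several particles.
    Radius 0 is the identity.
    """
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return m.copy()
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    opened = morphology.opening(m, footprint)
    return morphology.closing(opened, footprint)


def label_and_filter(
    mask: np.ndarray | BinaryMask,
    min_area: int = 150,
    max_area: int = 950,
    roi: RegionOfInterest | None = None,
    frame_id: int = 0,
) -> list[DetectionRecord]:
    """8-connected particle analysis with an inclusive area gate.

    Components are taken after intersecting the mask with the region of
    interest; those whose pixel count falls in ``[min_area, max_area]``
    become detection records, everything else is discarded.
    """
    if not 0 < min_area <= max_area:
        raise ValueError("need 0 < min_area <= max_area")
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if roi is not None:
        m = m & roi.mask(m.shape)
    labels = measure.label(m, connectivity=2)
    records = []
    for region in measure.regionprops(labels):
        if min_area <= region.area <= max_area:
            records.append(
                DetectionRecord(
                    frame_id=frame_id,
                    blob_id=region.label,
                    centroid=tuple(region.centroid),
                    area=int(region.area),
                    bbox=tuple(region.bbox),
                )
            )
    return records


def _frame_mask(frame, bg, config: DetectionConfig) -> np.ndarray:
    if config.convert_source == "raw":
        diff = subtract(to_8bit(frame), to_8bit(bg.image))
        eight = diff.astype(np.uint8)
    else:
        eight = to_8bit(subtract(frame, bg))
    binary = threshold(eight, config.threshold_method, config.fixed_value)
    return open_close(binary, config.radius)


def detect_stack(
    stack: ImageStack, config: DetectionConfig | None = None
) -> list[DetectionRecord]:
    """Run the full pipeline on every frame; return all detection records."""
    config = config or DetectionConfig()
    if config.rolling:
        backgrounds = rolling_backgrounds(stack, config.window, config.scheme)
    else:
        bg = build_background(stack, config.window, config.scheme)
        backgrounds = [bg] * len(stack)
    records: list[DetectionRecord] = []
    for t in range(len(stack)):
        m = _frame_mask(stack.frames[t], backgrounds[t], config)
        records.extend(
            label_and_filter(m, config.min_area, config.max_area, config.roi, frame_id=t)
        )
    return records


def count_flies(
    stack: ImageStack, config: DetectionConfig | None = None
) -> pd.DataFrame:
    """Per-frame fly counts for one camera's stack.

    Returns a tidy frame with columns ``frame``, ``timestamp``, ``surface``
    and ``count`` (one row per frame, zero counts included).
    """
    config = config or DetectionConfig()
    records = detect_stack(stack, config)
    counts = np.zeros(len(stack), dtype=int)
    for rec in records:
        counts[rec.frame_id] += 1
    return pd.DataFrame(
        {
            "frame": np.arange(len(stack)),
            "timestamp": stack.timestamps,
            "surface": stack.surface or "surface",
            "count": counts,
        }
    )


def image_set_counts(count_series: pd.DataFrame) -> pd.DataFrame:
    """Sum counts across a trap's surfaces at each time step.

    An image set is all simultaneous images of one trap; input is a
    concatenation of per-surface count series sharing a ``timestamp``
    column.
    """
    return (
        count_series.groupby("timestamp", as_index=False)["count"]
        .sum()
        .rename(columns={"count": "set_count"})
    )
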