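"""Core in-memory containers shared across the pipeline stages.

Conventions: images are 2-D numpy arrays indexed (row, col) with the origin
at the top-left; stacks are 3-D ``(frame, row, col)``; coordinates are
0-based; bounding boxes are half-open ``[min_row, max_row) x [min_col,
max_col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """An ordered sequence of equally-sized grayscale frames.

    Parameters
    ----------
    frames
        ``(n_frames, height, width)`` array, uint8.
    timestamps
        Seconds since the start of acquisition, one per frame.
    surface
        Optional label of the trap surface imaged (e.g. ``"Internal East"``).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    surface: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1:]


@dataclass(frozen=True)
class Blob:
    """One simulated fly: identity, position and rendered footprint."""

    blob_id: int
    centroid: tuple[float, float]  # (row, col)
    area: int                      # rendered pixel count
    surface: str
    # rasterised (rows, cols) pixel indices; excluded from equality/repr
    footprint: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )


@dataclass
class GroundTruth:
    """Per-frame record of every rendered fly blob.

    ``blobs[t]`` lists the flies present in frame ``t``; ``counts[t]`` is
    always ``len(blobs[t])``.
    """

    blobs: list[list[Blob]] = field(default_factory=list)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(b) for b in self.blobs], dtype=int)

    def __len__(self) -> int:
        return len(self.blobs)


@dataclass(frozen=True)
class DetectionRecord:
    """A single segmented particle accepted by the area gate."""

    frame_id: int
    blob_id: int
    centroid: tuple[float, float]          # (row, col)
    area: int
    bbox: tuple[int, int, int, int]        # (min_row, min_col, max_row, max_col), half-open

    def __post_init__(self) -> None:
        r, c = self.centroid
        min_r, min_c, max_r, max_c = self.bbox
        if not (min_r <= r < max_r and min_c <= c < max_c):
            raise ValueError("bounding box must contain the centroid")


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular region, half-open pixel intervals, clipped at use time."""

    min_row: int
    min_col: int
    max_row: int
    max_col: int

    def __post_init__(self) -> None:
        if self.max_row <= self.min_row or self.max_col <= self.min_col:
            raise ValueError("region of interest must be non-empty")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the region within a frame of the given shape."""
        if self.min_row >= shape[0] or self.min_col >= shape[1]:
            raise ValueError("region of interest lies outside the frame")
        m = np.zeros(shape, dtype=bool)
        m[self.min_row : self.max_row, self.min_col : self.max_col] = True
        return m
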