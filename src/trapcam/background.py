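"""Static-scene modelling and difference imaging.

The scene model is a weighted average of a window of frames; subtracting it
from a frame leaves only the changing content (flies).  The default weight
scheme is linear, increasing toward the most recent frame of the window so
the model tracks slow illumination drift; a uniform scheme (plain mean) is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ImageStack

__all__ = ["BackgroundImage", "build_background", "subtract", "rolling_backgrounds"]

_SCHEMES = ("linear", "uniform")


@dataclass
class BackgroundImage:
    """Weighted-average scene model.

    ``image`` is float-valued with the same shape as the frames it was
    built from; ``window_size`` and ``weight_scheme`` record how.
    """

    image: np.ndarray
    window_size: int
    weight_scheme: str


def _weights(window: int, scheme: str) -> np.ndarray:
    if scheme == "linear":
        w = np.arange(1, window + 1, dtype=float)
    elif scheme == "uniform":
        w = np.ones(window, dtype=float)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}; use one of {_SCHEMES}")
    return w / w.sum()


def build_background(
    stack: ImageStack | np.ndarray,
    window: int = 50,
    scheme: str = "linear",
    start: int = 0,
) -> BackgroundImage:
    """Weighted pixel-wise average of ``window`` frames starting at ``start``.

    Linear weights are proportional to 1..window from the earliest to the
    latest frame of the window; uniform weights reduce to the arithmetic
    mean.  Raises ``ValueError`` if fewer than ``window`` frames are
    available.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if window < 1:
        raise ValueError("window must be at least 1")
    if start < 0 or start + window > len(frames):
        raise ValueError(
            f"insufficient data: need {window} frames from index {start}, "
            f"stack has {len(frames)}"
        )
    w = _weights(window, scheme)
    chunk = frames[start : start + window].astype(float)
    # anchor the sum at the first frame: for a static scene the residual is
    # exactly zero instead of carrying float rounding residue
    image = chunk[0] + np.tensordot(w, chunk - chunk[0], axes=(0, 0))
    return BackgroundImage(image=image, window_size=window, weight_scheme=scheme)


def rolling_backgrounds(
    stack: ImageStack | np.ndarray, window: int = 50, scheme: str = "linear"
) -> list[BackgroundImage]:
    """One background per frame, each from the most recent complete window.

    Frame ``t`` gets the window ending at ``t`` once ``t >= window - 1``;
    earlier frames share the first complete window.  Intended for scenes
    whose illumination drifts too fast for a single leading-window model.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if len(frames) < window:
        raise ValueError("insufficient data for one complete window")
    out = []
    for t in range(len(frames)):
        start = max(0, t - window + 1)
        start = min(start, len(frames) - window)
        out.append(build_background(frames, window, scheme, start=start))
    return out


def subtract(frame: np.ndarray, background: BackgroundImage | np.ndarray) -> np.ndarray:
    """Pixel-wise absolute difference between a frame and the scene model.

    Absolute-valued so that objects darker or lighter than the background
    both survive; the result is float, non-negative, bounded by the valid
    intensity range of the inputs.
    """
    bg = background.image if isinstance(background, BackgroundImage) else np.asarray(background)
    frame = np.asarray(frame, dtype=float)
    if frame.shape != bg.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs background {bg.shape}")
    return np.abs(frame - bg)
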