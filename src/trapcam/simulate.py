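"""Synthetic trap-camera simulator.

Generates grayscale image sequences of a static trap surface with dark fly
blobs appearing and disappearing under a per-frame birth-death process, plus
replicate-level capture-count tables with treatment-dependent means.  Every
rendered blob is recorded in a ground-truth structure so downstream
detection can be validated without manual annotation.

The visual model: a bright, smoothly textured cardboard-like background,
optional linear illumination drift over the sequence, i.i.d. Gaussian pixel
noise, and flies rendered as filled dark ellipses whose rasterised area is
tuned to a requested pixel count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .types import Blob, GroundTruth, ImageStack

__all__ = [
    "SimConfig",
    "CaptureSimParams",
    "generate_image_sequence",
    "generate_capture_table",
    "simulate_occupancy",
    "render_blob",
]


@dataclass
class SimConfig:
    """Configuration of one simulated camera sequence.

    Parameters
    ----------
    image_height, image_width
        Frame geometry in pixels.
    n_frames
        Number of frames after the warmup period.
    frame_interval
        Seconds between frames.
    fly_area_range
        Closed interval of admissible blob pixel areas; matches the
        downstream particle-size gate by default.
    area_margin
        Blob target areas are sampled from the interior
        ``[min + margin, max - margin]`` so that the segmented area stays
        inside ``fly_area_range`` despite rasterisation and morphological
        smoothing.
    fly_contrast
        Intensity decrement of a fly relative to the local background
        (flies are darker than the pale trap surface).
    arrival_rate, departure_rate
        Per-frame probability of a new fly arriving / of each present fly
        leaving.
    drift_amplitude
        Total linear illumination change (intensity units) over the
        sequence.
    noise_sd
        Standard deviation of i.i.d. Gaussian pixel noise.
    warmup_frames
        Leading frames of the sequence during which no new fly arrives,
        mirroring acquisition that starts before flies are released; the
        default equals the background window used downstream so the
        leading-window background is fly-free.  Counted within
        ``n_frames``, not in addition to it.
    initial_areas
        Target pixel areas of flies present from frame 0 (before any
        warmup); empty for a fly-free start.
    surface
        Label attached to the stack and its ground-truth blobs.
    seed
        Seed of the generator; identical config + seed gives bit-identical
        output.
    """

    image_height: int = 480
    image_width: int = 640
    n_frames: int = 100
    frame_interval: float = 6.0
    fly_area_range: tuple[int, int] = (150, 950)
    area_margin: int = 25
    fly_contrast: float = 120.0
    arrival_rate: float = 0.05
    departure_rate: float = 0.05
    drift_amplitude: float = 0.0
    noise_sd: float = 0.0
    warmup_frames: int = 50
    initial_areas: tuple[int, ...] = ()
    background_level: float = 200.0
    texture_amplitude: float = 12.0
    texture_scale: float = 25.0
    surface: str = "surface"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        lo, hi = self.fly_area_range
        if lo <= 0 or hi <= lo:
            raise ValueError("fly_area_range must be positive with min < max")
        for rate in (self.arrival_rate, self.departure_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.warmup_frames < 0:
            raise ValueError("warmup_frames must be non-negative")


def render_blob(
    center: tuple[float, float],
    target_area: int,
    aspect: float,
    rotation: float,
    shape: tuple[int, int],
    tol: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a filled ellipse whose pixel count is ``target_area`` +/- tol.

    The ellipse has the requested aspect ratio (major/minor axis) and
    rotation; a scale factor on both semi-axes is found by bisection so the
    rasterised pixel count hits the target.  Pixel count is non-decreasing
    in the scale, so bisection converges; the best scale seen is kept if the
    tolerance window is skipped over by a discrete jump.
    """
    # semi-axes giving continuous area == target at scale 1
    a = math.sqrt(target_area * aspect / math.pi)
    b = a / aspect

    def raster(scale: float) -> tuple[np.ndarray, np.ndarray]:
        return draw_ellipse(
            center[0], center[1], a * scale, b * scale,
            shape=shape, rotation=rotation,
        )

    lo, hi = 0.7, 1.4
    best = raster(1.0)
    best_err = abs(len(best[0]) - target_area)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        rr, cc = raster(mid)
        err = len(rr) - target_area
        if abs(err) < best_err:
            best, best_err = (rr, cc), abs(err)
        if best_err <= tol:
            break
        if err < 0:
            lo = mid
        else:
            hi = mid
    return best


def _textured_background(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed smooth random field around the base level (float image)."""
    noise = rng.standard_normal((config.image_height, config.image_width))
    smooth = ndimage.gaussian_filter(noise, sigma=config.texture_scale)
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth = smooth / peak * config.texture_amplitude
    return config.background_level + smooth


def simulate_occupancy(
    config: SimConfig, rng: np.random.Generator
) -> list[list[Blob]]:
    """Run the per-frame birth-death fly dynamics without rendering frames.

    Each frame, every present fly departs independently with probability
    ``departure_rate`` and at most one new fly arrives with probability
    ``arrival_rate``.  Arrivals are placed uniformly, rejecting positions
    whose footprint leaves the frame or comes within a small separation of
    an existing fly (so blobs never touch or merge).  Returns the blob list
    for each of the ``n_frames`` post-warmup frames.
    """
    lo, hi = config.fly_area_range
    margin = min(config.area_margin, (hi - lo) // 2)
    area_lo, area_hi = lo + margin, hi - margin
    shape = (config.image_height, config.image_width)

    live: list[Blob] = []
    frames: list[list[Blob]] = []
    next_id = 0

    def try_arrival(target: int | None = None) -> Blob | None:
        nonlocal next_id
        if target is None:
            target = int(rng.integers(area_lo, area_hi + 1))
        aspect = float(rng.uniform(1.0, 2.5))
        rotation = float(rng.uniform(0.0, math.pi))
        # widest half-extent of the ellipse at the largest search scale
        reach = math.sqrt(target * aspect / math.pi) * 1.4 + 2
        if 2 * reach >= min(shape):
            return None
        for _ in range(50):
            r = float(rng.uniform(reach, shape[0] - reach))
            c = float(rng.uniform(reach, shape[1] - reach))
            ok = all(
                math.hypot(r - o.centroid[0], c - o.centroid[1])
                > reach + math.sqrt(area_hi * 2.5 / math.pi) * 1.4 + 4
                for o in live
            )
            if ok:
                rr, cc = render_blob((r, c), target, aspect, rotation, shape)
                blob = Blob(
                    next_id, (r, c), len(rr), config.surface, footprint=(rr, cc)
                )
                next_id += 1
                return blob
        return None

    for target in config.initial_areas:
        blob = try_arrival(target)
        if blob is not None:
            live.append(blob)

    for t in range(config.n_frames):
        if t > 0:
            live = [b for b in live if rng.random() >= config.departure_rate]
            if t >= config.warmup_frames and rng.random() < config.arrival_rate:
                blob = try_arrival()
                if blob is not None:
                    live.append(blob)
        frames.append(list(live))
    return frames


def generate_image_sequence(config: SimConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a full sequence and its ground truth.

    Frames are the textured static background plus linear-in-time
    illumination drift and Gaussian noise, with each present fly darkening
    its elliptical footprint by ``fly_contrast``.  The returned stack
    includes the warmup frames (so a leading-window background model can be
    built from fly-free frames); ground truth covers every frame.
    """
    rng = np.random.default_rng(config.seed)
    background = _textured_background(config, rng)
    occupancy = simulate_occupancy(config, rng)
    total = len(occupancy)

    frames = np.empty((total, config.image_height, config.image_width), dtype=np.uint8)
    for t, blobs in enumerate(occupancy):
        drift = (
            config.drift_amplitude * t / (total - 1) if total > 1 else 0.0
        )
        img = background + drift
        if blobs:
            img = img.copy()
            for blob in blobs:
                rr, cc = blob.footprint
                img[rr, cc] -= config.fly_contrast
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    timestamps = np.arange(total) * config.frame_interval
    stack = ImageStack(frames, timestamps, surface=config.surface)
    truth = GroundTruth(blobs=occupancy)
    return stack, truth


@dataclass
class CaptureSimParams:
    """Parameters of the replicate-level capture-count simulation.

    ``treatment_means`` maps each treatment label to ``(mean_trapped,
    mean_in_tub)``.  Counts are negative binomial with the given means and a
    common dispersion (gamma shape) parameter; totals are trapped + in-tub
    by construction.  Defaults emulate a seven-replicate field-cage
    experiment with lure-only, lure+insecticide, and unbaited arms.
    """

    treatment_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "tml": (324.0, 35.0),
            "tml_ddvp": (356.0, 92.0),
            "control": (51.0, 2.0),
        }
    )
    dispersion: float = 5.0
    n_replicates: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for label, (mt, mi) in self.treatment_means.items():
            if mt < 0 or mi < 0:
                raise ValueError(f"means for {label!r} must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def _negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """NB(mean, k) via the gamma-Poisson mixture; Poisson in the k→∞ limit."""
    if mean == 0:
        return np.zeros(size, dtype=int)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def generate_capture_table(params: CaptureSimParams) -> pd.DataFrame:
    """Simulate a wide capture table: one row per replicate.

    Columns are ``replicate`` plus ``{treatment}_trapped``,
    ``{treatment}_in_tub`` and ``{treatment}_total`` for each treatment.
    """
    rng = np.random.default_rng(params.seed)
    out: dict[str, np.ndarray] = {
        "replicate": np.arange(1, params.n_replicates + 1)
    }
    for label, (mean_trapped, mean_in_tub) in params.treatment_means.items():
        trapped = _negative_binomial(
            rng, mean_trapped, params.dispersion, params.n_replicates
        )
        in_tub = _negative_binomial(
            rng, mean_in_tub, params.dispersion, params.n_replicates
        )
        out[f"{label}_trapped"] = trapped
        out[f"{label}_in_tub"] = in_tub
        out[f"{label}_total"] = trapped + in_tub
    return pd.DataFrame(out)
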