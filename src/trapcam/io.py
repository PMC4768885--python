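"""File formats: image stacks (PNG series or multi-page TIFF), CSV tables,
YAML pipeline configuration, and the bundled capture-count dataset.

CSV convention: comma-separated, UTF-8, header row, numerics unquoted,
dates ISO-8601.
"""

from __future__ import annotations

import glob as _glob
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import ImageStack

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "load_capture_counts",
    "read_capture_table",
    "PipelineConfig",
]

# capture columns per treatment arm in the bundled dataset
TREATMENTS = ("tml", "tml_ddvp", "control")


def read_image_stack(
    path_spec: str | Path | list[str | Path],
    frame_interval: float = 6.0,
    surface: str | None = None,
) -> ImageStack:
    """Load frames from a multi-page TIFF, a directory, a glob, or a list.

    Files are ordered lexicographically (zero-padded numbering sorts
    correctly); multi-page TIFFs keep page order.  Timestamps follow a
    fixed cadence of ``frame_interval`` seconds.  Mixed frame dimensions or
    an unreadable file raise a ``ValueError`` naming the offender.
    """
    if isinstance(path_spec, (list, tuple)):
        files = [Path(p) for p in path_spec]
    else:
        p = Path(path_spec)
        if p.is_dir():
            files = sorted(q for q in p.iterdir() if q.suffix.lower() in (".png", ".tif", ".tiff"))
        elif p.is_file():
            files = [p]
        else:
            files = [Path(q) for q in sorted(_glob.glob(str(p)))]
    if not files:
        raise ValueError(f"no image files match {path_spec!r}")

    frames: list[np.ndarray] = []
    for f in files:
        try:
            if f.suffix.lower() in (".tif", ".tiff"):
                pages = tifffile.imread(f)
                if pages.ndim == 2:
                    pages = pages[None]
                frames.extend(pages)
            else:
                frames.append(iio.imread(f))
        except Exception as exc:  # noqa: BLE001 - re-raise with the file name
            raise ValueError(f"cannot read image file {f}") from exc
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame dimensions: {sorted(shapes)}")
    stack = np.stack(frames).astype(np.uint8)
    timestamps = np.arange(len(stack)) * frame_interval
    return ImageStack(stack, timestamps, surface=surface)


def write_image_stack(
    stack: ImageStack, path: str | Path, fmt: str = "tiff"
) -> list[Path]:
    """Write frames as one multi-page TIFF or zero-padded numbered PNGs.

    ``fmt='tiff'`` writes ``path`` as a single file; ``fmt='png'`` treats
    ``path`` as a directory and writes ``frame_000000.png`` etc.  Returns
    the written paths.
    """
    path = Path(path)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.frames)
        return [path]
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        out = []
        for i, frame in enumerate(stack.frames):
            f = path / f"frame_{i:06d}.png"
            iio.imwrite(f, frame)
            out.append(f)
        return out
    raise ValueError(f"unknown format {fmt!r}; use 'tiff' or 'png'")


def load_capture_counts() -> pd.DataFrame:
    """The bundled seven-replicate Jackson-trap capture-count table.

    One row per release date; ``released`` flies per replicate and, for
    each treatment arm (trimedlure only, trimedlure + DDVP strip, unbaited
    control), the number caught on the sticky panel (``*_trapped``), found
    dead in the tub under the trap (``*_in_tub``) and their sum
    (``*_total``).
    """
    ref = resources.files("trapcam") / "data" / "jackson_capture_counts.csv"
    with resources.as_file(ref) as f:
        return read_capture_table(f)


def read_capture_table(path: str | Path) -> pd.DataFrame:
    """Read a capture table CSV and check the total-count identity."""
    df = pd.read_csv(path)
    for t in TREATMENTS:
        cols = {f"{t}_trapped", f"{t}_in_tub", f"{t}_total"}
        if cols <= set(df.columns):
            bad = df[f"{t}_trapped"] + df[f"{t}_in_tub"] != df[f"{t}_total"]
            if bad.any():
                raise ValueError(f"total != trapped + in_tub for {t!r}")
    return df


@dataclass
class PipelineConfig:
    """Resolved settings of an end-to-end run; serialisable to YAML."""

    output_dir: str = "trapcam_out"
    stack_path: str | None = None
    window: int = 50
    scheme: str = "linear"
    threshold_method: str = "otsu"
    fixed_value: int | None = None
    radius: int = 1
    min_area: int = 150
    max_area: int = 950
    alpha: float = 0.05
    seed: int = 0
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as f:
            yaml.safe_dump(self.__dict__, f, sort_keys=False)
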