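"""Image-stack container and TIFF I/O shared by all analysis modules."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("wrinklekit")


@dataclass
class ImageStack:
    """Time-ordered grayscale frames with physical metadata.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), 8- or 16-bit unsigned integer (float is
        tolerated for intermediate computation).
    pixel_size_um
        Edge length of one pixel in micrometres. ``None`` means unknown;
        length outputs then fall back to pixels with a warning.
    frame_interval_s
        Time between consecutive frames in seconds.
    """

    frames: np.ndarray
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (T, H, W), got shape {self.frames.shape}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def fps(self) -> float:
        if self.frame_interval_s is None:
            raise ValueError("frame_interval_s is not set; pass --frame-interval or config")
        return 1.0 / self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        if self.frame_interval_s is None:
            raise ValueError("frame_interval_s is not set; pass --frame-interval or config")
        return np.arange(self.n_frames) * self.frame_interval_s


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Explicit metadata arguments win over TIFF resolution tags.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D grayscale frames, got shape {frames.shape}")
    if pixel_size_um is None and tag_px is not None:
        pixel_size_um = tag_px
        logger.info("pixel size %.4g um taken from TIFF resolution tags of %s", tag_px, path.name)
    return ImageStack(frames, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    per_unit = num / den  # pixels per resolution unit
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", None) and unit.value.real, None)
    if unit_um is None:
        return None
    return unit_um / per_unit


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF, preserving bit depth."""
    path = Path(path)
    kwargs = {"photometric": "minisblack"}
    if stack.pixel_size_um is not None:
        per_cm = 10000.0 / stack.pixel_size_um
        kwargs["resolution"] = (per_cm, per_cm)
        kwargs["resolutionunit"] = "CENTIMETER"
    tifffile.imwrite(path, stack.frames, **kwargs)


def write_config_echo(out_dir: str | Path, config: dict) -> Path:
    """Write a provenance record (parameters, seed, versions) beside outputs."""
    import wrinklekit

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    echo = dict(config)
    echo["wrinklekit_version"] = wrinklekit.__version__
    echo["numpy_version"] = np.__version__
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(echo, indent=2, default=str) + "\n")
    return path


def check_writable(out_dir: str | Path) -> Path:
    """Pre-flight check that ``out_dir`` exists (or can be created) and is writable."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    return out_dir
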