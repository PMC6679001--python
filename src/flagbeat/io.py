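"""Movie container and file I/O (multi-page TIFF + YAML sidecar metadata)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import tifffile
import yaml

__all__ = ["Movie", "read_movie", "write_movie"]


@dataclass
class Movie:
    """A grayscale movie stack with acquisition metadata.

    ``stack`` has shape (n_frames, height, width); ``frame_rate_hz`` and
    ``pixel_size_um`` are required for any kinematic interpretation.
    """

    stack: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ValueError(f"movie stack must be 3-D (frames, y, x), got {self.stack.shape}")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_hz and pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a 16-bit multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.stack, dtype=np.uint16))
    meta = dict(movie.meta)
    meta.update(frame_rate_hz=float(movie.frame_rate_hz), pixel_size_um=float(movie.pixel_size_um))
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_movie(
    path: str | Path,
    frame_rate_hz: Optional[float] = None,
    pixel_size_um: Optional[float] = None,
) -> Movie:
    """Read a multi-page TIFF; metadata from the sidecar unless overridden."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta: dict[str, Any] = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    fr = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if fr is None or px is None:
        raise ValueError(
            f"{path}: frame_rate_hz and pixel_size_um must come from the sidecar "
            "or be passed explicitly"
        )
    return Movie(stack=stack, frame_rate_hz=float(fr), pixel_size_um=float(px), meta=meta)
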