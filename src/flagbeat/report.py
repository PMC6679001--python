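"""One-beat-cycle waveform projection.

A visual summary of the flagellar waveform: the traces of exactly one beat
cycle — ``n = round(frame_rate / beat_frequency)`` consecutive frames — are
overlaid, each frame drawn in a distinct color from a perceptual colormap,
with a 50 µm scale bar.  Faster beats therefore use fewer frames, so every
projection spans one cycle regardless of condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .trace import FlagellarTrace

__all__ = ["BeatCycleProjection", "n_overlay_frames", "beat_cycle_projection"]


def n_overlay_frames(frame_rate_hz: float, beat_freq_hz: float) -> int:
    """Number of frames spanning one beat cycle: round(frame rate / beat frequency)."""
    if beat_freq_hz <= 0:
        raise ValueError("beat frequency must be positive")
    if beat_freq_hz >= frame_rate_hz / 2:
        raise ValueError("beat frequency must be below the Nyquist frequency")
    n = int(round(frame_rate_hz / beat_freq_hz))
    if n < 2:
        raise ValueError("fewer than 2 frames per beat cycle")
    return n


@dataclass
class BeatCycleProjection:
    n_overlay_frames: int
    frame_indices: np.ndarray
    figure: plt.Figure

    def save(self, path: str | Path, dpi: int = 150) -> Path:
        path = Path(path)
        self.figure.savefig(path, dpi=dpi, bbox_inches="tight")
        plt.close(self.figure)
        return path


def beat_cycle_projection(
    trace: FlagellarTrace,
    sperm_freq_hz: float,
    frame_rate_hz: float | None = None,
    start_frame: int = 0,
    scale_bar_um: float = 50.0,
    cmap: str = "viridis",
) -> BeatCycleProjection:
    """Overlay the traces of one beat cycle, color-coded by frame.

    Uses the first ``n = round(frame_rate / sperm_freq)`` traced frames from
    ``start_frame``; each source frame is used exactly once.
    """
    fr = frame_rate_hz if frame_rate_hz is not None else trace.frame_rate_hz
    n = n_overlay_frames(fr, sperm_freq_hz)
    if start_frame + n > trace.n_frames:
        raise ValueError(
            f"projection needs {n} frames from frame {start_frame} "
            f"but the movie has only {trace.n_frames}"
        )
    idx = np.arange(start_frame, start_frame + n)
    colors = plt.get_cmap(cmap)(np.linspace(0, 1, n))

    fig, ax = plt.subplots(figsize=(5, 5))
    for c, i in zip(colors, idx):
        f = trace.frames[i]
        if not f.ok:
            continue
        ax.plot(f.x_um, f.y_um, color=c, lw=1.5)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y down
    ax.axis("off")
    x0, x1 = ax.get_xlim()
    y0 = max(ax.get_ylim())
    ax.plot([x0 + 2, x0 + 2 + scale_bar_um], [y0 - 2, y0 - 2], color="k", lw=3)
    ax.text(x0 + 2, y0 - 4, f"{scale_bar_um:.0f} µm", fontsize=8)
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, n / fr * 1e3))
    fig.colorbar(sm, ax=ax, shrink=0.6, label="time within beat cycle (ms)")
    return BeatCycleProjection(n_overlay_frames=n, frame_indices=idx, figure=fig)
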