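"""Per-position beat-frequency estimation from the curvature-angle field.

At each flagellar position the curvature-angle time course is converted to a
one-sided power spectrum by FFT (rectangular window, mean subtracted, no
zero padding, window length 400 frames).  The frequencies of the highest
(f1) and second-highest (f2) spectral peaks are merged into the local beat
frequency ``f_local = (f1 + f2) / 2``; the sperm-level beat frequency is the
mean of ``f_local`` over all flagellar positions between 15 and 60 µm from
the head.

f2 is the second-highest *local maximum* of the spectrum (not merely the
second-largest bin, which would usually be a leakage shoulder of f1) and
must carry at least ``min_rel_power`` of the dominant peak's power; when no
such peak exists — e.g. a clean single-frequency beat — f2 falls back to f1
so the merge is a no-op.  Optionally, peaks at (half-)integer multiples of
f1 can be excluded as harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import CurvatureField

__all__ = [
    "SpectralConfig",
    "FrequencyProfile",
    "power_spectrum",
    "local_frequency",
    "frequency_profile",
    "sperm_frequency",
]

#: arc-length window (µm) over which local frequencies are averaged into the
#: sperm-level beat frequency
SPERM_FREQ_BAND_UM = (15.0, 60.0)


@dataclass(frozen=True)
class SpectralConfig:
    """FFT windowing and peak-picking parameters."""

    window_frames: int = 400
    #: maximum fraction of masked samples mean-imputed per window
    max_masked_frac: float = 0.05
    #: minimum power of an f2 candidate, relative to the f1 peak
    min_rel_power: float = 0.05
    exclude_harmonics: bool = False
    #: allow windows shorter than ``window_frames`` (explicit opt-in)
    allow_short_window: bool = False
    band_um: tuple[float, float] = SPERM_FREQ_BAND_UM


def power_spectrum(theta_series: np.ndarray, frame_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a mean-subtracted series.

    Rectangular window, no padding: the frequency resolution is
    ``frame_rate_hz / len(series)`` (0.5 Hz at 200 fps / 400 frames).
    """
    x = np.asarray(theta_series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("theta series must be 1-D with at least 2 samples")
    x = x - x.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / frame_rate_hz)
    return freqs, power


def local_frequency(
    freqs: np.ndarray, power: np.ndarray, config: SpectralConfig = SpectralConfig()
) -> tuple[float, float, float]:
    """(f1, f2, f_local) from a one-sided power spectrum.

    f1 is the frequency of maximum power over bins > 0 Hz; f2 the
    second-highest local maximum passing the relative-power floor, falling
    back to f1 when absent; ``f_local = (f1 + f2) / 2``.
    Raises on an all-zero spectrum (the caller masks that position).
    """
    power = np.asarray(power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    pos = freqs > 0
    if not pos.any() or not (power[pos] > 0).any():
        raise ValueError("degenerate (all-zero) spectrum")
    p = power.copy()
    p[~pos] = 0.0
    i1 = int(np.argmax(p))
    f1 = float(freqs[i1])
    peak = p[i1]

    # local maxima (plateau-tolerant) among positive-frequency bins
    interior = np.arange(1, len(p) - 1)
    is_max = (p[interior] >= p[interior - 1]) & (p[interior] >= p[interior + 1])
    cand = interior[is_max]
    if len(p) >= 2 and p[-1] > p[-2]:
        cand = np.append(cand, len(p) - 1)
    cand = cand[(cand != i1) & pos[cand] & (p[cand] >= config.min_rel_power * peak)]
    # drop the leakage shoulders directly adjacent to f1
    cand = cand[np.abs(cand - i1) > 1]
    if config.exclude_harmonics and len(cand):
        ratio = freqs[cand] / f1
        near_mult = np.minimum(np.abs(ratio - np.round(ratio)), np.abs(1 / ratio - np.round(1 / ratio)))
        cand = cand[near_mult > 0.05]
    if len(cand):
        i2 = cand[np.argmax(p[cand])]
        f2 = float(freqs[i2])
    else:
        f2 = f1
    return f1, f2, (f1 + f2) / 2.0


@dataclass
class FrequencyProfile:
    """Local beat frequencies per flagellar position plus the sperm summary."""

    s_um: np.ndarray
    f1_hz: np.ndarray
    f2_hz: np.ndarray
    f_local_hz: np.ndarray
    valid: np.ndarray
    window_start: int
    window_frames: int
    sperm_freq_hz: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_um": self.s_um,
            "f1_hz": self.f1_hz,
            "f2_hz": self.f2_hz,
            "f_local_hz": self.f_local_hz,
            "valid": self.valid,
        })


def frequency_profile(field: CurvatureField, config: SpectralConfig = SpectralConfig()) -> FrequencyProfile:
    """Per-position frequency analysis of a curvature field.

    Uses non-overlapping windows of ``window_frames`` starting at frame 0
    (power spectra averaged when the movie is longer than one window).
    Positions with more than ``max_masked_frac`` masked samples in any
    window are skipped; sparser gaps are mean-imputed.
    """
    n_s, n_t = field.theta_rad.shape
    win = config.window_frames
    if n_t < win:
        if not config.allow_short_window:
            raise ValueError(
                f"movie has {n_t} frames but the FFT window is {win}; "
                "reduce window_frames or pass allow_short_window=True"
            )
        win = n_t
    n_win = n_t // win

    f1 = np.full(n_s, np.nan)
    f2 = np.full(n_s, np.nan)
    fl = np.full(n_s, np.nan)
    valid = np.zeros(n_s, dtype=bool)
    for i in range(n_s):
        spectra = []
        for w in range(n_win):
            sl = slice(w * win, (w + 1) * win)
            th = field.theta_rad[i, sl].copy()
            mask = field.valid[i, sl]
            if (~mask).mean() > config.max_masked_frac:
                spectra = []
                break
            if (~mask).any():
                th[~mask] = th[mask].mean()
            freqs, power = power_spectrum(th, field.frame_rate_hz)
            spectra.append(power)
        if not spectra:
            continue
        power = np.mean(spectra, axis=0)
        try:
            f1[i], f2[i], fl[i] = local_frequency(freqs, power, config)
        except ValueError:
            continue
        valid[i] = True

    sperm = sperm_frequency(field.s_um, fl, valid, config.band_um)
    return FrequencyProfile(
        s_um=field.s_um, f1_hz=f1, f2_hz=f2, f_local_hz=fl, valid=valid,
        window_start=0, window_frames=win, sperm_freq_hz=sperm,
    )


def sperm_frequency(
    s_um: np.ndarray,
    f_local_hz: np.ndarray,
    valid: np.ndarray | None = None,
    band_um: tuple[float, float] = SPERM_FREQ_BAND_UM,
) -> float:
    """Mean local beat frequency over the closed arc-length band (15-60 µm)."""
    s = np.asarray(s_um, dtype=float)
    f = np.asarray(f_local_hz, dtype=float)
    ok = np.isfinite(f) if valid is None else (np.asarray(valid, bool) & np.isfinite(f))
    inband = ok & (s >= band_um[0]) & (s <= band_um[1])
    if not inband.any():
        raise ValueError(f"no valid positions in the {band_um} µm band")
    return float(f[inband].mean())
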