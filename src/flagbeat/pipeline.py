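"""Pipeline orchestration: movies in, CSV tables / projections / manifest out.

A run processes one or more conditions, each holding one or more single-sperm
movies.  Per sperm: preprocess + trace -> curvature-angle field -> frequency
profile + asymmetry profile -> beat-cycle projection; per condition pair:
difference curves and pointwise ANOVA.  Individual sperm failures are logged
and skipped; the run fails only if every sperm of a condition fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import AsymmetryProfile, asymmetry_profile, difference_curve, pointwise_anova
from .io import read_movie
from .kinematics import KinematicsConfig, build_field, write_field_csv
from .report import beat_cycle_projection
from .spectral import SpectralConfig, frequency_profile
from .trace import TraceSettings, trace_movie, write_trace_csv

logger = logging.getLogger("flagbeat")

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    conditions: dict[str, list[str]]  # condition label -> movie paths
    output_dir: str = "flagbeat_out"
    pixel_size_um: Optional[float] = None  # None: use each movie's sidecar
    frame_rate_hz: Optional[float] = None
    trace: TraceSettings = field(default_factory=TraceSettings)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    paired: bool = True
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("trace", TraceSettings), ("kinematics", KinematicsConfig),
                         ("spectral", SpectralConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "spectral" and "band_um" in sub and sub["band_um"] is not None:
                    sub["band_um"] = tuple(sub["band_um"])
                d[key] = typ(**sub)
        return cls(**d)

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("config lists no conditions")
        for cond, paths in self.conditions.items():
            if not paths:
                raise ValueError(f"condition {cond!r} lists no movies")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"condition {cond!r}: missing input {p}")


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _settings_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "flagbeat_version": __version__,
        "settings_hash": _settings_hash(config),
        "seed": config.seed,
        "conditions": {},
    }
    profiles: dict[str, list[AsymmetryProfile]] = {}
    summary_rows = []

    for cond, paths in config.conditions.items():
        t0 = time.time()
        cond_dir = out / cond
        cond_dir.mkdir(exist_ok=True)
        profiles[cond] = []
        entries = []
        for path in paths:
            sperm_id = Path(path).stem
            try:
                movie = read_movie(path, config.frame_rate_hz, config.pixel_size_um)
                trace = trace_movie(movie, config.trace)
                if trace.n_ok == 0:
                    raise RuntimeError("all frames failed to trace")
                write_trace_csv(trace, cond_dir / f"{sperm_id}_trace.csv")
                field_ = build_field(trace, config.kinematics)
                write_field_csv(field_, cond_dir / f"{sperm_id}_curvature.csv", config.kinematics)
                prof = frequency_profile(field_, config.spectral)
                prof.to_frame().to_csv(cond_dir / f"{sperm_id}_frequency.csv", index=False)
                asym = asymmetry_profile(field_, sperm_id=sperm_id, condition=cond)
                asym.to_frame().to_csv(cond_dir / f"{sperm_id}_asymmetry.csv", index=False)
                proj = beat_cycle_projection(trace, prof.sperm_freq_hz)
                proj.save(cond_dir / f"{sperm_id}_beat_cycle.png")
                profiles[cond].append(asym)
                summary_rows.append({
                    "sperm_id": sperm_id, "condition": cond,
                    "sperm_freq_hz": prof.sperm_freq_hz,
                    "n_overlay_frames": proj.n_overlay_frames,
                    "n_frames_traced": trace.n_ok,
                })
                entries.append({"movie": str(path), "sperm_id": sperm_id, "status": "ok"})
            except Exception as exc:  # per-sperm failures are survivable
                logger.warning("condition %s, movie %s failed: %s", cond, path, exc)
                entries.append({"movie": str(path), "sperm_id": sperm_id,
                                "status": "failed", "error": str(exc)})
        if not profiles[cond]:
            raise RuntimeError(f"condition {cond!r}: every sperm failed")
        manifest["conditions"][cond] = {
            "n_ok": len(profiles[cond]), "n_failed": len(paths) - len(profiles[cond]),
            "movies": entries, "elapsed_s": round(time.time() - t0, 2),
        }

    pd.DataFrame(summary_rows).to_csv(out / "sperm_summary.csv", index=False)

    names = sorted(profiles)
    if len(names) >= 2:
        a, b = names[0], names[1]
        comp = difference_curve(profiles[a], profiles[b], paired=config.paired,
                                alpha=config.alpha)
        try:
            anova = pointwise_anova({a: profiles[a], b: profiles[b]}, alpha=config.alpha)
            comp.p = anova.p
            comp.significant = anova.significant
            comp.regions = anova.regions
        except ValueError as exc:
            logger.warning("pointwise ANOVA skipped: %s", exc)
        comp.to_frame().to_csv(out / f"comparison_{a}_vs_{b}.csv", index=False)
        comp.regions_frame().to_csv(out / f"regions_{a}_vs_{b}.csv", index=False)
        manifest["comparison"] = {"A": a, "B": b,
                                  "n_significant_positions": int(np.sum(comp.significant))}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
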