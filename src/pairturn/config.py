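"""Arena geometry and run configuration.

All lengths are metres, all times seconds, frames are 0-based integers
sampled at ``fs`` Hz.  The default arena is an annular tank with a bottom
inner radius of 12.5 cm and outer radius of 17.5 cm holding rummy-nose
tetra of 33.3 mm mean body length, filmed at 50 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["ArenaConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of the annular tank and the animals swimming in it.

    Parameters
    ----------
    inner_radius, outer_radius : float
        Radii of the inner and outer walls (m).
    body_length : float
        Mean body length BL of the fish (m); all distances expressed in
        body lengths are normalised by this value.
    fs : float
        Sampling frequency of the trajectories (Hz).
    """

    inner_radius: float = 0.125
    outer_radius: float = 0.175
    body_length: float = 0.0333
    fs: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ConfigError(
                f"need 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius} / {self.outer_radius}"
            )
        if self.body_length <= 0:
            raise ConfigError("body_length must be positive")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")

    @property
    def mid_radius(self) -> float:
        """Radius of the annulus centreline (m)."""
        return 0.5 * (self.inner_radius + self.outer_radius)

    @property
    def half_width(self) -> float:
        """Half the annulus width (m)."""
        return 0.5 * (self.outer_radius - self.inner_radius)


@dataclass
class PipelineConfig:
    """Bundled settings for a full extraction + clustering run.

    Sections mirror the pipeline stages; every value can be overridden
    from a YAML file via :func:`load_config`.
    """

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    # preprocessing
    smooth_passes: int = 1
    # U-turn extraction
    p: int = 20                 # trim length of the detector (frames)
    q: int = 150                # half-width of the output turn window (frames)
    max_lag_s: float = 2.0      # maximum per-fish Epoint separation for pairing
    tau_s: float = 0.4          # nominal single-fish reversal duration (s)
    fix_frac: float = 0.9       # leader-constancy fraction for "dominated"
    ald_perp_max: float = 0.2   # ald threshold for "perpendicular to wall"
    # clustering
    k: int = 5
    w: int = 20
    lam: float = 0.11
    beta: float | None = None   # None -> 400 * n_channels
    seed: int = 0
    # interpretation
    edge_eps: float = 1e-3
    # column mapping for external trajectory exports
    columns: dict = field(default_factory=lambda: {
        "frame": "frame", "fish_id": "fish_id", "x": "x_m", "y": "y_m"})


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML configuration file.

    The file may contain any subset of the sections ``arena``,
    ``extraction``, ``ticc``, ``interpretation`` and ``columns``;
    missing entries keep their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    if "arena" in raw:
        cfg.arena = ArenaConfig(**{**asdict(cfg.arena), **raw["arena"]})
    for section in ("extraction", "ticc", "interpretation", "preprocessing"):
        for key, val in (raw.get(section) or {}).items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config key {section}.{key}")
            setattr(cfg, key, val)
    if "columns" in raw:
        cfg.columns.update(raw["columns"])
    return cfg
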