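"""Pipeline configuration with the published default parameter values."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = ["RegWeights", "PipelineConfig"]


@dataclass
class RegWeights:
    """Weights and scales of the hybrid registration objective.

    ``alpha_lncc`` is always derived as
    ``(1 - alpha_lmks) * (1 - alpha_be - alpha_le)`` and cannot be set
    directly.
    """

    alpha_be: float = 0.1
    alpha_le: float = 0.3
    alpha_lmks: float = 0.001
    lncc_kernel_sd_mm: float = 6.0
    grid_spacing_mm: float = 3.0
    pyramid_levels: int = 3

    def __post_init__(self) -> None:
        for name in ("alpha_be", "alpha_le", "alpha_lmks", "lncc_kernel_sd_mm", "grid_spacing_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")

    @property
    def alpha_lncc(self) -> float:
        return (1.0 - self.alpha_lmks) * (1.0 - self.alpha_be - self.alpha_le)


@dataclass
class PipelineConfig:
    """All tunable parameters of the atlas pipeline, with defaults.

    The temporal kernel uses ``sigma_days`` with the inclusion window
    ``window_days = 3 * sigma_days`` by default, so the window and the
    kernel truncation coincide.
    """

    sigma_days: float = 3.0
    window_days: int = 9
    min_group_size: int = 3
    week_range: Tuple[int, int] = (21, 34)
    target_mean: float = 2000.0
    target_sd: float = 500.0
    refinement_iterations: int = 2
    reg: RegWeights = field(default_factory=RegWeights)
    agreement_radius_mm: Optional[float] = None  # default: sqrt(3) * voxel size
    seed: int = 0
    output_dir: str = "atlas_out"

    def __post_init__(self) -> None:
        if isinstance(self.reg, dict):
            self.reg = RegWeights(**self.reg)
        self.week_range = tuple(int(w) for w in self.week_range)  # type: ignore[assignment]
        if self.sigma_days <= 0 or self.window_days <= 0 or self.min_group_size <= 0:
            raise ValueError("sigma_days, window_days and min_group_size must be positive")
        if self.week_range[0] > self.week_range[1]:
            raise ValueError("week_range must be (low, high)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["week_range"] = list(self.week_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)
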