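"""Runtime configuration for scoring and statistics.

All tunables live in two small dataclasses so that every numerical
convention (Gaussian amplitude, radii, SD divisor, outlier width) is
explicit and serialisable to/from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the Gaussian shape/color model and the optimizer.

    amplitude
        Height ``p`` of each atom-centred Gaussian (dimensionless).  The
        Gaussian width is calibrated from it so that an isolated atom's
        density integral equals its hard-sphere volume 4/3*pi*R^3.
    atom_radius
        Uniform heavy-atom radius in Angstrom (carbon-radius convention).
    color_radius
        Radius of the fictitious feature ("color") Gaussians, Angstrom.
    skip_exponent
        Pair terms with exponent arguments below ``-skip_exponent`` are
        dropped; at 30 the skipped mass is < 1e-13 of a typical term.
    max_iterations / ftol / gtol
        L-BFGS termination controls for the 6-DOF pose optimization.
    """

    amplitude: float = 2.7
    atom_radius: float = 1.70
    color_radius: float = 1.0
    skip_exponent: float = 30.0
    max_iterations: int = 200
    ftol: float = 1e-10
    gtol: float = 1e-8


@dataclass(frozen=True)
class StatsConfig:
    """Conventions of the per-assay statistics.

    sd_mode
        "population" (divisor n, default) or "sample" (divisor n-1).
    diff_sd_mode
        SD attached to the NN-NI mean difference: "independent" is
        sqrt(sd_nn^2 + sd_ni^2), the exact SD of the full cross-difference
        population; "pooled" is sqrt(sd_nn^2/n_nn + sd_ni^2/n_ni).
    """

    min_nn: int = 6
    min_ni: int = 6
    outlier_k: float = 1.0
    sd_mode: str = "population"
    diff_sd_mode: str = "independent"

    def __post_init__(self) -> None:
        if self.sd_mode not in ("population", "sample"):
            raise ValueError(f"unknown sd_mode: {self.sd_mode!r}")
        if self.diff_sd_mode not in ("independent", "pooled"):
            raise ValueError(f"unknown diff_sd_mode: {self.diff_sd_mode!r}")


@dataclass(frozen=True)
class Config:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            scoring=ScoringConfig(**raw.get("scoring", {})),
            stats=StatsConfig(**raw.get("stats", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


DEFAULT_CONFIG = Config()
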