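"""Experiment configuration and named presets.

An :class:`ExperimentConfig` bundles every simulator, damage, estimator
and precision-analysis parameter of a coverage-titration experiment and
validates them up front, before any stage runs.  Presets mirror three
archetypal ancient samples: a typically preserved ~24x genome, an
exceptionally preserved low-deamination ~38x genome, and a ~19x genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig", "PRESETS", "load_config"]

#: Canonical down-sampling grid (fold coverages).
FULL_GRID = (1, 3, 5, 10, 15, 20, 25, 30)


def _grid_below(full_cov: float) -> tuple[int, ...]:
    return tuple(c for c in FULL_GRID if c < full_cov)


@dataclass
class ExperimentConfig:
    """All knobs of one seeded coverage-titration experiment."""

    # Reference / methylome
    ref_length: int = 500_000
    n_cpg: int = 5_000
    ref_name: str = "chrS"
    p_high: float = 0.75
    beta_high: tuple[float, float] = (8.0, 2.0)
    beta_low: tuple[float, float] = (1.0, 9.0)
    block_len: int = 50
    # Damage / library
    delta_max: float = 0.30
    decay: float = 0.30
    delta_bg: float = 0.01
    rho: float = 2.0
    eps: float = 0.001
    mode: str = "non-UDG"
    fraglen_logmu: float = 4.0
    fraglen_logsigma: float = 0.35
    # Coverage design
    full_cov: float = 24.0
    grid: tuple[int, ...] = (1, 3, 5, 10, 15, 20)
    # Estimator
    ncpg: int = 25
    rho_est: float = 2.0
    eps_est: float = 0.001
    interior_start: int = 10
    t_frac_threshold: float = 0.9
    min_support: int = 5
    # Precision analysis
    trend_form: str = "exponential"
    sd_factor: float = 2.0
    # Provenance
    seed: int = 1
    name: str = "default"

    def __post_init__(self) -> None:
        self.grid = tuple(sorted(self.grid))
        self.beta_high = tuple(self.beta_high)
        self.beta_low = tuple(self.beta_low)
        self.validate()

    def validate(self) -> None:
        if self.ref_length < 1000:
            raise ValueError("ref_length must be >= 1000")
        if not 0 <= self.n_cpg <= self.ref_length // 10:
            raise ValueError("n_cpg out of range")
        if not 0 <= self.full_cov <= 10000:
            raise ValueError("full_cov out of range")
        # An empty grid is tolerated here (simulation-only configs);
        # run_experiment rejects it.
        if any(c <= 0 for c in self.grid):
            raise ValueError("grid levels must be positive")
        if any(c >= self.full_cov for c in self.grid):
            raise ValueError("grid levels must lie strictly below full_cov")
        if self.ncpg < 0:
            raise ValueError("ncpg must be >= 0")
        if self.mode not in ("non-UDG", "UDG"):
            raise ValueError("mode must be 'non-UDG' or 'UDG'")
        if self.trend_form not in ("sqrt-law", "power", "exponential"):
            raise ValueError("unknown trend_form")
        if self.sd_factor <= 0:
            raise ValueError("sd_factor must be positive")
        # Delegate range checks on the damage parameters.
        from .simulate import DamageModel

        DamageModel(
            delta_max=self.delta_max,
            decay=self.decay,
            delta_bg=self.delta_bg,
            rho=self.rho,
            eps=self.eps,
            mode=self.mode,
        )

    def damage_model(self):
        from .simulate import DamageModel

        return DamageModel(
            delta_max=self.delta_max,
            decay=self.decay,
            delta_bg=self.delta_bg,
            rho=self.rho,
            eps=self.eps,
            mode=self.mode,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["beta_high"] = list(self.beta_high)
        d["beta_low"] = list(self.beta_low)
        return d

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


#: Sample-archetype presets: full coverage and terminal deamination are
#: the properties that distinguish the three reference samples; the
#: exceptionally preserved 38x sample has the lowest terminal rate.
PRESETS: dict[str, dict] = {
    "ans017-like": {
        "name": "ans017-like",
        "full_cov": 24.0,
        "delta_max": 0.30,
        "grid": _grid_below(24.0),
    },
    "SF12-like": {
        "name": "SF12-like",
        "full_cov": 38.0,
        "delta_max": 0.15,
        "grid": _grid_below(38.0),
    },
    "stuttgart-like": {
        "name": "stuttgart-like",
        "full_cov": 19.0,
        "delta_max": 0.30,
        "grid": _grid_below(19.0),
    },
}


def load_config(
    path: str | Path | None = None,
    preset: str | None = None,
    **overrides,
) -> ExperimentConfig:
    """Build a config with precedence defaults < preset < file < overrides."""
    merged: dict = {}
    if preset is not None:
        key = preset if preset in PRESETS else preset.lower()
        if key not in PRESETS:
            # case-insensitive match
            lut = {k.lower(): k for k in PRESETS}
            if preset.lower() not in lut:
                raise ValueError(
                    f"unknown preset {preset!r}; "
                    f"choose from {sorted(PRESETS)}"
                )
            key = lut[preset.lower()]
        merged.update(PRESETS[key])
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        merged.update(data)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    return ExperimentConfig(**merged)
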