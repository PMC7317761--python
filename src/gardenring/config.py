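"""Run configuration for the analysis pipeline (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the input files.

    ``drought_years`` is either an explicit list of event years or
    ``"auto"`` to detect them from summer soil-moisture anomaly ratios.
    ``relatedness_r`` is the average within-family coefficient of
    relatedness used in the heritability and Q_ST estimators.
    """

    # input paths (None = simulate)
    rings_path: str | None = None
    design_path: str | None = None
    climate_path: str | None = None
    genotypes_path: str | None = None
    outdir: str = "gardenring_out"

    # analysis window
    first_year: int = 1989
    last_year: int = 2007

    # drought events
    drought_years: object = "auto"
    pre_years: int = 2
    post_years: int = 2
    drought_quantile: float = 0.15

    # soil moisture index
    w_max: float = 300.0
    w_crit: float = 400.0

    # quantitative genetics
    relatedness_r: float = 0.2573
    residual_structure: str = "ar1"  # iid | ar1 | arh1

    # bootstrap / rng
    n_boot: int = 1000
    seed: int = 1

    # simulation overrides applied when no input files are given
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pre_years < 1 or self.post_years < 1:
            raise ValueError("pre/post window lengths must be >= 1 year")
        if self.w_max <= 0 or self.w_crit <= 0:
            raise ValueError("w_max and w_crit must be positive")
        if not 0 < self.relatedness_r <= 0.5:
            raise ValueError("relatedness r must be in (0, 0.5]")
        if self.residual_structure not in ("iid", "ar1", "arh1"):
            raise ValueError("residual_structure must be iid, ar1 or arh1")
        if self.last_year < self.first_year:
            raise ValueError("analysis window is empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def as_dict(self) -> dict:
        return asdict(self)
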