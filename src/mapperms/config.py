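"""Pipeline configuration: every tunable of the end-to-end run in one place.

Defaults are the study settings: m/z bins 29–600, resolution ε = 0.08 with
separation ratio r = 0.3 (δ = 0.024, 3δ = 0.072), coarse view radius
γ = 3ε = 0.24, S = 1000 randomized views, B = 1000 bootstrap resamples,
cluster counts Q ∈ {2…15}, stability threshold 0.5, and an 8 s modulation
period.  Constraints (notably 3δ < ε < 4δ) are validated at load time and
unknown keys are rejected.  All randomness flows from ``base_seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .unique import SeparationParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocessing
    mz_min: int = 29
    mz_max: int = 600
    retention_window: tuple[float, float] | None = None
    coverage: float = 0.95
    epsilon_floor: float = 1e-6
    modulation_s: float = 8.0
    # separation geometry
    epsilon: float = 0.08
    r: float = 0.3
    gamma: float | None = None  # default 3ε via SeparationParams
    # ensemble / stability
    shuffles: int = 1000
    bootstraps: int = 1000
    q_min: int = 2
    q_max: int = 15
    ari_threshold: float = 0.5
    min_phi: int = 50
    base_seed: int = 0
    # I/O
    input_dir: str | None = None
    metadata_path: str | None = None
    out_dir: str = "mapperms_out"
    export_views: bool = False

    def __post_init__(self) -> None:
        self.separation  # validates 3δ < ε < 4δ
        if self.q_min < 2 or self.q_max < self.q_min:
            raise ValueError("Q range must satisfy 2 <= q_min <= q_max")
        if not 0 <= self.ari_threshold <= 1:
            raise ValueError("ari_threshold must be in [0, 1]")
        if self.shuffles < 1 or self.bootstraps < 1:
            raise ValueError("shuffles and bootstraps must be positive")
        if self.mz_min > self.mz_max:
            raise ValueError("mz_min must not exceed mz_max")

    @property
    def separation(self) -> SeparationParams:
        return SeparationParams(epsilon=self.epsilon, r=self.r)

    @property
    def effective_gamma(self) -> float:
        return self.gamma if self.gamma is not None else self.separation.gamma

    @property
    def q_range(self) -> range:
        return range(self.q_min, self.q_max + 1)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load from a flat YAML file; unknown keys are rejected.

        Keyword overrides (e.g. from CLI flags) take precedence over file
        values.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("retention_window"), list):
            raw["retention_window"] = tuple(raw["retention_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effective_gamma"] = self.effective_gamma
        d["delta"] = self.separation.delta
        return d
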