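"""Analysis configuration with validated defaults."""

from __future__ import annotations

import json
from os import PathLike
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class AnalysisConfig(BaseModel):
    """Tunable numerics of the pipeline.

    dt governs only the reporting grid of the balance trajectory (segment
    boundaries are exact); the tau bracket upper bound deliberately
    exceeds any plausible physiological value so that extreme outliers are
    solvable rather than clipped.
    """

    dt: float = Field(default=0.01, gt=0)
    tau_bracket: tuple[float, float] = (0.1, 1e6)
    tau_tolerance: float = Field(default=1e-3, gt=0)
    tte_cap: float = Field(default=7200.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    loa_k: float = Field(default=1.96, ge=0)
    exclusions: list[str] = Field(default_factory=list)
    seed: int = 0

    @model_validator(mode="after")
    def _check_bracket(self) -> "AnalysisConfig":
        lo, hi = self.tau_bracket
        if not 0 < lo < hi:
            raise ValueError(f"tau_bracket must be ordered positive, got {self.tau_bracket}")
        return self

    @classmethod
    def from_file(cls, path: str | PathLike) -> "AnalysisConfig":
        """Load from JSON or YAML depending on the extension."""
        p = Path(path)
        text = p.read_text()
        data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})
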