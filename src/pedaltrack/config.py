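"""Analysis configuration shared by the library and the CLI.

Defaults reproduce the validation protocol's settings: a 15 s bout gap, a
±1.5 RPM equivalence margin tested at one-sided α = 0.025 per boundary,
error thresholds at 1/3/5 RPM, and a 0.8 minimum per-minute coverage.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator


class RunConfig(BaseModel):
    """Validated bundle of analysis parameters."""

    gap_seconds: float = Field(default=15.0, gt=0)
    margin: float = Field(default=1.5, gt=0)  # equivalence half-width, RPM
    alpha_one_sided: float = Field(default=0.025, gt=0, lt=0.5)
    thresholds: tuple[float, ...] = (1.0, 3.0, 5.0)  # RPM error bands
    min_coverage: float = Field(default=0.8, gt=0, le=1)
    rpm_count_mode: Literal["literal", "interval"] = "literal"
    bias_mode: Literal["grand", "subject_means"] = "grand"
    cluster_robust_slope: bool = False
    seed: int = 0

    @field_validator("thresholds")
    @classmethod
    def _thresholds_positive_increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v or any(x <= 0 for x in v) or list(v) != sorted(v):
            raise ValueError("thresholds must be positive and increasing")
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def override(self, **kwargs) -> "RunConfig":
        """Copy with non-None keyword overrides (CLI flags beat file values)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return self.model_copy(update=updates) if updates else self
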