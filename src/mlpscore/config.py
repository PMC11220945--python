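"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class RunConfig(BaseModel):
    """Pipeline parameters with their defaults.

    ``adc_threshold`` is in 10⁻⁶ mm²/s; an ROI is restricted when its
    summary statistic falls strictly below it.
    """

    adc_threshold: float = Field(default=650.0, gt=0)
    roi_statistic: Literal["mean", "median"] = "mean"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    proportion_ci_method: Literal["clopper_pearson", "wilson"] = "clopper_pearson"
    rounding_mode: Literal["raw", "as_published"] = "raw"
    seed: int = 0
    atlas_path: Optional[Path] = None
    volumes_dir: Optional[Path] = None
    cohort_path: Optional[Path] = None
    out_dir: Optional[Path] = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a JSON or YAML config file (JSON is a YAML subset)."""
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with any non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return self.model_copy(update=updates) if updates else self
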