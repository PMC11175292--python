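"""Pipeline and I/O configuration, loadable from YAML."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field


class IOConfig(BaseModel):
    """CSV ingestion options.

    Timestamps label the start of their interval.  Energy columns are either
    watt-hours (``energy_wh``) or kilowatt-hours (``energy_kwh``, converted to
    Wh on ingest).
    """

    timestamp_column: str = "timestamp"
    energy_column: str = "energy_wh"
    energy_unit: Literal["wh", "kwh"] = "wh"
    timestamp_convention: Literal["interval_start"] = "interval_start"


class PipelineConfig(BaseModel):
    """Parameters of the threshold/scoring/assessment pipeline."""

    endpoint_policy: Literal["include", "exclude"] = "exclude"
    fallback: Literal["min"] = "min"
    threshold_window_days: int = Field(14, ge=1)
    norm_window_days: int = Field(28, ge=2)
    display_decimals: int = Field(2, ge=0)
    io: IOConfig = IOConfig()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file (empty file -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)
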