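"""Run configuration: one validated object tying the pipeline together.

Defaults follow the method's stated constants: 5 mm ray-matching
tolerance, 5 mm minor ellipsoid axes, 95% improvement fraction, 1 mm
detector sampling and voxel size.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field

from .errors import PmaaIOError, ValidationError
from .geometry import CArmGeometry

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    geometry: CArmGeometry = Field(default_factory=CArmGeometry)
    scoring_method: Literal["analytic", "rendered", "voxel"] = "analytic"
    fraction: float = Field(default=0.95, gt=0, le=1)
    minor_full_axis_mm: float = Field(default=5.0, gt=0)
    match_tolerance_mm: float = Field(default=5.0, gt=0)
    sampling_mm: float = Field(default=1.0, gt=0)
    voxel_size_mm: float = Field(default=1.0, gt=0)
    seed: int = 0
    output_dir: Path = Path(".")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from an optional YAML/JSON file plus overrides."""
    data: dict = {}
    if path is not None:
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except OSError as exc:
            raise PmaaIOError(f"cannot read config: {exc}") from exc
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except ValueError as exc:
        raise ValidationError(f"invalid configuration: {exc}") from exc
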