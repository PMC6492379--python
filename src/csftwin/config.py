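"""Structured run configuration with validated defaults.

The defaults encode the bench's baseline operating condition: 70 beats/min,
baseline ICP 12.68 mmHg, a 0.31 ml/mmHg cranial and 0.84 ml/mmHg spinal
compliance (1.15 ml/mmHg total), a three-segment spinal canal spanning
hydraulic diameters 15 -> 5 mm, and two cranial valve resistances that the
calibration step refines.  Unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError


class ChamberConfig(BaseModel):
    """One compliance chamber: give either the initial air volume or a target
    compliance at the operating point (mutually exclusive)."""

    model_config = ConfigDict(extra="forbid")

    v0_air_ml: Optional[float] = Field(default=None, gt=0)
    c_target_ml_per_mmHg: Optional[float] = Field(default=None, gt=0)
    lam: float = Field(default=1.4, ge=1.0, le=1.67)

    @model_validator(mode="after")
    def _exactly_one_spec(self):
        if (self.v0_air_ml is None) == (self.c_target_ml_per_mmHg is None):
            raise ValueError("specify exactly one of v0_air_ml / c_target_ml_per_mmHg")
        return self


class ChambersConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cranial: ChamberConfig = Field(
        default_factory=lambda: ChamberConfig(c_target_ml_per_mmHg=0.31)
    )
    spinal: ChamberConfig = Field(
        default_factory=lambda: ChamberConfig(c_target_ml_per_mmHg=0.84)
    )


class ValvesConfig(BaseModel):
    """Valve resistances in mmHg/(ml/min); start values for calibration."""

    model_config = ConfigDict(extra="forbid")

    valve1_parenchyma_path: float = Field(default=0.02, ge=0)
    valve2_cranial_sas: float = Field(default=0.02, ge=0)


class CanalSegmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    length_mm: float = Field(gt=0)
    hydraulic_diameter_mm: float = Field(gt=0)
    viscosity_mpa_s: float = Field(default=1.0, gt=0)


def _default_canal() -> list[CanalSegmentConfig]:
    # wide cervical, mid thoracic, narrow lumbar hydraulic diameters (15/10/5 mm)
    return [
        CanalSegmentConfig(length_mm=150, hydraulic_diameter_mm=15),
        CanalSegmentConfig(length_mm=250, hydraulic_diameter_mm=10),
        CanalSegmentConfig(length_mm=200, hydraulic_diameter_mm=5),
    ]


class CanalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    segments: list[CanalSegmentConfig] = Field(default_factory=_default_canal, min_length=1)


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dt_divisor: int = Field(default=2048, ge=32)
    warmup_cycles: int = Field(default=2, ge=0)
    record_cycles: int = Field(default=9, ge=1)


class Config(BaseModel):
    model_config = ConfigDict(extra="forbid")

    heart_rate_bpm: float = Field(default=70.0, gt=0)
    baseline_icp_mmHg: float = 12.68
    atmospheric_mmHg: float = Field(default=760.0, gt=0)
    chambers: ChambersConfig = Field(default_factory=ChambersConfig)
    valves: ValvesConfig = Field(default_factory=ValvesConfig)
    canal: CanalConfig = Field(default_factory=CanalConfig)
    sim: SimConfig = Field(default_factory=SimConfig)

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate_bpm


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a JSON configuration; an absent or empty file yields
    all documented defaults.  Schema violations raise :class:`ConfigError`
    naming the offending key."""
    if path is None:
        return Config()
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    try:
        return Config.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({locs})") from exc


def dump_config(cfg: Config) -> str:
    """Serialize a configuration back to JSON (round-trips through load)."""
    return json.dumps(cfg.model_dump(), indent=2)
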