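"""Pipeline configuration: one declarative, schema-validated document.

Every threshold the analyses use lives here with its working default, so a
run directory plus its config fully determines the outputs.  CLI flags
override config values.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class Thresholds(BaseModel):
    r2_cutoff: float = Field(0.7, gt=0, le=1)
    chicago_cutoff: float = Field(5.0, gt=0)
    tpm_min: float = Field(1.5, ge=0)
    pct_min: float = Field(50.0, ge=0, le=100)
    immobility_min: int = Field(5, ge=1)
    zf_threshold_sec: float = Field(0.5, gt=0, le=60)
    screen_k_sd: float = Field(2.0, gt=0)
    efficiency_cutoff: float = Field(0.9, ge=0)


class LandscapeConfig(BaseModel):
    n_loci: int = Field(8, ge=0)
    n_proxies_per_locus: int = Field(3, ge=1)
    genome_length: int = Field(100_000, ge=10_000)
    n_chroms: int = Field(2, ge=1)
    enzyme: str = "dpnii"
    fraction_open: float = Field(1.0, ge=0, le=1)
    fraction_looped: float = Field(1.0, ge=0, le=1)
    n_decoy_suites: int = Field(1, ge=0)


class FlyConfig(BaseModel):
    n_lines: int = Field(6, ge=1)
    n_flies_per_line: int = Field(16, ge=1)
    n_days: int = Field(2, ge=1)
    effects_sd: dict[str, float] = Field(default_factory=lambda: {"line000": 3.0})
    screen_reference: str = "all_animals"  # or "controls"
    drop_dead: bool = True


class ZfConfig(BaseModel):
    n_scramble: int = Field(42, ge=2)
    n_ko: int = Field(48, ge=2)
    planted_night_sleep_delta_min: float = 60.0
    total_hours: int = Field(72, ge=48)
    clock_start_min: int = Field(840, ge=0, lt=1440)
    analysis_days: int = Field(2, ge=1)


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "runs/demo"
    thresholds: Thresholds = Field(default_factory=Thresholds)
    landscape: LandscapeConfig = Field(default_factory=LandscapeConfig)
    fly: FlyConfig = Field(default_factory=FlyConfig)
    zf: ZfConfig = Field(default_factory=ZfConfig)
    # optional pre-existing inputs; when unset the synthetic stage provides them
    inputs: dict[str, str] = Field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def dump_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
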