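"""Run configuration: a validated YAML-backed description of a full run.

All stage parameters default to the study's stated protocol (20 coherence
trials, 50 MMN trials, 1-30 Hz coherence band, 1-35 Hz MMN band, group sizes
16/18/20); every seed and threshold is explicit after resolution so a config
round-trips losslessly and re-running it reproduces outputs bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class ParadigmConfig(BaseModel):
    optimum1_seed: int = 11
    memorytrace_seed: int = 12
    render_audio: bool = False
    sample_rate_hz: float = 50_000.0


class PreprocessConfig(BaseModel):
    abs_threshold_uv: float = Field(100.0, gt=0)
    pp_threshold_uv: float = Field(150.0, gt=0)
    resting_epoch_s: float = Field(2.0, gt=0)
    mmn_window_ms: tuple[float, float] = (-100.0, 500.0)
    mmn_baseline_ms: tuple[float, float] = (-100.0, 0.0)


class CoherenceConfig(BaseModel):
    band_hz: tuple[float, float] = (1.0, 30.0)
    n_trials: int = Field(20, ge=2)
    squared: bool = True


class MMNConfig(BaseModel):
    window_ms: tuple[float, float] = (100.0, 250.0)
    n_trials: int = Field(50, ge=1)
    cluster: tuple[str, ...] = ("Fz", "FCz", "Cz")


class CohortConfig(BaseModel):
    n_ct: int = Field(16, ge=2)
    n_pt: int = Field(18, ge=2)
    n_wlc: int = Field(20, ge=2)
    beta_lifestyle: float = 0.0
    beta_group_ct: float = 0.0
    beta_group_pt: float = 0.0
    residual_sd: float = Field(0.09, gt=0)
    subject_sd: float = Field(0.10, ge=0)
    sessions: tuple[str, ...] = ("pre", "post")


class SimulationConfig(BaseModel):
    coherence_mixing_a: float = Field(0.6, ge=0, le=1)
    resting_duration_s: float = Field(120.0, ge=60)
    resting_fs_hz: float = Field(200.0, ge=100)
    mmn_amplitude_short_uv: float = -2.5
    mmn_amplitude_long_uv: float = -1.0
    mmn_noise_sd_uv: float = Field(10.0, gt=0)
    mmn_fs_hz: float = 500.0
    n_standard: int = 150
    n_deviant: int = 75


class RunConfig(BaseModel):
    seed: int = 0
    out_dir: str = "mmncoh_run"
    paradigm: ParadigmConfig = ParadigmConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    coherence: CoherenceConfig = CoherenceConfig()
    mmn: MMNConfig = MMNConfig()
    cohort: CohortConfig = CohortConfig()
    simulation: SimulationConfig = SimulationConfig()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not (0 <= v < 2**31):
            raise ValueError("seed must lie in [0, 2^31)")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
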