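"""Schema-validated run configuration for the pipeline driver."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = ["BandConfig", "RunConfig", "config_hash"]


class BandConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lo: float
    hi: float

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lo < self.hi:
            raise ValueError(f"band lo={self.lo} must be < hi={self.hi}")
        return self


class RunConfig(BaseModel):
    """Every knob of an end-to-end run; unknown keys are rejected and every
    random draw is tied to an explicit seed."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "results"
    seed: int = 0
    n_subjects: int = 6
    n_eeg_subjects: int = 2
    eeg_samples: int = 10_000
    eeg_fs_hz: float = 500.0
    n_sensors: int = 64
    bands: dict[str, BandConfig] = {
        "low_beta": BandConfig(lo=13.0, hi=20.0),
        "high_beta": BandConfig(lo=21.0, hi=30.0),
        "low_gamma": BandConfig(lo=31.0, hi=60.0),
        "high_gamma": BandConfig(lo=61.0, hi=100.0),
    }
    hp_hz: float = 0.5
    lp_hz: float = 200.0
    notch_hz: tuple[float, ...] = (50.0, 100.0, 150.0)
    lcmv_shrinkage: float = 0.05
    mvar_order: int | str = 15
    mvar_max_order: int = 20
    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    cv_folds: int = 5
    cv_repeats: int = 10
    prediction_subjects: int = 38

    @field_validator("mvar_order")
    @classmethod
    def _order_ok(cls, v):
        if isinstance(v, str) and v != "bic":
            raise ValueError("mvar_order must be an integer or 'bic'")
        if isinstance(v, int) and v < 1:
            raise ValueError("mvar_order must be >= 1")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical JSON form; stamped on artifacts."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
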