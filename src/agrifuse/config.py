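"""Scenario configuration: schema, validation, YAML/JSON I/O.

All tunables of the pipeline live in one nested, strictly validated
:class:`ScenarioConfig`.  Unknown keys are rejected (typo guard) and a
minimal config such as ``{n_zones: 4}`` validates with every default
filled in.  A config hash over the canonical JSON dump is recorded in
run manifests so any output can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Names and order of the per-zone environmental variables.
ENV_VARIABLES = ("soil_moisture", "temperature", "nutrient_index", "canopy_vigor")
#: Variables clipped to the unit interval after every update.
BOUNDED_VARIABLES = ("soil_moisture", "nutrient_index", "canopy_vigor")
#: Names and order of the weather-series channels.
WEATHER_VARIABLES = ("air_temperature", "humidity", "wind_speed", "precipitation")
#: Resource order used everywhere (columns of every N x 3 allocation matrix).
RESOURCES = ("water", "fertilizer", "pesticide")

STRESS_TYPES = ("nutrient_deficiency", "fungal_infection", "drought", "insect_pest")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ObjectiveConfig(_StrictModel):
    """Coefficients of the yield / cost / environmental-impact objective.

    ``beta`` are per-unit yield gains for water, fertilizer and pesticide,
    ``gamma`` the quadratic over-application penalty on the summed input,
    ``costs`` and ``env_costs`` the per-unit monetary and environmental
    prices, ``lambda1``/``lambda2`` the scalarization trade-off weights.
    """

    beta: tuple[float, float, float] = (0.8, 0.6, 0.4)
    gamma: float = Field(0.01, gt=0.0)
    costs: tuple[float, float, float] = (0.1, 0.15, 0.2)
    env_costs: tuple[float, float, float] = (0.05, 0.1, 0.3)
    lambda1: float = Field(1.0, ge=0.0)
    lambda2: float = Field(1.0, ge=0.0)

    @field_validator("costs", "env_costs")
    @classmethod
    def _nonnegative(cls, v):
        if any(x < 0 for x in v):
            raise ValueError("cost coefficients must be nonnegative")
        return v


class StressEventConfig(_StrictModel):
    zone_ids: list[int] = Field(min_length=1)
    stress_type: Literal["nutrient_deficiency", "fungal_infection", "drought", "insect_pest"]
    severity: float = Field(ge=0.0, le=1.0)
    onset: int = Field(0, ge=0)
    duration: int = Field(1, ge=1)


class EnvironmentConfig(_StrictModel):
    """AR(1) dynamics of the per-zone environmental state."""

    ar_coefficient: float = Field(0.7, ge=0.0, le=1.0)
    innovation_sd: float = Field(0.05, ge=0.0)
    baseline: tuple[float, float, float, float] = (0.55, 22.0, 0.6, 0.75)
    #: innovation scale per variable, relative to ``innovation_sd``
    variable_scales: tuple[float, float, float, float] = (1.0, 20.0, 1.0, 1.0)


class RenderConfig(_StrictModel):
    """Sensor rendering: grid resolutions and per-modality noise."""

    sat_px_per_zone: int = Field(2, ge=1)
    uav_px_per_zone: int = Field(4, ge=1)
    noise_sd: float = Field(0.05, ge=0.0)
    weather_steps: int = Field(24, ge=1)
    smooth_sigma: float = Field(0.5, ge=0.0)

    @model_validator(mode="after")
    def _uav_finer(self):
        if self.uav_px_per_zone <= self.sat_px_per_zone:
            raise ValueError("uav_px_per_zone must exceed sat_px_per_zone (UAV is the finer modality)")
        return self


class DetectorConfig(_StrictModel):
    shrinkage: float = Field(0.1, ge=0.0, le=1.0)
    metric: Literal["mahalanobis", "euclidean"] = "mahalanobis"
    quantile: float = Field(0.95, gt=0.0, lt=1.0)


class FusionConfig(_StrictModel):
    latent_dim: int = Field(16, ge=1)
    key_dim: int = Field(8, ge=1)


class SolverConfig(_StrictModel):
    tol: float = Field(1e-8, gt=0.0)
    max_iter: int = Field(10_000, ge=1)


class PriorityConfig(_StrictModel):
    w_h: float = 1.0
    w_y: float = 0.0
    w_p: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


class ControllerConfig(_StrictModel):
    alpha_water: float = Field(0.1, ge=0.0)
    alpha_fertilizer: float = Field(0.05, ge=0.0)
    alpha_pesticide: float = Field(0.01, ge=0.0)
    #: maps environmental deviations (per ENV_VARIABLES) to priority adjustments
    beta_env: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 1.0)
    steps: int = Field(50, ge=1)
    reallocate_every: Optional[int] = Field(None, ge=1)


class ScenarioConfig(_StrictModel):
    """Full ground-truth world description for one synthetic field."""

    n_zones: int = Field(16, ge=1)
    grid_shape: Optional[tuple[int, int]] = None
    objective: ObjectiveConfig = Field(default_factory=ObjectiveConfig)
    budgets: tuple[float, float, float] = (400.0, 200.0, 100.0)
    cap_per_zone: tuple[float, float, float] = (40.0, 25.0, 15.0)
    noise_sd: float = Field(0.5, ge=0.0)
    env_corr_length: float = Field(1.5, gt=0.0)
    environment: EnvironmentConfig = Field(default_factory=EnvironmentConfig)
    render: RenderConfig = Field(default_factory=RenderConfig)
    #: linear weights turning stress-induced env shifts into yield loss
    yield_env_weights: tuple[float, float, float, float] = (4.0, 0.0, 3.0, 5.0)
    stresses: list[StressEventConfig] = Field(default_factory=list)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    fusion: FusionConfig = Field(default_factory=FusionConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    priority: PriorityConfig = Field(default_factory=PriorityConfig)
    seed: int = Field(0, ge=0)

    @field_validator("budgets", "cap_per_zone")
    @classmethod
    def _nonnegative(cls, v):
        if any(x < 0 for x in v):
            raise ValueError("budgets and caps must be nonnegative")
        return v

    @model_validator(mode="after")
    def _grid_consistent(self):
        if self.grid_shape is not None:
            rows, cols = self.grid_shape
            if rows < 1 or cols < 1:
                raise ValueError("grid_shape entries must be >= 1")
            if rows * cols != self.n_zones:
                raise ValueError(
                    f"grid_shape {self.grid_shape} does not tile n_zones={self.n_zones}"
                )
        for ev in self.stresses:
            bad = [z for z in ev.zone_ids if not 0 <= z < self.n_zones]
            if bad:
                raise ValueError(f"stress event references invalid zone ids {bad}")
        return self

    def resolved_grid(self) -> tuple[int, int]:
        """Grid shape, defaulting to the most square factorization of N."""
        if self.grid_shape is not None:
            return tuple(self.grid_shape)
        n = self.n_zones
        rows = int(n**0.5)
        while n % rows:
            rows -= 1
        return (rows, n // rows)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario config from a YAML or JSON file.

    YAML is a superset of JSON, so both parse through ``yaml.safe_load``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    return ScenarioConfig.model_validate(data)


def dump_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config(dump_config(c)) == c``."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )


def config_hash(config: ScenarioConfig) -> str:
    """SHA-256 over the canonical JSON dump (order-independent)."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
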