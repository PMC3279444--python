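"""Validated configuration objects for the synthetic city and the pipeline.

All models reject unknown keys so a typo in a YAML run config fails loudly
instead of silently falling back to a default.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

POLLUTANTS = ("PM2.5", "NOx", "O3")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PollutantFieldParams(_StrictModel):
    """Deterministic spatial field for one pollutant: a linear radial
    gradient from the urban core plus an exponential near-road increment,
    with Gaussian day-to-day noise at the monitor."""

    center_level: float = Field(gt=0, description="concentration at the core, ug/m3")
    gradient_per_km: float = Field(description="signed radial slope, ug/m3 per km")
    road_increment: float = Field(ge=0, default=0.0, description="added near freeways, ug/m3")
    road_scale_m: float = Field(gt=0, default=300.0, description="e-folding distance of the road term, m")
    noise_sd: float = Field(ge=0, default=2.0, description="daily Gaussian noise sd, ug/m3")


class ActivityModel(_StrictModel):
    """Zero-inflated log-normal weekly activity model.

    The probability of being nonsedentary and the active-transport share of
    activity both increase linearly with a latent central-ness covariate
    (1 at the urban core, 0 at the domain corner); nonsedentary weekly
    minutes are log-normal with a mean that declines toward the core.
    """

    p_nonsedentary_low: float = Field(ge=0, le=1, default=0.10)
    p_nonsedentary_high: float = Field(ge=0, le=1, default=0.27)
    mean_minutes_low: float = Field(gt=0, default=543.0)
    mean_minutes_high: float = Field(gt=0, default=410.0)
    log_sd_minutes: float = Field(gt=0, default=1.05)
    transport_share_low: float = Field(ge=0, le=1, default=0.18)
    transport_share_high: float = Field(ge=0, le=1, default=0.55)


class SyntheticCityConfig(_StrictModel):
    """Everything needed to generate one seeded synthetic city + cohort."""

    extent_km: float = Field(gt=0, default=30.0)
    n_participants: int = Field(ge=1, default=30000)
    n_monitors_per_pollutant: int = Field(ge=1, default=30)
    road_grid_spacing_m: float = Field(gt=0, default=500.0)
    core_radius_fraction: float = Field(gt=0, le=0.5, default=0.25)
    tract_grid_size: int = Field(ge=1, default=10)
    parcel_grid_per_tract: int = Field(ge=1, default=6)
    density_center: float = Field(gt=0, default=57000.0, description="people/km2 at the core")
    density_edge: float = Field(gt=0, default=2000.0, description="people/km2 floor far from the core")
    density_scale_km: float = Field(gt=0, default=5.5)
    pollutant_field_params: dict[str, PollutantFieldParams] = Field(
        default_factory=lambda: {
            "PM2.5": PollutantFieldParams(center_level=25.5, gradient_per_km=-0.50, road_increment=2.0, noise_sd=4.0),
            "NOx": PollutantFieldParams(center_level=115.0, gradient_per_km=-2.6, road_increment=25.0, noise_sd=18.0),
            "O3": PollutantFieldParams(center_level=82.0, gradient_per_km=1.4, road_increment=0.0, noise_sd=12.0),
        }
    )
    activity_model: ActivityModel = Field(default_factory=ActivityModel)
    seed: int = 0

    @model_validator(mode="after")
    def _check_pollutants(self) -> "SyntheticCityConfig":
        unknown = set(self.pollutant_field_params) - set(POLLUTANTS)
        if unknown:
            raise ValueError(f"unknown pollutant(s) in field params: {sorted(unknown)}")
        return self

    @property
    def extent_m(self) -> float:
        return self.extent_km * 1000.0


class ExposureSettings(_StrictModel):
    k_nearest: int = Field(ge=1, default=3)
    idw_power: float = Field(gt=0, default=1.0)
    referent_percentile: float = Field(gt=0, lt=100, default=10.0)
    coincidence_epsilon_m: float = Field(ge=0, default=1.0)


class WalkabilitySettings(_StrictModel):
    bins: Literal["tertiles", "deciles"] = "tertiles"
    buffer_radius_m: float = Field(gt=0, default=1000.0)
    exclude_freeways: bool = True
    snap_max_distance_m: float = Field(gt=0, default=500.0)
    footprint: Literal["convex_hull", "corridor"] = "convex_hull"
    corridor_half_width_m: float = Field(gt=0, default=50.0)


class DoseResponseConfig(_StrictModel):
    """Literature-derived IHD dose-response parameters.

    Pollutant slopes are relative risks per 10 ug/m3 above the referent;
    activity tiers follow the WHO three-tier scheme (inactive 0 min/week,
    insufficiently active 1-150, active >150)."""

    rr_per_10: dict[str, float] = Field(
        default_factory=lambda: {"PM2.5": 1.25, "NOx": 1.08, "O3": 1.008}
    )
    rr_per_10_ci: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "PM2.5": (0.99, 1.59),
            "NOx": (1.06, 1.11),
            "O3": (1.002, 1.013),
        }
    )
    rr_inactive: float = 1.47
    rr_insufficient: float = 1.31
    rr_active: float = 1.00
    active_cutoff_min_per_week: float = 150.0
    linear_rr0: dict[str, float] = Field(
        default_factory=lambda: {"low": 1.31, "medium": 1.47, "high": 1.63}
    )


class BaseRatesConfig(_StrictModel):
    """Background IHD mortality rates, deaths per 100,000 per year."""

    general: float = Field(gt=0, default=191.2)
    nox_male_45_54: float = Field(gt=0, default=81.9)

    def rate_for(self, factor: str) -> float:
        return self.nox_male_45_54 if factor == "NOx" else self.general


class MonteCarloScheme(_StrictModel):
    schedule: Literal["daily", "every_other_day", "every_third_day"] = "every_other_day"
    age_bins: list[float] = Field(default_factory=lambda: [25.0, 50.0])
    n_reps: int = Field(ge=1, default=100)
    seed: int = 0

    @property
    def k(self) -> int:
        return {"daily": 1, "every_other_day": 2, "every_third_day": 3}[self.schedule]


class RunConfig(_StrictModel):
    """Top-level run configuration for the end-to-end pipeline."""

    input_dir: Optional[str] = None
    synthetic_city: Optional[SyntheticCityConfig] = None
    exposure: ExposureSettings = Field(default_factory=ExposureSettings)
    walkability: WalkabilitySettings = Field(default_factory=WalkabilitySettings)
    dose_response: DoseResponseConfig = Field(default_factory=DoseResponseConfig)
    base_rates: BaseRatesConfig = Field(default_factory=BaseRatesConfig)
    monte_carlo: Optional[MonteCarloScheme] = None
    rr_convention: Literal["mean_over_all", "mean_over_exposed"] = "mean_over_all"
    activity_mode: Literal["stepwise", "linear_low", "linear_medium", "linear_high"] = "stepwise"
    seed: int = 0

    @model_validator(mode="after")
    def _check_inputs(self) -> "RunConfig":
        if self.input_dir is None and self.synthetic_city is None:
            raise ValueError("RunConfig needs either input_dir or a synthetic_city section")
        return self


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(cfg: BaseModel) -> dict:
    """Round-trippable plain-dict form of any config model."""
    return cfg.model_dump(mode="json")
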