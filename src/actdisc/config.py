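"""Validated run configuration for all model components.

Every model constant lives here with its default: the prediction update
constant ``k = 0.95``, initial intrinsic salience ``S_init = 0.45``,
habituation factors ``gamma_a = gamma_b = 0.95``, membrane time constant
``tau = 0.04 s``, selection threshold ``phi = 0.5``, phasic-dopamine gains
``a_plus = 2`` / ``a_minus = 1``, the VI mean interval of 120 s and the tonic
dopamine level ``lam = 0.2``.  Configs are loaded from YAML (JSON being a
subset); unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NetworkConfig(_Strict):
    tau: float = Field(0.04, gt=0, description="membrane time constant (s)")
    dt: float = Field(0.01, gt=0, description="integration step (s)")
    phi: float = Field(0.5, description="brainstem selection threshold")
    lam: float = Field(0.2, ge=0, lt=1, description="tonic dopamine level")
    noise_sigma: float = Field(0.1, ge=0, description="sensory-cortex input noise sd")
    motor_weight_init: float = Field(0.55, ge=0, description="calibrated motor weight")
    eps: dict[str, float] = Field(
        default_factory=dict,
        description="per-population output-threshold overrides (by population name)",
    )
    gains: dict[str, float] = Field(
        default_factory=dict, description="inter-nucleus gain overrides (by name)"
    )

    @model_validator(mode="after")
    def _check_dt(self) -> "NetworkConfig":
        if self.dt > self.tau:
            raise ValueError(f"dt={self.dt} must not exceed tau={self.tau}")
        return self


class PredictionConfig(_Strict):
    k: float = Field(0.95, gt=0, lt=1, description="prediction update constant")
    first_flash_value: float = Field(0.2, ge=0, le=1)
    s_init: float = Field(0.45, gt=0, description="initial intrinsic salience")
    gamma_a: float = Field(0.95, gt=0, le=1, description="across-day habituation")
    gamma_b: float = Field(0.95, gt=0, le=1, description="within-day habituation")
    explore_low: float = Field(0.0, description="explore-salience uniform lower bound")
    explore_high: float = Field(0.8, description="explore-salience uniform upper bound")
    explore_redraw: float = Field(1.0, gt=0, description="redraw period (s)")

    @model_validator(mode="after")
    def _check_bounds(self) -> "PredictionConfig":
        if self.explore_high <= self.explore_low:
            raise ValueError("explore_high must exceed explore_low")
        return self


class DopamineConfig(_Strict):
    a_plus: float = Field(2.0, ge=0, description="collicular (burst) gain")
    a_minus: float = Field(1.0, ge=0, description="canceling (dip) gain")
    pulse_width: float = Field(0.2, gt=0, description="triangular pulse width (s)")
    tau_snc: float = Field(0.04, gt=0, description="SNc membrane time constant (s)")
    rest: float = Field(0.2, ge=0, description="resting dopamine level d at a_snc=0")


class PlasticityConfig(_Strict):
    # eight plasticity coefficients on a near-unit scale; the sign pattern and
    # strong/weak ordering follow the in-vitro data, the magnitudes are calibrated
    a_plus_d1_hi: float = 0.85
    a_minus_d1_hi: float = -0.25
    a_plus_d1_lo: float = 0.25
    a_minus_d1_lo: float = -1.0
    a_plus_d2_hi: float = -1.0
    a_minus_d2_hi: float = -0.25
    a_plus_d2_lo: float = 1.0
    a_minus_d2_lo: float = 1.0
    eta: float = Field(0.002, gt=0, description="lumped learning rate A3*tau+*tau_y")
    c_gain: float = Field(80.0, gt=0, description="tau+ / (A3*tau+*tau_y) inside C_BCM")
    tau_ratio: float = Field(1.0, gt=0, description="tau- / tau+")
    ysq_tau: float = Field(5.0, gt=0, description="<y^2> EMA time constant (s)")
    w_min: float = Field(0.2, ge=0)
    w_max: float = Field(1.5, gt=0)
    window: float = Field(0.4, gt=0, description="plasticity window after events (s)")
    tonic_plasticity: bool = Field(
        False, description="also apply the rule between phasic events"
    )


class ArenaConfig(_Strict):
    size: float = Field(60.0, gt=0, description="square arena side (length units)")
    block_half_width: float = Field(5.0, gt=0)
    block_depth: float = Field(2.0, gt=0)
    agent_radius: float = Field(2.8, gt=0)
    contact_dist: float = Field(1.0, gt=0, description="bump range beyond radius")
    fov_half_angle_deg: float = Field(60.0, gt=0, le=180)
    fov_range: float = Field(32.0, gt=0)
    flash_duration: float = Field(0.2, gt=0)
    speed_explore: float = 5.0
    speed_approach: float = 6.5
    speed_backoff: float = 4.0
    speed_reapproach: float = 3.8
    speed_max: float = 10.0
    turn_gain: float = 6.0
    backoff_time: float = 0.55
    stop_time: float = 0.4
    avoid_dist: float = 3.0
    explore_heading_redraw: float = 3.0
    axle_length: float = 5.3


class ProtocolConfig(_Strict):
    schedule: str = Field("vi", pattern="^(vi|fr1)$")
    pda_enabled: bool = True
    days_habituation: int = Field(5, ge=0)
    days_response_contingent: int = Field(10, ge=0)
    session_length: float = Field(900.0, gt=0, description="session duration (s)")
    epoch_length: float = Field(300.0, gt=0)
    n_runs: int = Field(10, ge=1)
    base_seed: int = Field(0, ge=0)
    vi_mean: float = Field(120.0, gt=0, description="mean VI availability interval (s)")


class RunConfig(_Strict):
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    prediction: PredictionConfig = Field(default_factory=PredictionConfig)
    dopamine: DopamineConfig = Field(default_factory=DopamineConfig)
    plasticity: PlasticityConfig = Field(default_factory=PlasticityConfig)
    arena: ArenaConfig = Field(default_factory=ArenaConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    """Parse, default and validate a YAML/JSON config file.

    An empty file yields all defaults; unknown keys raise a validation error.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration (for output provenance)."""
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
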