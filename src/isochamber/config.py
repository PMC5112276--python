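"""Run configuration models (pydantic) and YAML round-trip helpers."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class AnParams(BaseModel):
    """Assimilation demand curve: A = a_max * L(PAR) * c_i/(c_i + k_ci) - r_dark."""

    a_max: float = Field(29.7, gt=0, description="light-saturated capacity, umol m-2 s-1")
    k_ci: float = Field(1023.0, gt=0, description="half-saturation c_i, umol mol-1")
    par_half: float = Field(120.0, gt=0, description="half-saturation PAR for L(PAR)")
    r_dark: float = Field(0.5, ge=0, description="dark respiration, umol m-2 s-1")


class SimConfig(BaseModel):
    """Full parameterisation of a synthetic control/drought chamber experiment.

    Defaults emulate a 3+3 sapling experiment with a 16/8 h photoperiod
    (3 h ramp-up / 5 h ramp-down around a 600 umol m-2 s-1 plateau), a soil
    moisture drawdown from ~31 to ~24 vol% with daytime VPD roughly doubling,
    and re-watering at 02:30 of ``rewater_day``.
    """

    # experiment layout
    n_control: int = Field(3, gt=0)
    n_drought: int = Field(3, gt=0)
    days: int = Field(31, gt=0)
    drought_start_day: int = Field(5, ge=0)
    drawdown_days: float = Field(8.0, gt=0, description="days from onset until SMC plateaus at its minimum")
    rewater_day: int = Field(22, gt=0)

    # light schedule
    light_max: float = Field(600.0, gt=0)
    photoperiod_h: float = Field(16.0, gt=0)
    ramp_up_h: float = Field(3.0, ge=0)
    ramp_down_h: float = Field(5.0, ge=0)
    lights_on_h: float = Field(7.0, ge=0, lt=24)

    # soil moisture / VPD drivers
    smc_start: float = Field(31.0, gt=0)
    smc_drought_min: float = Field(24.0, gt=0)
    smc_rewet: float = Field(32.5, gt=0)
    vpd_control_day: float = Field(8.7, gt=0)
    vpd_drought_day: float = Field(17.1, gt=0)
    vpd_night: float = Field(3.0, gt=0)

    # temperatures
    t_air_day: float = 25.4
    t_air_night: float = 17.2
    t_air_drought_extra: float = 1.3
    t_leaf_offset: float = -1.5
    t_soil_mean: float = 16.7
    t_soil_amp: float = 0.5

    # stomatal / assimilation model
    gs_max: float = Field(0.15, gt=0)
    vpd_half: float = Field(10.0, gt=0, description="hPa at which f_vpd = 0.5")
    smc_gs_min: float = Field(18.6, ge=0, description="SMC at which f_smc floors")
    gs_floor: float = Field(0.05, gt=0, le=1.0)
    an_params: AnParams = AnParams()

    # discrimination endpoints (permil)
    a_frac: float = 4.4
    b_frac: float = 32.0

    # soil respiration model
    sr_base: float = Field(4.2, gt=0)
    q10: float = Field(2.0, gt=0)
    t_soil_ref: float = 16.7
    smc_sensitivity: float = Field(1.9, ge=0)
    sr_floor: float = Field(0.05, gt=0, le=1.0)

    # aboveground -> belowground isotopic coupling
    delta_sr_base: float = -25.5
    coupling_k: float = Field(0.15, ge=0, le=1.0)
    coupling_lag_h: float = Field(0.0, ge=0)
    coupling_baseline_delta: float = 24.9
    coupling_par_threshold: float = Field(500.0, ge=0, description="PAR above which discrimination feeds the coupling")

    # measurement noise (white, quoted at 1 s averaging)
    noise_delta13c: float = Field(0.25, ge=0, description="permil at 1 s")
    noise_co2: float = Field(0.3, ge=0, description="umol mol-1 at 1 s")

    # instrument drift + calibration gas
    drift_enable: bool = False
    drift_per_day_626: float = 0.0
    drift_per_day_636: float = 0.0
    cal_interval_h: float = Field(1.0, gt=0)
    cal_duration_s: float = Field(360.0, gt=0)
    cal_co2: float = Field(400.0, gt=0)
    cal_delta13c: float = -9.0

    # chamber geometry / plumbing
    leaf_area: float = Field(0.1, gt=0, description="m2 per plant")
    soil_area: float = Field(0.05, gt=0, description="m2 per pot")
    shoot_flow: float = Field(14.0, gt=0, description="l min-1")
    soil_flow: float = Field(2.2, gt=0, description="l min-1")

    # inlet air (climate chamber supply)
    ambient_co2: float = Field(420.0, gt=0)
    ambient_delta13c: float = -8.5
    ambient_h2o: float = Field(0.010, ge=0, lt=0.1)

    # sampling cadence
    cycle_interval_s: float = Field(1620.0, gt=0, description="seconds between successive cycles of one chamber")
    inlet_s: float = Field(134.0, gt=0)
    outlet_s: float = Field(136.0, gt=0)
    sample_dt_s: float = Field(2.0, gt=0)

    # between-plant variability (relative SD of per-plant scale factors)
    plant_cv: float = Field(0.05, ge=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if not self.rewater_day < self.days:
            raise ValueError("rewater_day must be < days")
        if not self.drought_start_day < self.rewater_day:
            raise ValueError("drought_start_day must be < rewater_day")
        if not self.ramp_up_h + self.ramp_down_h < self.photoperiod_h:
            raise ValueError("ramp_up_h + ramp_down_h must be < photoperiod_h")
        if self.smc_drought_min >= self.smc_start:
            raise ValueError("smc_drought_min must be < smc_start")
        if self.inlet_s + self.outlet_s > self.cycle_interval_s:
            raise ValueError("cycle_interval_s too short for one inlet+outlet pair")
        return self


class Masks(BaseModel):
    """PAR thresholds splitting records into day / night / transition."""

    par_day: float = Field(500.0, gt=0)
    par_night: float = Field(20.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "Masks":
        if self.par_night >= self.par_day:
            raise ValueError("par_night must be < par_day")
        return self


class QcThresholds(BaseModel):
    min_dc: float = Field(5.0, gt=0, description="|c_in - c_out| needed for xi / mixing, umol mol-1")
    lag_s: float = Field(20.0, ge=0, description="seconds discarded after each valve switch")
    min_usable_s: float = Field(10.0, gt=0, description="minimum usable window beyond the lag")


class Constants(BaseModel):
    """Overridable physical conventions (see :mod:`isochamber.constants`)."""

    r_vpdb: float = Field(0.0111802, gt=0)
    magnus_a: float = 6.112
    magnus_b: float = 17.62
    magnus_c: float = 243.12
    flow_ref_t_k: float = 298.15
    flow_ref_p_pa: float = 101325.0
    total_co2_scale: float = 1.0
    dry_correction: bool = False


class RunConfig(BaseModel):
    """One reproducible end-to-end run: paths + simulator + thresholds."""

    out_dir: Path = Path("run_out")
    raw_path: Optional[Path] = None
    truth_path: Optional[Path] = None
    chambers_path: Optional[Path] = None
    cycles_path: Optional[Path] = None
    fluxes_path: Optional[Path] = None
    results_dir: Optional[Path] = None

    sim: SimConfig = SimConfig()
    masks: Masks = Masks()
    qc: QcThresholds = QcThresholds()
    constants: Constants = Constants()

    def resolved(self) -> "RunConfig":
        """Fill unset paths with defaults under ``out_dir``."""
        out = self.model_copy(deep=True)
        d = Path(out.out_dir)
        out.raw_path = out.raw_path or d / "raw_stream.csv"
        out.truth_path = out.truth_path or d / "truth.csv"
        out.chambers_path = out.chambers_path or d / "chambers.csv"
        out.cycles_path = out.cycles_path or d / "cycles.csv"
        out.fluxes_path = out.fluxes_path or d / "fluxes.csv"
        out.results_dir = out.results_dir or d / "results"
        return out


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    data = yaml.safe_load(cfg.model_dump_json())
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
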