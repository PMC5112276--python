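"""Synthetic chamber experiment: drivers, ground truth, raw streams.

The simulator works on the (total CO2, delta13C) scale and converts to
isotopologue mole fractions as the very last step, so that the downstream
pipeline inverts it exactly: with zero noise, parsing the emitted stream
and running the flux engine reproduces every prescribed quantity to
floating-point precision.

Outline per plant and measurement cycle:

1. drivers: trapezoidal PAR schedule, soil-moisture drawdown with a
   pre-dawn re-watering step, daytime VPD scaling with drought progress,
   air/leaf/soil temperatures;
2. truth: g_s from multiplicative moisture and VPD stress scalars, A_N
   from the supply/demand closure (unique positive root of a quadratic),
   E from the inverse of the conductance relation, discrimination linear
   in c_i/c_a, soil respiration from a Q10 x moisture model, and a damped
   lagged imprint of discrimination on the delta13C of soil-respired CO2;
3. stream: outlet mole fractions and deltas obtained by exact algebraic
   inversion of the open-system balances, emitted as alternating
   inlet/outlet valve blocks at 0.5 Hz with white Gaussian noise scaled
   from the quoted 1 s Allan deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants as K
from .config import SimConfig
from .isotopes import invert_discrimination, split_isotopologues

__all__ = [
    "plant_table",
    "chamber_table",
    "generate_environment",
    "simulate_plant_fluxes",
    "synthesize_raw_stream",
    "synthesize_cycles",
    "simulate_truth",
]

PRESSURE_HPA = 1013.25

RAW_COLUMNS = [
    "timestamp", "chamber_id", "plant_id", "compartment", "line",
    "x626", "x636", "w_h2o", "par", "t_air", "t_leaf", "t_soil",
    "smc", "rh", "flow_lpm",
]


def plant_table(config: SimConfig) -> pd.DataFrame:
    """Plant ids and treatment labels: C1..Cn control, D1..Dm drought."""
    rows = [(f"C{i+1}", "control") for i in range(config.n_control)]
    rows += [(f"D{i+1}", "drought") for i in range(config.n_drought)]
    return pd.DataFrame(rows, columns=["plant_id", "treatment"])


def chamber_table(config: SimConfig) -> pd.DataFrame:
    """Chamber metadata: one shoot and one soil chamber per plant."""
    rows = []
    for _, p in plant_table(config).iterrows():
        rows.append((f"{p.plant_id}-shoot", p.plant_id, p.treatment, "shoot",
                     config.leaf_area, config.shoot_flow))
        rows.append((f"{p.plant_id}-soil", p.plant_id, p.treatment, "soil",
                     config.soil_area, config.soil_flow))
    return pd.DataFrame(
        rows, columns=["chamber_id", "plant_id", "treatment", "compartment",
                       "area_m2", "flow_lpm"])


def _par_schedule(hour: np.ndarray, config: SimConfig) -> np.ndarray:
    x = hour - config.lights_on_h
    par = np.zeros_like(x)
    plateau_end = config.photoperiod_h - config.ramp_down_h
    if config.ramp_up_h > 0:
        m = (x >= 0) & (x < config.ramp_up_h)
        par[m] = config.light_max * x[m] / config.ramp_up_h
    m = (x >= config.ramp_up_h) & (x <= plateau_end)
    par[m] = config.light_max
    if config.ramp_down_h > 0:
        m = (x > plateau_end) & (x < config.photoperiod_h)
        par[m] = config.light_max * (config.photoperiod_h - x[m]) / config.ramp_down_h
    return par


def _drought_progress(t_days: np.ndarray, config: SimConfig) -> np.ndarray:
    """0 before onset, ramps to 1 over the drawdown, 0 after re-watering (02:30)."""
    rewater_t = config.rewater_day + 2.5 / 24.0
    span = min(config.drawdown_days, max(rewater_t - config.drought_start_day, 1e-9))
    p = np.clip((t_days - config.drought_start_day) / span, 0.0, 1.0)
    p[t_days >= rewater_t] = 0.0
    return p


def generate_environment(config: SimConfig) -> pd.DataFrame:
    """Driver time series (one row per plant per measurement cycle).

    Columns: plant_id, treatment, cycle_idx, time_s, day, hour, par,
    smc, vpd, t_air, t_leaf, t_soil, rh.
    """
    n_cycles = int(config.days * K.SECONDS_PER_DAY // config.cycle_interval_s)
    t0 = np.arange(n_cycles) * config.cycle_interval_s
    t_mid = t0 + (config.inlet_s + config.outlet_s) / 2.0
    hour = (t_mid % K.SECONDS_PER_DAY) / 3600.0
    day = (t_mid // K.SECONDS_PER_DAY).astype(int)
    t_days = t_mid / K.SECONDS_PER_DAY
    par = _par_schedule(hour, config)
    lf = par / config.light_max

    frames = []
    for _, p in plant_table(config).iterrows():
        drought = p.treatment == "drought"
        prog = _drought_progress(t_days, config) if drought else np.zeros_like(t_days)
        if drought:
            rewater_t = config.rewater_day + 2.5 / 24.0
            smc = config.smc_start - prog * (config.smc_start - config.smc_drought_min)
            smc = np.where(t_days >= rewater_t, config.smc_rewet, smc)
        else:
            smc = np.full_like(t_days, config.smc_start)
        vpd_day = config.vpd_control_day + prog * (config.vpd_drought_day - config.vpd_control_day)
        vpd = config.vpd_night + (vpd_day - config.vpd_night) * lf
        t_air = (config.t_air_night + (config.t_air_day - config.t_air_night) * lf
                 + config.t_air_drought_extra * prog * lf)
        t_leaf = t_air + config.t_leaf_offset
        t_soil = config.t_soil_mean + config.t_soil_amp * np.sin(2 * np.pi * (hour - 10.0) / 24.0)
        rh = 100.0 * (1.0 - vpd / K.esat_hpa(t_air))
        frames.append(pd.DataFrame({
            "plant_id": p.plant_id, "treatment": p.treatment,
            "cycle_idx": np.arange(n_cycles), "time_s": t_mid,
            "day": day, "hour": hour, "par": par, "smc": smc, "vpd": vpd,
            "t_air": t_air, "t_leaf": t_leaf, "t_soil": t_soil, "rh": rh,
        }))
    return pd.concat(frames, ignore_index=True)


def _plant_scales(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-plant multiplicative factors (biological spread)."""
    plants = plant_table(config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = len(plants)
    cv = config.plant_cv
    scales = np.clip(rng.normal(1.0, cv, size=(n, 3)), 0.5, 1.5) if cv > 0 else np.ones((n, 3))
    plants = plants.copy()
    plants[["gs_scale", "amax_scale", "sr_scale"]] = scales
    return plants


def simulate_plant_fluxes(drivers: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Prescribed ground truth plus the exact chamber-outlet quantities.

    Returns one row per plant per cycle, carrying both the physiological
    truth (g_s, e, a_n, c_i, ci_ca, disc_true, sr, delta_sr_true) and the
    inlet/outlet gas composition that realises it in the two chambers.
    """
    scales = _plant_scales(config).set_index("plant_id")
    an = config.an_params
    shoot_flow = K.lpm_to_mol_s(config.shoot_flow)
    soil_flow = K.lpm_to_mol_s(config.soil_flow)
    lag_steps = int(round(config.coupling_lag_h * 3600.0 / config.cycle_interval_s))

    out = []
    for plant_id, g in drivers.groupby("plant_id", sort=False):
        g = g.sort_values("cycle_idx").reset_index(drop=True)
        sc = scales.loc[plant_id]
        par = g["par"].to_numpy()
        smc = g["smc"].to_numpy()
        vpd = g["vpd"].to_numpy()
        t_leaf = g["t_leaf"].to_numpy()
        t_air = g["t_air"].to_numpy()
        t_soil = g["t_soil"].to_numpy()

        f_smc = np.clip((smc - config.smc_gs_min) / (config.smc_start - config.smc_gs_min),
                        config.gs_floor, 1.0)
        f_vpd = 1.0 / (1.0 + vpd / config.vpd_half)
        gs = config.gs_max * sc.gs_scale * f_smc * f_vpd

        w_leaf = K.esat_hpa(t_leaf) / PRESSURE_HPA
        w_out = (K.esat_hpa(t_air) - vpd) / PRESSURE_HPA
        e_mol = gs * (w_leaf - w_out) / (1.0 - (w_leaf + w_out) / 2.0)
        w_in = w_out - e_mol * config.leaf_area * (1.0 - w_out) / shoot_flow

        # supply/demand closure, consistent with the engine's ternary-corrected
        # c_i relation and the chamber CO2 balance (unique positive root)
        c_in = np.full_like(par, config.ambient_co2)
        big_f = shoot_flow / config.leaf_area
        gc = gs / 1.6
        denom = big_f + e_mol + gc - e_mol / 2.0
        alpha = (gc - e_mol / 2.0) * big_f * c_in / denom
        beta = (gc + e_mol / 2.0) * (big_f + e_mol) / denom
        a_pot = an.a_max * sc.amax_scale * par / (par + an.par_half)
        r_dark = an.r_dark * sc.amax_scale
        b_q = a_pot + beta * an.k_ci - alpha - r_dark
        c_i = (-b_q + np.sqrt(b_q ** 2 + 4.0 * beta * (alpha + r_dark) * an.k_ci)) / (2.0 * beta)
        a_n = alpha - beta * c_i
        c_out_shoot = (big_f * c_in - a_n) / (big_f + e_mol)
        ci_ca = c_i / c_out_shoot

        disc = np.where(
            (a_n > 0) & (ci_ca > 0) & (ci_ca < 1),
            config.a_frac + (config.b_frac - config.a_frac) * ci_ca,
            np.nan,
        )
        delta_in = np.full_like(par, config.ambient_delta13c)
        dc = c_in - c_out_shoot
        xi = np.where(np.abs(dc) > 1e-9, c_in / np.where(dc == 0, np.nan, dc), np.nan)
        d_out_disc = invert_discrimination(disc, xi, delta_in)
        # night / transition: shoot respires CO2 of a fixed signature
        d_resp = config.delta_sr_base
        with np.errstate(divide="ignore", invalid="ignore"):
            d_out_mix = (delta_in * c_in + d_resp * (c_out_shoot - c_in)) / c_out_shoot
        delta_out_shoot = np.where(np.isfinite(d_out_disc), d_out_disc, d_out_mix)

        h_smc = np.clip(1.0 - config.smc_sensitivity * (config.smc_start - smc) / config.smc_start,
                        config.sr_floor, 1.0)
        sr = config.sr_base * sc.sr_scale * config.q10 ** ((t_soil - config.t_soil_ref) / 10.0) * h_smc

        # coupling input: full-light discrimination only, held through ramps and
        # night (the respired substrate carries the signature of assimilates
        # fixed under full illumination, not the dusk light-limited values)
        disc_day = np.where(par > config.coupling_par_threshold, disc, np.nan)
        disc_filled = pd.Series(disc_day).ffill().bfill().fillna(config.coupling_baseline_delta)
        disc_lagged = disc_filled.shift(lag_steps).bfill().to_numpy()
        delta_sr = config.delta_sr_base - config.coupling_k * (disc_lagged - config.coupling_baseline_delta)

        c_out_soil = c_in + sr * config.soil_area / soil_flow
        delta_out_soil = (delta_sr * (c_out_soil - c_in) + delta_in * c_in) / c_out_soil

        res = g.copy()
        res["g_s"] = gs
        res["e"] = e_mol * 1e3  # mmol m-2 s-1
        res["a_n"] = a_n
        res["c_i"] = c_i
        res["ci_ca"] = ci_ca
        res["disc_true"] = disc
        res["sr"] = sr
        res["delta_sr_true"] = delta_sr
        res["c_in"] = c_in
        res["delta_in"] = delta_in
        res["w_in_shoot"] = w_in
        res["w_out_shoot"] = w_out
        res["c_out_shoot"] = c_out_shoot
        res["delta_out_shoot"] = delta_out_shoot
        res["c_out_soil"] = c_out_soil
        res["delta_out_soil"] = delta_out_soil
        out.append(res)
    return pd.concat(out, ignore_index=True)


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Convenience: drivers + plant fluxes in one call."""
    return simulate_plant_fluxes(generate_environment(config), config)


def _gains(config: SimConfig, t_seconds: np.ndarray):
    if not config.drift_enable:
        one = np.ones_like(t_seconds, dtype=float)
        return one, one
    frac = t_seconds / K.SECONDS_PER_DAY
    return (1.0 + config.drift_per_day_626 * frac,
            1.0 + config.drift_per_day_636 * frac)


def synthesize_raw_stream(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Emit the 0.5 Hz valve-switched raw sample stream for all chambers.

    Each truth row becomes one inlet block (``inlet_s``) followed by one
    outlet block (``outlet_s``) for the shoot and the soil chamber of that
    plant. White Gaussian noise on total CO2 and delta13C is scaled from
    the configured 1 s deviations by 1/sqrt(sample_dt). With
    ``drift_enable`` a slow multiplicative per-isotopologue gain is applied
    and hourly calibration-gas blocks of known composition are appended.
    Deterministic for a given config (seeded from ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sample_dt_s
    n_in = int(config.inlet_s // dt)
    n_out = int(config.outlet_s // dt)
    n_blk = n_in + n_out
    offsets = np.arange(n_blk) * dt
    is_outlet = np.arange(n_blk) >= n_in

    sd_delta = config.noise_delta13c / np.sqrt(dt)
    sd_co2 = config.noise_co2 / np.sqrt(dt)

    frames = []
    for compartment in ("shoot", "soil"):
        if compartment == "shoot":
            c_out, d_out = truth["c_out_shoot"], truth["delta_out_shoot"]
            w_in, w_out = truth["w_in_shoot"], truth["w_out_shoot"]
            flow = config.shoot_flow
        else:
            c_out, d_out = truth["c_out_soil"], truth["delta_out_soil"]
            w_in = w_out = pd.Series(config.ambient_h2o, index=truth.index)
            flow = config.soil_flow
        n_cyc = len(truth)
        t0 = (truth["cycle_idx"].to_numpy() * config.cycle_interval_s)
        ts = np.repeat(t0, n_blk) + np.tile(offsets, n_cyc)
        outlet = np.tile(is_outlet, n_cyc)
        c = np.where(outlet, np.repeat(c_out.to_numpy(), n_blk), np.repeat(truth["c_in"].to_numpy(), n_blk))
        d = np.where(outlet, np.repeat(d_out.to_numpy(), n_blk), np.repeat(truth["delta_in"].to_numpy(), n_blk))
        w = np.where(outlet, np.repeat(w_out.to_numpy(), n_blk), np.repeat(w_in.to_numpy(), n_blk))
        if sd_co2 > 0:
            c = c + rng.normal(0.0, sd_co2, size=c.size)
        if sd_delta > 0:
            d = d + rng.normal(0.0, sd_delta, size=d.size)
        x626, x636 = split_isotopologues(c, d)
        g626, g636 = _gains(config, ts)
        frame = pd.DataFrame({
            "timestamp": ts,
            "chamber_id": np.repeat(truth["plant_id"].to_numpy(), n_blk),
            "plant_id": np.repeat(truth["plant_id"].to_numpy(), n_blk),
            "compartment": compartment,
            "line": np.where(outlet, "outlet", "inlet"),
            "x626": x626 * g626,
            "x636": x636 * g636,
            "w_h2o": w,
            "par": np.repeat(truth["par"].to_numpy(), n_blk),
            "t_air": np.repeat(truth["t_air"].to_numpy(), n_blk),
            "t_leaf": np.repeat(truth["t_leaf"].to_numpy(), n_blk),
            "t_soil": np.repeat(truth["t_soil"].to_numpy(), n_blk),
            "smc": np.repeat(truth["smc"].to_numpy(), n_blk),
            "rh": np.repeat(truth["rh"].to_numpy(), n_blk),
            "flow_lpm": flow,
        })
        frame["chamber_id"] = frame["chamber_id"] + "-" + compartment
        frames.append(frame)

    if config.drift_enable:
        frames.append(_cal_blocks(truth, config, rng))

    stream = pd.concat(frames, ignore_index=True)
    stream = stream.sort_values(["chamber_id", "timestamp"], kind="stable").reset_index(drop=True)
    return stream[RAW_COLUMNS]


def _cal_blocks(truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    t_end = (truth["cycle_idx"].max() + 1) * config.cycle_interval_s
    dt = config.sample_dt_s
    starts = np.arange(0.0, t_end, config.cal_interval_h * 3600.0)
    n_per = int(config.cal_duration_s // dt)
    offsets = np.arange(n_per) * dt
    ts = (starts[:, None] + offsets[None, :]).ravel()
    c = np.full(ts.size, config.cal_co2)
    d = np.full(ts.size, config.cal_delta13c)
    if config.noise_co2 > 0:
        c = c + rng.normal(0.0, config.noise_co2 / np.sqrt(dt), size=ts.size)
    if config.noise_delta13c > 0:
        d = d + rng.normal(0.0, config.noise_delta13c / np.sqrt(dt), size=ts.size)
    x626, x636 = split_isotopologues(c, d)
    g626, g636 = _gains(config, ts)
    return pd.DataFrame({
        "timestamp": ts, "chamber_id": "CAL", "plant_id": "CAL",
        "compartment": "cal", "line": "cal",
        "x626": x626 * g626, "x636": x636 * g636,
        "w_h2o": 0.0, "par": np.nan, "t_air": np.nan, "t_leaf": np.nan,
        "t_soil": np.nan, "smc": np.nan, "rh": np.nan, "flow_lpm": 0.5,
    })


def synthesize_cycles(truth: pd.DataFrame, config: SimConfig,
                      lag_s: float = 20.0) -> pd.DataFrame:
    """Fast path: cycle-averaged observations without the 0.5 Hz stream.

    Statistically equivalent to ``synthesize_raw_stream`` followed by
    cycle parsing: the cycle-mean noise SD of a white process quoted at
    1 s is sigma_1s / sqrt(T_eff) where T_eff is the usable averaging
    window (block length minus the valve-switch lag). Used for Monte
    Carlo studies where synthesising every raw sample would dominate
    run time. Drift/calibration are not modelled on this path.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sample_dt_s
    n_in_kept = len(np.arange(0.0, config.inlet_s, dt)[np.arange(0.0, config.inlet_s, dt) >= lag_s])
    n_out_kept = len(np.arange(0.0, config.outlet_s, dt)[np.arange(0.0, config.outlet_s, dt) >= lag_s])
    t_in = n_in_kept * dt
    t_out = n_out_kept * dt

    frames = []
    for compartment in ("shoot", "soil"):
        if compartment == "shoot":
            c_out, d_out = truth["c_out_shoot"].to_numpy(), truth["delta_out_shoot"].to_numpy()
            w_in, w_out = truth["w_in_shoot"].to_numpy(), truth["w_out_shoot"].to_numpy()
            flow = config.shoot_flow
        else:
            c_out, d_out = truth["c_out_soil"].to_numpy(), truth["delta_out_soil"].to_numpy()
            w_in = w_out = np.full(len(truth), config.ambient_h2o)
            flow = config.soil_flow
        n = len(truth)
        c_in = truth["c_in"].to_numpy().copy()
        d_in = truth["delta_in"].to_numpy().copy()
        c_out = c_out.copy()
        d_out = d_out.copy()
        if config.noise_co2 > 0:
            c_in = c_in + rng.normal(0.0, config.noise_co2 / np.sqrt(t_in), n)
            c_out = c_out + rng.normal(0.0, config.noise_co2 / np.sqrt(t_out), n)
        if config.noise_delta13c > 0:
            d_in = d_in + rng.normal(0.0, config.noise_delta13c / np.sqrt(t_in), n)
            d_out = d_out + rng.normal(0.0, config.noise_delta13c / np.sqrt(t_out), n)
        t0 = truth["cycle_idx"].to_numpy() * config.cycle_interval_s
        frames.append(pd.DataFrame({
            "plant_id": truth["plant_id"], "compartment": compartment,
            "chamber_id": truth["plant_id"] + "-" + compartment,
            "cycle_start": t0, "cycle_end": t0 + config.inlet_s + config.outlet_s,
            "t_mid": t0 + (config.inlet_s + config.outlet_s) / 2.0,
            "c_in": c_in, "c_out": c_out, "delta_in": d_in, "delta_out": d_out,
            "w_in": w_in, "w_out": w_out,
            "flow_lpm": flow, "flow_molar": K.lpm_to_mol_s(flow),
            "par": truth["par"], "t_air": truth["t_air"], "t_leaf": truth["t_leaf"],
            "t_soil": truth["t_soil"], "smc": truth["smc"], "rh": truth["rh"],
            "n_in": n_in_kept, "n_out": n_out_kept, "qc_flags": "",
        }))
    return pd.concat(frames, ignore_index=True)
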