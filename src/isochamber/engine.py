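"""Per-cycle gas-exchange fluxes and isotope quantities.

Every public function is vectorised over numpy arrays and also accepts
scalars. Unit conventions:

* CO2 mole fractions ``c`` in umol mol-1, water vapour ``w`` in mol mol-1
* ``flow_molar`` in mol air s-1, areas in m2
* ``delta13c`` in permil on the V-PDB scale; inside the discrimination
  formula deltas are converted to dimensionless fractions (permil / 1000),
  the only scale on which the ``1 + delta_out`` term is consistent
* net assimilation A_N in umol m-2 s-1, transpiration E in mmol m-2 s-1,
  stomatal conductance g_s in mol m-2 s-1, soil respiration SR in
  umol m-2 s-1

QC behaviour: functions return NaN (never raise) for records that fail a
quantitative guard, and :func:`compute_fluxes` records the reason in the
``qc_flags`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants as K
from .config import Masks, QcThresholds

__all__ = [
    "transpiration",
    "stomatal_conductance",
    "net_assimilation",
    "intercellular_co2",
    "soil_respiration",
    "discrimination_obs",
    "delta_soil_respired",
    "vpd",
    "compute_fluxes",
    "FLUX_COLUMNS",
]


def transpiration(flow_molar, w_in, w_out, leaf_area):
    """Transpiration E (mmol H2O m-2 s-1) from the open-system water balance.

    E = flow * (w_out - w_in) / (leaf_area * (1 - w_out)).
    """
    w_out = np.asarray(w_out, dtype=float)
    if np.any(w_out >= 1.0):
        raise ValueError("w_out must be < 1 mol mol-1")
    if np.any(np.asarray(leaf_area, dtype=float) <= 0):
        raise ValueError("leaf_area must be > 0")
    e_mol = np.asarray(flow_molar, float) * (w_out - np.asarray(w_in, float)) / (
        np.asarray(leaf_area, float) * (1.0 - w_out)
    )
    return _maybe_scalar(e_mol * 1e3)


def stomatal_conductance(e_mmol, w_out, t_leaf, pressure_hpa=1013.25):
    """Stomatal conductance to water vapour (mol m-2 s-1).

    The leaf intercellular air space is assumed saturated at leaf
    temperature (Magnus form); boundary-layer resistance is neglected
    (fan-stirred chamber). Records in the condensation regime
    (w_leaf <= w_out) come back NaN.
    """
    e_mol = np.asarray(e_mmol, float) * 1e-3
    w_leaf = K.esat_hpa(t_leaf) / np.asarray(pressure_hpa, float)
    w_out = np.asarray(w_out, float)
    grad = w_leaf - w_out
    with np.errstate(divide="ignore", invalid="ignore"):
        gs = e_mol * (1.0 - (w_leaf + w_out) / 2.0) / grad
    gs = np.where(grad > 0, gs, np.nan)
    return _maybe_scalar(gs)


def net_assimilation(flow_molar, c_in, c_out, e_mmol, leaf_area):
    """Net shoot assimilation A_N (umol m-2 s-1), dilution corrected.

    A_N = flow * (c_in - c_out) / leaf_area - E * c_out, with E in mol units
    so that the dilution term carries umol m-2 s-1.
    """
    if np.any(np.asarray(leaf_area, float) <= 0):
        raise ValueError("leaf_area must be > 0")
    e_mol = np.asarray(e_mmol, float) * 1e-3
    a = np.asarray(flow_molar, float) * (np.asarray(c_in, float) - np.asarray(c_out, float)) / np.asarray(
        leaf_area, float
    ) - e_mol * np.asarray(c_out, float)
    return _maybe_scalar(a)


def intercellular_co2(a_n, gs, e_mmol, c_out):
    """Intercellular CO2 mole fraction and its ratio to chamber air.

    Uses the ternary-corrected open-system relation with CO2 conductance
    g_c = g_s / 1.6:

        c_i = ((g_c - E/2) * c_out - A_N) / (g_c + E/2)

    Returns ``(c_i, ci_ca)`` where ci_ca = c_i / c_out clipped to [0, 1.5];
    NaN where g_s is not positive.
    """
    gs = np.asarray(gs, float)
    e_mol = np.asarray(e_mmol, float) * 1e-3
    gc = gs / 1.6
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = ((gc - e_mol / 2.0) * np.asarray(c_out, float) - np.asarray(a_n, float)) / (gc + e_mol / 2.0)
    ci = np.where(gs > 0, ci, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(ci / np.asarray(c_out, float), 0.0, 1.5)
    return _maybe_scalar(ci), _maybe_scalar(ratio)


def soil_respiration(flow_molar, c_in, c_out, soil_area):
    """Soil CO2 efflux SR (umol m-2 s-1) from the steady-state balance."""
    if np.any(np.asarray(soil_area, float) <= 0):
        raise ValueError("soil_area must be > 0")
    sr = np.asarray(flow_molar, float) * (np.asarray(c_out, float) - np.asarray(c_in, float)) / np.asarray(
        soil_area, float
    )
    return _maybe_scalar(sr)


def discrimination_obs(c_in, c_out, delta_in, delta_out, min_dc=5.0):
    """On-line photosynthetic 13C discrimination (permil) and xi.

    With xi = c_in / (c_in - c_out) and deltas as fractions d = delta/1000:

        D = xi * (d_out - d_in) / (1 + d_out - xi * (d_out - d_in))

    Records with |c_in - c_out| <= ``min_dc`` come back NaN (xi blow-up).
    Returns ``(delta_permil, xi)``.
    """
    c_in = np.asarray(c_in, float)
    c_out = np.asarray(c_out, float)
    dc = c_in - c_out
    ok = np.abs(dc) > min_dc
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = np.where(ok, c_in / dc, np.nan)
    d_in = np.asarray(delta_in, float) / 1e3
    d_out = np.asarray(delta_out, float) / 1e3
    num = xi * (d_out - d_in)
    with np.errstate(invalid="ignore"):
        disc = num / (1.0 + d_out - num)
    return _maybe_scalar(disc * 1e3), _maybe_scalar(xi)


def delta_soil_respired(c_in, c_out, delta_in, delta_out, min_dc=5.0):
    """delta13C of soil-respired CO2 (permil) by two-member mass balance.

        delta_SR = (delta_out * c_out - delta_in * c_in) / (c_out - c_in)

    Linear in delta, so permil passes straight through. NaN unless
    c_out > c_in + ``min_dc``.
    """
    c_in = np.asarray(c_in, float)
    c_out = np.asarray(c_out, float)
    dc = c_out - c_in
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (np.asarray(delta_out, float) * c_out - np.asarray(delta_in, float) * c_in) / dc
    d = np.where(dc > min_dc, d, np.nan)
    return _maybe_scalar(d)


def vpd(t_air, rh, pressure_hpa=1013.25):
    """Vapour pressure deficit (hPa): e_sat(T_air) * (1 - RH/100)."""
    rh = np.asarray(rh, float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("RH must lie in [0, 100] %")
    out = K.esat_hpa(t_air) * (1.0 - rh / 100.0)
    return _maybe_scalar(out)


def _maybe_scalar(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


FLUX_COLUMNS = [
    "plant_id", "treatment", "compartment", "time_s", "day", "hour",
    "a_n", "e", "g_s", "c_i", "ci_ca", "sr", "disc_obs", "delta_sr",
    "xi", "vpd", "par", "t_air", "t_leaf", "t_soil", "smc", "rh",
    "c_in", "c_out", "delta_in", "delta_out", "qc_flags",
]


def compute_fluxes(cycles: pd.DataFrame, chambers: pd.DataFrame,
                   masks: Masks | None = None,
                   qc: QcThresholds | None = None) -> pd.DataFrame:
    """Turn parsed chamber cycles into one flux record per cycle.

    ``chambers`` must provide plant_id, compartment, treatment, area_m2.
    Shoot cycles yield A_N, E, g_s, c_i and (under the day mask) the
    observed discrimination; soil cycles yield SR and the mixing-derived
    delta13C of soil-respired CO2.
    """
    masks = masks or Masks()
    qc = qc or QcThresholds()
    meta = chambers.set_index(["plant_id", "compartment"])
    df = cycles.copy()
    df["area_m2"] = [
        meta.loc[(p, c), "area_m2"] for p, c in zip(df["plant_id"], df["compartment"])
    ]
    df["treatment"] = [
        meta.loc[(p, c), "treatment"] for p, c in zip(df["plant_id"], df["compartment"])
    ]

    out = pd.DataFrame(index=df.index)
    for col in ("plant_id", "treatment", "compartment", "par", "t_air", "t_leaf",
                "t_soil", "smc", "rh", "c_in", "c_out", "delta_in", "delta_out"):
        out[col] = df[col]
    out["time_s"] = df["t_mid"]
    out["day"] = (df["t_mid"] // K.SECONDS_PER_DAY).astype(int)
    out["hour"] = (df["t_mid"] % K.SECONDS_PER_DAY) / 3600.0
    out["vpd"] = vpd(df["t_air"].to_numpy(), df["rh"].to_numpy())

    shoot = df["compartment"].to_numpy() == "shoot"
    soil = ~shoot
    n = len(df)
    a_n = np.full(n, np.nan)
    e = np.full(n, np.nan)
    g_s = np.full(n, np.nan)
    c_i = np.full(n, np.nan)
    ci_ca = np.full(n, np.nan)
    sr = np.full(n, np.nan)
    disc = np.full(n, np.nan)
    d_sr = np.full(n, np.nan)
    xi = np.full(n, np.nan)

    flow = df["flow_molar"].to_numpy()
    cin = df["c_in"].to_numpy()
    cout = df["c_out"].to_numpy()
    din = df["delta_in"].to_numpy()
    dout = df["delta_out"].to_numpy()
    area = df["area_m2"].to_numpy()
    par = df["par"].to_numpy()

    if shoot.any():
        s = shoot
        e[s] = transpiration(flow[s], df["w_in"].to_numpy()[s], df["w_out"].to_numpy()[s], area[s])
        g_s[s] = stomatal_conductance(e[s], df["w_out"].to_numpy()[s], df["t_leaf"].to_numpy()[s])
        a_n[s] = net_assimilation(flow[s], cin[s], cout[s], e[s], area[s])
        c_i[s], ci_ca[s] = intercellular_co2(a_n[s], g_s[s], e[s], cout[s])
        day = s & (par > masks.par_day)
        disc[day], xi[day] = discrimination_obs(cin[day], cout[day], din[day], dout[day], qc.min_dc)
    if soil.any():
        sr[soil] = soil_respiration(flow[soil], cin[soil], cout[soil], area[soil])
        d_sr[soil] = delta_soil_respired(cin[soil], cout[soil], din[soil], dout[soil], qc.min_dc)

    out["a_n"] = a_n
    out["e"] = e
    out["g_s"] = g_s
    out["c_i"] = c_i
    out["ci_ca"] = ci_ca
    out["sr"] = sr
    out["disc_obs"] = disc
    out["delta_sr"] = d_sr
    out["xi"] = xi

    flags = df.get("qc_flags", pd.Series([""] * n, index=df.index)).fillna("").astype(str)
    flags = flags.to_numpy(dtype=object)
    _append_flag(flags, shoot & (par > masks.par_day) & np.isnan(disc), "disc_low_dc")
    _append_flag(flags, soil & np.isnan(d_sr), "dsr_low_dc")
    _append_flag(flags, soil & (sr < 0), "negative_sr")
    _append_flag(flags, shoot & np.isnan(g_s), "gs_undefined")
    _append_flag(flags, shoot & ((ci_ca < 0) | (ci_ca > 1.0)), "cica_outside_unit")
    out["qc_flags"] = flags
    return out[FLUX_COLUMNS]


def _append_flag(flags: np.ndarray, mask, token: str) -> None:
    mask = np.asarray(mask) & np.ones(len(flags), dtype=bool)
    for i in np.nonzero(mask)[0]:
        flags[i] = token if not flags[i] else flags[i] + ";" + token
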