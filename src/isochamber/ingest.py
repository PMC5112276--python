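"""Raw valve-switched streams -> calibrated, paired inlet/outlet cycles.

A "block" is a maximal run of samples from one chamber on one line
(inlet/outlet); a cycle pairs an inlet block with the immediately
following outlet block of the same chamber. The first ``lag_s`` seconds
of every block are discarded (valve-switch transient) and blocks whose
usable window is shorter than ``min_usable_s`` are dropped with a QC flag.

delta13C of a cycle is computed from the cycle-averaged isotopologue mole
fractions (ratio of means, which is less noise-biased than the mean of
per-sample ratios at low signal-to-noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as K
from .config import Constants, QcThresholds
from .isotopes import compute_delta, split_isotopologues

__all__ = ["parse_cycles", "apply_calibration", "CalibrationFit", "CYCLE_COLUMNS"]

log = logging.getLogger(__name__)

CYCLE_COLUMNS = [
    "plant_id", "compartment", "chamber_id", "cycle_start", "cycle_end", "t_mid",
    "x626_in", "x636_in", "x626_out", "x636_out",
    "c_in", "c_out", "delta_in", "delta_out", "w_in", "w_out",
    "flow_lpm", "flow_molar", "par", "t_air", "t_leaf", "t_soil", "smc", "rh",
    "n_in", "n_out", "qc_flags",
]

ENV_CHANNELS = ["par", "t_air", "t_leaf", "t_soil", "smc", "rh"]


@dataclass
class CalibrationFit:
    """Per-isotopologue multiplicative gain valid around ``time_s``."""

    time_s: float
    gain_626: float
    gain_636: float
    offset_626: float = 0.0
    offset_636: float = 0.0
    residual_permil: float = 0.0

    def __post_init__(self) -> None:
        if self.gain_626 <= 0 or self.gain_636 <= 0:
            raise ValueError("calibration gains must be > 0")


def _blocks(chamber: pd.DataFrame, gap_tol: float) -> list[pd.DataFrame]:
    ts = chamber["timestamp"].to_numpy()
    line = chamber["line"].to_numpy()
    new = np.zeros(len(chamber), dtype=bool)
    new[0] = True
    new[1:] = (line[1:] != line[:-1]) | (np.diff(ts) > gap_tol)
    return [g for _, g in chamber.groupby(new.cumsum())]


def parse_cycles(stream: pd.DataFrame, qc: QcThresholds | None = None,
                 consts: Constants | None = None) -> pd.DataFrame:
    """Average each valve block past the lag and pair inlet -> outlet.

    Raises ``ValueError`` on non-monotone timestamps within a chamber.
    Unpairable or too-short blocks are dropped (counted in the log); the
    result never contains more cycles than there are outlet blocks.
    """
    qc = qc or QcThresholds()
    consts = consts or Constants()
    required = {"timestamp", "chamber_id", "line", "x626", "x636", "w_h2o"}
    missing = required - set(stream.columns)
    if missing:
        raise ValueError(f"raw stream is missing columns: {sorted(missing)}")

    rows = []
    n_short = n_unpaired = 0
    data = stream[stream["line"] != "cal"]
    for chamber_id, cham in data.groupby("chamber_id", sort=False):
        ts = cham["timestamp"].to_numpy()
        if np.any(np.diff(ts) < 0):
            raise ValueError(f"non-monotone timestamps in chamber {chamber_id}")
        dt = float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
        summaries = []
        for blk in _blocks(cham, gap_tol=2.5 * dt):
            t0 = blk["timestamp"].iloc[0]
            keep = blk[blk["timestamp"] - t0 >= qc.lag_s]
            span = blk["timestamp"].iloc[-1] - t0 + dt
            if span < qc.lag_s + qc.min_usable_s or keep.empty:
                n_short += 1
                continue
            summaries.append({
                "line": blk["line"].iloc[0],
                "start": t0,
                "end": blk["timestamp"].iloc[-1] + dt,
                "n": len(keep),
                "x626": keep["x626"].mean(),
                "x636": keep["x636"].mean(),
                "w": keep["w_h2o"].mean(),
                "flow_lpm": blk["flow_lpm"].mean() if "flow_lpm" in blk else np.nan,
                "env": {ch: blk[ch].mean() for ch in ENV_CHANNELS if ch in blk},
                "plant_id": blk["plant_id"].iloc[0] if "plant_id" in blk else chamber_id,
                "compartment": blk["compartment"].iloc[0] if "compartment" in blk else "",
            })
        i = 0
        while i < len(summaries):
            blk = summaries[i]
            if blk["line"] == "inlet" and i + 1 < len(summaries) and summaries[i + 1]["line"] == "outlet":
                rows.append(_make_cycle(chamber_id, blk, summaries[i + 1], consts))
                i += 2
            else:
                n_unpaired += 1
                i += 1
    if n_short or n_unpaired:
        log.info("parse_cycles: dropped %d short and %d unpaired blocks", n_short, n_unpaired)
    if not rows:
        return pd.DataFrame(columns=CYCLE_COLUMNS)
    return pd.DataFrame(rows, columns=CYCLE_COLUMNS)


def _make_cycle(chamber_id: str, inlet: dict, outlet: dict, consts: Constants) -> dict:
    env = {}
    for ch in ENV_CHANNELS:
        vals = [b["env"][ch] for b in (inlet, outlet) if ch in b["env"]]
        env[ch] = float(np.mean(vals)) if vals else np.nan
    flow_lpm = np.nanmean([inlet["flow_lpm"], outlet["flow_lpm"]])
    c_in = (inlet["x626"] + inlet["x636"]) * consts.total_co2_scale
    c_out = (outlet["x626"] + outlet["x636"]) * consts.total_co2_scale
    if consts.dry_correction:
        c_in = c_in / (1.0 - inlet["w"])
        c_out = c_out / (1.0 - outlet["w"])
    return {
        "plant_id": inlet["plant_id"], "compartment": inlet["compartment"],
        "chamber_id": chamber_id,
        "cycle_start": inlet["start"], "cycle_end": outlet["end"],
        "t_mid": (inlet["start"] + outlet["end"]) / 2.0,
        "x626_in": inlet["x626"], "x636_in": inlet["x636"],
        "x626_out": outlet["x626"], "x636_out": outlet["x636"],
        "c_in": c_in, "c_out": c_out,
        "delta_in": compute_delta(inlet["x626"], inlet["x636"], consts.r_vpdb),
        "delta_out": compute_delta(outlet["x626"], outlet["x636"], consts.r_vpdb),
        "w_in": inlet["w"], "w_out": outlet["w"],
        "flow_lpm": flow_lpm,
        "flow_molar": K.lpm_to_mol_s(flow_lpm, consts.flow_ref_t_k, consts.flow_ref_p_pa),
        **env,
        "n_in": inlet["n"], "n_out": outlet["n"],
        "qc_flags": "",
    }


def apply_calibration(cycles: pd.DataFrame, stream: pd.DataFrame,
                      known_co2: float, known_delta13c: float,
                      qc: QcThresholds | None = None,
                      consts: Constants | None = None,
                      ) -> tuple[pd.DataFrame, list[CalibrationFit]]:
    """Correct cycle-averaged isotopologue readings against cal-gas blocks.

    Fits one multiplicative gain per isotopologue to every calibration
    block (measured mean / assigned value) and linearly interpolates the
    gains in time across cycles. Without any calibration rows the cycles
    pass through unchanged with a ``no_calibration`` QC flag.
    """
    qc = qc or QcThresholds()
    consts = consts or Constants()
    cal = stream[stream["line"] == "cal"]
    out = cycles.copy()
    if cal.empty:
        log.warning("no calibration blocks found; applying identity calibration")
        out["qc_flags"] = [f + (";" if f else "") + "no_calibration" for f in out["qc_flags"]]
        return out, []

    known_626, known_636 = split_isotopologues(known_co2, known_delta13c, consts.r_vpdb)
    fits = []
    ts = cal["timestamp"].to_numpy()
    dt = float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    block_id = np.concatenate([[0], (np.diff(ts) > 2.5 * dt).cumsum()])
    for _, blk in cal.groupby(block_id):
        t0 = blk["timestamp"].iloc[0]
        keep = blk[blk["timestamp"] - t0 >= qc.lag_s]
        if keep.empty:
            continue
        g626 = keep["x626"].mean() / known_626
        g636 = keep["x636"].mean() / known_636
        resid = compute_delta(keep["x626"].mean() / g626, keep["x636"].mean() / g636,
                              consts.r_vpdb) - known_delta13c
        fits.append(CalibrationFit(time_s=float(keep["timestamp"].mean()),
                                   gain_626=float(g626), gain_636=float(g636),
                                   residual_permil=float(resid)))
    if not fits:
        out["qc_flags"] = [f + (";" if f else "") + "no_calibration" for f in out["qc_flags"]]
        return out, []

    t_fit = np.array([f.time_s for f in fits])
    g626 = np.array([f.gain_626 for f in fits])
    g636 = np.array([f.gain_636 for f in fits])
    t_cyc = out["t_mid"].to_numpy()
    gi626 = np.interp(t_cyc, t_fit, g626)
    gi636 = np.interp(t_cyc, t_fit, g636)
    for side in ("in", "out"):
        out[f"x626_{side}"] = out[f"x626_{side}"] / gi626
        out[f"x636_{side}"] = out[f"x636_{side}"] / gi636
        c = (out[f"x626_{side}"] + out[f"x636_{side}"]) * consts.total_co2_scale
        if consts.dry_correction:
            c = c / (1.0 - out[f"w_{side}"])
        out[f"c_{side}"] = c
        out[f"delta_{side}"] = compute_delta(out[f"x626_{side}"].to_numpy(),
                                             out[f"x636_{side}"].to_numpy(), consts.r_vpdb)
    return out, fits
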