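"""Treatment-level aggregation and drought/recovery statistics.

Aggregation always averages within plant first (per window) and only then
across plants, so the reported SD is the between-plant spread. Points with
fewer than two replicates are kept in the table but marked unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .config import Masks

__all__ = [
    "classify_daynight",
    "aggregate",
    "propagate_sd",
    "drought_effect",
    "effect_series",
    "recovery_day",
    "exact_rank_sum",
    "treatment_test",
    "coupling_regression",
    "fraction_enrichment",
    "summary_table",
    "MixedFit",
]


def classify_daynight(par, masks: Masks | None = None):
    """'day' (PAR > day threshold), 'night' (PAR < night threshold) or 'transition'."""
    masks = masks or Masks()
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be >= 0")
    out = np.where(par > masks.par_day, "day",
                   np.where(par < masks.par_night, "night", "transition"))
    return out.item() if out.ndim == 0 else out


def aggregate(fluxes: pd.DataFrame, variable: str, window: str = "daily",
              mask: str | None = "day", masks: Masks | None = None,
              min_replicates: int = 2) -> pd.DataFrame:
    """Per-treatment series of across-plant means and SDs.

    window: 'daily' or 'hourly' (day-of-run plus hour-of-day bins).
    mask: 'day', 'night' or None; masked records are selected with
    :func:`classify_daynight` (transition excluded from both).
    """
    masks = masks or Masks()
    if window not in ("daily", "hourly"):
        raise ValueError("window must be 'daily' or 'hourly'")
    df = fluxes.dropna(subset=[variable]).copy()
    if mask is not None:
        df = df[classify_daynight(df["par"].to_numpy(), masks) == mask]
    keys = ["treatment", "day"] + (["hour_bin"] if window == "hourly" else [])
    if window == "hourly":
        df["hour_bin"] = df["hour"].astype(int)
    if df.empty:
        return pd.DataFrame(columns=keys + ["mean", "sd", "n", "available"])
    plant_means = df.groupby(keys + ["plant_id"], sort=True)[variable].mean().reset_index()
    g = plant_means.groupby(keys, sort=True)[variable]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["available"] = out["n"] >= min_replicates
    return out


def propagate_sd(sd_wet, sd_dry):
    """SD of a control-vs-treated difference: sqrt(sd_wet^2 + sd_dry^2)."""
    sd_wet = np.asarray(sd_wet, dtype=float)
    sd_dry = np.asarray(sd_dry, dtype=float)
    if np.any(sd_wet < 0) or np.any(sd_dry < 0):
        raise ValueError("standard deviations must be >= 0")
    out = np.sqrt(sd_wet ** 2 + sd_dry ** 2)
    return float(out) if out.ndim == 0 else out


def drought_effect(control_mean, treated_mean):
    """Percent deviation of treated from control: 100 * treated/control - 100.

    NaN where the control mean is zero.
    """
    c = np.asarray(control_mean, dtype=float)
    t = np.asarray(treated_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c != 0, 100.0 * t / c - 100.0, np.nan)
    return float(out) if out.ndim == 0 else out


def effect_series(fluxes: pd.DataFrame, variable: str, mask: str | None = "day",
                  masks: Masks | None = None, min_replicates: int = 2) -> pd.DataFrame:
    """Daily drought-effect series with propagated SDs and recovery level.

    Columns: day, control_mean, control_sd, treated_mean, treated_sd,
    effect, sd_diff, recovery_level, available.
    """
    agg = aggregate(fluxes, variable, window="daily", mask=mask, masks=masks,
                    min_replicates=min_replicates)
    ctl = agg[agg["treatment"] == "control"].set_index("day")
    trt = agg[agg["treatment"] == "drought"].set_index("day")
    days = sorted(set(ctl.index) & set(trt.index))
    out = pd.DataFrame({"day": days})
    out["control_mean"] = ctl.loc[days, "mean"].to_numpy()
    out["control_sd"] = ctl.loc[days, "sd"].to_numpy()
    out["treated_mean"] = trt.loc[days, "mean"].to_numpy()
    out["treated_sd"] = trt.loc[days, "sd"].to_numpy()
    out["effect"] = drought_effect(out["control_mean"], out["treated_mean"])
    out["sd_diff"] = propagate_sd(out["control_sd"], out["treated_sd"])
    out["recovery_level"] = out["effect"] + 100.0
    out["available"] = (ctl.loc[days, "available"].to_numpy()
                        & trt.loc[days, "available"].to_numpy())
    return out


def recovery_day(effect, sd_diff=None, mode: str = "full", consecutive: int = 1,
                 level: float = 90.0):
    """First day (1-indexed from re-watering) meeting the recovery criterion.

    mode 'full': effect + sd_diff >= 0 (mean effect plus its propagated SD
    reaches the control level), sustained for ``consecutive`` days.
    mode 'level90': recovery level (effect + 100) >= ``level``.
    Returns ``None`` when never met.
    """
    effect = np.asarray(effect, dtype=float)
    if mode == "full":
        if sd_diff is None:
            raise ValueError("mode 'full' requires sd_diff")
        ok = effect + np.asarray(sd_diff, dtype=float) >= 0.0
    elif mode == "level90":
        ok = effect + 100.0 >= level
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ok = np.asarray(ok, dtype=bool)
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= consecutive:
            return i - consecutive + 2  # 1-indexed start of the qualifying run
    return None


def exact_rank_sum(group_a, group_b, alternative: str = "two-sided") -> float:
    """Exact Wilcoxon-Mann-Whitney p by full enumeration of label assignments.

    The statistic is the rank sum of ``group_a`` over the pooled mid-rank
    vector; all C(n_a + n_b, n_a) assignments are enumerated, which handles
    ties exactly. 'less' means group_a is stochastically smaller. Limited to
    2..8 observations per group (the exact enumeration regime).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if not (2 <= len(a) <= 8 and 2 <= len(b) <= 8):
        raise ValueError("exact enumeration supports 2..8 observations per group; "
                         "use a large-sample approximation otherwise")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[: len(a)].sum()
    n = len(pooled)
    total = comb(n, len(a))
    mu = len(a) * (n + 1) / 2.0
    n_le = n_ge = n_extreme = 0
    for idx in combinations(range(n), len(a)):
        w = ranks[list(idx)].sum()
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
        n_extreme += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    if alternative == "less":
        return n_le / total
    if alternative == "greater":
        return n_ge / total
    if alternative == "two-sided":
        return n_extreme / total
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class MixedFit:
    estimate: float
    p_value: float
    method: str


def _mixedlm(df: pd.DataFrame, formula: str, term: str, ddf: int) -> MixedFit:
    """REML random-intercept fit; Wald statistic referred to a t distribution
    with ``ddf`` denominator degrees of freedom (between-plant effects get
    n_plants - 2, within-plant covariates N - n_plants - 1, the convention of
    the usual grouped-data mixed-model software)."""
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["plant_id"])
        fit = model.fit(reml=True)
    tval = float(fit.params[term]) / float(fit.bse[term])
    p = 2.0 * stats.t.sf(abs(tval), max(ddf, 1))
    return MixedFit(float(fit.params[term]), float(p), "mixedlm")


def treatment_test(values, treatments, plant_ids) -> MixedFit:
    """Treatment fixed effect with a random intercept per plant.

    Thin contract over a standard REML mixed-model routine; on a singular
    or failed fit it falls back to a two-sample t-test on plant means.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "treatment": np.asarray(treatments),
                       "plant_id": np.asarray(plant_ids)})
    levels = sorted(df["treatment"].unique())
    if len(levels) != 2:
        raise ValueError("exactly two treatment levels required")
    term = f"C(treatment, Treatment('{levels[0]}'))[T.{levels[1]}]"
    ddf = df["plant_id"].nunique() - 2
    try:
        fit = _mixedlm(df, f"value ~ C(treatment, Treatment('{levels[0]}'))", term, ddf)
        if np.isfinite(fit.p_value):
            return fit
    except Exception:
        pass
    means = df.groupby(["plant_id", "treatment"])["value"].mean().reset_index()
    a = means.loc[means["treatment"] == levels[0], "value"]
    b = means.loc[means["treatment"] == levels[1], "value"]
    t = stats.ttest_ind(b, a)
    warnings.warn("mixed model failed; fell back to t-test on plant means")
    return MixedFit(float(b.mean() - a.mean()), float(t.pvalue), "ttest_plant_means")


def coupling_regression(x, y, plant_ids) -> MixedFit:
    """Slope of y on x with a random intercept per plant (repeated measures)."""
    df = pd.DataFrame({"x": np.asarray(x, dtype=float),
                       "y": np.asarray(y, dtype=float),
                       "plant_id": np.asarray(plant_ids)}).dropna()
    if len(df) < 3 or df.groupby("plant_id").size().max() < 3:
        raise ValueError("need at least 3 shared time points per plant")
    if np.ptp(df["x"].to_numpy()) == 0:
        raise ValueError("predictor is constant; slope undefined")
    ddf = len(df) - df["plant_id"].nunique() - 1
    try:
        fit = _mixedlm(df, "y ~ x", "x", ddf)
        if np.isfinite(fit.p_value) and np.isfinite(fit.estimate):
            return fit
    except Exception:
        pass
    # near-zero variance components can make the REML fit singular; the
    # within-plant (plant-demeaned) OLS slope is the same estimand
    gx = df.groupby("plant_id")["x"].transform("mean")
    gy = df.groupby("plant_id")["y"].transform("mean")
    xc = (df["x"] - gx).to_numpy()
    yc = (df["y"] - gy).to_numpy()
    slope = float(xc @ yc / (xc @ xc))
    resid = yc - slope * xc
    se = float(np.sqrt((resid @ resid) / max(ddf, 1) / (xc @ xc)))
    p = 2.0 * stats.t.sf(abs(slope) / se, max(ddf, 1)) if se > 0 else 0.0
    return MixedFit(slope, float(p), "within_ols")


def fraction_enrichment(treated, control) -> tuple[float, float]:
    """Difference of group means (treated - control, permil) and its SE.

    SE combines the group standard errors in quadrature (0 for n = 1).
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(t) < 1 or len(c) < 1:
        raise ValueError("need at least one sample per group")
    se_t = t.std(ddof=1) / np.sqrt(len(t)) if len(t) > 1 else 0.0
    se_c = c.std(ddof=1) / np.sqrt(len(c)) if len(c) > 1 else 0.0
    return float(t.mean() - c.mean()), float(np.hypot(se_t, se_c))


SUMMARY_VARIABLES = [
    ("vpd", "day"), ("t_air", "day"), ("t_leaf", "day"), ("t_soil", "day"),
    ("smc", "day"), ("a_n", "day"), ("g_s", "day"), ("e", "day"),
    ("disc_obs", "day"), ("sr", "day"), ("delta_sr", "day"),
    ("sr", "night"), ("delta_sr", "night"),
]


def summary_table(fluxes: pd.DataFrame, day_start: int, day_end: int,
                  masks: Masks | None = None) -> pd.DataFrame:
    """Drought-window summary: per-variable treatment means, SDs and effect %.

    Means are taken over plant window means within [day_start, day_end]
    (inclusive); SD is the between-plant spread of those window means.
    """
    window = fluxes[(fluxes["day"] >= day_start) & (fluxes["day"] <= day_end)]
    rows = []
    for variable, mask in SUMMARY_VARIABLES:
        df = window.dropna(subset=[variable])
        df = df[classify_daynight(df["par"].to_numpy(), masks) == mask]
        if df.empty:
            continue
        stats_ = df.groupby(["treatment", "plant_id"])[variable].mean().groupby("treatment").agg(["mean", "std", "count"])
        if not {"control", "drought"} <= set(stats_.index):
            continue
        c, d = stats_.loc["control"], stats_.loc["drought"]
        rows.append({
            "variable": variable, "mask": mask,
            "control_mean": c["mean"], "control_sd": c["std"], "n_control": int(c["count"]),
            "treated_mean": d["mean"], "treated_sd": d["std"], "n_treated": int(d["count"]),
            "effect_pct": drought_effect(c["mean"], d["mean"]),
        })
    columns = ["variable", "mask", "control_mean", "control_sd", "n_control",
               "treated_mean", "treated_sd", "n_treated", "effect_pct"]
    return pd.DataFrame(rows, columns=columns)
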