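"""Activation-trend statistics on per-cell surface-parameter tables.

The study design is cross-sectional: independent cohorts of cells are
imaged after 5-120 min of activation, plus two unactivated control cohorts
(before the experiment, ``CTR 0m``, and after 120 min in plain medium,
``CTR 120m``).  For every (parameter, channel) pair the screen asks three
questions:

1. does the parameter track activation time across the activated cohorts
   (Spearman rank correlation, Benjamini-Hochberg adjusted across all
   parameter x channel tests, with an effect-size gate |rho| >= 0.5)?
2. is it stable between the two control cohorts (Mann-Whitney p >= 0.05
   and absolute standardized difference < 0.5)?
3. only pairs passing both are *selected* as activation markers.

A calibration fitted on the selected monotone spatial indices of the
restored-adhesion channel (S_rwi rising, S_hw falling with activation)
inverts a query cell's parameters into an activation level in [0, 1] with
a bootstrap interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .maps import remove_plane_tilt
from .synthetic import SeriesRecord
from .texture import PARAMETER_NAMES, SpectrumOptions, parameter_suite

__all__ = [
    "compute_parameter_table",
    "summarize",
    "control_stability",
    "screen_correlation",
    "ActivationCalibration",
    "fit_activation_calibration",
    "estimate_activation",
]

TIDY_COLUMNS = ("group", "time_min", "level", "cell_id", "channel", "parameter", "value")


def compute_parameter_table(
    records: list[SeriesRecord],
    options: SpectrumOptions | None = None,
    tilt_remove_height: bool = True,
) -> pd.DataFrame:
    """Evaluate the 37-parameter suite for every record into a tidy table.

    Height maps are plane-tilt corrected before the suite (their origin
    and tilt are instrumental); adhesion channels enter as recorded.
    Columns: group, time_min, level, cell_id, channel, parameter, value.
    """
    rows = []
    for rec in records:
        smap = rec.map
        if tilt_remove_height and rec.channel == "height":
            smap = remove_plane_tilt(smap)
        pset = parameter_suite(smap, options)
        for name in PARAMETER_NAMES:
            rows.append(
                (
                    rec.group,
                    rec.time_min,
                    rec.level,
                    rec.cell_id,
                    rec.channel,
                    name,
                    pset[name],
                )
            )
    return pd.DataFrame(rows, columns=list(TIDY_COLUMNS))


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Group x channel x parameter summary (mean, sd, n) of per-cell values."""
    if table.empty:
        raise ValueError("empty parameter table")
    counts = table.groupby("group")["value"].size()
    if (counts == 0).any():
        raise ValueError("empty group in parameter table")
    out = (
        table.groupby(["group", "channel", "parameter"], sort=False)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def control_stability(
    table: pd.DataFrame, parameter: str, channel: str
) -> dict:
    """Mann-Whitney comparison of CTR 0m vs CTR 120m for one parameter.

    Returns a dict with ``p``, ``standardized_difference`` (difference of
    means over pooled sd) and ``stable`` (p >= 0.05 and |d| < 0.5); groups
    smaller than 3 yield ``evaluable = False``.
    """
    sel = (table["parameter"] == parameter) & (table["channel"] == channel)
    a = table.loc[sel & (table["group"] == "CTR 0m"), "value"].dropna().to_numpy()
    b = table.loc[sel & (table["group"] == "CTR 120m"), "value"].dropna().to_numpy()
    if a.size < 3 or b.size < 3:
        return {"evaluable": False, "stable": False, "p": math.nan, "standardized_difference": math.nan}
    pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    stable = p >= 0.05 and abs(d) < 0.5
    return {"evaluable": True, "stable": bool(stable), "p": p, "standardized_difference": float(d)}


def screen_correlation(
    table: pd.DataFrame,
    fdr: float = 0.05,
    rho_gate: float = 0.5,
    require_control_stability: bool = True,
) -> pd.DataFrame:
    """Rank-correlation screen of every (parameter, channel) against time.

    Spearman correlation of per-cell values versus activation time is
    computed over the activated (ACT) cohorts only; p-values are
    Benjamini-Hochberg adjusted across all tests jointly.  A pair is
    ``selected`` when adjusted p < ``fdr``, |rho| >= ``rho_gate`` and the
    control-stability check passes.  Constant parameters are excluded with
    a note in the ``note`` column.
    """
    act = table[table["group"].str.startswith("ACT")]
    if act["time_min"].nunique() < 3:
        raise ValueError("need at least 3 activation time points")
    rows = []
    for (param, channel), sub in act.groupby(["parameter", "channel"], sort=False):
        vals = sub["value"].to_numpy()
        times = sub["time_min"].to_numpy()
        ok = np.isfinite(vals)
        note = ""
        if ok.sum() < 3 or np.all(vals[ok] == vals[ok][0]):
            rho, p, note = math.nan, math.nan, "constant or insufficient data"
        else:
            rho, p = stats.spearmanr(times[ok], vals[ok])
        rows.append([param, channel, rho, p, note])
    res = pd.DataFrame(rows, columns=["parameter", "channel", "rho", "p", "note"])

    testable = res["p"].notna()
    adj = np.full(len(res), np.nan)
    if testable.any():
        adj[testable.to_numpy()] = multipletests(
            res.loc[testable, "p"].to_numpy(), method="fdr_bh"
        )[1]
    res["p_adj"] = adj
    res["direction"] = np.sign(res["rho"]).fillna(0.0)

    stable_flags = []
    for _, row in res.iterrows():
        if require_control_stability and not math.isnan(row["rho"]):
            st = control_stability(table, row["parameter"], row["channel"])
            stable_flags.append(bool(st["stable"]) if st["evaluable"] else True)
        else:
            stable_flags.append(True)
    res["control_stable"] = stable_flags
    res["selected"] = (
        (res["p_adj"] < fdr)
        & (res["rho"].abs() >= rho_gate)
        & res["control_stable"]
    ).fillna(False)
    return res


@dataclass
class ActivationCalibration:
    """Monotone calibration curves mapping spatial indices to activation level.

    One isotonic regression per parameter (S_rwi increasing, S_hw
    decreasing with level), fitted on a training series; inversion is by
    linear interpolation of the fitted monotone curve.  ``weights`` holds
    inverse-variance weights from bootstrap resampling of the calibration
    cells.  S_tdi is deliberately excluded: it is non-monotone near
    saturation and cannot be inverted.
    """

    parameters: tuple[str, ...]
    levels: dict[str, np.ndarray]
    fitted: dict[str, np.ndarray]
    weights: dict[str, float]
    level_range: tuple[float, float]
    boot_curves: dict[str, list[np.ndarray]]


CALIBRATION_PARAMETERS = ("Srwi", "Shw")


def _invert_monotone(levels: np.ndarray, fitted: np.ndarray, query: float) -> float:
    order = np.argsort(fitted)
    f_sorted = fitted[order]
    l_sorted = levels[order]
    q = min(max(query, f_sorted[0]), f_sorted[-1])  # clamp to calibration range
    return float(np.interp(q, f_sorted, l_sorted))


def fit_activation_calibration(
    table: pd.DataFrame,
    channel: str = "restored adhesion",
    parameters=CALIBRATION_PARAMETERS,
    n_boot: int = 200,
    seed: int = 0,
) -> ActivationCalibration:
    """Fit isotonic level-vs-parameter curves on a training series."""
    sub = table[(table["channel"] == channel) & table["parameter"].isin(parameters)]
    if sub.empty:
        raise ValueError(f"no rows for channel {channel!r}")
    rng = np.random.default_rng(seed)
    levels_d: dict[str, np.ndarray] = {}
    fitted_d: dict[str, np.ndarray] = {}
    weights: dict[str, float] = {}
    boot_curves: dict[str, list[np.ndarray]] = {}
    for param in parameters:
        s = sub[sub["parameter"] == param].dropna(subset=["value"])
        lv = s["level"].to_numpy()
        val = s["value"].to_numpy()
        iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
        iso.fit(lv, val)
        grid = np.unique(lv)
        levels_d[param] = grid
        fitted_d[param] = iso.predict(grid)
        # bootstrap the calibration cells to weight parameters by the
        # variance of the inverted level at mid-range
        mid = float(np.interp(0.5, grid, fitted_d[param])) if grid.size > 1 else 0.0
        boots = []
        curves = []
        n = lv.size
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            iso_b = IsotonicRegression(increasing="auto", out_of_bounds="clip")
            iso_b.fit(lv[idx], val[idx])
            curve = iso_b.predict(grid)
            curves.append(curve)
            boots.append(_invert_monotone(grid, curve, mid))
        var = float(np.var(boots))
        weights[param] = 1.0 / var if var > 0 else 1e6
        boot_curves[param] = curves
    return ActivationCalibration(
        parameters=tuple(parameters),
        levels=levels_d,
        fitted=fitted_d,
        weights=weights,
        level_range=(float(min(g.min() for g in levels_d.values())),
                     float(max(g.max() for g in levels_d.values()))),
        boot_curves=boot_curves,
    )


def estimate_activation(
    params: dict[str, float] | "pd.Series",
    calibration: ActivationCalibration,
) -> dict:
    """Estimate the activation level of one cell from its parameter values.

    Each calibration parameter is inverted through its monotone curve;
    the per-parameter levels are combined by inverse-variance weighting,
    and the interval is the 2.5-97.5 percentile of the combined estimate
    across the stored bootstrap calibration curves.  Queries outside the
    calibration range are clamped and flagged ``extrapolated``.
    """
    per_param = {}
    extrapolated = False
    for p in calibration.parameters:
        if p not in params or not np.isfinite(params[p]):
            continue
        q = float(params[p])
        fitted = calibration.fitted[p]
        if q < fitted.min() or q > fitted.max():
            extrapolated = True
        per_param[p] = _invert_monotone(calibration.levels[p], fitted, q)
    if not per_param:
        raise ValueError("no usable calibration parameters in query")
    w = np.array([calibration.weights[p] for p in per_param])
    est = float(np.average(list(per_param.values()), weights=w))

    boot_est = []
    n_boot = len(next(iter(calibration.boot_curves.values())))
    for b in range(n_boot):
        vals = []
        for p in per_param:
            vals.append(
                _invert_monotone(
                    calibration.levels[p], calibration.boot_curves[p][b], float(params[p])
                )
            )
        boot_est.append(np.average(vals, weights=w))
    lo, hi = np.percentile(boot_est, [2.5, 97.5])
    return {
        "level": est,
        "interval": (float(lo), float(hi)),
        "per_parameter": per_param,
        "extrapolated": extrapolated,
    }
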