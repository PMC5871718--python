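"""Thermal proteome profiling: melting curves and dose-response fits.

TPP-TR experiments measure, per protein, the fraction of non-denatured
protein (fold change relative to the lowest temperature) across a
temperature gradient.  Each protein is fitted with the three-parameter
sigmoid

    f(T) = (1 - plateau) / (1 + exp(b - a/T)) + plateau

a decreasing function of temperature T with a lower asymptote
``plateau``.  The melting point Tm is the temperature at which the fitted
curve equals 0.5; it has the closed form Tm = a / (b - ln(0.5/(0.5 -
plateau))) and is undefined when the curve never reaches 0.5.

2D-TPP experiments measure apparent stability (fold change relative to
vehicle) across compound concentrations at each temperature.  Proteins
whose top-dose fold change exceeds 3/2 (potentially stabilized) or falls
below 2/3 (potentially destabilized) are fitted, after a 0-1 min-max
transformation, with the log-logistic dose-response curve

    Y(x) = 1 / (1 + 10^((logEC50 - x) * slope)),   x = log10(concentration)

and summarised by pEC50 = -logEC50 when the fit's R^2 exceeds 0.8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import dynamics

logger = logging.getLogger(__name__)

STABILIZED_THRESHOLD = 1.5      # top-dose fold change > 3/2
DESTABILIZED_THRESHOLD = 2 / 3  # top-dose fold change < 2/3
MIN_R2 = 0.8
MAX_VEHICLE_PLATEAU = 0.3
MIN_SLOPE = -0.06               # per degree C; curves shallower than this fail QC


@dataclass
class MeltingFit:
    a: float
    b: float
    plateau: float
    tm: float | None             # degrees C; None when the curve misses 0.5
    inflection_slope: float      # curve derivative at its steepest point, 1/degC
    r_squared: float
    converged: bool


@dataclass
class DoseResponseFit:
    direction: str               # 'stabilized' | 'destabilized' | 'none'
    log_ec50: float | None       # log10 molar
    slope: float | None
    r_squared: float | None
    pec50: float | None          # -log10 molar
    pec50_valid: bool
    accepted: bool               # R^2 > 0.8 and converged


def melting_curve(temperature, a, b, plateau, literal_form: bool = False):
    """Three-parameter melting sigmoid.

    The default exponent ``b - a/T`` gives the physically expected
    decrease of the non-denatured fraction with temperature.  With
    ``literal_form`` the exponent is ``-(a*T - b)``, an increasing curve
    retained only for comparison.
    """
    T = np.asarray(temperature, dtype=float)
    if literal_form:
        z = -(a * T - b)
    else:
        z = b - a / T
    return (1.0 - plateau) / (1.0 + np.exp(z)) + plateau


def melting_point(a: float, b: float, plateau: float) -> float | None:
    """Closed-form temperature where the fitted melting curve equals 0.5.

    Undefined (None) when plateau >= 0.5 (the curve never falls to 0.5)
    or when the solution is non-positive.
    """
    if plateau >= 0.5:
        return None
    denom = b - math.log(0.5 / (0.5 - plateau))
    if denom <= 0:
        return None
    tm = a / denom
    return tm if tm > 0 else None


def _melting_derivative(T, a, b, plateau):
    z = b - a / T
    e = np.exp(z)
    return -(1.0 - plateau) * e / (1.0 + e) ** 2 * (a / T**2)


def inflection_slope(a: float, b: float, plateau: float, t_lo: float, t_hi: float) -> float:
    """Steepest (most negative) slope of the curve within [t_lo, t_hi]."""
    res = optimize.minimize_scalar(
        lambda T: _melting_derivative(T, a, b, plateau),
        bounds=(t_lo, t_hi),
        method="bounded",
    )
    return float(res.fun)


def _r_squared(y, y_hat) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_melting_curve(
    temperatures,
    fold_changes,
    max_iter: int = 500,
) -> MeltingFit:
    """Nonlinear least-squares fit of the melting sigmoid to one protein.

    Fold changes must be relative to the lowest temperature.  The fit uses
    fixed multi-start initialisation (plateau in {0, 0.1, 0.3}; b from the
    half-maximum temperature; a from the local slope), with the plateau
    bounded to [0, 1); the start with the smallest residual sum of squares
    wins.  Non-convergence is reported via ``converged`` rather than an
    exception so callers can exclude the protein downstream.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(fold_changes, dtype=float)
    if T.size < 5:
        raise ValueError("melting-curve fit needs at least 5 temperature points")
    order = np.argsort(T)
    T, y = T[order], y[order]

    # half-max temperature from the data for the b = a/Tm relation
    i_half = int(np.argmin(np.abs(y - 0.5)))
    t_half = T[i_half]
    dy = np.diff(y) / np.diff(T)
    slope_est = float(dy.min()) if dy.size else -0.05
    best = None
    for pl0 in (0.0, 0.1, 0.3):
        # at Tm the derivative is -(1-pl) * a / (4 Tm^2)
        a0 = max(-slope_est, 1e-3) * 4.0 * t_half**2 / max(1.0 - pl0, 0.5)
        b0 = a0 / t_half
        try:
            popt, _ = optimize.curve_fit(
                melting_curve,
                T,
                y,
                p0=(a0, b0, pl0),
                bounds=([1e-6, 1e-6, 0.0], [np.inf, np.inf, 1.0 - 1e-9]),
                maxfev=max_iter * 10,
                xtol=1e-10,
                ftol=1e-10,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - melting_curve(T, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return MeltingFit(np.nan, np.nan, np.nan, None, np.nan, np.nan, False)
    (a, b, plateau), _ = best
    tm = melting_point(a, b, plateau)
    slope = inflection_slope(a, b, plateau, T.min() - 5.0, T.max() + 5.0)
    r2 = _r_squared(y, melting_curve(T, a, b, plateau))
    return MeltingFit(float(a), float(b), float(plateau), tm, slope, r2, True)


def tm_shift_significance(
    fits: pd.DataFrame,
    min_bin_size: int = dynamics.DEFAULT_MIN_BIN_SIZE,
    min_r2: float = MIN_R2,
    max_vehicle_plateau: float = MAX_VEHICLE_PLATEAU,
    min_slope: float = MIN_SLOPE,
) -> pd.DataFrame:
    """Significance of compound-induced melting-point shifts.

    ``fits`` has one row per protein with columns ``tm_``, ``r2_``,
    ``plateau_`` and ``slope_`` for each of the four experiments
    ``v1, t1, v2, t2`` (two vehicle/treatment replicate pairs, label-swap
    design).  Proteins enter the statistical evaluation only when all four
    R^2 exceed ``min_r2`` and both vehicle plateaus are below
    ``max_vehicle_plateau``.  Eligible proteins are binned by their
    shallowest slope (at least ``min_bin_size`` per bin, shallow curves
    first, since shallow curves yield noisier melting points), a z-test on
    the melting-point difference is run per bin with a robust percentile
    SD, and BH adjustment is applied across the full set.  A shift is
    significant iff (i) one adjusted p < 0.05 and the other < 0.1,
    (ii) both replicate pairs shift in the same direction, (iii) both
    |dTm| exceed the vehicle-vehicle melting-point difference, and
    (iv) the steepest slope of each vehicle/treatment pair is below
    ``min_slope``.
    """
    df = fits.copy()
    df["dtm_1"] = df["tm_t1"] - df["tm_v1"]
    df["dtm_2"] = df["tm_t2"] - df["tm_v2"]
    df["dtm_vehicle"] = df["tm_v2"] - df["tm_v1"]
    df["min_slope_1"] = df[["slope_v1", "slope_t1"]].min(axis=1)
    df["min_slope_2"] = df[["slope_v2", "slope_t2"]].min(axis=1)

    r2_cols = ["r2_v1", "r2_t1", "r2_v2", "r2_t2"]
    eligible = (
        (df[r2_cols] > min_r2).all(axis=1)
        & (df["plateau_v1"] < max_vehicle_plateau)
        & (df["plateau_v2"] < max_vehicle_plateau)
        & df[["dtm_1", "dtm_2", "dtm_vehicle"]].notna().all(axis=1)
    )
    df["eligible"] = eligible
    df["p_1"] = np.nan
    df["p_2"] = np.nan
    df["adj_p_1"] = np.nan
    df["adj_p_2"] = np.nan

    sub = df.loc[eligible].copy()
    if len(sub) >= 2:
        # shallowest (least negative) slope of the pair, shallow first
        sub["slope_key"] = -sub[["min_slope_1", "min_slope_2"]].max(axis=1)
        bins = dynamics.bin_by_ssm(
            sub, min_bin_size=min_bin_size, key="slope_key"
        )
        indexed = sub.set_index("protein_group")
        p_series = {1: pd.Series(dtype=float), 2: pd.Series(dtype=float)}
        for b in bins:
            members = indexed.loc[b.protein_groups]
            for rep in (1, 2):
                d = members[f"dtm_{rep}"].to_numpy(dtype=float)
                center = np.median(d)
                lo, hi = np.percentile(d - center, [15.87, 84.13])
                sd = (hi - lo) / 2.0
                if sd <= 0:
                    continue
                p = 2.0 * stats.norm.sf(np.abs(d - center) / sd)
                p_series[rep] = pd.concat(
                    [p_series[rep], pd.Series(p, index=members.index)]
                )
        for rep in (1, 2):
            df[f"p_{rep}"] = df["protein_group"].map(p_series[rep])
            mask = df[f"p_{rep}"].notna()
            if mask.any():
                df.loc[mask, f"adj_p_{rep}"] = dynamics.bh_adjust(
                    df.loc[mask, f"p_{rep}"].to_numpy()
                )

    p_lo = df[["adj_p_1", "adj_p_2"]].min(axis=1)
    p_hi = df[["adj_p_1", "adj_p_2"]].max(axis=1)
    with np.errstate(invalid="ignore"):
        df["significant"] = (
            df["eligible"]
            & (p_lo < 0.05)
            & (p_hi < 0.1)
            & (np.sign(df["dtm_1"]) == np.sign(df["dtm_2"]))
            & (df["dtm_1"].abs() > df["dtm_vehicle"].abs())
            & (df["dtm_2"].abs() > df["dtm_vehicle"].abs())
            & (df["min_slope_1"] < min_slope)
            & (df["min_slope_2"] < min_slope)
        ).fillna(False)
    return df


def detect_direction(
    fold_changes,
    concentrations,
    stabilized_threshold: float = STABILIZED_THRESHOLD,
    destabilized_threshold: float = DESTABILIZED_THRESHOLD,
) -> str:
    """Classify a dose series by its fold change at the highest concentration.

    Fold changes are relative to vehicle.  Above 3/2 the protein is
    potentially stabilized, below 2/3 potentially destabilized; otherwise
    it is not considered for dose-response fitting.
    """
    fc = np.asarray(fold_changes, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    top = fc[np.argmax(conc)]
    if top > stabilized_threshold:
        return "stabilized"
    if top < destabilized_threshold:
        return "destabilized"
    return "none"


def dose_response_curve(x, log_ec50, slope):
    """Log-logistic dose-response model on x = log10(concentration)."""
    z = np.clip((np.asarray(log_ec50) - x) * slope, -300.0, 300.0)
    return 1.0 / (1.0 + 10.0**z)


def fit_sigmoid(x, y, max_iter: int = 500):
    """Least-squares fit of the dose-response sigmoid; returns
    ``(log_ec50, slope, r_squared)`` or ``None`` on non-convergence.

    Fixed multi-start over slope sign and EC50 position; no randomness.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = None
    lo, hi = x.min(), x.max()
    for s0 in (1.0, -1.0, 3.0, -3.0):
        for e0 in (np.median(x), lo, hi):
            try:
                popt, _ = optimize.curve_fit(
                    dose_response_curve,
                    x,
                    y,
                    p0=(e0, s0),
                    bounds=([lo - 3.0, -50.0], [hi + 3.0, 50.0]),
                    maxfev=max_iter * 10,
                    xtol=1e-10,
                    ftol=1e-10,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((y - dose_response_curve(x, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return None
    (log_ec50, slope), _ = best
    r2 = _r_squared(y, dose_response_curve(x, log_ec50, slope))
    return float(log_ec50), float(slope), r2


def transform_dose_series(fold_changes) -> np.ndarray:
    """Min-max transform of a dose series onto [0, 1].

    Stabilized series then run 0 -> 1 with concentration and destabilized
    series 1 -> 0; the direction is carried by the data, not flipped here.
    """
    fc = np.asarray(fold_changes, dtype=float)
    lo, hi = np.nanmin(fc), np.nanmax(fc)
    if hi == lo:
        return np.zeros_like(fc)
    return (fc - lo) / (hi - lo)


def fit_dose_response(
    fold_changes,
    concentrations,
    direction: str | None = None,
    min_r2: float = MIN_R2,
    vehicle_pseudo_decades: float = 2.0,
) -> DoseResponseFit:
    """Dose-response fit for one protein at one temperature.

    ``concentrations`` are molar with 0 for vehicle; ``fold_changes`` are
    relative to vehicle.  The series is min-max transformed to [0, 1] and
    fitted against x = log10(concentration); the vehicle point enters at a
    pseudo-concentration ``vehicle_pseudo_decades`` below the lowest tested
    dose (a zero concentration has no log).  The fit is accepted when
    R^2 > ``min_r2``; the pEC50 is flagged invalid when the fitted EC50
    lies below the lowest non-vehicle concentration (extrapolated outside
    the tested range).
    """
    fc = np.asarray(fold_changes, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if direction is None:
        direction = detect_direction(fc, conc)
    if direction == "none":
        return DoseResponseFit("none", None, None, None, None, False, False)

    y = transform_dose_series(fc)
    nonzero = conc > 0
    min_conc = conc[nonzero].min()
    x = np.where(nonzero, np.log10(np.where(nonzero, conc, min_conc)), np.log10(min_conc) - vehicle_pseudo_decades)
    fit = fit_sigmoid(x, y)
    if fit is None:
        return DoseResponseFit(direction, None, None, None, None, False, False)
    log_ec50, slope, r2 = fit
    accepted = r2 > min_r2
    pec50 = -log_ec50
    pec50_valid = accepted and (log_ec50 >= math.log10(min_conc))
    if accepted and not pec50_valid:
        logger.info(
            "pEC50 %.2f below the lowest tested concentration; reported but "
            "not considered valid",
            pec50,
        )
    return DoseResponseFit(
        direction, log_ec50, slope, r2, pec50, pec50_valid, accepted
    )
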