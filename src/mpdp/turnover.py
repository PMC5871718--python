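"""Protein decay rates and half-lives from nascent/mature ratio time courses.

After a pulsed-SILAC medium switch the ratio r(t) of nascent to mature
protein grows as e^(k t) - 1 for a protein degraded with first-order rate
k, so ln(r + 1) is linear in time through the origin.  The decay-rate
estimator is the through-origin least-squares slope

    k_dp = sum_i ln(r_ti + 1) * t_i / sum_i t_i^2

over the time points with a defined ratio.  In dividing cells the apparent
decay includes dilution by growth; subtracting ln(2)/t_cc for cell-cycle
time t_cc yields the division-corrected degradation rate.  Half-life is
ln(2) over the rate used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)


@dataclass
class TurnoverEstimate:
    """Decay-rate fit for one protein."""

    protein_group: str
    k_dp: float                  # apparent decay rate, 1/h
    k_corrected: float | None    # division-corrected rate, 1/h
    half_life: float | None      # hours, from the corrected rate if present
    r_squared: float
    qc: str                      # 'good' | 'weak' | 'poor'
    flags: list


def decay_rate(times, ratios) -> float:
    """Through-origin least-squares slope of ln(r+1) on t.

    Time points with an undefined (NaN) ratio are dropped from both sums.
    Raises if no time point has a defined ratio.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    ok = np.isfinite(r)
    if not ok.any():
        raise ValueError("no time point with a defined nascent/mature ratio")
    t, r = t[ok], r[ok]
    if (t <= 0).any():
        raise ValueError("time points must be strictly positive")
    y = np.log(r + 1.0)
    return float(np.sum(y * t) / np.sum(t * t))


def cell_cycle_correct(k_dp: float, t_cc: float) -> tuple[float, bool]:
    """Subtract the growth-dilution rate ln(2)/t_cc from the apparent decay.

    Returns ``(k_corrected, below_dilution_limit)``; the flag marks
    proteins whose apparent decay does not exceed dilution (corrected rate
    <= 0), for which no degradation half-life can be derived.
    """
    if t_cc <= 0:
        raise ValueError(f"cell cycle time must be positive, got {t_cc}")
    k = k_dp - LN2 / t_cc
    return k, k <= 0


def half_life(rate: float) -> float:
    """Half-life in hours, T_1/2 = ln(2)/k.  Undefined (NaN) for k <= 0."""
    if rate <= 0:
        return float("nan")
    return LN2 / rate


def fit_r_squared(times, ratios, k: float) -> float:
    """Coefficient of determination of the through-origin model ln(r+1) = k t.

    Uses the uncentred total sum of squares, the convention for
    regression through the origin.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    ok = np.isfinite(r)
    t, r = t[ok], r[ok]
    y = np.log(r + 1.0)
    ss_res = float(np.sum((y - k * t) ** 2))
    ss_tot = float(np.sum(y**2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def qc_label(ratios, n_peptides, n_design_points: int = 4) -> str:
    """Quality label for a time course designed with four time points.

    'good'  — at least 3 of the 4 fold changes rest on >= 3 quantified
              peptides;
    'weak'  — a fold change could be determined at >= 3 of the 4 points
              but the 'good' support criterion fails;
    'poor'  — everything else.  'good' takes precedence over 'weak'.
    """
    r = np.asarray(ratios, dtype=float)
    npep = np.asarray(n_peptides, dtype=float)
    defined = np.isfinite(r)
    need = n_design_points - 1
    if np.sum(defined & (npep >= 3)) >= need:
        return "good"
    if np.sum(defined) >= need:
        return "weak"
    return "poor"


def estimate_turnover(
    protein_group: str,
    times,
    ratios,
    n_peptides=None,
    t_cc: float | None = None,
) -> TurnoverEstimate:
    """Full turnover estimate for one protein time course.

    ``t_cc`` (hours) enables the cell-division correction; without it the
    apparent rate k_dp is used for the half-life.  ``n_peptides`` (per
    time point) feeds the QC label; omitted counts are treated as zero
    support.
    """
    flags = []
    k_dp = decay_rate(times, ratios)
    r2 = fit_r_squared(times, ratios, k_dp)
    if t_cc is not None:
        k_corr, below = cell_cycle_correct(k_dp, t_cc)
        if below:
            flags.append("below_dilution_limit")
        rate_for_t12 = k_corr
    else:
        k_corr = None
        rate_for_t12 = k_dp
    t12 = half_life(rate_for_t12)
    if not np.isfinite(t12):
        flags.append("half_life_undefined")
        t12 = None
    if n_peptides is None:
        n_peptides = np.zeros(len(np.atleast_1d(times)))
    qc = qc_label(ratios, n_peptides)
    return TurnoverEstimate(
        protein_group=protein_group,
        k_dp=k_dp,
        k_corrected=k_corr,
        half_life=t12,
        r_squared=r2,
        qc=qc,
        flags=flags,
    )
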