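"""End-to-end orchestration: PSM tables in, significance calls out.

Composes the published analysis steps — spectrum filtering, ion-area
quantification, per-replicate protein fold changes, the replicate-based
significance framework, and chaperone-dependence classification — plus
the thermal-profiling workflows, behind plain functions that consume and
return pandas DataFrames.  Every run returns a machine-readable log of
the thresholds applied.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from . import classify, dynamics, quant, thermal, turnover

logger = logging.getLogger(__name__)

#: label-swap duplicate design: which SILAC channel carries which pool
DEFAULT_DESIGN = {
    1: {"mature": "light", "nascent": "heavy"},
    2: {"mature": "heavy", "nascent": "light"},
}

REQUIRED_PSM_COLUMNS = set(quant.PSM_COLUMNS)


def validate_psm_table(psms: pd.DataFrame) -> list[str]:
    """Itemised schema validation; returns a list of problems (empty = ok)."""
    problems = []
    missing = REQUIRED_PSM_COLUMNS - set(psms.columns)
    for col in sorted(missing):
        problems.append(f"missing required column: {col}")
    if not quant.reporter_columns(psms):
        problems.append("no reporter intensity columns (intensity_<channel>)")
    if "replicate" in psms.columns:
        reps = set(psms["replicate"].unique())
        if not reps <= {1, 2}:
            problems.append(f"unexpected replicate labels: {sorted(reps)}")
    return problems


def protein_fold_changes(
    psms: pd.DataFrame,
    reference_channel: str = "vehicle",
    design: dict | None = None,
    min_score: float = quant.MIN_ION_SCORE,
    min_s2b: float = quant.MIN_S2B,
    min_s2i: float = quant.MIN_S2I,
    min_unique_peptides: int = 2,
) -> pd.DataFrame:
    """Per-protein log2 fold changes from a PSM table.

    Spectra are quality-filtered, converted to ion areas and summed per
    protein, pool (via the replicate's SILAC label orientation) and
    reporter channel; each non-reference channel's fold change is the
    ratio of its ion-area sum to the reference channel's.  Proteins with
    fewer than ``min_unique_peptides`` distinct unique peptides in a
    replicate are skipped for that replicate.
    """
    design = design or DEFAULT_DESIGN
    problems = validate_psm_table(psms)
    if problems:
        raise ValueError("invalid PSM table:\n" + "\n".join(problems))
    filtered = quant.filter_psms(
        psms, min_score=min_score, min_s2b=min_s2b, min_s2i=min_s2i
    )
    areas = quant.ion_area_table(filtered)
    cols = quant.reporter_columns(areas)
    channels = [c.removeprefix("intensity_") for c in cols]
    conditions = [c for c in channels if c != reference_channel]
    ref_col = f"intensity_{reference_channel}"

    rows = []
    for (replicate, protein), run_grp in areas.groupby(
        ["replicate", "protein_group"], sort=True
    ):
        # identification is per MS run: unique peptides are counted across
        # both SILAC channels of the replicate
        n_unique = run_grp.loc[
            run_grp["is_unique"].astype(bool), "peptide_sequence"
        ].nunique()
        if n_unique < min_unique_peptides:
            continue
        for silac, grp in run_grp.groupby("silac_channel"):
            pool = next(
                (p for p, ch in design[replicate].items() if ch == silac), None
            )
            if pool is None:
                continue
            ref_sum = grp[ref_col].sum()
            if ref_sum <= 0:
                logger.warning(
                    "zero reference-channel sum for %s (rep %s, %s pool); "
                    "skipped",
                    protein, replicate, pool,
                )
                continue
            for cond in conditions:
                fc = grp[f"intensity_{cond}"].sum() / ref_sum
                rows.append(
                    {
                        "protein_group": protein,
                        "condition": cond,
                        "pool": pool,
                        "replicate": replicate,
                        "log2_fc": math.log2(fc) if fc > 0 else np.nan,
                        "n_ssm": len(grp),
                    }
                )
    return pd.DataFrame(rows)


def run_mpdp(
    psms: pd.DataFrame,
    reference_channel: str = "vehicle",
    design: dict | None = None,
    min_bin_size: int = dynamics.DEFAULT_MIN_BIN_SIZE,
    fc_threshold: float = dynamics.DEFAULT_FC_THRESHOLD,
    alpha: float = dynamics.DEFAULT_ALPHA,
    use_mature_factors_for_nascent: bool = False,
    classify_dependence: bool = True,
    **quant_kwargs,
) -> dict:
    """Full mPDP analysis of one PSM table.

    Returns a bundle with the protein fold-change table, the significance
    calls, the dependence classification (conditions interpreted as
    treatment time points) and the effective configuration.
    """
    fc = protein_fold_changes(
        psms, reference_channel=reference_channel, design=design, **quant_kwargs
    )
    calls = dynamics.analyze(
        fc,
        min_bin_size=min_bin_size,
        fc_threshold=fc_threshold,
        alpha=alpha,
        use_mature_factors_for_nascent=use_mature_factors_for_nascent,
    )
    result = {
        "fold_changes": fc,
        "calls": calls,
        "run_log": {
            "reference_channel": reference_channel,
            "min_bin_size": min_bin_size,
            "fc_threshold": fc_threshold,
            "alpha": alpha,
            "use_mature_factors_for_nascent": use_mature_factors_for_nascent,
            **quant_kwargs,
        },
    }
    if classify_dependence:
        result["classification"] = classify.classify_dependence(calls)
    return result


def run_turnover(
    time_courses: pd.DataFrame, t_cc: float | None = None
) -> pd.DataFrame:
    """Turnover estimates from a long ratio time-course table.

    Columns: ``protein_group``, ``time`` (h), ``ratio`` (nascent/mature,
    NaN where undetermined) and optionally ``n_peptides``.
    """
    rows = []
    for protein, grp in time_courses.groupby("protein_group", sort=True):
        grp = grp.sort_values("time")
        npep = grp["n_peptides"] if "n_peptides" in grp else None
        try:
            est = turnover.estimate_turnover(
                protein, grp["time"], grp["ratio"], npep, t_cc=t_cc
            )
        except ValueError as err:
            logger.warning("no turnover estimate for %s: %s", protein, err)
            continue
        rows.append(
            {
                "protein_group": protein,
                "k_dp": est.k_dp,
                "k_corrected": est.k_corrected,
                "half_life": est.half_life,
                "r_squared": est.r_squared,
                "qc": est.qc,
                "flags": ";".join(est.flags),
            }
        )
    return pd.DataFrame(rows)


def run_thermal_tr(
    tr: pd.DataFrame,
    min_bin_size: int = dynamics.DEFAULT_MIN_BIN_SIZE,
) -> dict:
    """TPP-TR analysis: fit per-protein melting curves for the four
    experiments (v1/t1/v2/t2) and call significant melting-point shifts.

    ``tr`` is long-format with columns ``protein_group``, ``experiment``,
    ``temperature``, ``fold_change``.
    """
    expected = {"v1", "t1", "v2", "t2"}
    seen = set(tr["experiment"].unique())
    if not expected <= seen:
        raise ValueError(
            f"missing replicate experiments: {sorted(expected - seen)}"
        )
    rows = []
    for protein, grp in tr.groupby("protein_group", sort=True):
        row = {"protein_group": protein}
        ok = True
        for exp in ("v1", "t1", "v2", "t2"):
            sub = grp[grp["experiment"] == exp]
            if len(sub) < 5:
                ok = False
                break
            fit = thermal.fit_melting_curve(
                sub["temperature"], sub["fold_change"]
            )
            if not fit.converged or fit.tm is None:
                ok = False
                break
            row[f"tm_{exp}"] = fit.tm
            row[f"r2_{exp}"] = fit.r_squared
            row[f"plateau_{exp}"] = fit.plateau
            row[f"slope_{exp}"] = fit.inflection_slope
        if ok:
            rows.append(row)
    fits = pd.DataFrame(rows)
    shifts = thermal.tm_shift_significance(fits, min_bin_size=min_bin_size)
    return {"fits": fits, "shifts": shifts, "run_log": {"min_bin_size": min_bin_size}}


def run_thermal_2d(two_d: pd.DataFrame) -> pd.DataFrame:
    """2D-TPP analysis: direction calls and dose-response fits per protein.

    ``two_d`` is long-format with columns ``protein_group``,
    ``concentration`` (molar, 0 = vehicle), ``fold_change``.
    """
    rows = []
    for protein, grp in two_d.groupby("protein_group", sort=True):
        grp = grp.sort_values("concentration")
        fit = thermal.fit_dose_response(
            grp["fold_change"].to_numpy(), grp["concentration"].to_numpy()
        )
        rows.append(
            {
                "protein_group": protein,
                "direction": fit.direction,
                "log_ec50": fit.log_ec50,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "pec50": fit.pec50,
                "pec50_valid": fit.pec50_valid,
                "accepted": fit.accepted,
            }
        )
    return pd.DataFrame(rows)
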