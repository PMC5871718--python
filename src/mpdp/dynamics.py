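"""Replicate-based significance framework for mPDP fold changes.

Pulsed-SILAC / isobaric-tag experiments yield, for every protein, a log2
fold change per condition, per pool (mature or nascent) and per biological
replicate, supported by a number of quantified spectrum-sequence matches
(SSMs).  Calling treatment effects proceeds in five steps:

1. median normalisation per condition/pool/replicate (optionally carrying
   the mature pool's factors over to the nascent pool, for treatments
   that regulate a large share of nascent proteins);
2. binning of proteins by SSM count, at least 300 proteins per bin;
3. a robust standard deviation per bin from the distribution of
   replicate-replicate differences scaled by 1/sqrt(2), estimated from
   the 15.87/50/84.13 percentiles;
4. a two-sided Z-test per replicate against the bin SD, followed by
   Benjamini-Hochberg adjustment across all bins;
5. a protein is significant only if the adjusted p is <= 0.05 in *both*
   replicates, the absolute log2 fold change exceeds the cutoff
   (default 0.37, a 30% change) in both, and the direction agrees.

Because the test is anchored on replicate disagreement rather than on the
spread of the population, it stays valid when many proteins are truly
regulated.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_BIN_SIZE = 300
DEFAULT_FC_THRESHOLD = 0.37  # |log2 FC| cutoff equivalent to a 30% change
DEFAULT_ALPHA = 0.05

#: percentiles bracketing +-1 SD of a normal distribution
_LOWER_PCTL = 15.87
_UPPER_PCTL = 84.13


@dataclass
class Bin:
    """A data-quality bin: proteins with similar values of the binning key
    (spectral support for mPDP data, curve slope for melting-point shifts)."""

    protein_groups: list
    key_min: float
    key_max: float
    robust_sd: float | None = None


def median_normalize(
    fold_changes: pd.DataFrame,
    use_mature_factors_for_nascent: bool = False,
) -> pd.DataFrame:
    """Centre log2 fold changes at zero per condition/pool/replicate.

    The normalisation factor is the median log2 fold change of the group.
    With ``use_mature_factors_for_nascent`` the factors computed on the
    mature pool are applied to the nascent pool of the same condition and
    replicate instead of the nascent pool's own medians — appropriate when
    a substantial fraction of nascent proteins is genuinely regulated and
    the nascent median is therefore not a null reference.
    """
    df = fold_changes.copy()
    med = df.groupby(["condition", "pool", "replicate"])["log2_fc"].transform(
        "median"
    )
    if use_mature_factors_for_nascent:
        mature = df[df["pool"] == "mature"]
        factors = mature.groupby(["condition", "replicate"])["log2_fc"].median()
        is_nascent = df["pool"] == "nascent"
        keys = pd.MultiIndex.from_frame(df.loc[is_nascent, ["condition", "replicate"]])
        med = med.copy()
        med.loc[is_nascent] = factors.reindex(keys).to_numpy()
    df["log2_fc"] = df["log2_fc"] - med
    return df


def bin_by_ssm(
    proteins: pd.DataFrame,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    key: str = "n_ssm",
) -> list[Bin]:
    """Greedy data-quality binning by spectral support.

    Proteins are sorted ascending by ``key`` (ties broken by protein
    identifier for reproducibility) and cut into consecutive bins of
    ``min_bin_size``; the remainder is merged into the last
    (highest-support) bin so every bin holds at least ``min_bin_size``
    proteins.  Fewer than ``min_bin_size`` proteins in total yield a
    single bin with a warning.
    """
    if len(proteins) == 0:
        raise ValueError("cannot bin an empty protein table")
    ordered = proteins.sort_values([key, "protein_group"], kind="mergesort")
    n = len(ordered)
    n_bins = n // min_bin_size
    if n_bins == 0:
        warnings.warn(
            f"only {n} proteins in total (< {min_bin_size}); using a single bin",
            stacklevel=2,
        )
        n_bins = 1
    bounds = [i * min_bin_size for i in range(n_bins)] + [n]
    bins = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chunk = ordered.iloc[lo:hi]
        bins.append(
            Bin(
                protein_groups=chunk["protein_group"].tolist(),
                key_min=float(chunk[key].min()),
                key_max=float(chunk[key].max()),
            )
        )
    return bins


def robust_sd(rep1, rep2) -> float:
    """Robust SD of a single replicate measurement from paired replicates.

    For each protein the replicate difference d = (x1 - x2)/sqrt(2) is the
    shortest distance to the replicate-equality line; under i.i.d. noise
    its SD equals the per-measurement SD.  The spread of d is estimated
    robustly as half the distance between the 15.87th and 84.13th
    percentiles (the +-1 SD quantiles of a normal) after median-centering,
    making the estimate insensitive to genuinely regulated outliers.
    """
    d = (np.asarray(rep1, dtype=float) - np.asarray(rep2, dtype=float)) / math.sqrt(2)
    if d.size < 2:
        raise ValueError("robust SD needs at least 2 replicate pairs")
    d = d - np.median(d)
    lo, hi = np.percentile(d, [_LOWER_PCTL, _UPPER_PCTL])
    return float((hi - lo) / 2.0)


def z_test_p(log2_fc, sd: float):
    """Two-sided Z-test p-value of a log2 fold change against a null SD."""
    if sd <= 0:
        raise ValueError(f"robust SD must be positive, got {sd}")
    z = np.abs(np.asarray(log2_fc, dtype=float)) / sd
    return 2.0 * stats.norm.sf(z)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    calls: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Dual-replicate significance verdicts.

    ``calls`` is wide-format, one row per protein/condition/pool, with
    columns ``log2_fc_rep1``, ``log2_fc_rep2``, ``adj_p_rep1``,
    ``adj_p_rep2``.  A protein is significant iff the adjusted p-value is
    <= ``alpha`` in both replicates, |log2 FC| is strictly greater than
    ``fc_threshold`` in both, and the sign agrees.  Rows with a missing
    replicate are never significant and flagged incomplete.
    """
    out = calls.copy()
    fc1 = out["log2_fc_rep1"].to_numpy(dtype=float)
    fc2 = out["log2_fc_rep2"].to_numpy(dtype=float)
    p1 = out["adj_p_rep1"].to_numpy(dtype=float)
    p2 = out["adj_p_rep2"].to_numpy(dtype=float)
    incomplete = ~(
        np.isfinite(fc1) & np.isfinite(fc2) & np.isfinite(p1) & np.isfinite(p2)
    )
    with np.errstate(invalid="ignore"):
        sig = (
            (p1 <= alpha)
            & (p2 <= alpha)
            & (np.abs(fc1) > fc_threshold)
            & (np.abs(fc2) > fc_threshold)
            & (np.sign(fc1) == np.sign(fc2))
        )
    sig &= ~incomplete
    direction = np.where(sig, np.where(fc1 > 0, "up", "down"), "none")
    out["significant"] = sig
    out["direction"] = direction
    out["incomplete"] = incomplete
    return out


def analyze(
    fold_changes: pd.DataFrame,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    use_mature_factors_for_nascent: bool = False,
    normalize: bool = True,
) -> pd.DataFrame:
    """Run the full significance framework on a long fold-change table.

    ``fold_changes`` columns: ``protein_group``, ``condition``, ``pool``,
    ``replicate`` (1 or 2), ``log2_fc``, ``n_ssm``.  Returns one row per
    protein/condition/pool with per-replicate p and BH-adjusted p (BH is
    applied per condition and pool, jointly across all bins) plus the
    dual-replicate verdict.
    """
    df = fold_changes
    if normalize:
        df = median_normalize(df, use_mature_factors_for_nascent)

    wide = df.pivot_table(
        index=["condition", "pool", "protein_group"],
        columns="replicate",
        values=["log2_fc", "n_ssm"],
        aggfunc="first",
    )
    results = []
    for (condition, pool), grp in wide.groupby(level=["condition", "pool"]):
        grp = grp.droplevel(["condition", "pool"])
        tbl = pd.DataFrame(
            {
                "protein_group": grp.index,
                "log2_fc_rep1": grp[("log2_fc", 1)].to_numpy(),
                "log2_fc_rep2": grp[("log2_fc", 2)].to_numpy(),
                "n_ssm": grp["n_ssm"].min(axis=1).to_numpy(),
            }
        )
        complete = tbl.dropna(subset=["log2_fc_rep1", "log2_fc_rep2", "n_ssm"])
        tbl["p_rep1"] = np.nan
        tbl["p_rep2"] = np.nan
        if len(complete) >= 2:
            bins = bin_by_ssm(complete, min_bin_size=min_bin_size)
            sd_by_protein = {}
            for b in bins:
                members = complete.set_index("protein_group").loc[b.protein_groups]
                b.robust_sd = robust_sd(
                    members["log2_fc_rep1"], members["log2_fc_rep2"]
                )
                if b.robust_sd <= 0:
                    logger.warning(
                        "bin with zero replicate spread (n_ssm %g-%g); "
                        "p-values undefined for its members",
                        b.key_min,
                        b.key_max,
                    )
                for pg in b.protein_groups:
                    sd_by_protein[pg] = b.robust_sd
            sd = tbl["protein_group"].map(sd_by_protein)
            ok = sd.notna() & (sd > 0)
            for rep in (1, 2):
                # bin SD varies per protein, so form the z-scores directly
                z = tbl.loc[ok, f"log2_fc_rep{rep}"].to_numpy() / sd[ok].to_numpy()
                tbl.loc[ok, f"p_rep{rep}"] = 2.0 * stats.norm.sf(np.abs(z))
        for rep in (1, 2):
            p = tbl[f"p_rep{rep}"]
            adj = np.full(len(tbl), np.nan)
            mask = p.notna().to_numpy()
            if mask.any():
                adj[mask] = bh_adjust(p[mask].to_numpy())
            tbl[f"adj_p_rep{rep}"] = adj
        tbl.insert(0, "condition", condition)
        tbl.insert(1, "pool", pool)
        results.append(tbl)

    combined = pd.concat(results, ignore_index=True)
    return call_significant(combined, fc_threshold=fc_threshold, alpha=alpha)
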