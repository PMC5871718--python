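"""Spectrum-level quantification of isobaric reporter-ion and SILAC data.

The atomic unit of quantification is the PSM (peptide-spectrum match).
Reporter-ion intensities are converted to *ion areas* (intensity x ion
accumulation time, proportional to the number of ions), spectra are
filtered on identification and interference quality, reporter channels
are corrected for isotope impurity and precursor co-isolation, and
protein-level relative abundances are obtained by a sum-based bootstrap
over spectra.  Precursor-intensity (SILAC) quantification summarises
peptide heavy/light ratios by the median over valid peptides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default spectrum-quality thresholds; all applied as strict inequalities
MIN_ION_SCORE = 15.0
MIN_S2B = 4.0
MIN_S2I = 0.5

#: PSM table schema. Reporter intensity columns are named ``intensity_<channel>``.
PSM_COLUMNS = [
    "protein_group",
    "peptide_sequence",
    "is_unique",
    "silac_channel",
    "replicate",
    "identification_score",
    "precursor_s2b",
    "s2i",
    "accumulation_time",
    "peptide_length",
]


def reporter_columns(psms: pd.DataFrame) -> list[str]:
    """Names of the reporter-intensity columns present in a PSM table."""
    return [c for c in psms.columns if c.startswith("intensity_")]


@dataclass
class ProteinQuant:
    """Protein-level relative quantification from the spectra of one protein.

    Fold changes are ratios of per-channel ion-area sums relative to the
    reference channel.  95% bootstrap confidence intervals are attached only
    when the protein was quantified with more than three spectra.
    """

    protein_group: str
    reference_channel: str
    channel_sums: dict[str, float]
    fold_changes: dict[str, float]
    ci_low: dict[str, float] | None
    ci_high: dict[str, float] | None
    n_spectra: int
    n_unique_peptides: int
    flags: list[str] = field(default_factory=list)


def compute_ion_areas(intensities, accumulation_time_ms: float) -> np.ndarray:
    """Ion areas: reporter intensities scaled by the ion accumulation time.

    The product of intensity and accumulation time (milliseconds) is
    proportional to the number of ions collected, and is the quantity all
    downstream sums operate on.

    Raises
    ------
    ValueError
        if the accumulation time is not strictly positive.
    """
    if accumulation_time_ms <= 0:
        raise ValueError(
            f"non-positive ion accumulation time ({accumulation_time_ms} ms); "
            "record rejected"
        )
    return np.asarray(intensities, dtype=float) * accumulation_time_ms


def ion_area_table(psms: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ion-area computation over a PSM table.

    Returns a copy in which each ``intensity_<channel>`` column has been
    multiplied by the row's accumulation time.  Rows with non-positive
    accumulation times are dropped with a warning.
    """
    bad = psms["accumulation_time"] <= 0
    if bad.any():
        logger.warning(
            "dropping %d PSMs with non-positive accumulation time", int(bad.sum())
        )
        psms = psms.loc[~bad]
    out = psms.copy()
    cols = reporter_columns(psms)
    out[cols] = out[cols].to_numpy(dtype=float) * out[
        "accumulation_time"
    ].to_numpy(dtype=float)[:, None]
    return out


def filter_psms(
    psms: pd.DataFrame,
    min_score: float = MIN_ION_SCORE,
    min_s2b: float = MIN_S2B,
    min_s2i: float = MIN_S2I,
) -> pd.DataFrame:
    """Spectrum-quality filter: ion score, precursor signal-to-background
    and signal-to-interference must all *strictly* exceed their thresholds.

    Boundary values are rejected.  An empty result is allowed.
    """
    keep = (
        (psms["identification_score"] > min_score)
        & (psms["precursor_s2b"] > min_s2b)
        & (psms["s2i"] > min_s2i)
    )
    return psms.loc[keep]


def correct_isotope_purity(areas, purity) -> np.ndarray:
    """Undo reporter-channel isotope-impurity mixing.

    ``purity`` is the square mixing matrix with rows = observed channel and
    columns = true channel, so observed = purity @ true.  The correction
    solves that linear system; negative components (possible with noisy
    observations) are clipped to zero with a warning.
    """
    areas = np.asarray(areas, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if purity.shape != (areas.size, areas.size):
        raise ValueError(
            f"purity matrix shape {purity.shape} does not match "
            f"{areas.size} reporter channels"
        )
    try:
        true = np.linalg.solve(purity, areas)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular isotope purity matrix:\n{purity}") from err
    if (true < 0).any():
        warnings.warn(
            "isotope purity correction produced negative channel areas; "
            "clipped to 0",
            stacklevel=2,
        )
        true = np.clip(true, 0.0, None)
    return true


def adjust_interference(
    fold_change: float, s2i: float, background_ratio: float = 1.0
) -> float:
    """De-mix a reporter fold change for precursor co-isolation.

    Model: in each reporter channel the observed signal is
    ``s2i * target + (1 - s2i) * background`` with the background at
    ``background_ratio`` (default 1.0, unregulated) and the same
    denominator-channel scale as the target, so

        observed_ratio = s2i * true_ratio + (1 - s2i) * background_ratio

    which is inverted here.  At ``s2i == 1`` the input is returned
    unchanged; ``s2i == 0`` carries no target signal and is undefined.
    """
    if not 0 < s2i <= 1:
        raise ValueError(f"s2i must be in (0, 1], got {s2i}; record excluded")
    true = (fold_change - (1.0 - s2i) * background_ratio) / s2i
    if true < 0:
        warnings.warn(
            "interference adjustment produced a negative ratio; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    return true


def bootstrap_protein_quant(
    psms: pd.DataFrame,
    reference_channel: str,
    n_boot: int = 1000,
    seed: int | None = 0,
    min_unique_peptides: int = 2,
    min_spectra_for_ci: int = 4,
) -> ProteinQuant | None:
    """Sum-based bootstrap protein quantification from filtered PSMs.

    The point estimate for each channel is the ratio of per-channel
    ion-area sums to the reference channel's sum.  Confidence intervals are
    2.5/97.5 percentile intervals over ``n_boot`` resamples of whole spectra
    (with replacement) and are attached only when more than three spectra
    support the protein.

    Returns ``None`` when the protein has fewer than ``min_unique_peptides``
    distinct unique-peptide sequences (protein not reliably identified).
    """
    if len(psms) == 0:
        raise ValueError("no PSMs supplied")
    n_unique = psms.loc[psms["is_unique"].astype(bool), "peptide_sequence"].nunique()
    if n_unique < min_unique_peptides:
        return None

    cols = reporter_columns(psms)
    ref_col = f"intensity_{reference_channel}"
    if ref_col not in cols:
        raise ValueError(f"reference channel {reference_channel!r} not in table")
    areas = psms[cols].to_numpy(dtype=float)
    sums = areas.sum(axis=0)
    channels = [c.removeprefix("intensity_") for c in cols]
    ref_idx = cols.index(ref_col)
    flags = []
    if sums[ref_idx] <= 0:
        flags.append("zero_reference_sum")
        fc = np.full(len(cols), np.nan)
    else:
        fc = sums / sums[ref_idx]

    n = len(psms)
    ci_low = ci_high = None
    if n >= min_spectra_for_ci and sums[ref_idx] > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_sums = areas[idx].sum(axis=1)  # (n_boot, n_channels)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_fc = boot_sums / boot_sums[:, [ref_idx]]
        lo, hi = np.nanpercentile(boot_fc, [2.5, 97.5], axis=0)
        ci_low = dict(zip(channels, lo))
        ci_high = dict(zip(channels, hi))

    return ProteinQuant(
        protein_group=str(psms["protein_group"].iloc[0]),
        reference_channel=reference_channel,
        channel_sums=dict(zip(channels, sums)),
        fold_changes=dict(zip(channels, fc)),
        ci_low=ci_low,
        ci_high=ci_high,
        n_spectra=n,
        n_unique_peptides=int(n_unique),
        flags=flags,
    )


def silac_protein_ratio(
    peptides: pd.DataFrame,
    min_score: float = MIN_ION_SCORE,
    min_length: int = 6,
    max_lsq_fit: float = 0.1,
    max_prior_ion_ratio: float = 0.2,
) -> float:
    """Protein heavy/light ratio: median over valid SILAC peptide ratios.

    A peptide is valid when its identification score exceeds ``min_score``,
    its length is at least ``min_length``, the least-squares fit quality of
    the light/heavy pair is at most ``max_lsq_fit`` and its prior ion ratio
    is at most ``max_prior_ion_ratio``.  Peptides with an undetermined
    (NaN) ratio are excluded from the median as soon as at least one
    positive ratio exists; with no positive ratio at all the protein is
    unquantified (NaN).
    """
    valid = peptides.loc[
        (peptides["identification_score"] > min_score)
        & (peptides["peptide_length"] >= min_length)
        & (peptides["lsq_fit_quality"] <= max_lsq_fit)
        & (peptides["prior_ion_ratio"] <= max_prior_ion_ratio)
    ]
    ratios = valid["ratio"]
    positive = ratios[ratios > 0]
    if positive.empty:
        return float("nan")
    return float(positive.median())


def impute_missing_abundance(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing abundances by half the experiment-wide minimum.

    Proteins robustly quantified in one condition can escape identification
    in the paired condition when strongly downregulated; a global proxy of
    half the smallest detected relative abundance lets the fold change be
    formed while recording the direction of the loss.

    Returns the imputed table and a boolean mask of imputed cells.
    """
    values = table.to_numpy(dtype=float)
    if np.isnan(values).all():
        raise ValueError("cannot impute: no detected abundances in the table")
    proxy = np.nanmin(values) / 2.0
    mask = table.isna()
    return table.fillna(proxy), mask


def donor_consistency_filter(
    table: pd.DataFrame,
    max_discordance: float = 8.0,
    min_ssm: int = 3,
) -> pd.DataFrame:
    """Remove proteins with discordant donors or too little spectral support.

    ``table`` is long-format with columns ``protein_group``, ``condition``,
    ``donor``, ``fold_change`` and ``n_ssm``.  A protein is dropped when its
    between-donor fold changes in any condition differ by more than
    ``max_discordance``-fold, or when any of its quantifications rests on
    fewer than ``min_ssm`` spectrum-sequence matches.
    """

    def _ok(group: pd.DataFrame) -> bool:
        if (group["n_ssm"] < min_ssm).any():
            return False
        for _, cond in group.groupby("condition"):
            fc = cond["fold_change"].to_numpy(dtype=float)
            fc = fc[np.isfinite(fc) & (fc > 0)]
            if fc.size >= 2 and fc.max() / fc.min() > max_discordance:
                return False
        return True

    keep = table.groupby("protein_group", sort=False).apply(
        _ok, include_groups=False
    )
    return table.loc[table["protein_group"].map(keep)]
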