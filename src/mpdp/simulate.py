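"""Seeded synthetic data generators with known ground truth.

Every analysis stage of the package can be exercised without any
download: this module emulates the pulsed-SILAC + isobaric-tag design
(pre-existing proteins decay exponentially, newly synthesized proteins
accumulate after the medium switch, treatments act multiplicatively on
degradation and/or synthesis rates, and two biological replicates carry
opposite label orientations), the per-PSM reporter noise and
spectral-count heterogeneity of real runs, and sigmoidal melting /
dose-response behaviour for thermal profiling.

All generators are pure functions of their configuration and seed:
the same inputs always yield byte-identical tables.  Ground-truth tables
sharing the protein identifiers accompany every generated dataset.

Not modelled: amino-acid recycling / partial label incorporation (full
incorporation is assumed), spectrum-level detail (m/z peaks, isotope
envelopes) and chromatography effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import thermal

LN2 = math.log(2.0)

#: default temperature gradient: 12 temperatures across 42.0-63.9 degC
DEFAULT_TEMPERATURES = np.round(np.linspace(42.0, 63.9, 12), 1)

#: default dose series, molar, vehicle first
DEFAULT_CONCENTRATIONS = np.array([0.0, 0.1e-6, 1e-6, 5e-6, 20e-6])

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimProteinSpec:
    """Ground-truth kinetics of one simulated protein.

    ``synthesis_rate`` (abundance units/h) and ``degradation_rate`` (1/h)
    define the untreated steady state M0 = s/k.  Treatment multipliers
    act on k and s from treatment time zero; multipliers of 1 mean no
    effect.  ``noise_sd`` is the per-channel reporter noise on the log2
    scale; ``mean_n_ssm`` sets the expected spectral support.
    """

    protein_id: str
    synthesis_rate: float = 10.0
    degradation_rate: float = 0.08
    k_multipliers: dict = field(default_factory=dict)
    s_multipliers: dict = field(default_factory=dict)
    mean_n_ssm: float = 8.0
    noise_sd: float = 0.25


@dataclass
class SimExperiment:
    """Design of one simulated mPDP run.

    Two biological replicates with opposite SILAC label orientation:
    replicate 1 has the mature pool light and the nascent pool heavy,
    replicate 2 the reverse.  Each condition (plus vehicle) occupies one
    isobaric reporter channel; all conditions share the treatment /
    labeling time.
    """

    conditions: list
    treatment_time: float = 6.0  # hours of treatment == labeling time
    seed: int = 0
    quality_fail_fraction: float = 0.1

    @property
    def channels(self) -> list:
        return ["vehicle"] + list(self.conditions)

    def pool_channel(self, replicate: int, pool: str) -> str:
        swap = {"mature": "heavy", "nascent": "light"}
        base = {"mature": "light", "nascent": "heavy"}
        return (base if replicate == 1 else swap)[pool]


def simulate_pools(
    spec: SimProteinSpec, times, condition: str = "vehicle"
) -> tuple[np.ndarray, np.ndarray]:
    """True mature and nascent abundances over time under one condition.

    Starting from the untreated steady state M0 = s/k, the mature pool
    decays as M0 * exp(-k_c t) and the nascent pool accumulates as
    (s_c/k_c) * (1 - exp(-k_c t)), with the condition's multipliers
    applied to k and s from t = 0.
    """
    t = np.asarray(times, dtype=float)
    k = spec.degradation_rate
    s = spec.synthesis_rate
    if k <= 0:
        raise ValueError("degradation rate must be positive")
    k_c = k * spec.k_multipliers.get(condition, 1.0)
    s_c = s * spec.s_multipliers.get(condition, 1.0)
    m0 = s / k
    mature = m0 * np.exp(-k_c * t)
    nascent = (s_c / k_c) * (1.0 - np.exp(-k_c * t))
    return mature, nascent


def _random_peptides(rng: np.random.Generator, n: int, length: int = 10):
    idx = rng.integers(0, len(_AMINO_ACIDS), size=(n, length))
    return ["".join(_AMINO_ACIDS[row]) for row in idx]


def ground_truth_fold_changes(
    specs: list[SimProteinSpec], experiment: SimExperiment
) -> pd.DataFrame:
    """True log2 fold changes (condition vs vehicle) per protein and pool."""
    t = experiment.treatment_time
    rows = []
    for spec in specs:
        m_v, n_v = simulate_pools(spec, [t], "vehicle")
        for cond in experiment.conditions:
            m_c, n_c = simulate_pools(spec, [t], cond)
            for pool, c, v in (("mature", m_c[0], m_v[0]), ("nascent", n_c[0], n_v[0])):
                rows.append(
                    {
                        "protein_group": spec.protein_id,
                        "condition": cond,
                        "pool": pool,
                        "true_log2_fc": math.log2(c / v),
                    }
                )
    return pd.DataFrame(rows)


def emit_psm_table(
    experiment: SimExperiment,
    specs: list[SimProteinSpec],
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated PSM table in the schema the quant module consumes.

    Per replicate and protein, the number of spectra per pool follows a
    long-tailed negative-binomial-like distribution (to exercise the
    >= 300 binning downstream); each spectrum's reporter intensities are
    the true pool abundances under each channel's condition, scaled by a
    shared spectrum intensity factor and independent per-channel lognormal
    noise.  Identification score, signal-to-background and
    signal-to-interference are drawn so that about
    ``experiment.quality_fail_fraction`` of spectra fail the default
    quality filters.  Deterministic given the seed.
    """
    rng = np.random.default_rng(experiment.seed if seed is None else seed)
    t = experiment.treatment_time
    channels = experiment.channels
    ln2_sd = LN2  # converts log2-scale SD to natural-log scale

    records: dict[str, list] = {c: [] for c in [
        "protein_group", "peptide_sequence", "is_unique", "silac_channel",
        "replicate", "identification_score", "precursor_s2b", "s2i",
        "accumulation_time", "peptide_length",
    ]}
    intensity_cols: dict[str, list] = {f"intensity_{c}": [] for c in channels}

    for spec in specs:
        abund = {}
        for cond in channels:
            m, n = simulate_pools(spec, [t], cond)
            abund[cond] = {"mature": m[0], "nascent": n[0]}
        # long-tailed spectral support, at least 1 per pool
        p_nb = 2.0 / (2.0 + spec.mean_n_ssm)
        for replicate in (1, 2):
            n_ssm = 1 + rng.negative_binomial(2, p_nb)
            peptides = _random_peptides(rng, max(2, math.ceil(n_ssm / 3)))
            for pool_i, pool in enumerate(("mature", "nascent")):
                silac = experiment.pool_channel(replicate, pool)
                pep_idx = rng.integers(0, len(peptides), size=n_ssm)
                # emulate identified proteins: each replicate run carries at
                # least two distinct peptides across its two SILAC pools
                pep_idx[0] = pool_i
                scale = rng.lognormal(mean=math.log(1e4), sigma=1.0, size=n_ssm)
                fails = rng.random(n_ssm) < experiment.quality_fail_fraction
                which = rng.integers(0, 3, size=n_ssm)
                score = np.where(
                    fails & (which == 0),
                    rng.uniform(5, 15, n_ssm),
                    rng.uniform(20, 80, n_ssm),
                )
                s2b = np.where(
                    fails & (which == 1),
                    rng.uniform(1, 4, n_ssm),
                    rng.uniform(5, 50, n_ssm),
                )
                s2i = np.where(
                    fails & (which == 2),
                    rng.uniform(0.1, 0.5, n_ssm),
                    rng.uniform(0.55, 1.0, n_ssm),
                )
                acc = rng.uniform(5, 100, n_ssm)
                noise = rng.lognormal(
                    mean=0.0,
                    sigma=spec.noise_sd * ln2_sd,
                    size=(n_ssm, len(channels)),
                )
                for ci, cond in enumerate(channels):
                    vals = abund[cond][pool] * scale * noise[:, ci]
                    intensity_cols[f"intensity_{cond}"].extend(vals)
                records["protein_group"].extend([spec.protein_id] * n_ssm)
                records["peptide_sequence"].extend(
                    [peptides[i] for i in pep_idx]
                )
                records["is_unique"].extend([True] * n_ssm)
                records["silac_channel"].extend([silac] * n_ssm)
                records["replicate"].extend([replicate] * n_ssm)
                records["identification_score"].extend(score)
                records["precursor_s2b"].extend(s2b)
                records["s2i"].extend(s2i)
                records["accumulation_time"].extend(acc)
                records["peptide_length"].extend(
                    [len(peptides[i]) for i in pep_idx]
                )

    return pd.DataFrame({**records, **intensity_cols})


def make_protein_specs(
    n_proteins: int,
    seed: int = 0,
    conditions: list | None = None,
    k_multiplier_by_protein: dict | None = None,
    s_multiplier_by_protein: dict | None = None,
    noise_sd: float = 0.25,
    mean_n_ssm: float = 8.0,
) -> list[SimProteinSpec]:
    """A population of protein specs with realistic turnover spread.

    Degradation rates are drawn lognormally around a ~10 h half-life,
    synthesis rates lognormally around 10 units/h.  Effect dictionaries
    map protein id -> multiplier applied in every listed condition.
    """
    rng = np.random.default_rng(seed)
    conditions = conditions or []
    k_eff = k_multiplier_by_protein or {}
    s_eff = s_multiplier_by_protein or {}
    specs = []
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        k = float(rng.lognormal(mean=math.log(LN2 / 10.0), sigma=0.6))
        s = float(rng.lognormal(mean=math.log(10.0), sigma=0.8))
        km = {c: k_eff.get(pid, 1.0) for c in conditions}
        sm = {c: s_eff.get(pid, 1.0) for c in conditions}
        specs.append(
            SimProteinSpec(
                protein_id=pid,
                synthesis_rate=s,
                degradation_rate=k,
                k_multipliers=km,
                s_multipliers=sm,
                mean_n_ssm=mean_n_ssm,
                noise_sd=noise_sd,
            )
        )
    return specs


def simulate_melting_fold_changes(
    a: float,
    b: float,
    plateau: float,
    temperatures=DEFAULT_TEMPERATURES,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Fold changes from the melting model plus Gaussian noise.

    The model value is already on the relative (fraction non-denatured)
    scale, so no further normalisation is applied.
    """
    rng = np.random.default_rng(seed)
    T = np.asarray(temperatures, dtype=float)
    y = thermal.melting_curve(T, a, b, plateau)
    return y + rng.normal(0.0, noise_sd, size=T.size)


def melting_params_for_tm(
    tm: float, inflection: float = -0.1, plateau: float = 0.05
) -> tuple[float, float, float]:
    """Melting-model constants (a, b, plateau) with the given melting point
    and approximate inflection slope (1/degC)."""
    a = -inflection * 4.0 * tm**2 / (1.0 - plateau)
    b = a / tm + math.log(0.5 / (0.5 - plateau))
    return a, b, plateau


def emit_thermal_tr(
    n_proteins: int,
    seed: int = 0,
    temperatures=DEFAULT_TEMPERATURES,
    noise_sd: float = 0.01,
    dtm_by_protein: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPP-TR fold-change tables for a label-swap replicate design.

    Four experiments per protein (vehicle and treatment, two replicate
    pairs: v1/t1/v2/t2).  Treatment curves of proteins listed in
    ``dtm_by_protein`` are shifted by the given melting-point difference
    (degrees C); all other proteins are nulls.  Small replicate-to-
    replicate Tm jitter is applied to every curve.  Returns the long
    fold-change table and the ground-truth parameter table.
    """
    rng = np.random.default_rng(seed)
    dtm_by_protein = dtm_by_protein or {}
    rows = []
    truth = []
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        tm0 = float(rng.uniform(46.0, 58.0))
        infl = float(rng.uniform(-0.15, -0.08))
        pl = float(rng.uniform(0.0, 0.15))
        dtm = float(dtm_by_protein.get(pid, 0.0))
        truth.append({"protein_group": pid, "tm": tm0, "true_dtm": dtm,
                      "inflection": infl, "plateau": pl})
        for exp_name, shift in (
            ("v1", 0.0), ("t1", dtm), ("v2", 0.0), ("t2", dtm)
        ):
            jitter = float(rng.normal(0.0, 0.15))
            a, b, plateau = melting_params_for_tm(tm0 + shift + jitter, infl, pl)
            y = thermal.melting_curve(
                np.asarray(temperatures, dtype=float), a, b, plateau
            ) + rng.normal(0.0, noise_sd, size=len(temperatures))
            for T, fc in zip(temperatures, y):
                rows.append(
                    {
                        "protein_group": pid,
                        "experiment": exp_name,
                        "temperature": T,
                        "fold_change": fc,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_dose_response(
    log_ec50: float,
    slope: float,
    concentrations=DEFAULT_CONCENTRATIONS,
    noise_sd: float = 0.02,
    seed: int = 0,
    vehicle_pseudo_decades: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Transformed apparent-stability responses from the dose-response
    model plus Gaussian noise.

    Returns ``(x, y)`` with x = log10 concentration (vehicle placed at a
    pseudo-dose below the tested range, matching the fitting convention).
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    nonzero = conc > 0
    min_conc = conc[nonzero].min()
    x = np.where(
        nonzero,
        np.log10(np.where(nonzero, conc, min_conc)),
        math.log10(min_conc) - vehicle_pseudo_decades,
    )
    y = thermal.dose_response_curve(x, log_ec50, slope)
    y = y + rng.normal(0.0, noise_sd, size=x.size)
    return x, y


def emit_thermal_2d(
    n_proteins: int,
    seed: int = 0,
    concentrations=DEFAULT_CONCENTRATIONS,
    noise_sd: float = 0.02,
    effects: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2D-TPP fold-change tables (one temperature layer).

    ``effects`` maps protein id -> (direction, log_ec50, amplitude) where
    direction is 'stabilized' or 'destabilized' and amplitude is the
    top-dose fold change (> 3/2 or < 2/3 respectively).  Proteins without
    an entry have no compound effect.  Fold changes are relative to
    vehicle (vehicle fold change 1 by construction).
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    conc = np.asarray(concentrations, dtype=float)
    nonzero = conc > 0
    min_conc = conc[nonzero].min()
    x = np.where(
        nonzero,
        np.log10(np.where(nonzero, conc, min_conc)),
        math.log10(min_conc) - 2.0,
    )
    rows = []
    truth = []
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        eff = effects.get(pid)
        if eff is None:
            fc = np.ones_like(conc)
            truth.append({"protein_group": pid, "direction": "none",
                          "true_pec50": np.nan})
        else:
            direction, log_ec50, amplitude = eff
            y = thermal.dose_response_curve(x, log_ec50, 1.0)
            fc = 1.0 + (amplitude - 1.0) * y
            truth.append({"protein_group": pid, "direction": direction,
                          "true_pec50": -log_ec50})
        fc = fc + rng.normal(0.0, noise_sd, size=conc.size)
        fc[conc == 0] = 1.0  # fold changes are defined relative to vehicle
        for c, v in zip(conc, fc):
            rows.append(
                {
                    "protein_group": pid,
                    "concentration": c,
                    "fold_change": v,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth)
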