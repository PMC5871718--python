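# Methods

## The measurement model

A pulsed-SILAC experiment switches cells from light to heavy amino acids
at treatment start. Proteins made before the switch (the *mature* pool)
carry the light label and decay; proteins made after it (the *nascent*
pool) carry the heavy label and accumulate. With first-order synthesis s
and degradation k and a pre-switch steady state M0 = s/k,

    mature(t)  = M0 · e^(−k t)
    nascent(t) = (s/k) · (1 − e^(−k t))

so the nascent/mature ratio is r(t) = e^(k t) − 1 when treatment leaves s
and k unchanged, and ln(r + 1) is linear in t through the origin. Both
pools are quantified in one MS run: each condition occupies one isobaric
reporter channel and the SILAC label separates the pools. The biological
duplicate swaps the label orientation so that label-specific artefacts
appear with opposite sign in the two replicates.

Assumptions: full and immediate label incorporation, time-invariant rates
within a condition, and multiplicative (lognormal) reporter noise.

## Quantification

Reporter intensities are multiplied by the ion accumulation time (ms) to
give ion areas proportional to ion counts; protein-level sums of ion
areas are therefore count-weighted rather than spectrum-averaged.
Spectrum filters (ion score > 15, precursor S/B > 4, S2I > 0.5) are
strict inequalities; boundary values are rejected. Isotope-impurity
correction solves the linear mixing system observed = P·true and clips
negative solutions to zero. Interference adjustment inverts the mixing
model observed_ratio = s2i·true + (1 − s2i)·background with the
background ratio defaulting to 1 (unregulated co-eluting material);
the background ratio is configurable per experiment because the
co-isolated population need not be null in heavily regulated samples.

The bootstrap resamples whole spectra with replacement (default 1,000
resamples, 2.5/97.5 percentile interval, seeded generator recorded in the
output). The resample count and percentile method are package choices;
intervals are only attached to proteins with more than three spectra,
below which a percentile interval is not meaningful. Protein
identification requires two distinct unique peptides per MS run —
identification is a run-level property, so a pool quantified by a single
spectrum is retained as long as the run identifies the protein.

## Significance framework

The null SD is estimated from replicate disagreement, not from the
population spread, so the test remains calibrated when a large fraction
of proteins is genuinely regulated (the motivation for carrying mature
normalisation factors to the nascent pool under strong synthesis
inhibition). The estimator is half the 15.87–84.13 percentile spread of
the median-centred replicate differences divided by √2: those
percentiles are the ±1 SD quantiles of a normal, making the estimator
exact under normality and insensitive to a small fraction of true
regulation. Percentiles use linear interpolation between order
statistics.

Binning by spectral support uses greedy ascending bins of ≥ 300
proteins with the remainder merged into the highest-support bin; ties
break on the protein identifier so runs are reproducible. Each protein's
binning key is the minimum spectrum count across its two replicates (the
quality-limiting replicate). BH adjustment is applied per condition and
pool, jointly across all bins, separately per replicate. With fewer than
300 proteins in total a single bin is used and a warning emitted.

The fold-change cutoff defaults to 0.37 on the log2 scale. A 30% change
corresponds to log2(1.3) = 0.3785…; the published constant truncates
this to two decimals and the package keeps 0.37 as the default while
leaving it configurable.

## Turnover

k_dp is the through-origin least-squares slope of ln(r+1) on t, computed
over the time points with a defined ratio; R² uses the uncentred total
sum of squares (the through-origin convention), matching the model
actually fitted rather than a free-intercept regression. The cell-cycle
correction subtracts the growth dilution rate ln2/t_cc; t_cc is a
required user input (hours) because no default generalises across cell
types, and proteins whose apparent decay does not exceed dilution are
flagged rather than assigned a negative rate. QC: 'good' needs ≥ 3 of
the 4 design time points supported by ≥ 3 peptides; 'weak' needs a
defined fold change at ≥ 3 points; 'good' takes precedence.

## Thermal profiling

The melting sigmoid is implemented with exponent b − a/T, the decreasing
form consistent with thermal denaturation and with Tm defined at
f(T) = 0.5; an increasing literal variant is available behind a flag for
comparison only. Tm has the closed form a/(b − ln(0.5/(0.5 − plateau))),
defined only for plateau < 0.5, and is cross-checked in the test suite
against numerical root finding. Fits use fixed multi-start initialisation
(plateau ∈ {0, 0.1, 0.3}; b from the half-maximum temperature; a from the
steepest local slope), plateau bounded to [0, 1), tolerances 1e−10 —
there is no randomness in the fitting path.

Melting-point shift calls require R² > 0.8 for all four curves and
vehicle plateaus < 0.3, bin eligible proteins by their shallowest slope
(≥ 300 per bin, shallow first — shallow curves give noisier melting
points), apply a z-test per bin with the same robust percentile SD as
the mPDP framework, and BH-adjust across the full set. The p-value
criteria (one adjusted p < 0.05, the other < 0.1), direction agreement,
both |ΔTm| above the vehicle–vehicle difference, and pair-wise minimum
slope < −0.06 must all hold.

Dose-response series are classified by the top-dose fold change (> 3/2
stabilized, < 2/3 destabilized, otherwise excluded), min-max transformed
to [0, 1], and fitted on x = log10 molar concentration. The vehicle
point enters at a pseudo-dose two decades below the lowest tested
concentration, since zero has no logarithm; placing it further away
changes fitted pEC50 values by far less than the acceptance tolerance.
Fits are accepted at R² > 0.8; a pEC50 whose EC50 falls below the lowest
tested dose is reported but flagged invalid, because it is an
extrapolation outside the measured range.

## Synthetic data

The generators emulate: steady-state initial conditions, treatment
multipliers on k and s acting from t = 0, label-swap duplicates,
long-tailed spectral support (negative-binomial, mean 8 spectra per pool
per run) to exercise the ≥ 300 binning, per-channel lognormal reporter
noise (default SD 0.25 on the log2 scale, a typical reporter-ion spread),
a configurable fraction of spectra failing the quality filters (default
10%), and melting/dose-response behaviour with known Tm and pEC50.
Protein baseline rates are lognormal around a 10 h half-life and
10 units/h synthesis. Every generator is a pure function of its
configuration and seed, and every dataset ships with a ground-truth
table keyed by the same protein identifiers.

Not emulated: amino-acid recycling and partial label incorporation,
abundance-dependent identification loss, co-isolation structure between
specific proteins, retention-time or batch effects. Passing tests on
this data therefore demonstrate correctness of the statistical machinery
under its stated assumptions, not robustness to those real-data
artefacts.

## Problem sizes and determinism

The test suite runs null and spike-in mPDP experiments at 1,000–2,000
proteins, thermal-shift experiments at 320 proteins, robust-SD recovery
at 100,000 pairs and the bootstrap coverage study at 150 repetitions of
50 spectra — sizes chosen so the full suite completes in a few minutes
on a single core while keeping every empirical check comfortably away
from its threshold. All stochastic tests fix their seeds; reruns are
bit-identical.

## Known limitations

- The interference correction is a linear two-component mixing model;
  it does not model channel-specific interference spectra.
- The melting-curve normalisation across experiments ("global
  normalisation" of TR curve sets) is implemented as identity for
  synthetic data, which is generated pre-normalised; real TR data sets
  normalised differently upstream should be normalised before input.
- Dependence classification is down-regulation-only by design;
  stabilised/up-regulated proteins are reported as metadata.
- The spike-in recovery of mature-pool degradation depends on k·t: at a
  6 h labeling time, proteins with half-lives ≫ 20 h cannot show a 30%
  mature-pool change regardless of the statistics; recovery studies use
  a 24 h design for that reason.
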