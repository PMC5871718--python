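# mpdp

Analysis toolkit for **multiplexed proteome dynamics profiling (mPDP)**:
pulsed-SILAC labeling combined with isobaric mass tags, which splits every
protein into a **mature** pool (synthesized before the medium switch and
treatment start) and a **nascent** pool (synthesized after it) and
quantifies both across conditions in a single MS run. The package is aimed
at computational proteomics groups who want to analyse such experiments —
or prototype them on realistic synthetic data — without a pipeline of
one-off scripts.

## What it computes

- **Quantification** (`mpdp.quant`) — reporter-ion intensities are scaled
  by ion accumulation time to *ion areas*, spectra are filtered
  (ion score > 15, precursor signal-to-background > 4,
  signal-to-interference > 0.5), channels are corrected for isotope
  impurity and co-isolation interference, and protein relative abundances
  are derived by a sum-based bootstrap over spectra with 95% percentile
  confidence intervals for proteins with more than three spectra. SILAC
  precursor quantification (median of valid peptide heavy/light ratios),
  missing-value imputation and a donor-consistency filter are included.
- **Significance framework** (`mpdp.dynamics`) — per condition, pool and
  replicate the log2 fold changes are median-normalised, proteins are
  binned by the number of quantified spectrum-sequence matches
  (≥ 300 per bin) and each bin's null SD is estimated robustly from
  replicate differences, sigma = (P84.13 − P15.87)/2 of
  d = (log2FC_rep1 − log2FC_rep2)/√2. A two-sided Z-test per replicate
  plus Benjamini–Hochberg adjustment yields the verdict: significant iff
  adjusted p ≤ 0.05 in both replicates, |log2 FC| > 0.37 (a 30% change)
  in both, and the direction agrees.
- **Turnover** (`mpdp.turnover`) — decay rate from a nascent/mature ratio
  time course, k_dp = Σ ln(r_ti + 1)·t_i / Σ t_i², optional cell-cycle
  correction k − ln2/t_cc, half-life T½ = ln2/k, through-origin R² and a
  good/weak/poor QC label.
- **Thermal profiling** (`mpdp.thermal`) — TPP-TR melting curves
  f(T) = (1 − plateau)/(1 + e^(b − a/T)) + plateau with Tm at f = 0.5,
  slope-binned z-tests for melting-point shifts, and 2D-TPP dose-response
  curves Y = 1/(1 + 10^((logEC50 − x)·slope)) with pEC50 validity checks.
- **Classification** (`mpdp.classify`) — constitutive vs
  synthesis-dependent chaperone clients from significance calls over a
  time course, with Fisher's exact enrichment against an interactor list.
- **Synthetic data** (`mpdp.simulate`) — seeded generators with ground
  truth for every stage: exponential decay of the mature pool, nascent
  accumulation s/k·(1 − e^(−kt)), label-swap duplicates, per-PSM reporter
  noise and long-tailed spectral support, melting and dose-response
  behaviour.

## Worked example

Simulate an experiment in which 20 of 2,000 proteins degrade 4× faster
under treatment, then run the full analysis:

```python
from mpdp import simulate, pipeline

effects = {f"P{i:05d}": 4.0 for i in range(20)}
specs = simulate.make_protein_specs(
    2000, seed=42, conditions=["treated"], k_multiplier_by_protein=effects
)
exp = simulate.SimExperiment(conditions=["treated"], treatment_time=24.0, seed=42)
psms = simulate.emit_psm_table(exp, specs)

result = pipeline.run_mpdp(psms)
mature = result["calls"].query("pool == 'mature' and significant")
print(len(mature), sorted(mature.protein_group)[:3])
```

```
19 ['P00000', 'P00001', 'P00002']
```

19 of the 20 injected degraders are called significantly down in the
mature pool and no null protein is called (the remaining one is lost to
replicate dropout, not mis-called). The same workflow is available from
the shell:

```sh
mpdp simulate-mpdp --n-proteins 2000 --seed 42 --out psms.tsv
mpdp mpdp psms.tsv --out-dir results/
```

which writes `fold_changes.tsv`, `significance_calls.tsv`,
`classification.tsv` and a `run_log.json` recording every threshold
applied.

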