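# vesiclequant

Quantitative analysis of pHluorin-based synaptic-vesicle exocytosis imaging,
from raw ROI fluorescence traces to genotype–function–phenotype correlation.

pHluorin is a pH-sensitive GFP that is quenched inside acidic synaptic
vesicles and fluoresces on exocytosis. With the vATPase blocked by
bafilomycin A1 there is no reacidification, so evoked fluorescence rises are
a cumulative read-out of vesicle fusion, and an alkaline NH₄Cl pulse
dequenches everything to reveal the total pool. `vesiclequant` implements
the standard quantification chain for such experiments:

- **Trace processing** — single-exponential photobleach correction fitted to
  background ROIs, background subtraction, ΔF/F₀ with F₀ the mean of the 5
  pre-stimulation frames, responsiveness screening (an ROI must respond to
  both stimulation and NH₄Cl; a field needs > 20 responsive ROIs), field
  averaging and normalization to the stimulation or NH₄Cl peak.
- **Exocytosis metrics** per field: recycling pool (end-of-stimulation
  ΔF/F₀ as % of the NH₄Cl peak), mobilization time constant τ from a
  one-phase fit `P·(1 − e^{−t/τ})` over the stimulation window, initial
  exocytic rate (least-squares slope over the first 5 s of the
  NH₄Cl-normalized trace), % of vesicles fused by *N* AP, and the readily
  releasable pool from a 40 AP / 20 Hz burst protocol.
- **Localization metrics** — axonal coefficient of variation (SD/mean over
  > 60 µm line profiles), membrane partitioning
  `surface% = 100·(F_saline − F_MES)/(F_NH₄Cl − F_MES)`, and
  background-subtracted expression fold-change.
- **Group statistics** — Shapiro–Wilk-gated choice between one-way ANOVA
  with Dunnett's many-to-one comparisons and Kruskal–Wallis with Dunn's
  rank comparisons against the control, plus per-timepoint Dunnett
  comparison of ΔF/F₀ time courses.
- **Phenotype correlation** — permutation-based Spearman correlations
  between per-variant functional metrics and phenotype scores (exact
  enumeration of all n! permutations at n ≤ 8), rank partial correlation
  controlling for age where scores are not age-standardised, and
  Benjamini–Hochberg step-up FDR over the whole family.
- **Synthetic data** — a generative model of bouton traces
  (`F(t) = bleach(t)·[background + T·V(t)] + ε`, with closed-form cumulative
  fusion kinetics), fields, line profiles and phenotype cohorts, so the
  entire pipeline is testable end to end with known ground truth.

## Worked example

```python
import vesiclequant as vq
from vesiclequant.traces import process_field

protocol = vq.get_preset("pool_1200ap")          # 1200 AP @ 10 Hz, NH4Cl at 140 s
priors   = vq.GroundTruthPriors.for_variant(tau=20.0, recycling=0.55)
noise    = vq.NoiseModel(sigma_rel=0.02, background_level=50.0, bleach_tau=600.0)

field = vq.simulate_field(25, 5, 4, priors, protocol, noise, seed=1)
proc  = process_field(field, protocol)
m     = vq.field_metrics(proc.mean_dff, protocol)
print(m.recycling_pool_pct, m.tau_s, m.initial_rate, m.frac_fused_200AP_pct)
```

prints (seed 1):

```
54.49  20.40  0.0248  33.46
```

i.e. the field mobilized 54.5% of its total vesicle pool over the 2-minute
train, with a mobilization time constant of 20.4 s, an initial rate of
0.0248 (ΔF/F₀)/s and 33.5% of the pool fused by 200 AP — recovering the
generative ground truth (τ = 20 s, 55% recycling fraction) from noisy,
bleached traces. The `examples/` directory has one short script per
capability (processing, localization, group statistics, correlation, full
pipeline), and `vesiclequant --help` exposes the same stages as a CLI
(`simulate`, `process`, `metrics`, `localize`, `stats`, `correlate`, `run`).

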