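# Methods

## The generative model

Each synaptic bouton is described by a total pHluorin fluorescence `T`
(arbitrary units), a surface fraction `s` of protein resident on the plasma
membrane, a recycling-pool fraction `R` of the vesicular protein that can be
mobilized by stimulation, a readily-releasable fraction `rrp ≤ R` of primed
vesicles, a mobilization time constant `τ` (seconds), and a residual
vesicular visibility `q_v` (pHluorin is ~94% quenched at vesicular pH ≈ 5.5,
so `q_v` defaults to 0.06). A simulated trace is

```
F(t) = bleach(t) · [ background + T · V(t) ] + ε,   ε ~ N(0, σ_rel·T)
```

with `bleach(t) = exp(−(t − t₀)/τ_bleach)` shared by every ROI of a field,
and the visible fraction

```
V(t) = s + (1 − s) · ( c(t) + q_v · (1 − c(t)) )      (pH 7.4 bath)
V(t) = q_MES                                           (acidic MES bath)
V(t) = 1                                               (NH4Cl bath)
```

Under bafilomycin there is no reacidification, so the cumulative fused
fraction `c(t)` is non-decreasing. During sustained 10 Hz stimulation it
follows one-phase kinetics `c(t) = R·(1 − e^{−t/τ})`. For the
readily-releasable-pool protocol, `c` rises linearly to `rrp` over the 2 s
burst (release of a finite primed pool at constant drive), holds through the
3 s recovery, then resumes `dc/dt = (R − c)/τ` during the subsequent 10 Hz
train, giving `c(t) = R − (R − rrp)·e^{−(t−5)/τ}`.

A useful identity: on the ΔF/F₀ scale the quench parameters cancel exactly —
`(V(t) − V₀)/(1 − V₀) = c(t)` with `V₀ = s + (1−s)q_v` — so NH₄Cl-normalized
ΔF/F₀ traces estimate `c(t)` directly regardless of `s` and `q_v`. The
membrane-partitioning estimate does *not* enjoy this cancellation: its
expectation is `(s + (1−s)q_v − q_MES)/(1 − q_MES)`, an upward bias of about
`(1−s)q_v` that the tests verify in closed form.

## Protocols

Three presets encode the assay timings: `pool_1200ap` (1200 AP at 10 Hz for
2 min, frames at 1 s from t = −5 s, NH₄Cl at 140–160 s), `rrp_40ap` (40 AP
at 20 Hz for 2 s, 3 s recovery — both sampled at 10 Hz — then 10 Hz for
2 min and NH₄Cl at 145–165 s), and `partitioning` (saline / MES / NH₄Cl,
40 s each, no stimulation). Time zero is stimulation onset; windows are
half-open `[start, end)` in seconds; frames are 0-indexed.

## Trace processing

The bleach model is a pure exponential without offset, fitted by nonlinear
least squares to the *mean* background-ROI trace over all frames before
NH₄Cl onset; the rate is constrained non-negative (a non-decaying background
yields the identity correction rather than an amplifying one), and when the
exponential fits the data exactly the log-linear solution is used directly,
which keeps the noiseless pipeline exact to machine precision. Correction
multiplies each trace by `e^{+b(t−t₀)}`, anchored so the first frame is
unchanged. The mean corrected background trace is then subtracted from
synaptic ROIs frame-wise before ΔF/F₀ (background subtraction is applied
uniformly; without it the baseline would include bath autofluorescence).

F₀ is the mean of the last 5 frames before stimulation. The responsiveness
screen requires mean ΔF/F₀ over the stimulation window *and* peak ΔF/F₀ in
the NH₄Cl window to exceed `noise_k` (default 2.0) baseline standard
deviations; the baseline SD uses the same 5 frames as F₀. A field enters
the final data only with strictly more than 20 responsive ROIs.
"Peak at the end of stimulation" is operationalized as the mean of the last
5 stimulation-window frames (robust to single-frame noise); the NH₄Cl peak
is the window maximum.

## Metric read-outs

- Recycling pool: `100 · (end-of-stim ΔF/F₀)/(NH₄Cl peak ΔF/F₀)`. Note the
  assay measures the pool *mobilized by the train*: at τ = 40 s a 2-minute
  train reaches only `1 − e^{−3} ≈ 95%` of the asymptotic fraction, so
  recovery is judged against the closed-form end-of-train value, not the
  asymptote.
- τ: fit of `P·(1 − e^{−t/τ})` to the stim-peak-normalized trace over the
  entire stimulation window. `P` is free and bounded (0, 1.5] because the
  normalization pins the endpoint, not the asymptote, at 1 (fixing P = 1
  would bias τ downward for non-saturating traces); τ is bounded
  (0.1 s, 10 × window] and the fit is flagged degenerate when either
  parameter lands on a bound. The stim-peak normalization (rather than
  NH₄Cl) for the τ fit is an interpretive choice, matching how
  peak-normalized time courses are displayed.
- Initial rate: least-squares slope of the NH₄Cl-normalized trace over
  t ∈ [0, 5] s, where release is approximately linear.
- % fused by N AP: NH₄Cl-normalized value at the frame nearest
  `t* = time of the N-th action potential` (nearest-frame lookup; at 1 s
  frame spacing 200 AP at 10 Hz is an exact frame).
- RRP: mean NH₄Cl-normalized ΔF/F₀ over the 3 s recovery gap, which the
  protocol samples at 10 Hz — more stable than a single burst-end frame.

All metrics are field-level (one value per coverslip), and per-variant
statistics are computed across fields (mean ± SEM, n), matching how
replicate experiments are reported; correlations use per-variant means.

## Statistics

Group comparisons are gated by per-group Shapiro–Wilk at α = 0.05 (an
unstated-threshold default): all groups normal → one-way ANOVA with
Dunnett's many-to-one multivariate-t adjustment (scipy); otherwise
Kruskal–Wallis with Dunn's pooled-rank z-tests against the control,
tie-corrected and Bonferroni-adjusted for the number of variant-vs-control
comparisons (the many-to-one family, not all pairwise). Brown–Forsythe
(median-centered Levene) is reported as a homoscedasticity diagnostic only.
Time courses are compared per timepoint with Dunnett adjustment — the
quantity actually displayed as significance bars — with a
Geisser–Greenhouse-corrected mixed-ANOVA omnibus available as an optional
diagnostic rather than a full REML mixed model, since the displayed output
depends only on the per-timepoint comparisons.

Permutation Spearman tests enumerate all `n!` permutations exactly for
n ≤ 8 (8! = 40,320; the study design has 8 variants), counting the observed
statistic among the permuted ones, so p ≥ 1/n!. Above n = 8 a Monte-Carlo
null with `(extreme + 1)/(n_perm + 1)` (default n_perm = 10,000) is used;
|r| comparisons use a 1e−12 tolerance so ties count as extreme. Measures
that are not age-standardised (CVI total, DBC self-injury) use a rank
partial correlation: ranks of x and y are residualized on age ranks and the
residual correlation is tested by permuting y residuals (Freedman–Lane).
A variable that is an exact rank-function of age has nothing left after the
control; its partial correlation is reported as (0, 1) by convention.
BH-FDR is the standard step-up procedure over all computed cells; the
largest significant p is reported as the data-dependent cutoff. Two-sided
alternatives throughout; confidence intervals for ρ are out of scope.

## Synthetic study conditions

Default noise is additive Gaussian with σ = 2% of a bouton's total
fluorescence, applied after bleach scaling — no Poisson/shot noise, no
focus drift, no spontaneous release, no endocytosis (bafilomycin assumed),
and trace-level simulation only (no 2-D images). Background autofluorescence
defaults to 50 a.u. with τ_bleach = 600 s shared by all ROIs of a field, the
assumption the correction relies on. Fields default to 25 responsive + 5
dead (15% dead exercises QC) + 4 background ROIs; bouton heterogeneity is
uniform (brightness 700–1300 a.u., ±0.05 on pool fractions, ±10% relative
on τ). The paper-shaped cohort is one wild type plus eight variants with
graded slowing (τ 22→52 s) and pool shrinkage (R 0.55→0.38); phenotype
scores link the adaptive-function (VABS) measures linearly to the true
%-fused-by-200-AP with ~2-score-unit noise, while CVI, movement-disorder
counts and self-injury scores are pure noise around instrument-typical
baselines. Because the generator shares the pipeline's kinetic form,
passing recovery tests demonstrates correctness of the estimation chain,
not robustness to model misspecification in real recordings (non-exponential
bleaching, correlated noise, drift).

## Numerical choices and limitations

Curve fits use scipy `curve_fit` with bounded parameters and tight
tolerances; bleach fits retry from alternative starts before raising with
diagnostics. Plateau means in the partitioning assay use the central 80% of
each buffer window to avoid perfusion transitions. Negative noise-driven
surface estimates are clipped to 0 and flagged. Degenerate inputs raise
informative errors: all-zero backgrounds, non-positive F₀, constant groups
under Shapiro–Wilk, zero-variance correlation inputs, missing NH₄Cl
windows. Exact permutation enumeration is cached per n. All stochastic
stages take explicit seeds and the pipeline derives per-field seeds from
one root seed, so runs are byte-reproducible. Problem sizes in the test
suite and acceptance script (9 fields per condition, 25–100 replicate
fields, 400–2000 simulation replicates) are chosen to keep full runs in the
minutes range while leaving binomial error bars well inside the tested
tolerances.
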