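"""Correlate per-variant functional metrics with participant phenotype scores.

A cohort of eight variants with graded exocytic deficits is generated; the
adaptive-function (VABS) scores are linked to the true deficit while the
other measures are noise. The permutation-Spearman family (exact enumeration
at n=8) with BH-FDR should flag only the VABS rows.
"""

from vesiclequant import CorrelationConfig, run_correlation_family
from vesiclequant.pipeline import true_cohort_metrics
from vesiclequant.synthetic import DEFAULT_COHORT, PhenotypeLink, simulate_cohort_phenotypes

metrics = true_cohort_metrics(DEFAULT_COHORT).drop(index="WT")
phenotypes = simulate_cohort_phenotypes(metrics, PhenotypeLink.vabs_deficit_default(),
                                        seed=1)

res = run_correlation_family(metrics, phenotypes, CorrelationConfig(seed=1))
cols = ["measure", "metric", "n", "r", "p", "age_controlled", "bh_significant"]
print(res[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nBH cutoff (largest significant p): {res.attrs['bh_cutoff']:.4g}")
print("Flags should sit on the six VABS cells: both VABS measures track the")
print("deficit, and all three functional metrics are rank-equivalent to it.")
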