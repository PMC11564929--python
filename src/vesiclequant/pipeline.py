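"""End-to-end reproducible runs: simulate → process → metrics → stats → correlate.

:class:`RunConfig` collects every path, preset, threshold and seed of a run
and round-trips losslessly through YAML/JSON. :func:`run_pipeline` executes
the enabled stages, writes tidy CSVs for each stage boundary, a
machine-readable JSON summary and a human-readable report, and logs every
excluded ROI and field with its reason.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .correlation import CorrelationConfig, run_correlation_family
from .exocytosis import field_metrics, summarize_metrics
from .groupstats import compare_to_control, normality_gate, significance_stars
from .io import write_json_summary, write_trace_table
from .protocols import get_preset
from .synthetic import (
    DEFAULT_COHORT,
    GroundTruthPriors,
    NoiseModel,
    PhenotypeLink,
    simulate_cohort_phenotypes,
    simulate_field,
)
from .traces import process_field

__all__ = ["RunConfig", "RunResult", "run_pipeline", "true_cohort_metrics"]

log = logging.getLogger("vesiclequant")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serializes losslessly."""

    outdir: str = "vesiclequant_run"
    seed: int = 0
    # synthetic experiment layout
    cohort: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COHORT.items()})
    control_label: str = "WT"
    fields_per_variant: int = 9
    n_responsive: int = 25
    n_dead: int = 5
    n_background: int = 4
    sigma_rel: float = 0.02
    background_level: float = 50.0
    bleach_tau: float = 600.0
    # stage toggles and inputs
    simulate: bool = True
    include_rrp: bool = True
    run_stats: bool = True
    run_correlation: bool = True
    write_traces: bool = False
    trace_csv: str | None = None
    phenotype_csv: str | None = None
    # thresholds
    noise_k: float = 2.0
    alpha: float = 0.05
    q: float = 0.05
    n_perm: int = 10_000

    def validate(self) -> None:
        if not self.simulate and self.trace_csv is None:
            raise ValueError("simulation disabled and no trace_csv provided")
        if self.run_correlation and not self.simulate and self.phenotype_csv is None:
            raise ValueError(
                "correlation enabled but no phenotype table: provide "
                "phenotype_csv or enable the simulate stage"
            )
        if self.control_label not in self.cohort:
            raise ValueError(f"control {self.control_label!r} missing from cohort")
        if len(self.cohort) < 2:
            raise ValueError("cohort needs a control and at least one variant")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    config: RunConfig
    metrics: pd.DataFrame
    metric_summary: pd.DataFrame
    stats_tables: dict[str, pd.DataFrame]
    correlations: pd.DataFrame | None
    qc_log: pd.DataFrame
    summary: dict
    outdir: Path


def true_cohort_metrics(cohort: dict, protocol=None) -> pd.DataFrame:
    """Closed-form per-variant functional metrics from generative parameters.

    Evaluates the noiseless cumulative-fusion curve on the pool protocol's
    frame grid and applies the same read-out definitions as the estimators:
    least-squares slope over the first 5 s (as a fraction of the total pool),
    the variant's tau, and the fused fraction at the 200-AP frame.
    """
    if protocol is None:
        protocol = get_preset("pool_1200ap")
    rows = {}
    for variant, params in cohort.items():
        gt = GroundTruthPriors.for_variant(**params).center()
        t = protocol.frame_times
        c = synthetic.cumulative_fused_fraction(gt, protocol, t)
        onset = protocol.stim_onset
        m5 = (t >= onset) & (t <= onset + 5.0)
        slope = float(np.polyfit(t[m5] - onset, c[m5], 1)[0])
        t200 = protocol.time_of_ap(200)
        i200 = int(np.argmin(np.abs(t - t200)))
        rows[variant] = {
            "initial_rate": slope,
            "tau_s": gt.tau_true,
            "frac_fused_200AP_pct": 100.0 * float(c[i200]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


class _Seeds:
    """Deterministic seed derivation keyed on (stage, variant, field)."""

    def __init__(self, seed: int) -> None:
        self.seed = int(seed)

    def derive(self, *key: int) -> int:
        return int(
            np.random.SeedSequence([self.seed, *key]).generate_state(1)[0] % 2**31
        )


def run_pipeline(config: RunConfig) -> RunResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _Seeds(config.seed)
    noise = NoiseModel(
        sigma_rel=config.sigma_rel, background_level=config.background_level,
        bleach_tau=config.bleach_tau,
    )
    pool = get_preset("pool_1200ap")
    rrp = get_preset("rrp_40ap")
    variants = list(config.cohort)

    # -- stage 1+2: simulate (or load) and process ------------------------
    metric_rows, qc_rows = [], []
    all_fields = []
    if config.simulate:
        assays = [("pool", pool, 0)] + ([("rrp", rrp, 1)] if config.include_rrp else [])
        for v_idx, variant in enumerate(variants):
            priors = GroundTruthPriors.for_variant(**config.cohort[variant])
            for assay_name, protocol, a_idx in assays:
                for f_idx in range(config.fields_per_variant):
                    fid = f"{variant}_{assay_name}_{f_idx:02d}"
                    fr = simulate_field(
                        config.n_responsive, config.n_dead, config.n_background,
                        priors, protocol, noise, field_id=fid, variant=variant,
                        seed=seeds.derive(a_idx, v_idx, f_idx),
                    )
                    all_fields.append((fr, protocol))
    else:
        from .io import read_trace_table

        for fr in read_trace_table(config.trace_csv):
            all_fields.append((fr, rrp if fr.assay == "rrp_40ap" else pool))

    for fr, protocol in all_fields:
        proc = process_field(fr, protocol, noise_k=config.noise_k)
        excluded = proc.qc.roi_status[~proc.qc.roi_status["included"]]
        for _, row in excluded.iterrows():
            log.info("excluded ROI %s/%s: %s", fr.field_id, row.roi_id, row.reason)
        qc_rows.append({
            "field_id": fr.field_id, "variant": fr.variant, "assay": fr.assay,
            "n_responsive": proc.qc.n_responsive, "field_pass": proc.qc.field_pass,
        })
        if not proc.qc.field_pass:
            log.info("excluded field %s: %d responsive ROIs",
                     fr.field_id, proc.qc.n_responsive)
            continue
        m = field_metrics(proc.mean_dff, protocol,
                          field_id=fr.field_id, variant=fr.variant)
        metric_rows.append({
            "field_id": m.field_id, "variant": m.variant,
            "recycling_pool_pct": m.recycling_pool_pct, "tau_s": m.tau_s,
            "initial_rate": m.initial_rate,
            "frac_fused_200AP_pct": m.frac_fused_200AP_pct, "rrp_pct": m.rrp_pct,
        })
    metrics_df = pd.DataFrame(metric_rows)
    qc_df = pd.DataFrame(qc_rows)
    summary_df = summarize_metrics(metrics_df) if not metrics_df.empty else pd.DataFrame()

    if config.write_traces:
        write_trace_table([fr for fr, _ in all_fields], outdir / "traces.csv")
    metrics_df.to_csv(outdir / "field_metrics.csv", index=False)
    summary_df.to_csv(outdir / "variant_summary.csv", index=False)
    qc_df.to_csv(outdir / "qc_report.csv", index=False)

    # -- stage 3: group statistics ---------------------------------------
    stats_tables: dict[str, pd.DataFrame] = {}
    if config.run_stats and not metrics_df.empty:
        for metric in ("recycling_pool_pct", "tau_s", "initial_rate",
                       "frac_fused_200AP_pct", "rrp_pct"):
            if metric not in metrics_df.columns:
                continue
            groups = {
                v: grp[metric].dropna().to_numpy()
                for v, grp in metrics_df.groupby("variant", sort=False)
            }
            groups = {v: a for v, a in groups.items() if a.size >= 3}
            if config.control_label not in groups or len(groups) < 2:
                continue
            gate = normality_gate(groups, alpha=config.alpha)
            cmp_res = compare_to_control(
                groups, control_label=config.control_label, gate=gate, metric=metric
            )
            stats_tables[metric] = cmp_res.table.assign(
                metric=metric, test_used=cmp_res.test_used
            )
        if stats_tables:
            pd.concat(stats_tables.values(), ignore_index=True).to_csv(
                outdir / "group_comparisons.csv", index=False
            )

    # -- stage 4: phenotype correlation ----------------------------------
    correlations = None
    if config.run_correlation:
        variant_only = [v for v in variants if v != config.control_label]
        if config.phenotype_csv is not None:
            phenotypes = pd.read_csv(config.phenotype_csv, index_col=0)
        else:
            true_metrics = true_cohort_metrics(config.cohort).loc[variant_only]
            phenotypes = simulate_cohort_phenotypes(
                true_metrics, PhenotypeLink.vabs_deficit_default(),
                seed=seeds.derive(900),
            )
            phenotypes.to_csv(outdir / "phenotypes.csv")
        est = (
            metrics_df[metrics_df["variant"] != config.control_label]
            .groupby("variant")[list(synthetic.FUNCTIONAL_METRICS)]
            .mean()
        )
        correlations = run_correlation_family(
            est, phenotypes,
            CorrelationConfig(q=config.q, n_perm=config.n_perm,
                              seed=seeds.derive(901)),
        )
        correlations.to_csv(outdir / "correlations.csv", index=False)

    # -- summary + report -------------------------------------------------
    summary = {
        "seed": config.seed,
        "n_fields_simulated": len(all_fields),
        "n_fields_passed_qc": int(qc_df["field_pass"].sum()) if not qc_df.empty else 0,
        "variants": variants,
        "metric_summary": summary_df.to_dict(orient="records"),
        "group_tests": {
            k: v[["variant", "p_adj"]].set_index("variant")["p_adj"].to_dict()
            for k, v in stats_tables.items()
        },
    }
    if correlations is not None:
        summary["bh_flagged_cells"] = [
            f"{r.measure}|{r.metric}"
            for r in correlations.itertuples() if r.bh_significant
        ]
        summary["bh_cutoff"] = correlations.attrs.get("bh_cutoff", float("nan"))
    write_json_summary(summary, outdir / "summary.json")
    _write_report(outdir / "report.txt", summary_df, stats_tables, correlations)
    return RunResult(
        config=config, metrics=metrics_df, metric_summary=summary_df,
        stats_tables=stats_tables, correlations=correlations, qc_log=qc_df,
        summary=summary, outdir=outdir,
    )


def _write_report(path, summary_df, stats_tables, correlations) -> None:
    lines = ["vesiclequant run report", "=" * 40, ""]
    if not summary_df.empty:
        lines.append("Per-variant metrics (mean +/- SEM, n):")
        for row in summary_df.itertuples():
            lines.append(
                f"  {row.variant:>8s}  {row.metric:<22s} "
                f"{row.mean:10.4f} +/- {row.sem:8.4f}  (n={row.n})"
            )
        lines.append("")
    for metric, table in stats_tables.items():
        lines.append(f"Group comparison vs control [{metric}] "
                     f"({table['test_used'].iloc[0]}):")
        for row in table.itertuples():
            if np.isfinite(row.p_adj):
                lines.append(f"  {row.variant:>8s}  p_adj={row.p_adj:8.4g}  {row.stars}")
        lines.append("")
    if correlations is not None:
        lines.append("Phenotype correlations (Spearman, permutation p, BH flag):")
        for row in correlations.itertuples():
            if row.computed:
                flag = "*" if row.bh_significant else " "
                lines.append(
                    f"  {row.measure:<24s} x {row.metric:<22s} "
                    f"r={row.r:+.3f}  p={row.p:.4g} {flag}"
                )
        lines.append("")
    Path(path).write_text("\n".join(lines))
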