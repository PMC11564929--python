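"""Variant-vs-control group comparisons with a normality-gated test choice.

Per-metric comparisons follow common practice for many-to-one designs:
Shapiro–Wilk normality testing per group gates the family — one-way ANOVA
with Dunnett's many-to-one adjustment when every group passes, otherwise
Kruskal–Wallis with Dunn's rank comparisons against the control. The
Brown–Forsythe statistic (Levene with median centering) is reported as a
homoscedasticity diagnostic only.

For ΔF/F0 time courses, :func:`pointwise_timecourse_comparison` compares
each variant's per-field values against the control at every frame with
Dunnett adjustment — the data behind "significance bars" above group time
courses — with a sphericity-corrected mixed-ANOVA omnibus available as a
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateResult",
    "GroupComparison",
    "PointwiseComparison",
    "normality_gate",
    "compare_to_control",
    "dunn_vs_control",
    "pointwise_timecourse_comparison",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GateResult:
    test_used: str  # 'anova_dunnett' | 'kw_dunn'
    shapiro_pvals: dict
    brown_forsythe_p: float
    alpha: float


def _as_groups(groups: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 3:
            raise ValueError(f"group {name!r} has n={arr.size} < 3")
        out[name] = arr
    return out


def normality_gate(groups: Mapping[str, np.ndarray], alpha: float = 0.05) -> GateResult:
    """Shapiro–Wilk per group; parametric branch iff every group passes.

    Constant groups make the Shapiro–Wilk statistic undefined and raise.
    """
    groups = _as_groups(groups)
    pvals = {}
    for name, arr in groups.items():
        if np.ptp(arr) == 0:
            raise ValueError(
                f"group {name!r} is constant; Shapiro–Wilk is undefined"
            )
        pvals[name] = float(stats.shapiro(arr).pvalue)
    choice = "anova_dunnett" if all(p > alpha for p in pvals.values()) else "kw_dunn"
    bf_p = float(stats.levene(*groups.values(), center="median").pvalue)
    return GateResult(
        test_used=choice, shapiro_pvals=pvals, brown_forsythe_p=bf_p, alpha=alpha
    )


def dunn_vs_control(
    groups: Mapping[str, np.ndarray], control_label: str
) -> dict[str, float]:
    """Dunn's rank z-tests of each group against the control.

    Pooled-rank z statistics with the usual tie correction; two-sided p-values
    Bonferroni-adjusted for the number of variant-vs-control comparisons
    (many-to-one family, not all pairwise).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    control = groups[control_label]
    variants = [k for k in groups if k != control_label]
    pooled = np.concatenate([groups[k] for k in groups])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # mean rank per group
    mean_ranks, sizes, start = {}, {}, 0
    for k in groups:
        n_k = groups[k].size
        mean_ranks[k] = float(np.mean(ranks[start: start + n_k]))
        sizes[k] = n_k
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    k_comp = len(variants)
    out = {}
    for v in variants:
        se = np.sqrt(var_base * (1.0 / sizes[v] + 1.0 / control.size))
        z = (mean_ranks[v] - mean_ranks[control_label]) / se
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * k_comp)
        out[v] = float(p)
    return out


@dataclass
class GroupComparison:
    metric: str
    test_used: str
    table: pd.DataFrame  # variant, n, mean, sem, p_adj, stars
    gate: GateResult


def compare_to_control(
    groups: Mapping[str, np.ndarray],
    control_label: str = "WT",
    gate: GateResult | str | None = None,
    metric: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Many-to-one adjusted comparisons of each variant against the control."""
    groups = _as_groups(groups)
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if gate is None:
        gate = normality_gate(groups, alpha=alpha)
    choice = gate.test_used if isinstance(gate, GateResult) else str(gate)
    if isinstance(gate, str):
        gate = GateResult(test_used=choice, shapiro_pvals={}, brown_forsythe_p=np.nan,
                          alpha=alpha)
    variants = [k for k in groups if k != control_label]
    if choice == "anova_dunnett":
        res = stats.dunnett(
            *[groups[v] for v in variants], control=groups[control_label]
        )
        padj = {v: float(p) for v, p in zip(variants, res.pvalue)}
    elif choice == "kw_dunn":
        padj = dunn_vs_control(groups, control_label)
    else:
        raise ValueError(f"unknown test choice {choice!r}")
    rows = []
    for name in groups:
        arr = groups[name]
        p = padj.get(name, np.nan)
        rows.append({
            "variant": name, "n": arr.size, "mean": float(np.mean(arr)),
            "sem": float(np.std(arr, ddof=1) / np.sqrt(arr.size)),
            "p_adj": p,
            "stars": significance_stars(p) if np.isfinite(p) else "",
        })
    return GroupComparison(
        metric=metric, test_used=choice, table=pd.DataFrame(rows), gate=gate
    )


@dataclass
class PointwiseComparison:
    time_s: np.ndarray
    pvals: pd.DataFrame  # index time_s, one column per variant
    mask: pd.DataFrame  # adjusted p < alpha
    alpha: float
    omnibus: dict | None  # sphericity-corrected mixed-ANOVA diagnostic


def pointwise_timecourse_comparison(
    traces_by_variant: Mapping[str, np.ndarray],
    time_s,
    control_label: str = "WT",
    alpha: float = 0.05,
    compute_omnibus: bool = False,
) -> PointwiseComparison:
    """Dunnett-adjusted variant-vs-control comparison at every timepoint.

    ``traces_by_variant`` maps a variant to an (n_fields, n_timepoints) array
    of per-field mean traces on a shared frame grid. Returns adjusted
    p-values and the p < alpha mask per (variant, timepoint); optionally a
    Geisser–Greenhouse-corrected mixed-ANOVA omnibus as a diagnostic.
    """
    time_s = np.asarray(time_s, dtype=float)
    arrays = {k: np.atleast_2d(np.asarray(v, dtype=float))
              for k, v in traces_by_variant.items()}
    if control_label not in arrays:
        raise ValueError(f"control group {control_label!r} missing")
    n_t = time_s.size
    for k, arr in arrays.items():
        if arr.shape[1] != n_t:
            raise ValueError(
                f"variant {k!r} has {arr.shape[1]} timepoints, expected {n_t}"
            )
    variants = [k for k in arrays if k != control_label]
    if not variants:
        raise ValueError("need at least one variant besides the control")
    pmat = np.empty((n_t, len(variants)))
    control = arrays[control_label]
    for j in range(n_t):
        res = stats.dunnett(
            *[arrays[v][:, j] for v in variants], control=control[:, j]
        )
        pmat[j] = res.pvalue
    pvals = pd.DataFrame(pmat, index=time_s, columns=variants)
    omnibus = None
    if compute_omnibus:
        omnibus = _mixed_anova_omnibus(arrays, time_s, control_label)
    return PointwiseComparison(
        time_s=time_s, pvals=pvals, mask=pvals < alpha, alpha=alpha, omnibus=omnibus
    )


def _mixed_anova_omnibus(arrays, time_s, control_label) -> dict | None:
    """GG-corrected mixed ANOVA (variant x time) via pingouin; diagnostic only."""
    try:
        import pingouin as pg

        rows = []
        subj = 0
        for variant, arr in arrays.items():
            for i in range(arr.shape[0]):
                for j, t in enumerate(time_s):
                    rows.append((f"s{subj}", variant, j, arr[i, j]))
                subj += 1
        df = pd.DataFrame(rows, columns=["subject", "variant", "time", "dff"])
        aov = pg.mixed_anova(
            data=df, dv="dff", within="time", subject="subject",
            between="variant", correction=True,
        )
        inter = aov[aov["Source"] == "Interaction"]
        time_row = aov[aov["Source"] == "time"]
        return {
            "p_interaction": float(inter["p-unc"].iloc[0]) if not inter.empty else np.nan,
            "p_time_gg": float(
                time_row["p-GG-corr"].iloc[0]
                if "p-GG-corr" in aov.columns and not time_row.empty
                and np.isfinite(time_row["p-GG-corr"].iloc[0])
                else time_row["p-unc"].iloc[0]
            ) if not time_row.empty else np.nan,
        }
    except Exception:  # diagnostic only; never block the pointwise result
        return None
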