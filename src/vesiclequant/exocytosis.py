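"""Field-level exocytosis metrics from normalized ΔF/F0 traces.

Four headline read-outs of synaptic-vesicle exocytosis under bafilomycin:

* **recycling pool** — end-of-stimulation ΔF/F0 as a percentage of the
  NH4Cl-revealed total (1200 AP at 10 Hz mobilizes the recycling pool);
* **tau** — time constant of a one-phase association ``P*(1 - exp(-t/tau))``
  fitted over the entire stimulation window of the stim-peak-normalized
  trace (overall mobilization rate);
* **initial rate** — least-squares slope of the NH4Cl-normalized trace over
  the first 5 s of stimulation, where release is approximately linear;
* **% fused by N AP** — NH4Cl-normalized ΔF/F0 at the frame nearest the time
  the N-th action potential is delivered (200 AP at 10 Hz → t = 20 s);
* **RRP** — mean NH4Cl-normalized ΔF/F0 over the 3 s recovery gap after a
  40 AP / 20 Hz burst, i.e. the fraction of the total pool released by the
  burst.

All metrics are computed per field (one value per coverslip), matching how
replicate statistics are reported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocols import Protocol, Window
from .traces import (
    BASELINE_FRAMES,
    ROITrace,
    nh4cl_peak_reference,
    normalize_trace,
    stim_peak_reference,
)

__all__ = [
    "OnePhaseFit",
    "ExocytosisMetrics",
    "recycling_pool_fraction",
    "fit_one_phase",
    "initial_exocytic_rate",
    "fraction_fused_at_ap",
    "rrp_fraction",
    "field_metrics",
    "summarize_metrics",
]

#: tau upper bound, as a multiple of the stimulation-window duration
TAU_BOUND_FACTOR = 10.0
#: stimulation window for the initial-rate regression, seconds from onset
INITIAL_RATE_WINDOW_S = 5.0


@dataclass(frozen=True)
class OnePhaseFit:
    tau_s: float
    plateau: float
    rss: float
    converged: bool
    tau_at_bound: bool
    plateau_at_bound: bool = False

    @property
    def degenerate(self) -> bool:
        """True when the optimum landed on a parameter bound (e.g. a linear
        ramp that the one-phase model cannot represent)."""
        return self.tau_at_bound or self.plateau_at_bound


def recycling_pool_fraction(mean_dff: ROITrace, protocol: Protocol) -> float:
    """Recycling pool as % of the total pool revealed by NH4Cl.

    End-of-stimulation value (mean of the last 5 stimulation frames) divided
    by the NH4Cl-window peak, both on the ΔF/F0 trace.
    """
    end_of_stim = stim_peak_reference(mean_dff, protocol)
    nh4_peak = nh4cl_peak_reference(mean_dff, protocol)
    if nh4_peak <= 0:
        raise ValueError(f"NH4Cl peak {nh4_peak:.4g} <= 0; no total-pool reference")
    return 100.0 * end_of_stim / nh4_peak


def fit_one_phase(stim_norm_trace: ROITrace, protocol: Protocol) -> OnePhaseFit:
    """Fit P*(1 - exp(-t/tau)) over the entire stimulation window.

    The trace must be normalized to the stimulation peak. The plateau P is
    free (bounded (0, 1.5]) because the normalization pins the *endpoint*,
    not the asymptote, at 1; tau is bounded (0.1 s, 10x window] and flagged
    when the fit lands on a bound.
    """
    if "normalized_stim_peak" not in stim_norm_trace.flags:
        raise ValueError("trace must be normalized to the stimulation peak")
    idx = protocol.frames_in(protocol.stim_window)
    if idx.size < 30:
        raise ValueError(f"stimulation window has {idx.size} frames; need >= 30")
    t = stim_norm_trace.time_s[idx] - protocol.stim_onset
    y = stim_norm_trace.intensity[idx]
    window = protocol.stim_window.duration_s
    tau_hi = TAU_BOUND_FACTOR * window

    def model(tt, plateau, tau):
        return plateau * -np.expm1(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[1.0, window / 4.0],
            bounds=([1e-9, 0.1], [1.5, tau_hi]), maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except (RuntimeError, ValueError) as err:
        rss0 = float(np.sum((y - model(t, 1.0, window / 4.0)) ** 2))
        raise RuntimeError(
            f"one-phase fit did not converge (rss at p0 = {rss0:.4g}): {err}"
        ) from err
    plateau, tau = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - model(t, plateau, tau)) ** 2))
    tau_at_bound = tau >= tau_hi * (1 - 1e-6) or tau <= 0.1 * (1 + 1e-6)
    plateau_at_bound = plateau >= 1.5 * (1 - 1e-6)
    return OnePhaseFit(
        tau_s=tau, plateau=plateau, rss=rss, converged=True,
        tau_at_bound=tau_at_bound, plateau_at_bound=plateau_at_bound,
    )


def initial_exocytic_rate(nh4_norm_trace: ROITrace, protocol: Protocol) -> float:
    """Least-squares slope of the NH4Cl-normalized trace over t in [0, 5] s."""
    if "normalized_nh4cl" not in nh4_norm_trace.flags:
        raise ValueError("trace must be normalized to the NH4Cl peak")
    onset = protocol.stim_onset
    mask = (nh4_norm_trace.time_s >= onset) & (
        nh4_norm_trace.time_s <= onset + INITIAL_RATE_WINDOW_S
    )
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} frames in the first "
            f"{INITIAL_RATE_WINDOW_S:.0f} s; need >= 3"
        )
    t = nh4_norm_trace.time_s[mask] - onset
    y = nh4_norm_trace.intensity[mask]
    return float(np.polyfit(t, y, 1)[0])


def fraction_fused_at_ap(
    nh4_norm_trace: ROITrace, protocol: Protocol, n_ap: int
) -> float:
    """% of the total pool fused by the n_ap-th action potential.

    Reads the NH4Cl-normalized trace at the frame nearest
    t* = time_of_ap(n_ap) (nearest-frame lookup, no interpolation).
    """
    if "normalized_nh4cl" not in nh4_norm_trace.flags:
        raise ValueError("trace must be normalized to the NH4Cl peak")
    t_star = protocol.time_of_ap(n_ap)
    if not protocol.stim_onset <= t_star <= protocol.stim_end:
        raise ValueError(f"t*={t_star:.2f} s outside the stimulation window")
    i = int(np.argmin(np.abs(nh4_norm_trace.time_s - t_star)))
    return 100.0 * float(nh4_norm_trace.intensity[i])


def rrp_fraction(nh4_norm_trace: ROITrace, rrp_protocol: Protocol) -> float:
    """RRP size as % of the total pool: mean over the post-burst recovery gap.

    The RRP protocol's burst (40 AP at 20 Hz) is followed by a 3 s recovery
    sampled at 10 Hz; the plateau over that gap reflects the vesicles fused
    by the burst.
    """
    if "normalized_nh4cl" not in nh4_norm_trace.flags:
        raise ValueError("trace must be normalized to the NH4Cl peak")
    segs = sorted(rrp_protocol.stim_segments, key=lambda s: s.t_start)
    if len(segs) != 2:
        raise ValueError("rrp_fraction requires a burst + sustained protocol")
    gap = Window(segs[0].t_end, segs[1].t_start)
    idx = rrp_protocol.frames_in(gap)
    if idx.size == 0:
        raise ValueError("no frames inside the post-burst recovery gap")
    return 100.0 * float(np.mean(nh4_norm_trace.intensity[idx]))


@dataclass
class ExocytosisMetrics:
    """Per-field exocytosis read-outs (None when the assay does not apply)."""

    field_id: str
    variant: str
    recycling_pool_pct: float | None = None
    tau_s: float | None = None
    initial_rate: float | None = None
    frac_fused_200AP_pct: float | None = None
    rrp_pct: float | None = None
    fit: OnePhaseFit | None = None

    def __post_init__(self) -> None:
        if self.tau_s is not None and self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")


def field_metrics(
    mean_dff: ROITrace,
    protocol: Protocol,
    field_id: str = "field_0",
    variant: str = "WT",
    n_ap: int = 200,
) -> ExocytosisMetrics:
    """Compute all metrics available from one field's mean ΔF/F0 trace.

    Pool protocols (single stimulation segment) yield recycling pool, tau,
    initial rate and % fused by ``n_ap``; RRP protocols (burst + sustained)
    yield the RRP percentage.
    """
    nh4_norm = normalize_trace(mean_dff, "nh4cl_peak", protocol)
    if len(protocol.stim_segments) == 2:
        return ExocytosisMetrics(
            field_id=field_id, variant=variant,
            rrp_pct=rrp_fraction(nh4_norm, protocol),
        )
    stim_norm = normalize_trace(mean_dff, "stim_peak", protocol)
    fit = fit_one_phase(stim_norm, protocol)
    return ExocytosisMetrics(
        field_id=field_id, variant=variant,
        recycling_pool_pct=recycling_pool_fraction(mean_dff, protocol),
        tau_s=fit.tau_s,
        initial_rate=initial_exocytic_rate(nh4_norm, protocol),
        frac_fused_200AP_pct=fraction_fused_at_ap(nh4_norm, protocol, n_ap),
        fit=fit,
    )


def summarize_metrics(metrics_df: pd.DataFrame) -> pd.DataFrame:
    """Per-variant mean ± SEM and n for each metric column.

    ``metrics_df`` has one row per field with a ``variant`` column; returns a
    tidy frame with one row per (variant, metric).
    """
    value_cols = [
        c for c in (
            "recycling_pool_pct", "tau_s", "initial_rate",
            "frac_fused_200AP_pct", "rrp_pct",
        ) if c in metrics_df.columns
    ]
    rows = []
    for variant, grp in metrics_df.groupby("variant", sort=False):
        for col in value_cols:
            vals = grp[col].dropna()
            if vals.empty:
                continue
            rows.append({
                "variant": variant, "metric": col, "n": len(vals),
                "mean": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)
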