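"""Localization metrics: axonal punctateness, membrane partitioning, expression.

* :func:`coefficient_of_variation` — SD/mean of fluorescence along >60 um
  axonal line profiles; a punctate (synaptically enriched) distribution gives
  a high CV, a diffuse one a low CV. A field-level value is the mean over 5
  independent segments.
* :func:`membrane_partition` — fraction of nerve-terminal pHluorin on the
  plasma membrane vs in synaptic vesicles, from sequential saline / acid
  (MES) / alkaline (NH4Cl) perfusion plateaus.
* :func:`expression_fold_change` — transfected over non-transfected ROI
  intensity after background subtraction (a value near 2 mimics the
  heterozygous condition, where the tagged copy doubles total protein).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocols import Protocol
from .synthetic import MIN_PROFILE_UM, PIXEL_SIZE_UM
from .traces import ROITrace

__all__ = [
    "PartitionResult",
    "ExpressionResult",
    "profile_cv",
    "coefficient_of_variation",
    "membrane_partition",
    "expression_fold_change",
]

#: number of axonal segments averaged for one field-level CV
PROFILES_PER_FIELD = 5

#: fraction of each buffer window used for plateau means (central 80%,
#: trimming perfusion-transition frames at both ends)
PLATEAU_CENTRAL_FRAC = 0.8


def profile_cv(profile, min_length_px: int | None = None) -> float:
    """Sample SD / mean of one line-profile intensity sequence."""
    profile = np.asarray(profile, dtype=float)
    min_px = (
        int(np.ceil(MIN_PROFILE_UM / PIXEL_SIZE_UM))
        if min_length_px is None else min_length_px
    )
    if profile.size < min_px:
        raise ValueError(
            f"profile of {profile.size} px is shorter than the "
            f"{min_px} px (60 um) minimum"
        )
    mean = float(np.mean(profile))
    if mean <= 0:
        raise ValueError(f"profile mean {mean:.4g} <= 0")
    return float(np.std(profile, ddof=1)) / mean


def coefficient_of_variation(profiles, min_length_px: int | None = None) -> float:
    """Field-level CV: arithmetic mean of per-profile CVs over >= 5 segments."""
    if len(profiles) < PROFILES_PER_FIELD:
        raise ValueError(
            f"a field-level CV requires {PROFILES_PER_FIELD} profiles, "
            f"got {len(profiles)}"
        )
    return float(np.mean([profile_cv(p, min_length_px) for p in profiles]))


@dataclass(frozen=True)
class PartitionResult:
    surface_pct: float
    vesicular_pct: float
    window_means: dict
    clipped: bool

    def __post_init__(self) -> None:
        if abs(self.surface_pct + self.vesicular_pct - 100.0) > 1e-9:
            raise ValueError("surface and vesicular percentages must sum to 100")


def _plateau_mean(trace: ROITrace, protocol: Protocol, buffer: str) -> float:
    idx = protocol.frames_in(protocol.perfusion[buffer])
    if idx.size < 3:
        raise ValueError(f"{buffer} window has {idx.size} frames; need >= 3")
    trim = int(np.floor(idx.size * (1 - PLATEAU_CENTRAL_FRAC) / 2))
    core = idx[trim: idx.size - trim] if trim > 0 else idx
    return float(np.mean(trace.intensity[core]))


def membrane_partition(trace: ROITrace, buffer_protocol: Protocol) -> PartitionResult:
    """Surface vs vesicular percentages from buffer-window plateau means.

    surface% = 100 * (F_saline - F_MES) / (F_NH4Cl - F_MES); noise-driven
    negative estimates are clipped to 0 and flagged.
    """
    missing = {"saline", "mes", "nh4cl"} - set(buffer_protocol.perfusion)
    if missing:
        raise ValueError(f"buffer protocol lacks windows: {sorted(missing)}")
    means = {b: _plateau_mean(trace, buffer_protocol, b) for b in ("saline", "mes", "nh4cl")}
    dyn = means["nh4cl"] - means["mes"]
    if dyn <= 0:
        raise ValueError(
            f"no dynamic range: F_NH4Cl={means['nh4cl']:.4g} <= F_MES={means['mes']:.4g}"
        )
    surface = 100.0 * (means["saline"] - means["mes"]) / dyn
    clipped = surface < 0
    surface = max(surface, 0.0)
    return PartitionResult(
        surface_pct=surface, vesicular_pct=100.0 - surface,
        window_means=means, clipped=clipped,
    )


@dataclass(frozen=True)
class ExpressionResult:
    fold_change: float
    compartment: str
    n_rois: dict

    def __post_init__(self) -> None:
        if self.compartment not in ("terminal", "soma"):
            raise ValueError("compartment must be 'terminal' or 'soma'")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


def expression_fold_change(
    transfected_rois,
    untransfected_rois,
    background_rois,
    compartment: str = "terminal",
) -> ExpressionResult:
    """Background-subtracted expression fold-change over untransfected cells."""
    trans = np.asarray(transfected_rois, dtype=float)
    untrans = np.asarray(untransfected_rois, dtype=float)
    bg = np.asarray(background_rois, dtype=float)
    for name, arr in (("transfected", trans), ("untransfected", untrans),
                      ("background", bg)):
        if arr.size < 1:
            raise ValueError(f"need >= 1 {name} ROI")
    denom = float(untrans.mean() - bg.mean())
    if denom <= 0:
        raise ValueError(
            f"untransfected mean {untrans.mean():.4g} does not exceed "
            f"background {bg.mean():.4g}"
        )
    fold = float(trans.mean() - bg.mean()) / denom
    return ExpressionResult(
        fold_change=fold, compartment=compartment,
        n_rois={"transfected": trans.size, "untransfected": untrans.size,
                "background": bg.size},
    )
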