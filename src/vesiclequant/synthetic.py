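"""In-silico pHluorin experiments: traces, fields, line profiles, cohorts.

The generative model for a bouton trace is

    F(t) = bleach(t) * [background + T * V(t)] + eps,   eps ~ N(0, sigma_rel*T)

where ``T`` is the bouton's total pHluorin fluorescence in arbitrary units
and ``V(t)`` is the visible fraction of that fluorescence:

* pH 7.4 bath:  V = s + (1-s) * (c(t) + q_v * (1 - c(t))) — the surface
  fraction ``s`` is always visible, fused vesicles (cumulative fused fraction
  ``c``) become visible, and unfused vesicles retain a residual ``q_v``
  (pHluorin is ~94% quenched at vesicular pH, so q_v defaults to 0.06);
* MES (pH 5.5) bath:  V = q_mes (default 0.03) — surface pHluorin quenched;
* NH4Cl bath:  V = 1 — all compartments dequenched (the total pool).

Under bafilomycin there is no reacidification, so ``c(t)`` is non-decreasing:
during sustained 10 Hz stimulation it follows one-phase kinetics
``c(t) = R*(1 - exp(-t/tau))`` toward the recycling-pool fraction ``R``; for
the RRP protocol it rises linearly to ``rrp_frac`` over the 2 s burst, holds
through the 3 s recovery, then resumes one-phase kinetics toward ``R``.

Photobleaching is a single exponential shared by all ROIs of a field, and
noise is additive Gaussian applied after bleach scaling (no shot noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocols import Protocol
from .traces import FieldRecord, ROITrace

__all__ = [
    "BoutonGroundTruth",
    "NoiseModel",
    "GroundTruthPriors",
    "PhenotypeLink",
    "MeasureLink",
    "PHENOTYPE_MEASURES",
    "FUNCTIONAL_METRICS",
    "Q_MES_DEFAULT",
    "DEFAULT_COHORT",
    "cumulative_fused_fraction",
    "visible_fraction",
    "simulate_bouton_trace",
    "simulate_background_trace",
    "simulate_field",
    "simulate_partitioning_trace",
    "simulate_line_profile",
    "simulate_cohort_phenotypes",
]

#: residual visibility of surface pHluorin in the acidic MES bath
Q_MES_DEFAULT = 0.03

#: camera pixel size used to convert line-profile lengths to microns
PIXEL_SIZE_UM = 0.227

#: minimum axonal segment length for a valid line profile
MIN_PROFILE_UM = 60.0


@dataclass(frozen=True)
class BoutonGroundTruth:
    """Latent quantities of one bouton that the pipeline later estimates."""

    total_units: float = 1000.0
    surface_frac: float = 0.25
    recycling_frac: float = 0.55
    rrp_frac: float = 0.08
    tau_true: float = 20.0
    vesicular_quench: float = 0.06
    responsive: bool = True

    def __post_init__(self) -> None:
        if self.total_units <= 0:
            raise ValueError("total_units must be > 0")
        if self.tau_true <= 0:
            raise ValueError("tau_true must be > 0")
        for name in ("surface_frac", "recycling_frac", "rrp_frac", "vesicular_quench"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rrp_frac > self.recycling_frac:
            raise ValueError("rrp_frac must not exceed recycling_frac")


@dataclass(frozen=True)
class NoiseModel:
    """Additive-Gaussian noise, background autofluorescence, and photobleach."""

    sigma_rel: float = 0.02
    background_level: float = 50.0
    bleach_tau: float = 600.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be > 0 (use np.inf to disable)")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def bleach(self, time_s: np.ndarray) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        if np.isinf(self.bleach_tau):
            return np.ones_like(t)
        return np.exp(-(t - t[0]) / self.bleach_tau)


def cumulative_fused_fraction(
    gt: BoutonGroundTruth, protocol: Protocol, time_s
) -> np.ndarray:
    """Closed-form cumulative fused fraction c(t) under bafilomycin.

    Monotone non-decreasing; zero for unresponsive boutons or before
    stimulation; held at its end-of-stimulation value afterwards.
    """
    t = np.asarray(time_s, dtype=float)
    if not gt.responsive or not protocol.has_stim:
        return np.zeros_like(t)
    segs = sorted(protocol.stim_segments, key=lambda s: s.t_start)
    if len(segs) == 1:
        seg = segs[0]
        tt = np.clip(t - seg.t_start, 0.0, seg.duration_s)
        return gt.recycling_frac * -np.expm1(-tt / gt.tau_true)
    if len(segs) == 2:
        burst, sustained = segs
        c = np.zeros_like(t)
        # linear release of the primed pool over the burst
        in_burst = t > burst.t_start
        c = np.where(
            in_burst,
            gt.rrp_frac * np.clip((t - burst.t_start) / burst.duration_s, 0.0, 1.0),
            c,
        )
        # hold through the recovery gap, then resume one-phase kinetics
        tt = np.clip(t - sustained.t_start, 0.0, sustained.duration_s)
        resumed = gt.recycling_frac - (gt.recycling_frac - gt.rrp_frac) * np.exp(
            -tt / gt.tau_true
        )
        return np.where(t >= sustained.t_start, resumed, c)
    raise ValueError("protocols with more than two stimulation segments unsupported")


def visible_fraction(
    gt: BoutonGroundTruth, protocol: Protocol, time_s, q_mes: float = Q_MES_DEFAULT
) -> np.ndarray:
    """Visible fraction V(t) of total bouton fluorescence at each frame."""
    t = np.asarray(time_s, dtype=float)
    c = cumulative_fused_fraction(gt, protocol, t)
    s, qv = gt.surface_frac, gt.vesicular_quench
    v = s + (1.0 - s) * (c + qv * (1.0 - c))
    if "mes" in protocol.perfusion:
        v = np.where(protocol.perfusion["mes"].contains(t), q_mes, v)
    if "nh4cl" in protocol.perfusion:
        v = np.where(protocol.perfusion["nh4cl"].contains(t), 1.0, v)
    return v


def simulate_bouton_trace(
    gt: BoutonGroundTruth,
    protocol: Protocol,
    noise: NoiseModel,
    q_mes: float = Q_MES_DEFAULT,
    roi_id: str = "roi_0",
    rng: np.random.Generator | None = None,
) -> ROITrace:
    """Simulate one synaptic ROI trace under the generative model."""
    protocol.nh4cl  # noqa: B018 - raises if the total pool is unrecoverable
    if protocol.has_stim and protocol.n_baseline_frames < 5:
        raise ValueError("protocol needs >= 5 baseline frames before stimulation")
    t = protocol.frame_times
    v = visible_fraction(gt, protocol, t, q_mes=q_mes)
    f = noise.bleach(t) * (noise.background_level + gt.total_units * v)
    if noise.sigma_rel > 0:
        if rng is None:
            rng = noise.rng()
        f = f + rng.normal(0.0, noise.sigma_rel * gt.total_units, size=t.shape)
    return ROITrace(roi_id=roi_id, roi_role="synaptic", time_s=t, intensity=f)


def simulate_background_trace(
    protocol: Protocol,
    noise: NoiseModel,
    roi_id: str = "bg_0",
    rng: np.random.Generator | None = None,
) -> ROITrace:
    """Background autofluorescence ROI: bleaching background plus noise."""
    t = protocol.frame_times
    f = noise.bleach(t) * noise.background_level
    if noise.sigma_rel > 0:
        if rng is None:
            rng = noise.rng()
        f = f + rng.normal(0.0, noise.sigma_rel * noise.background_level, size=t.shape)
    return ROITrace(roi_id=roi_id, roi_role="background", time_s=t, intensity=f)


@dataclass(frozen=True)
class GroundTruthPriors:
    """Uniform per-bouton parameter ranges for one variant's fields.

    Bouton-to-bouton heterogeneity is modelled as independent uniform draws:
    brightness varies widely between boutons while kinetic parameters scatter
    moderately around the variant's characteristic values.
    """

    total_units: tuple[float, float] = (700.0, 1300.0)
    surface_frac: tuple[float, float] = (0.20, 0.30)
    recycling_frac: tuple[float, float] = (0.50, 0.60)
    rrp_frac: tuple[float, float] = (0.06, 0.10)
    tau_s: tuple[float, float] = (18.0, 22.0)
    vesicular_quench: float = 0.06

    @classmethod
    def for_variant(
        cls,
        tau: float = 20.0,
        recycling: float = 0.55,
        surface: float = 0.25,
        rrp: float = 0.08,
        tau_rel_jitter: float = 0.10,
        frac_jitter: float = 0.05,
        rrp_jitter: float = 0.02,
        total_units: tuple[float, float] = (700.0, 1300.0),
        vesicular_quench: float = 0.06,
    ) -> "GroundTruthPriors":
        clip01 = lambda lo, hi: (max(lo, 0.0), min(hi, 1.0))  # noqa: E731
        return cls(
            total_units=total_units,
            surface_frac=clip01(surface - frac_jitter, surface + frac_jitter),
            recycling_frac=clip01(recycling - frac_jitter, recycling + frac_jitter),
            rrp_frac=clip01(rrp - rrp_jitter, rrp + rrp_jitter),
            tau_s=(tau * (1 - tau_rel_jitter), tau * (1 + tau_rel_jitter)),
            vesicular_quench=vesicular_quench,
        )

    def center(self) -> BoutonGroundTruth:
        mid = lambda r: 0.5 * (r[0] + r[1])  # noqa: E731
        return BoutonGroundTruth(
            total_units=mid(self.total_units),
            surface_frac=mid(self.surface_frac),
            recycling_frac=mid(self.recycling_frac),
            rrp_frac=mid(self.rrp_frac),
            tau_true=mid(self.tau_s),
            vesicular_quench=self.vesicular_quench,
        )

    def draw(self, rng: np.random.Generator, responsive: bool = True) -> BoutonGroundTruth:
        u = lambda r: float(rng.uniform(*r))  # noqa: E731
        recycling = u(self.recycling_frac)
        rrp = min(u(self.rrp_frac), recycling)
        return BoutonGroundTruth(
            total_units=u(self.total_units),
            surface_frac=u(self.surface_frac),
            recycling_frac=recycling,
            rrp_frac=rrp,
            tau_true=u(self.tau_s),
            vesicular_quench=self.vesicular_quench,
            responsive=responsive,
        )


def simulate_field(
    n_responsive: int,
    n_dead: int,
    n_background: int,
    priors: GroundTruthPriors,
    protocol: Protocol,
    noise: NoiseModel,
    field_id: str = "field_0",
    variant: str = "WT",
    seed: int | None = None,
    q_mes: float = Q_MES_DEFAULT,
) -> FieldRecord:
    """Simulate one field of view: responsive + dead synaptic ROIs + background.

    All traces share the field's bleach constant and protocol; per-ROI ground
    truth is retained in ``FieldRecord.ground_truth``.
    """
    if n_responsive + n_dead + n_background <= 0:
        raise ValueError("field must contain at least one ROI")
    if n_background < 1:
        raise ValueError("need >= 1 background ROI for the bleach fit")
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    traces: list[ROITrace] = []
    gt_rows = []
    for i in range(n_responsive + n_dead):
        gt = priors.draw(rng, responsive=i < n_responsive)
        roi_id = f"syn_{i:03d}"
        traces.append(
            simulate_bouton_trace(gt, protocol, noise, q_mes=q_mes, roi_id=roi_id, rng=rng)
        )
        gt_rows.append({"roi_id": roi_id, **vars(gt)})
    for j in range(n_background):
        traces.append(
            simulate_background_trace(protocol, noise, roi_id=f"bg_{j:03d}", rng=rng)
        )
    return FieldRecord(
        field_id=field_id, variant=variant, assay=protocol.name,
        traces=traces, ground_truth=pd.DataFrame(gt_rows),
    )


def simulate_partitioning_trace(
    gt: BoutonGroundTruth,
    buffer_sequence: Protocol,
    noise: NoiseModel,
    q_mes: float = Q_MES_DEFAULT,
    roi_id: str = "roi_0",
    rng: np.random.Generator | None = None,
) -> ROITrace:
    """Simulate a membrane-partitioning trace (saline → MES → NH4Cl)."""
    missing = {"saline", "mes", "nh4cl"} - set(buffer_sequence.perfusion)
    if missing:
        raise ValueError(f"buffer sequence lacks windows: {sorted(missing)}")
    return simulate_bouton_trace(
        gt, buffer_sequence, noise, q_mes=q_mes, roi_id=roi_id, rng=rng
    )


def simulate_line_profile(
    length_px: int,
    n_puncta: int,
    punctum_amp: float,
    baseline: float,
    noise_sd: float,
    seed: int | None = None,
    punctum_sigma_px: float = 4.0,
    px_size_um: float = PIXEL_SIZE_UM,
) -> np.ndarray:
    """Axonal line-profile intensity: baseline + Gaussian puncta + noise.

    The profile must correspond to an axonal segment longer than 60 um
    (>= 265 px at 0.227 um/px).
    """
    if length_px * px_size_um < MIN_PROFILE_UM:
        raise ValueError(
            f"profile of {length_px} px is {length_px * px_size_um:.1f} um; "
            f"need > {MIN_PROFILE_UM:.0f} um"
        )
    rng = np.random.default_rng(seed)
    x = np.arange(length_px, dtype=float)
    profile = np.full(length_px, float(baseline))
    margin = 3.0 * punctum_sigma_px
    for _ in range(n_puncta):
        pos = rng.uniform(margin, length_px - margin)
        profile += punctum_amp * np.exp(-0.5 * ((x - pos) / punctum_sigma_px) ** 2)
    if noise_sd > 0:
        profile += rng.normal(0.0, noise_sd, size=length_px)
    return profile


# --------------------------------------------------------------------------
# cohort phenotypes

PHENOTYPE_MEASURES = (
    "VABS_communication",
    "VABS_motor",
    "CVI_total",
    "movement_disorder_count",
    "DBC_self_injury",
)

FUNCTIONAL_METRICS = ("initial_rate", "tau_s", "frac_fused_200AP_pct")

#: baseline score around which an unlinked (null) measure scatters
_NULL_BASELINES = {
    "VABS_communication": 60.0,
    "VABS_motor": 60.0,
    "CVI_total": 20.0,
    "movement_disorder_count": 2.0,
    "DBC_self_injury": 4.0,
}

#: measure-specific noise SD in score units (dimensionless defaults chosen so
#: linked scores stay clearly monotone at realistic between-variant spreads)
_NOISE_SD = {
    "VABS_communication": 2.0,
    "VABS_motor": 2.0,
    "CVI_total": 3.0,
    "movement_disorder_count": 1.0,
    "DBC_self_injury": 1.5,
}


@dataclass(frozen=True)
class MeasureLink:
    """Linear link: score = slope * metric + intercept + noise."""

    metric: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.metric not in FUNCTIONAL_METRICS:
            raise ValueError(f"unknown functional metric {self.metric!r}")


@dataclass(frozen=True)
class PhenotypeLink:
    """Monotone link between true exocytic deficit and phenotype scores.

    ``links`` maps a phenotype measure to its :class:`MeasureLink`;
    every other measure in ``null_measures`` is pure noise around a
    measure-typical baseline. A measure may not be both linked and null.
    """

    links: dict[str, MeasureLink] = field(default_factory=dict)
    null_measures: tuple[str, ...] = ()
    noise_sd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.links) & set(self.null_measures)
        if overlap:
            raise ValueError(f"measures both linked and null: {sorted(overlap)}")
        for m in list(self.links) + list(self.null_measures):
            if m not in PHENOTYPE_MEASURES:
                raise ValueError(f"unknown phenotype measure {m!r}")
        sd = dict(_NOISE_SD if self.noise_sd is None else self.noise_sd)
        if any(v < 0 for v in sd.values()):
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "noise_sd", sd)

    @classmethod
    def vabs_deficit_default(cls) -> "PhenotypeLink":
        """Study-condition default: adaptive-function (VABS) scores track the
        exocytic deficit; CVI, movement-disorder and self-injury scores do not.

        Slopes map a 10-50% fused-by-200AP range onto VABS standard scores of
        roughly 45-95.
        """
        return cls(
            links={
                "VABS_communication": MeasureLink("frac_fused_200AP_pct", 1.25, 33.0),
                "VABS_motor": MeasureLink("frac_fused_200AP_pct", 1.25, 33.0),
            },
            null_measures=("CVI_total", "movement_disorder_count", "DBC_self_injury"),
        )


def simulate_cohort_phenotypes(
    variant_metrics: pd.DataFrame,
    link: PhenotypeLink,
    ages=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-variant phenotype scores generated from true functional metrics.

    ``variant_metrics`` is indexed by variant label with the three functional
    metric columns. Returns one row per variant with the five phenotype
    measures, age (years) and participant count; ordinal measures are rounded
    and clipped to their instrument ranges (movement-disorder count >= 0,
    DBC self-injury sum in [0, 10]).
    """
    if variant_metrics.index.duplicated().any():
        dups = variant_metrics.index[variant_metrics.index.duplicated()].tolist()
        raise ValueError(f"duplicated variant labels: {dups}")
    if len(variant_metrics) < 5:
        raise ValueError("need >= 5 variants for a cohort")
    missing = set(FUNCTIONAL_METRICS) - set(variant_metrics.columns)
    if missing:
        raise ValueError(f"variant_metrics lacks columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = len(variant_metrics)
    if ages is None:
        ages = rng.uniform(3.0, 25.0, size=n)
    ages = np.asarray(ages, dtype=float)
    out = pd.DataFrame(index=variant_metrics.index.copy())
    for measure in PHENOTYPE_MEASURES:
        sd = link.noise_sd.get(measure, 0.0)
        eps = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        if measure in link.links:
            ml = link.links[measure]
            score = ml.slope * variant_metrics[ml.metric].to_numpy() + ml.intercept + eps
        else:
            score = _NULL_BASELINES[measure] + eps
        if measure == "movement_disorder_count":
            score = np.clip(np.round(score), 0, None)
        elif measure == "DBC_self_injury":
            score = np.clip(np.round(score), 0, 10)
        out[measure] = score
    out["age"] = ages
    out["n_participants"] = 1
    return out


#: paper-shaped cohort of one wild-type reference and eight variants with
#: graded slowing (tau multiplier) and pool-size deficits (recycling factor)
DEFAULT_COHORT: dict[str, dict] = {
    "WT": dict(tau=20.0, recycling=0.55, rrp=0.080, surface=0.25),
    "V01": dict(tau=22.0, recycling=0.55, rrp=0.078, surface=0.25),
    "V02": dict(tau=25.0, recycling=0.54, rrp=0.075, surface=0.25),
    "V03": dict(tau=28.0, recycling=0.53, rrp=0.070, surface=0.25),
    "V04": dict(tau=32.0, recycling=0.51, rrp=0.065, surface=0.25),
    "V05": dict(tau=36.0, recycling=0.49, rrp=0.058, surface=0.25),
    "V06": dict(tau=40.0, recycling=0.46, rrp=0.050, surface=0.25),
    "V07": dict(tau=46.0, recycling=0.42, rrp=0.042, surface=0.25),
    "V08": dict(tau=52.0, recycling=0.38, rrp=0.035, surface=0.25),
}
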