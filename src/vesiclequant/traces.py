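"""ROI-trace processing: bleach correction, ΔF/F0, QC screening, averaging.

The processing chain mirrors standard pHluorin practice for evoked-exocytosis
assays run under bafilomycin:

1. fit a single exponential to the mean background-ROI trace over the frames
   before NH4Cl superfusion (:func:`fit_background_bleach`);
2. divide every trace by the fitted decay, anchored so the first frame is
   unchanged (:func:`apply_bleach_correction`);
3. subtract the mean background trace from synaptic ROIs
   (:func:`subtract_background`);
4. convert to ΔF/F0 with F0 the mean of the 5 frames before stimulation
   (:func:`compute_dff`);
5. screen ROIs — only ROIs that respond to both stimulation and NH4Cl are
   kept, and a field enters the final data only if it has more than
   ``RESPONSIVE_ROI_MIN`` (20) responsive ROIs (:func:`screen_rois`);
6. average included ROIs frame-wise (:func:`field_average`) and normalize to
   either the end-of-stimulation plateau or the NH4Cl peak
   (:func:`normalize_trace`).

:func:`process_field` runs the whole chain on one :class:`FieldRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

from .protocols import Protocol, Window

__all__ = [
    "ROITrace",
    "FieldRecord",
    "BleachModel",
    "QCReport",
    "RESPONSIVE_ROI_MIN",
    "BASELINE_FRAMES",
    "fit_background_bleach",
    "apply_bleach_correction",
    "subtract_background",
    "compute_dff",
    "screen_rois",
    "field_average",
    "normalize_trace",
    "stim_peak_reference",
    "nh4cl_peak_reference",
    "corrected_background_slope_ci",
    "ProcessedField",
    "process_field",
]

#: fields need strictly more than this many responsive ROIs to be included
RESPONSIVE_ROI_MIN = 20

#: number of pre-stimulation frames defining the F0 baseline
BASELINE_FRAMES = 5


@dataclass(frozen=True)
class ROITrace:
    """One ROI's fluorescence time series with a role and processing flags."""

    roi_id: str
    roi_role: str  # 'synaptic' | 'background'
    time_s: np.ndarray
    intensity: np.ndarray
    flags: frozenset = frozenset({"raw"})

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", f)
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.roi_role not in ("synaptic", "background"):
            raise ValueError(f"roi_role must be synaptic|background, got {self.roi_role!r}")
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("time_s and intensity must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"time must be strictly increasing (roi {self.roi_id})")
        if not np.all(np.isfinite(f)):
            raise ValueError(f"intensity must be finite (roi {self.roi_id})")

    def with_intensity(self, intensity, add_flags=()) -> "ROITrace":
        return replace(
            self, intensity=np.asarray(intensity, dtype=float),
            flags=self.flags | frozenset(add_flags),
        )


@dataclass
class FieldRecord:
    """All ROI traces of one field of view (one coverslip) plus metadata."""

    field_id: str
    variant: str
    assay: str
    traces: list[ROITrace] = field(default_factory=list)
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.traces) == 0:
            raise ValueError(f"field {self.field_id!r} has no ROI traces")

    @property
    def synaptic_traces(self) -> list[ROITrace]:
        return [t for t in self.traces if t.roi_role == "synaptic"]

    @property
    def background_traces(self) -> list[ROITrace]:
        return [t for t in self.traces if t.roi_role == "background"]


@dataclass(frozen=True)
class BleachModel:
    """Single-exponential photobleach model a*exp(-b*(t - t0))."""

    amplitude: float
    rate: float  # 1/s, >= 0
    t0: float
    fit_window: Window
    rss: float

    def decay(self, time_s) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * (np.asarray(time_s) - self.t0))


def _mean_trace(traces: list[ROITrace]) -> tuple[np.ndarray, np.ndarray]:
    ref = traces[0].time_s
    for tr in traces[1:]:
        if tr.time_s.shape != ref.shape or not np.allclose(tr.time_s, ref):
            raise ValueError("traces do not share a common frame schedule")
    return ref, np.mean([tr.intensity for tr in traces], axis=0)


def fit_background_bleach(
    background_traces: list[ROITrace], nh4cl_onset: float
) -> BleachModel:
    """Fit a*exp(-b*t) to the mean background trace before NH4Cl onset.

    The rate ``b`` is constrained to be non-negative: a non-decaying
    background yields b = 0 rather than an amplifying "correction".
    """
    if not background_traces:
        raise ValueError("at least one background ROI is required")
    t_all, f_all = _mean_trace(background_traces)
    mask = t_all < nh4cl_onset
    t, f = t_all[mask], f_all[mask]
    if t.size < 10:
        raise ValueError(
            f"need >= 10 frames before NH4Cl onset for the bleach fit, got {t.size}"
        )
    if np.allclose(f, 0.0):
        raise ValueError("background trace is all zero; cannot fit bleach decay")

    t0 = t[0]
    ts = t - t0

    def model(tt, a, b):
        return a * np.exp(-b * tt)

    # log-linear initialization when the trace is positive; if the
    # exponential model fits the data exactly (noiseless input), the
    # log-space solution is the least-squares solution — use it directly
    a0 = max(float(f[0]), 1e-12)
    if np.all(f > 0):
        logf = np.log(f)
        slope, intercept = np.polyfit(ts, logf, 1)
        if np.max(np.abs(logf - (intercept + slope * ts))) < 1e-10:
            a, b = float(np.exp(intercept)), float(max(-slope, 0.0))
            return BleachModel(
                amplitude=a, rate=b, t0=float(t0),
                fit_window=Window(float(t0), float(nh4cl_onset)), rss=0.0,
            )
        b0 = max(-slope, 1e-9)
    else:
        b0 = 1e-3
    last_err: Exception | None = None
    for p0 in ([a0, b0], [float(np.mean(f)), 1e-3], [a0, 1e-6]):
        try:
            popt, _ = curve_fit(
                model, ts, f, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
            break
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    else:  # pragma: no cover - rare
        raise RuntimeError(
            f"bleach fit failed after retries (n={t.size}, "
            f"mean={np.mean(f):.3g}, last error: {last_err})"
        )
    a, b = float(popt[0]), float(max(popt[1], 0.0))
    rss = float(np.sum((f - model(ts, a, b)) ** 2))
    return BleachModel(
        amplitude=a, rate=b, t0=float(t0),
        fit_window=Window(float(t0), float(nh4cl_onset)), rss=rss,
    )


def apply_bleach_correction(trace: ROITrace, model: BleachModel) -> ROITrace:
    """Divide out the fitted decay, leaving the first frame unchanged."""
    if "bleach_corrected" in trace.flags:
        raise ValueError(f"roi {trace.roi_id} is already bleach-corrected")
    corrected = trace.intensity * np.exp(model.rate * (trace.time_s - model.t0))
    return trace.with_intensity(corrected, add_flags={"bleach_corrected"})


def subtract_background(trace: ROITrace, background_mean: np.ndarray) -> ROITrace:
    background_mean = np.asarray(background_mean, dtype=float)
    if background_mean.shape != trace.intensity.shape:
        raise ValueError("background trace length does not match ROI trace")
    return trace.with_intensity(
        trace.intensity - background_mean, add_flags={"background_subtracted"}
    )


def _baseline_slice(trace: ROITrace, stim_onset: float) -> np.ndarray:
    idx = np.flatnonzero(trace.time_s < stim_onset)
    if idx.size < BASELINE_FRAMES:
        raise ValueError(
            f"need >= {BASELINE_FRAMES} frames before stimulation, got {idx.size}"
        )
    return idx[-BASELINE_FRAMES:]


def compute_dff(trace: ROITrace, stim_onset: float) -> ROITrace:
    """ΔF/F0 with F0 the mean of the last 5 frames before stimulation."""
    idx = _baseline_slice(trace, stim_onset)
    f0 = float(np.mean(trace.intensity[idx]))
    if f0 <= 0:
        raise ValueError(
            f"roi {trace.roi_id}: baseline F0={f0:.4g} <= 0 "
            "(background subtraction may have failed)"
        )
    return trace.with_intensity((trace.intensity - f0) / f0, add_flags={"dff"})


@dataclass
class QCReport:
    """Per-ROI inclusion decisions and the field-level verdict."""

    roi_status: pd.DataFrame  # columns: roi_id, included, reason
    n_responsive: int
    field_pass: bool

    @property
    def included_ids(self) -> list[str]:
        df = self.roi_status
        return df.loc[df["included"], "roi_id"].tolist()


def screen_rois(
    dff_traces: list[ROITrace], protocol: Protocol, noise_k: float = 2.0
) -> QCReport:
    """Screen ΔF/F0 synaptic ROIs for responsiveness.

    An ROI is responsive iff its mean ΔF/F0 over the stimulation window
    exceeds ``noise_k`` baseline SDs AND its peak ΔF/F0 in the NH4Cl window
    does too. A field passes only with strictly more than
    ``RESPONSIVE_ROI_MIN`` responsive ROIs.
    """
    stim = protocol.stim_window
    nh4cl = protocol.nh4cl
    rows = []
    for tr in dff_traces:
        if tr.roi_role != "synaptic":
            continue
        if "dff" not in tr.flags:
            raise ValueError(f"roi {tr.roi_id} is not ΔF/F0-processed")
        base = tr.intensity[_baseline_slice(tr, protocol.stim_onset)]
        sd = float(np.std(base, ddof=1))
        thresh = noise_k * sd
        stim_mean = float(np.mean(tr.intensity[protocol.frames_in(stim)]))
        nh4_peak = float(np.max(tr.intensity[protocol.frames_in(nh4cl)]))
        if stim_mean <= thresh:
            rows.append((tr.roi_id, False, "no_stim_response"))
        elif nh4_peak <= thresh:
            rows.append((tr.roi_id, False, "no_nh4cl_response"))
        else:
            rows.append((tr.roi_id, True, "ok"))
    status = pd.DataFrame(rows, columns=["roi_id", "included", "reason"])
    n_resp = int(status["included"].sum())
    return QCReport(
        roi_status=status, n_responsive=n_resp,
        field_pass=n_resp > RESPONSIVE_ROI_MIN,
    )


def field_average(dff_traces: list[ROITrace], qc: QCReport) -> ROITrace:
    """Frame-wise mean ΔF/F0 over QC-included ROIs."""
    if not qc.field_pass:
        raise ValueError(
            f"field excluded: {qc.n_responsive} responsive ROIs "
            f"(need > {RESPONSIVE_ROI_MIN})"
        )
    included = set(qc.included_ids)
    kept = [t for t in dff_traces if t.roi_id in included]
    time_s, mean = _mean_trace(kept)
    flags = frozenset.intersection(*(t.flags for t in kept))
    return ROITrace(
        roi_id="field_mean", roi_role="synaptic",
        time_s=time_s, intensity=mean, flags=flags,
    )


def stim_peak_reference(trace: ROITrace, protocol: Protocol) -> float:
    """Peak fluorescence at the end of stimulation: mean of the last 5 stim frames."""
    idx = protocol.frames_in(protocol.stim_window)
    if idx.size < BASELINE_FRAMES:
        raise ValueError("stimulation window has fewer than 5 frames")
    return float(np.mean(trace.intensity[idx[-BASELINE_FRAMES:]]))


def nh4cl_peak_reference(trace: ROITrace, protocol: Protocol) -> float:
    """Peak fluorescence in the NH4Cl window: the window maximum."""
    idx = protocol.frames_in(protocol.nh4cl)
    if idx.size == 0:
        raise ValueError("no frames inside the NH4Cl window")
    return float(np.max(trace.intensity[idx]))


def normalize_trace(trace: ROITrace, mode: str, protocol: Protocol) -> ROITrace:
    """Normalize a field-mean ΔF/F0 trace to the stim or NH4Cl peak."""
    if mode == "stim_peak":
        ref = stim_peak_reference(trace, protocol)
        flag = "normalized_stim_peak"
    elif mode == "nh4cl_peak":
        ref = nh4cl_peak_reference(trace, protocol)
        flag = "normalized_nh4cl"
    else:
        raise ValueError(f"mode must be 'stim_peak' or 'nh4cl_peak', got {mode!r}")
    if flag in trace.flags:  # idempotent: reference is 1 by construction
        return trace
    if ref <= 0:
        raise ValueError(f"normalization reference {ref:.4g} <= 0")
    return trace.with_intensity(trace.intensity / ref, add_flags={flag})


def corrected_background_slope_ci(
    corrected_background: ROITrace, nh4cl_onset: float, conf: float = 0.95
) -> tuple[float, float, float]:
    """OLS slope of a corrected background trace with a confidence interval.

    Returns ``(slope, lo, hi)``; a successful bleach correction leaves a
    background trace whose interval contains zero.
    """
    mask = corrected_background.time_s < nh4cl_onset
    t = corrected_background.time_s[mask]
    y = corrected_background.intensity[mask]
    n = t.size
    if n < 3:
        raise ValueError("need >= 3 frames for a slope CI")
    tc = t - t.mean()
    slope = float(np.sum(tc * y) / np.sum(tc**2))
    resid = y - y.mean() - slope * tc
    se = float(np.sqrt(np.sum(resid**2) / (n - 2) / np.sum(tc**2)))
    half = t_dist.ppf(0.5 + conf / 2, n - 2) * se
    return slope, slope - half, slope + half


@dataclass
class ProcessedField:
    """Output of the per-field processing chain."""

    field_id: str
    variant: str
    bleach_model: BleachModel
    dff_traces: list[ROITrace]
    qc: QCReport
    mean_dff: ROITrace | None  # None when the field fails QC


def process_field(
    field_record: FieldRecord, protocol: Protocol, noise_k: float = 2.0
) -> ProcessedField:
    """Run bleach correction → background subtraction → ΔF/F0 → QC → average."""
    backgrounds = field_record.background_traces
    model = fit_background_bleach(backgrounds, protocol.nh4cl.t_start)
    corr_bg = [apply_bleach_correction(tr, model) for tr in backgrounds]
    _, bg_mean = _mean_trace(corr_bg)
    dff_traces = []
    for tr in field_record.synaptic_traces:
        corrected = apply_bleach_correction(tr, model)
        subtracted = subtract_background(corrected, bg_mean)
        dff_traces.append(compute_dff(subtracted, protocol.stim_onset))
    qc = screen_rois(dff_traces, protocol, noise_k=noise_k)
    mean_dff = field_average(dff_traces, qc) if qc.field_pass else None
    return ProcessedField(
        field_id=field_record.field_id, variant=field_record.variant,
        bleach_model=model, dff_traces=dff_traces, qc=qc, mean_dff=mean_dff,
    )
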