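"""Stimulation and perfusion protocols for pHluorin imaging experiments.

A :class:`Protocol` describes everything the analysis needs to know about an
acquisition: when frames were captured, when field stimulation was delivered
(action-potential count and frequency), and when each perfusion buffer
(saline at pH 7.4, acidic MES, alkaline NH4Cl) was present in the bath.

Three presets encode the standard assays:

``pool_1200ap``
    Recycling-pool assay — 1200 AP at 10 Hz for 2 min under bafilomycin,
    followed by NH4Cl dequenching to reveal the total vesicle pool.
    Frames at 1 s intervals, 5 baseline frames at t = -5 ... -1 s.
``rrp_40ap``
    Readily-releasable-pool assay — 40 AP at 20 Hz for 2 s, a 3 s recovery,
    then continuous 10 Hz stimulation for 2 min and NH4Cl. Frames at 1 s
    intervals except during the 5 s burst + recovery, acquired at 10 Hz.
``partitioning``
    Membrane-partitioning assay — sequential saline / MES / NH4Cl perfusion
    with no stimulation.

All time windows are half-open ``[t_start, t_end)`` in seconds, with t = 0 at
stimulation onset (or at the start of acquisition for unstimulated assays).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "StimSegment",
    "Window",
    "Protocol",
    "pool_1200ap",
    "rrp_40ap",
    "partitioning",
    "get_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class StimSegment:
    """A constant-frequency train of field-stimulation action potentials."""

    n_ap: int
    frequency_hz: float
    t_start: float

    def __post_init__(self) -> None:
        if self.n_ap <= 0:
            raise ValueError("n_ap must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.n_ap / self.frequency_hz

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_s


@dataclass(frozen=True)
class Window:
    """Half-open time window [t_start, t_end) in seconds."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("window must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.t_start) & (t < self.t_end)


@dataclass
class Protocol:
    name: str
    frame_times: np.ndarray
    stim_segments: list[StimSegment] = field(default_factory=list)
    perfusion: dict[str, Window] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.ndim != 1 or self.frame_times.size < 2:
            raise ValueError("frame_times must be a 1-D array of >= 2 times")
        if not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        for key in self.perfusion:
            if key not in ("saline", "mes", "nh4cl"):
                raise ValueError(f"unknown perfusion buffer {key!r}")

    # -- stimulation ------------------------------------------------------
    @property
    def has_stim(self) -> bool:
        return bool(self.stim_segments)

    @property
    def stim_onset(self) -> float:
        if not self.stim_segments:
            raise ValueError(f"protocol {self.name!r} has no stimulation")
        return min(s.t_start for s in self.stim_segments)

    @property
    def stim_end(self) -> float:
        if not self.stim_segments:
            raise ValueError(f"protocol {self.name!r} has no stimulation")
        return max(s.t_end for s in self.stim_segments)

    @property
    def stim_window(self) -> Window:
        return Window(self.stim_onset, self.stim_end)

    def time_of_ap(self, n_ap: int) -> float:
        """Time at which the n_ap-th action potential has been delivered.

        Counts cumulatively across stimulation segments; ``n_ap=0`` maps to
        stimulation onset.
        """
        if n_ap < 0:
            raise ValueError("n_ap must be >= 0")
        segments = sorted(self.stim_segments, key=lambda s: s.t_start)
        if not segments:
            raise ValueError("protocol has no stimulation")
        if n_ap == 0:
            return segments[0].t_start
        remaining = n_ap
        for seg in segments:
            if remaining <= seg.n_ap:
                return seg.t_start + remaining / seg.frequency_hz
            remaining -= seg.n_ap
        total = sum(s.n_ap for s in segments)
        raise ValueError(f"n_ap={n_ap} exceeds the {total} AP delivered")

    # -- perfusion --------------------------------------------------------
    @property
    def nh4cl(self) -> Window:
        try:
            return self.perfusion["nh4cl"]
        except KeyError:
            raise ValueError(
                f"protocol {self.name!r} has no NH4Cl window; "
                "total pool is unrecoverable"
            ) from None

    # -- frame bookkeeping ------------------------------------------------
    def frames_in(self, window: Window) -> np.ndarray:
        """Indices of frames falling inside a half-open window."""
        return np.flatnonzero(window.contains(self.frame_times))

    @property
    def n_baseline_frames(self) -> int:
        if not self.stim_segments:
            return 0
        return int(np.sum(self.frame_times < self.stim_onset))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "frame_times": self.frame_times.tolist(),
            "stim_segments": [
                {"n_ap": s.n_ap, "frequency_hz": s.frequency_hz, "t_start": s.t_start}
                for s in self.stim_segments
            ],
            "perfusion": {
                k: {"t_start": w.t_start, "t_end": w.t_end}
                for k, w in self.perfusion.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            name=d["name"],
            frame_times=np.asarray(d["frame_times"], dtype=float),
            stim_segments=[StimSegment(**s) for s in d.get("stim_segments", [])],
            perfusion={k: Window(**w) for k, w in d.get("perfusion", {}).items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_file(cls, path) -> "Protocol":
        text = open(path).read()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)


def pool_1200ap() -> Protocol:
    """Recycling-pool assay: 1200 AP at 10 Hz, NH4Cl at 140-160 s."""
    return Protocol(
        name="pool_1200ap",
        frame_times=np.arange(-5.0, 161.0, 1.0),
        stim_segments=[StimSegment(n_ap=1200, frequency_hz=10.0, t_start=0.0)],
        perfusion={"nh4cl": Window(140.0, 160.0)},
    )


def rrp_40ap() -> Protocol:
    """RRP assay: 40 AP at 20 Hz, 3 s rest, 10 Hz for 2 min, NH4Cl at 145-165 s.

    Frames at 1 s intervals except the burst + recovery (t in [0, 5) s),
    acquired at 10 Hz.
    """
    frame_times = np.concatenate(
        [
            np.arange(-5.0, 0.0, 1.0),
            np.round(np.arange(0.0, 5.0, 0.1), 6),
            np.arange(5.0, 166.0, 1.0),
        ]
    )
    return Protocol(
        name="rrp_40ap",
        frame_times=frame_times,
        stim_segments=[
            StimSegment(n_ap=40, frequency_hz=20.0, t_start=0.0),
            StimSegment(n_ap=1200, frequency_hz=10.0, t_start=5.0),
        ],
        perfusion={"nh4cl": Window(145.0, 165.0)},
    )


def partitioning() -> Protocol:
    """Membrane-partitioning assay: saline / MES / NH4Cl, 40 s each, no stim."""
    return Protocol(
        name="partitioning",
        frame_times=np.arange(0.0, 120.0, 1.0),
        stim_segments=[],
        perfusion={
            "saline": Window(0.0, 40.0),
            "mes": Window(40.0, 80.0),
            "nh4cl": Window(80.0, 120.0),
        },
    )


PRESETS = {
    "pool_1200ap": pool_1200ap,
    "rrp_40ap": rrp_40ap,
    "partitioning": partitioning,
}


def get_preset(name: str) -> Protocol:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown protocol preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
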