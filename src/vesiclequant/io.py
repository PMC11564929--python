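"""Long-format CSV I/O for ROI traces, ground truth and phenotype tables.

Trace schema (one row per frame): ``field_id, roi_id, roi_role, frame_idx,
time_s, intensity`` plus optional ``variant`` and ``assay`` columns. Rows
may arrive in any order; records are canonically sorted by
(field_id, roi_id, frame_idx) on read, and malformed files raise
:class:`ParseError` naming the offending lines.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .traces import FieldRecord, ROITrace

__all__ = [
    "ParseError",
    "TRACE_COLUMNS",
    "read_trace_table",
    "write_trace_table",
    "write_json_summary",
]

TRACE_COLUMNS = ["field_id", "roi_id", "roi_role", "frame_idx", "time_s", "intensity"]

SCHEMA_VERSION = "1.0"


class ParseError(ValueError):
    """Malformed trace table; message carries file line numbers (1-based,
    header = line 1)."""


def read_trace_table(path) -> list[FieldRecord]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = df[~np.isfinite(df["intensity"])]
    if not bad.empty:
        raise ParseError(
            f"{path}: non-finite intensity at lines {(bad.index + 2).tolist()[:10]}"
        )
    dup = df.duplicated(subset=["field_id", "roi_id", "frame_idx"], keep="first")
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ParseError(f"{path}: duplicated (field, roi, frame) rows at lines {lines[:10]}")
    df = df.sort_values(["field_id", "roi_id", "frame_idx"], kind="stable")
    fields = []
    for field_id, fgrp in df.groupby("field_id", sort=True):
        traces = []
        for roi_id, rgrp in fgrp.groupby("roi_id", sort=True):
            t = rgrp["time_s"].to_numpy(dtype=float)
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                first_bad = int(rgrp.index[np.argmin(np.diff(t) > 0) + 1]) + 2
                raise ParseError(
                    f"{path}: non-monotone time for roi {roi_id!r} "
                    f"(field {field_id!r}) near line {first_bad}"
                )
            roles = rgrp["roi_role"].unique()
            if roles.size != 1:
                raise ParseError(
                    f"{path}: roi {roi_id!r} (field {field_id!r}) has "
                    f"inconsistent roles {roles.tolist()}"
                )
            traces.append(ROITrace(
                roi_id=str(roi_id), roi_role=str(roles[0]),
                time_s=t, intensity=rgrp["intensity"].to_numpy(dtype=float),
            ))
        variant = str(fgrp["variant"].iloc[0]) if "variant" in fgrp.columns else "unknown"
        assay = str(fgrp["assay"].iloc[0]) if "assay" in fgrp.columns else "unknown"
        fields.append(FieldRecord(
            field_id=str(field_id), variant=variant, assay=assay, traces=traces
        ))
    return fields


def write_trace_table(fields: list[FieldRecord], path) -> None:
    frames = []
    for fr in fields:
        for tr in fr.traces:
            frames.append(pd.DataFrame({
                "field_id": fr.field_id,
                "roi_id": tr.roi_id,
                "roi_role": tr.roi_role,
                "frame_idx": np.arange(tr.time_s.size),
                "time_s": tr.time_s,
                "intensity": tr.intensity,
                "variant": fr.variant,
                "assay": fr.assay,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, lineterminator="\r\n")


def write_json_summary(summary: dict, path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **summary}

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
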