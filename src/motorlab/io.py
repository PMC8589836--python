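"""Stable text formats for traces, event tables and reports.

Traces are TSV with header rows (``time_s`` plus ``intensity_au`` or
``extension_nm`` and ``trace_id``), event tables are TSV
(``start_s``/``end_s``/``class``/``end_reason``), pause tables are TSV, and
reports are JSON with units in the field names.  Floats round-trip at full
precision (shortest-repr formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engagements import EndReason, EngagementClass, EngagementEvent
from .trap import ExtensionTrace, PauseAnnotation, PauseType

__all__ = [
    "write_intensity_trace",
    "read_intensity_trace",
    "write_extension_trace",
    "read_extension_trace",
    "write_events",
    "read_events",
    "write_pauses",
    "read_pauses",
    "write_report",
    "read_report",
]


def write_intensity_trace(trace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "intensity_au": trace.intensities, "trace_id": trace.trace_id}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_intensity_trace(path, channel: str = "Cy3"):
    from .synth import IntensityTrace

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    trace_id = str(df["trace_id"].iloc[0]) if "trace_id" in df and len(df) else ""
    return IntensityTrace(
        df["time_s"].to_numpy(), df["intensity_au"].to_numpy(), channel, trace_id
    )


def write_extension_trace(trace: ExtensionTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "extension_nm": trace.extension_nm,
            "force_pN": trace.force_pN,
            "trace_id": trace.trace_id,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_extension_trace(path) -> ExtensionTrace:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    trace_id = str(df["trace_id"].iloc[0]) if "trace_id" in df and len(df) else ""
    return ExtensionTrace(
        df["time_s"].to_numpy(),
        df["extension_nm"].to_numpy(),
        float(df["force_pN"].iloc[0]),
        trace_id=trace_id,
    )


def write_events(events: list[EngagementEvent], path) -> None:
    pd.DataFrame(
        {
            "start_s": [ev.start for ev in events],
            "end_s": [ev.end for ev in events],
            "class": [ev.event_class.value for ev in events],
            "end_reason": [ev.end_reason.value for ev in events],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> list[EngagementEvent]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        EngagementEvent(float(s), float(e), EngagementClass(c), EndReason(r))
        for s, e, c, r in zip(df["start_s"], df["end_s"], df["class"], df["end_reason"])
    ]


def write_pauses(pauses: PauseAnnotation, path) -> None:
    pd.DataFrame(
        {
            "start_s": [s for s, _ in pauses.intervals],
            "end_s": [e for _, e in pauses.intervals],
            "pause_type": [t.value for t in pauses.pause_types],
            "pause_velocity_bp_s": pauses.pause_velocities_bp_s,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pauses(path) -> PauseAnnotation:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ann = PauseAnnotation()
    for row in df.itertuples(index=False):
        ann.intervals.append((float(row.start_s), float(row.end_s)))
        ann.pause_types.append(PauseType(row.pause_type))
        ann.pause_velocities_bp_s.append(float(row.pause_velocity_bp_s))
    return ann


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
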