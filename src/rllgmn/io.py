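"""File round-trips: record / RRI / event CSVs, weight files, reports.

CSV schemas (UTF-8, comma-separated, ``.`` decimal):

* record: ``time_s,<ch1>,<ch2>,...``
* RRI: ``beat_time_s,rri_ms``
* events: ``record_id,event_time_s,event_type``

Weight files are JSON with an explicit format version and term ordering;
round-trips are bit-exact (write -> read -> write yields identical bytes).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ModelShape, RLLGMNWeights
from .exceptions import InvalidParameterError
from .preprocess import RRISequence, VitalRecord

logger = logging.getLogger(__name__)

WEIGHT_FORMAT_VERSION = 1
TERM_ORDER = "const,linear,upper_tri"

__all__ = [
    "read_record_csv", "write_record_csv",
    "read_rri_csv", "write_rri_csv",
    "read_events_csv", "write_events_csv",
    "read_weights", "write_weights",
    "write_report",
]


def read_record_csv(path, record_id: str | None = None,
                    event_time: float | None = None) -> VitalRecord:
    """Read ``time_s,<channels...>``; rows with any missing value are dropped."""
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise InvalidParameterError(f"{path}: first column must be time_s")
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.warning("%s: dropped %d rows with missing values", path, n0 - len(df))
    if len(df) < 2:
        raise InvalidParameterError(f"{path}: fewer than 2 complete samples")
    t = df["time_s"].to_numpy(dtype=float)
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise InvalidParameterError(f"{path}: time_s must be strictly increasing")
    dt = float(np.median(dts))
    if np.ptp(dts) > 1e-6 * dt:
        logger.warning("%s: non-uniform sampling after dropped rows; dt=%.3g", path, dt)
    return VitalRecord(
        record_id=record_id or Path(path).stem,
        dt=dt,
        channels=[c for c in df.columns[1:]],
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        event_time=event_time,
    )


def write_record_csv(path, record: VitalRecord) -> None:
    t = np.arange(record.n_samples) * record.dt
    df = pd.DataFrame({"time_s": t})
    for j, ch in enumerate(record.channels):
        df[ch] = record.values[:, j]
    df.to_csv(path, index=False)


def read_rri_csv(path) -> RRISequence:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["beat_time_s", "rri_ms"]:
        raise InvalidParameterError(f"{path}: header must be beat_time_s,rri_ms")
    df = df.dropna()
    return RRISequence(
        df["beat_time_s"].to_numpy(dtype=float), df["rri_ms"].to_numpy(dtype=float)
    )


def write_rri_csv(path, rri: RRISequence) -> None:
    pd.DataFrame({"beat_time_s": rri.beat_times, "rri_ms": rri.rri}).to_csv(
        path, index=False
    )


def read_events_csv(path) -> dict[str, list[float]]:
    df = pd.read_csv(path)
    need = {"record_id", "event_time_s"}
    if not need.issubset(df.columns):
        raise InvalidParameterError(f"{path}: header must include record_id,event_time_s")
    out: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["record_id"]), []).append(float(row["event_time_s"]))
    return out


def write_events_csv(path, events: dict[str, list[float]],
                     event_type: str = "deterioration") -> None:
    rows = [
        {"record_id": rid, "event_time_s": t, "event_type": event_type}
        for rid, times in events.items() for t in times
    ]
    pd.DataFrame(rows, columns=["record_id", "event_time_s", "event_type"]).to_csv(
        path, index=False
    )


def _ragged_weights(w: np.ndarray, shape: ModelShape) -> list:
    return [
        [
            [
                [w[c, kp, k, m].tolist() for m in range(shape.M[c][k])]
                for k in range(shape.K[c])
            ]
            for kp in range(shape.K[c])
        ]
        for c in range(shape.C)
    ]


def _dense_weights(ragged: list, shape: ModelShape) -> np.ndarray:
    w = np.zeros(shape.weight_array_shape)
    for c in range(shape.C):
        for kp in range(shape.K[c]):
            for k in range(shape.K[c]):
                for m in range(shape.M[c][k]):
                    w[c, kp, k, m] = ragged[c][kp][k][m]
    return w


def write_weights(path, weights: RLLGMNWeights, metadata: dict | None = None) -> None:
    shape = weights.shape
    doc = {
        "format_version": WEIGHT_FORMAT_VERSION,
        "term_order": TERM_ORDER,
        "shape": {"C": shape.C, "K": list(shape.K),
                  "M": [list(r) for r in shape.M], "d": shape.d},
        "weights": _ragged_weights(weights.w, shape),
        "first_step_weights": (
            None if weights.w_first is None else _ragged_weights(weights.w_first, shape)
        ),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def read_weights(path) -> RLLGMNWeights:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != WEIGHT_FORMAT_VERSION:
        raise InvalidParameterError(
            f"{path}: unsupported weight-file version {doc.get('format_version')!r}"
        )
    if doc.get("term_order") != TERM_ORDER:
        raise InvalidParameterError(f"{path}: unknown term order {doc.get('term_order')!r}")
    sh = doc["shape"]
    shape = ModelShape(sh["C"], sh["K"], sh["M"], sh["d"])
    w = _dense_weights(doc["weights"], shape)
    wf = doc.get("first_step_weights")
    return RLLGMNWeights(
        shape, w, None if wf is None else _dense_weights(wf, shape)
    )


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def write_features(path, sequences) -> None:
    """Serialize a list of FeatureSequence to JSON (text-only artifact)."""
    doc = [
        {
            "x": fs.x.tolist(), "label": int(fs.label),
            "teacher": fs.teacher.tolist(), "record_id": fs.record_id,
            "window_end": fs.window_end, "group": fs.group,
        }
        for fs in sequences
    ]
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def read_features(path):
    from .preprocess import FeatureSequence

    doc = json.loads(Path(path).read_text())
    return [
        FeatureSequence(
            x=np.asarray(e["x"], dtype=float), label=e["label"],
            teacher=np.asarray(e["teacher"], dtype=float),
            record_id=e.get("record_id", ""), window_end=e.get("window_end"),
            group=e.get("group"),
        )
        for e in doc
    ]
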