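"""Biosignal preprocessing: HRV indices, normalization, differential
filtering, and horizon-labelled windowing.

Two input families are supported.  Vital-sign records (heart rate and
systolic/diastolic/mean blood pressure at a fixed sampling interval, the
usual 1-min ICU trend data) are cut into trailing windows of per-channel
standardized samples.  RR-interval (beat-to-beat) streams are reduced to
three time-domain HRV indices on a sliding window — CVRR (coefficient of
variation of the RR intervals), RMSSD (root mean square of successive
differences, a vagal-tone proxy) and pNN50 (fraction of successive
differences with |diff| >= 50 ms) — which then form short feature sequences.

A window is labelled class 2 ("deterioration") when an event occurs within
the prediction horizon P minutes after the window ends, class 1 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateInputError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "RRISequence",
    "VitalRecord",
    "NormalizationSpec",
    "WindowSpec",
    "FeatureSequence",
    "compute_cvrr",
    "compute_rmssd",
    "compute_pnn50",
    "hrv_feature_stream",
    "normalize_signal",
    "differential_filter",
    "make_windows",
]

HRV_FEATURE_NAMES = ("CVRR", "RMSSD", "pNN50")


@dataclass(frozen=True)
class RRISequence:
    """Beat-to-beat intervals: ``rri`` in ms, aligned to ``beat_times`` in s."""

    beat_times: np.ndarray
    rri: np.ndarray

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.rri, dtype=float)
        if bt.shape != rr.shape or bt.ndim != 1:
            raise InvalidParameterError("beat_times and rri must be equal-length 1-D")
        if len(bt) and np.any(np.diff(bt) <= 0):
            raise InvalidParameterError("beat_times must be strictly increasing")
        if np.any(rr <= 0):
            raise InvalidParameterError("all RR intervals must be positive")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rri", rr)

    def __len__(self) -> int:
        return len(self.rri)

    def slice_window(self, t_start: float, t_end: float) -> "RRISequence":
        """Beats with t_start < beat_time <= t_end (trailing-window convention)."""
        m = (self.beat_times > t_start) & (self.beat_times <= t_end)
        return RRISequence(self.beat_times[m], self.rri[m])


@dataclass
class VitalRecord:
    """A multichannel vital-sign record sampled every ``dt`` seconds."""

    record_id: str
    dt: float
    channels: list[str]
    values: np.ndarray
    event_time: float | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.values.shape[1] != len(self.channels) or len(self.channels) < 1:
            raise InvalidParameterError("values must be samples x channels")
        if np.any(~np.isfinite(self.values)):
            raise InvalidParameterError(
                "record contains non-finite samples; drop them at ingestion"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt


@dataclass(frozen=True)
class NormalizationSpec:
    """Standardize each series to mean 0 and standard deviation ``sigma_d``.

    ``sigma_d`` is the customary hyperparameter of this network family:
    0.01 for multichannel inputs, 0.1 for a one-dimensional RRI input.
    A constant series (zero variance) maps to all zeros.
    """

    sigma_d: float = 0.01

    def __post_init__(self):
        if self.sigma_d <= 0:
            raise InvalidParameterError("sigma_d must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """Windowing geometry and prediction horizon.

    window_len_s : analysis window length (vitals: 720 s = 12 min of 1-min
        samples; hrv: 30 s analysis segment).
    step_s : spacing between successive window ends (hrv: 10 s output period).
    horizon_min : P, minutes ahead within which an event makes a window
        positive.
    mode : "vitals" or "hrv".
    hrv_window_s / hrv_step_s : trailing window and grid spacing for the HRV
        index stream (hrv mode only).
    """

    window_len_s: float
    step_s: float
    horizon_min: float = 1.0
    mode: str = "vitals"
    hrv_window_s: float = 30.0
    hrv_step_s: float = 10.0

    def __post_init__(self):
        if self.window_len_s <= 0 or self.step_s <= 0:
            raise InvalidParameterError("window_len_s and step_s must be positive")
        if self.horizon_min < 1:
            raise InvalidParameterError("horizon_min must be >= 1")
        if self.mode not in ("vitals", "hrv"):
            raise InvalidParameterError("mode must be 'vitals' or 'hrv'")

    def with_horizon(self, P: float) -> "WindowSpec":
        return replace(self, horizon_min=P)


@dataclass
class FeatureSequence:
    """A T x d preprocessed input with its one-hot teacher vector."""

    x: np.ndarray
    label: int
    teacher: np.ndarray
    record_id: str = ""
    window_end: float | None = None
    group: str | None = None

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.teacher = np.asarray(self.teacher, dtype=float)
        if self.x.shape[0] < 1 or self.x.shape[1] < 1:
            raise InvalidParameterError("feature matrix must be T>=1 by d>=1")
        if not np.all(np.isin(self.teacher, (0.0, 1.0))) or self.teacher.sum() != 1.0:
            raise InvalidParameterError("teacher must be one-hot")
        if not 1 <= int(self.label) <= len(self.teacher):
            raise InvalidParameterError("label outside 1..C")
        if self.teacher[int(self.label) - 1] != 1.0:
            raise InvalidParameterError("teacher does not match label")

    @property
    def T(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]


def _rri_values(rri_window) -> np.ndarray:
    rr = rri_window.rri if isinstance(rri_window, RRISequence) else np.asarray(
        rri_window, dtype=float
    )
    if len(rr) < 2:
        raise DegenerateInputError("HRV indices need at least 2 beats in the window")
    return rr


def compute_cvrr(rri_window) -> float:
    """Coefficient of variation of the RR intervals (dimensionless).

    Sample standard deviation (N-1 divisor) divided by the mean interval.
    """
    rr = _rri_values(rri_window)
    return float(np.std(rr, ddof=1) / np.mean(rr))


def compute_rmssd(rri_window) -> float:
    """Root mean square of successive RR-interval differences (ms).

    Averages the squared differences over the N-1 adjacent pairs.
    """
    rr = _rri_values(rri_window)
    diffs = np.diff(rr)
    return float(np.sqrt(np.mean(diffs**2)))


def compute_pnn50(rri_window) -> float:
    """Fraction of successive RR differences with |diff| >= 50 ms, in [0, 1]."""
    rr = _rri_values(rri_window)
    diffs = np.abs(np.diff(rr))
    return float(np.mean(diffs >= 50.0))


def hrv_feature_stream(
    rri: RRISequence, spec: WindowSpec
) -> list[tuple[float, np.ndarray]]:
    """[CVRR, RMSSD, pNN50] on a step grid of trailing windows.

    Evaluation times start one ``hrv_window_s`` after the first beat and
    advance by ``hrv_step_s``; each uses the beats in the trailing window
    ``(t - hrv_window_s, t]``.  Windows with fewer than 2 beats are skipped
    (logged).
    """
    if len(rri) == 0 or rri.beat_times[-1] - rri.beat_times[0] < spec.hrv_window_s:
        logger.warning("RRI stream shorter than one HRV window; no output")
        return []
    t0 = rri.beat_times[0]
    out: list[tuple[float, np.ndarray]] = []
    t = t0 + spec.hrv_window_s
    while t <= rri.beat_times[-1] + 1e-9:
        win = rri.slice_window(t - spec.hrv_window_s, t)
        if len(win) < 2:
            logger.info("skipping HRV window ending at %.1f s (<2 beats)", t)
        else:
            out.append(
                (t, np.array([compute_cvrr(win), compute_rmssd(win), compute_pnn50(win)]))
            )
        t += spec.hrv_step_s
    return out


def normalize_signal(series, spec: NormalizationSpec) -> np.ndarray:
    """Standardize a series to sample mean 0 and sample std ``sigma_d``.

    A zero-variance series returns all zeros (logged) — scaling cannot
    manufacture information from a flat signal.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1:
        raise InvalidParameterError("normalize_signal expects a 1-D series")
    if len(s) < 2:
        raise DegenerateInputError("need at least 2 samples to standardize")
    sd = np.std(s, ddof=1)
    if sd == 0.0:
        logger.warning("constant series: normalization returns zeros")
        return np.zeros_like(s)
    return (s - np.mean(s)) / sd * spec.sigma_d


def differential_filter(series, dt: float) -> np.ndarray:
    """Noise-robust time derivative based on the centred difference:

    ``ds(t) = (1/(18 dt)) [ sum_{n=2..4} s(t+n dt) - sum_{n=2..4} s(t-n dt) ]``

    Evaluated only where all six taps exist, so the output is 8 samples
    shorter than the input.  Exact on linear ramps (returns the slope).
    """
    s = np.asarray(series, dtype=float)
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if s.ndim != 1 or len(s) < 9:
        raise DegenerateInputError("differential filter needs at least 9 samples")
    n = len(s)
    fwd = s[6 : n - 2] + s[7 : n - 1] + s[8:n]
    bwd = s[2 : n - 6] + s[1 : n - 7] + s[0 : n - 8]
    return (fwd - bwd) / (18.0 * dt)


def _label_for_window(window_end: float, events: Sequence[float], P_min: float) -> int:
    for t_e in events:
        if 0.0 < t_e - window_end <= P_min * 60.0:
            return 2
    return 1


def _feature_sequence(x, label, record_id, window_end, C=2):
    teacher = np.zeros(C)
    teacher[label - 1] = 1.0
    return FeatureSequence(
        x=x, label=label, teacher=teacher, record_id=record_id,
        window_end=window_end, group=record_id,
    )


def _normalize_columns(x: np.ndarray, norm: NormalizationSpec) -> np.ndarray:
    return np.column_stack([normalize_signal(x[:, j], norm) for j in range(x.shape[1])])


def make_windows(
    record,
    spec: WindowSpec,
    norm: NormalizationSpec,
    events: Iterable[float] | None = None,
) -> list[FeatureSequence]:
    """Cut a record into horizon-labelled, normalized feature sequences.

    vitals mode: ``record`` is a :class:`VitalRecord`; each window is the
    trailing ``window_len_s`` of per-channel standardized samples
    (T = window_len/dt rows, d = channels), windows stepping by ``step_s``.

    hrv mode: ``record`` is an :class:`RRISequence`; the HRV index stream is
    computed on the ``hrv_step_s`` grid and consecutive stretches of
    ``window_len_s / hrv_step_s`` vectors form each sequence, standardized
    per dimension within the segment.

    A window ending at time ``t`` is class 2 iff an event time ``t_e``
    satisfies ``0 < t_e - t <= P`` minutes; windows extending past the record
    are not emitted.
    """
    if events is None:
        events = []
        if isinstance(record, VitalRecord) and record.event_time is not None:
            events = [record.event_time]
    events = list(events)

    out: list[FeatureSequence] = []
    if spec.mode == "vitals":
        if not isinstance(record, VitalRecord):
            raise InvalidParameterError("vitals mode requires a VitalRecord")
        T = int(round(spec.window_len_s / record.dt))
        step = max(1, int(round(spec.step_s / record.dt)))
        if T < 2:
            raise InvalidParameterError("window shorter than 2 samples")
        for j0 in range(0, record.n_samples - T + 1, step):
            x = _normalize_columns(record.values[j0 : j0 + T], norm)
            end = (j0 + T - 1) * record.dt
            label = _label_for_window(end, events, spec.horizon_min)
            out.append(_feature_sequence(x, label, record.record_id, end))
    else:
        if not isinstance(record, RRISequence):
            raise InvalidParameterError("hrv mode requires an RRISequence")
        stream = hrv_feature_stream(record, spec)
        if not stream:
            return []
        T = max(1, int(round(spec.window_len_s / spec.hrv_step_s)))
        step = max(1, int(round(spec.step_s / spec.hrv_step_s)))
        times = np.array([t for t, _ in stream])
        feats = np.stack([v for _, v in stream])
        rid = "rri"
        for j0 in range(0, len(stream) - T + 1, step):
            seg = feats[j0 : j0 + T]
            if T >= 2:
                seg = _normalize_columns(seg, norm)
            end = float(times[j0 + T - 1])
            label = _label_for_window(end, events, spec.horizon_min)
            out.append(_feature_sequence(seg, label, rid, end))
    return out
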