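"""HRV indices, normalization, differential filter, and windowing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rllgmn as rl
from rllgmn.exceptions import DegenerateInputError, InvalidParameterError
from rllgmn.preprocess import (
    NormalizationSpec,
    RRISequence,
    VitalRecord,
    WindowSpec,
    compute_cvrr,
    compute_pnn50,
    compute_rmssd,
    differential_filter,
    hrv_feature_stream,
    make_windows,
    normalize_signal,
)


def _rri(rri_ms):
    rri_ms = np.asarray(rri_ms, dtype=float)
    return RRISequence(np.cumsum(rri_ms) / 1000.0, rri_ms)


@pytest.mark.parametrize(
    "func,rri,expected",
    [
        (compute_cvrr, [800, 800, 800], 0.0),
        (compute_cvrr, [700, 800, 900], 0.125),
        (compute_rmssd, [800, 800, 800], 0.0),
        (compute_rmssd, [800, 850, 800], 50.0),
        (compute_pnn50, [800, 850, 800], 1.0),
        (compute_pnn50, [800, 810, 820], 0.0),
        (compute_pnn50, [800, 850, 860], 0.5),
    ],
)
def test_hrv_index_worked_values(func, rri, expected):
    assert func(_rri(rri)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("func", [compute_cvrr, compute_rmssd, compute_pnn50])
def test_hrv_indices_need_two_beats(func):
    with pytest.raises(DegenerateInputError):
        func(_rri([800.0]))


@given(
    st.lists(st.floats(min_value=400.0, max_value=1500.0), min_size=2, max_size=30),
    st.floats(min_value=0.1, max_value=5.0),
)
def test_hrv_scaling_laws(rri, a):
    """CVRR is scale-invariant, RMSSD scales linearly, both non-negative."""
    base = np.asarray(rri)
    scaled = _rri(base * a)
    orig = _rri(base)
    assert compute_cvrr(scaled) == pytest.approx(compute_cvrr(orig), abs=1e-9)
    assert compute_rmssd(scaled) == pytest.approx(a * compute_rmssd(orig), rel=1e-9)
    assert compute_rmssd(orig) >= 0.0 and compute_cvrr(orig) >= 0.0


def test_hrv_stream_grid_and_constant_rri():
    rri = _rri([800.0] * 76)  # ~60 s of beats
    spec = WindowSpec(window_len_s=30, step_s=10, mode="hrv")
    stream = hrv_feature_stream(rri, spec)
    times = [t for t, _ in stream]
    start = rri.beat_times[0]
    assert times == pytest.approx([start + 30, start + 40, start + 50, start + 60])
    for _, v in stream:
        assert np.allclose(v, 0.0)


def test_hrv_stream_gap_windows_skipped():
    lead = np.cumsum([0.8] * 40)
    tail = lead[-1] + 35.0 + np.cumsum([0.8] * 40)
    bt = np.concatenate([lead, tail])
    rri = RRISequence(bt, np.full(len(bt), 800.0))
    spec = WindowSpec(window_len_s=30, step_s=10, mode="hrv")
    stream = hrv_feature_stream(rri, spec)
    spanned = {t for t, _ in stream}
    # windows wholly inside the silent 35-s gap must be absent
    gap_lo, gap_hi = lead[-1], lead[-1] + 35.0
    assert not any(gap_lo + 30 < t <= gap_hi for t in spanned)
    assert len(stream) > 0


def test_hrv_stream_too_short_returns_empty():
    rri = _rri([800.0] * 5)
    spec = WindowSpec(window_len_s=30, step_s=10, mode="hrv")
    assert hrv_feature_stream(rri, spec) == []


def test_normalize_worked_and_degenerate():
    spec = NormalizationSpec(sigma_d=1.0)
    assert normalize_signal([1.0, 2.0, 3.0], spec) == pytest.approx([-1, 0, 1])
    z = normalize_signal([5.0, 5.0, 5.0], NormalizationSpec(sigma_d=0.01))
    assert np.all(z == 0.0)
    with pytest.raises(DegenerateInputError):
        normalize_signal([1.0], spec)


@given(
    st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=50).filter(
        lambda s: np.std(s, ddof=1) > 1e-6
    ),
    st.floats(min_value=1e-3, max_value=1.0),
)
def test_normalize_moments_and_idempotence(series, sigma_d):
    spec = NormalizationSpec(sigma_d=sigma_d)
    z = normalize_signal(series, spec)
    assert abs(np.mean(z)) <= 1e-9 * sigma_d
    assert np.std(z, ddof=1) == pytest.approx(sigma_d, rel=1e-9)
    z2 = normalize_signal(z, spec)
    assert np.max(np.abs(z2 - z)) <= 1e-9


def test_differential_filter_linear_ramp_and_edges():
    t = np.arange(20.0)
    out = differential_filter(5.0 * t, dt=1.0)
    assert out.shape == (12,)
    assert np.allclose(out, 5.0)
    assert np.allclose(differential_filter(np.full(15, 3.7), dt=0.5), 0.0)
    with pytest.raises(DegenerateInputError):
        differential_filter(np.arange(8.0), dt=1.0)


@given(st.floats(min_value=-5, max_value=5), st.floats(min_value=-10, max_value=10))
def test_differential_filter_exact_on_affine(a, b):
    t = np.arange(30.0) * 2.0
    out = differential_filter(a * t + b, dt=2.0)
    assert np.allclose(out, a, atol=1e-9)


def _record(n=40, dt=60.0, event_time=None, rng=None):
    rng = rng or np.random.default_rng(0)
    vals = rng.normal(0, 1, (n, 3)) + [80.0, 120.0, 70.0]
    return VitalRecord("rec", dt, ["HR", "SBP", "DBP"], vals, event_time)


@pytest.mark.parametrize(
    "event_min,P,end_min,expected",
    [(40.0, 5.0, 36.0, 2), (40.0, 5.0, 34.0, 1), (None, 5.0, 36.0, 1)],
)
def test_window_label_horizon_rule(event_min, P, end_min, expected):
    rec = _record(n=int(end_min) + 1, event_time=None if event_min is None else event_min * 60)
    spec = WindowSpec(window_len_s=(end_min + 1) * 60, step_s=60.0, horizon_min=P)
    wins = make_windows(rec, spec, NormalizationSpec(0.01))
    assert len(wins) == 1
    assert wins[0].window_end == pytest.approx(end_min * 60)
    assert wins[0].label == expected
    assert wins[0].teacher[wins[0].label - 1] == 1.0


def test_windows_shape_and_positive_count_monotone_in_P():
    rec = _record(n=40, event_time=35 * 60.0, rng=np.random.default_rng(3))
    counts = []
    for P in [1, 3, 5, 8, 12]:
        spec = WindowSpec(window_len_s=720.0, step_s=60.0, horizon_min=P)
        wins = make_windows(rec, spec, NormalizationSpec(0.01))
        assert all(w.x.shape == (12, 3) for w in wins)
        assert all(w.label in (1, 2) for w in wins)
        counts.append(sum(w.label == 2 for w in wins))
    assert counts == sorted(counts)
    # every window's channels standardized to sigma_d
    w0 = make_windows(rec, WindowSpec(720.0, 60.0, 1.0), NormalizationSpec(0.01))[0]
    assert np.allclose(np.std(w0.x, axis=0, ddof=1), 0.01)


def test_windows_never_cross_record_boundary():
    rec = _record(n=15)
    spec = WindowSpec(window_len_s=720.0, step_s=60.0, horizon_min=1.0)
    wins = make_windows(rec, spec, NormalizationSpec(0.01))
    assert len(wins) == 4  # starts 0..3 only
    assert max(w.window_end for w in wins) <= rec.duration_s


def test_hrv_mode_windows():
    rng = np.random.default_rng(5)
    rri = rl.generate_rri_stream(300.0, rng=rng)
    spec = WindowSpec(window_len_s=30.0, step_s=10.0, horizon_min=1.0, mode="hrv")
    wins = make_windows(rri, spec, NormalizationSpec(0.1), events=[250.0])
    assert wins, "expected hrv windows"
    assert all(w.x.shape == (3, 3) for w in wins)
    assert any(w.label == 2 for w in wins) and any(w.label == 1 for w in wins)


def test_rri_sequence_invariants():
    with pytest.raises(InvalidParameterError):
        RRISequence([1.0, 0.5], [800.0, 800.0])
    with pytest.raises(InvalidParameterError):
        RRISequence([1.0, 2.0], [800.0, -5.0])
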