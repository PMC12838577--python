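import numpy as np
import pytest
from hypothesis import given, strategies as st

from meanet import (
    AnalysisError,
    burst_spike_rate,
    detect_bursts,
    firing_rate,
    isi,
    joint_isi_hist,
    mfr_recovery_check,
    short_interval_metrics,
)
from meanet.io import SpikeTrain

from conftest import make_recording


def train(times, duration=10.0, ch="c"):
    return SpikeTrain(ch, np.asarray(times, dtype=float), duration)


def test_isi_basic():
    assert np.allclose(isi(train([0.1, 0.2, 0.4])), [0.1, 0.2])
    assert isi(train([0.5])).size == 0
    assert isi(train([])).size == 0


@given(st.lists(st.floats(0, 9.99), min_size=2, max_size=30, unique=True))
def test_isi_telescopes(times):
    t = train(sorted(times))
    d = isi(t)
    assert np.all(d > 0)
    assert d.sum() == pytest.approx(t.times[-1] - t.times[0])


def test_joint_isi_regular_train_single_cell():
    t = np.arange(100) * 0.01  # exact 10 ms spacing
    rec = make_recording({"a": t}, duration=2.0)
    h = joint_isi_hist(rec)
    assert h.n_pairs == 98
    assert h.counts.max() == 98 and h.counts.sum() == 98
    rec2 = make_recording({"a": t, "b": t + 0.001}, duration=2.0)
    h2 = joint_isi_hist(rec2)
    assert h2.n_pairs == 196 and h2.counts.max() == 196


def test_joint_isi_requires_three_spikes():
    rec = make_recording({"a": [0.1, 0.2], "b": [0.3]}, duration=1.0)
    with pytest.raises(AnalysisError):
        joint_isi_hist(rec)


@given(
    st.lists(
        st.lists(st.floats(0, 9.99), max_size=25, unique=True),
        min_size=1, max_size=5,
    )
)
def test_joint_isi_pair_counting_identity(channel_times):
    """Total pairs = sum over channels of max(0, n_spikes - 2) when the
    edges span all data."""
    spikes = {f"c{i}": sorted(ts) for i, ts in enumerate(channel_times)}
    if not any(len(ts) >= 3 for ts in spikes.values()):
        return
    rec = make_recording(spikes, duration=10.0)
    h = joint_isi_hist(rec, bin_edges=np.logspace(-9, 2, 40))
    expected = sum(max(0, len(ts) - 2) for ts in spikes.values())
    assert h.n_pairs == expected


def test_short_interval_metrics_extremes():
    fast = make_recording({"a": np.arange(50) * 0.01}, duration=1.0)
    assert short_interval_metrics(fast).proportion == 1.0
    slow = make_recording({"a": np.arange(9)}, duration=10.0)
    assert short_interval_metrics(slow).proportion == 0.0


def test_short_interval_alternating_has_no_qualifying_pairs():
    # ISIs alternate 10 ms / 500 ms: no two consecutive short intervals
    times = np.cumsum([0] + [0.01, 0.5] * 5)
    rec = make_recording({"a": times}, duration=5.0)
    m = short_interval_metrics(rec, window_s=0.05, mode="pair")
    assert m.count == 0
    # the single-interval reading sees the short ISIs
    m2 = short_interval_metrics(rec, window_s=0.05, mode="single")
    assert m2.count == 5


def test_firing_rate_and_mfr():
    rec = make_recording(
        {"a": np.linspace(0, 179.5, 180), "b": []}, duration=180.0
    )
    rates, mfr = firing_rate(rec)
    assert rates["a"] == pytest.approx(1.0)
    assert rates["b"] == 0.0
    assert mfr == pytest.approx(0.5)  # silent channel included


@given(
    st.lists(
        st.lists(st.floats(0, 99.9), max_size=30, unique=True),
        min_size=1, max_size=6,
    )
)
def test_mfr_identity(channel_times):
    spikes = {f"c{i}": sorted(ts) for i, ts in enumerate(channel_times)}
    rec = make_recording(spikes, duration=100.0)
    _, mfr = firing_rate(rec)
    assert mfr == pytest.approx(rec.total_spikes / (len(spikes) * 100.0))


@pytest.mark.parametrize(
    "times,expected",
    [
        ([0, 0.01, 0.02, 0.03], [(0.0, 0.03, 4)]),
        (list(np.arange(8)), []),  # regular 1 Hz: no bursts
        ([0, 0.05, 0.3, 0.35, 0.40, 2.0], [(0.3, 0.40, 3)]),
    ],
)
def test_detect_bursts_run_rule(times, expected):
    bursts = detect_bursts(train(times), max_isi_s=0.1, min_spikes=3)
    assert [(b.start_s, b.end_s, b.n_spikes) for b in bursts] == [
        (pytest.approx(s), pytest.approx(e), n) for s, e, n in expected
    ]


def test_burst_spike_rate_extremes():
    one_burst = make_recording({"a": np.arange(10) * 0.01}, duration=1.0)
    assert burst_spike_rate(one_burst) == 1.0
    sparse = make_recording({"a": np.arange(5) * 2.0}, duration=10.0)
    assert burst_spike_rate(sparse) == 0.0
    mixed = make_recording(
        {"a": [0.0, 0.01, 0.02, 0.03, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]}, duration=10.0
    )
    assert burst_spike_rate(mixed) == pytest.approx(0.4)
    with pytest.raises(AnalysisError):
        burst_spike_rate(make_recording({"a": []}, duration=1.0))


def test_burst_spike_rate_monotonic_in_parameters():
    rng = np.random.default_rng(0)
    times = np.sort(rng.uniform(0, 60, 300))
    times = np.unique(times)
    rec = make_recording({"a": times}, duration=60.0)
    rates_min = [
        burst_spike_rate(rec, max_isi_s=0.1, min_spikes=k) for k in (2, 3, 4, 6, 8)
    ]
    assert all(a >= b for a, b in zip(rates_min, rates_min[1:]))
    rates_isi = [
        burst_spike_rate(rec, max_isi_s=w, min_spikes=3) for w in (0.02, 0.05, 0.1, 0.3)
    ]
    assert all(a <= b for a, b in zip(rates_isi, rates_isi[1:]))


def test_mfr_recovery_check_boundaries():
    base = make_recording({"a": np.linspace(0, 99, 100)}, duration=100.0)

    def post(n):
        return make_recording({"a": np.linspace(0, 99, n)}, duration=100.0)

    assert mfr_recovery_check(base, post(110)).passed
    assert not mfr_recovery_check(base, post(150)).passed
    assert mfr_recovery_check(base, post(120)).passed  # boundary inclusive
    silent = make_recording({"a": []}, duration=100.0)
    with pytest.raises(AnalysisError):
        mfr_recovery_check(silent, base)
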