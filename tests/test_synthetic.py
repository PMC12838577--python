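import numpy as np
import pytest
from hypothesis import given, strategies as st

from meanet import (
    StimCondition,
    ValidationError,
    bin_spikes,
    pearson_matrix,
    stimulus_effect,
    synthetic,
)
from meanet.synthetic import (
    FrequencyGains,
    StimulusEffectParams,
    expected_rate,
    generate_disrupt_stabilize_series,
    generate_ground_truth,
    simulate_trial,
)


@pytest.mark.parametrize(
    "n,k,sizes",
    [(60, 4, [15] * 4), (5, 5, [1] * 5), (7, 3, [3, 2, 2])],
)
def test_ground_truth_block_sizes(n, k, sizes):
    gt = generate_ground_truth(n_channels=n, k_communities=k)
    got = sorted(
        np.bincount([gt.community_of[c] for c in gt.channel_ids]).tolist(), reverse=True
    )
    assert got == sorted(sizes, reverse=True)
    # contiguous blocks in channel order
    labels = [gt.community_of[c] for c in gt.channel_ids]
    assert labels == sorted(labels)


def test_stimulus_effect_control_identity_and_validation():
    eff = stimulus_effect(0, 0)
    assert (eff.rate_mult, eff.sync_mult, eff.burst_mult) == (1, 1, 1)
    with pytest.raises(ValidationError):
        stimulus_effect(40.0, 0)


def test_stimulus_effect_default_gap_sequence():
    """Defaults: 1.5 / 1.1 / 0.7 at 40 Hz vs constant 0.7 at 7.8 Hz,
    so the gap runs 0.8, 0.4, 0.0 over N in {100, 1000, 10000}."""
    mults40 = [stimulus_effect(40.0, n).rate_mult for n in (100, 1000, 10000)]
    assert mults40 == pytest.approx([1.5, 1.1, 0.7])
    mults78 = [stimulus_effect(7.8, n).rate_mult for n in (100, 1000, 10000)]
    assert mults78 == pytest.approx([0.7, 0.7, 0.7])
    gaps = [a - b for a, b in zip(mults40, mults78)]
    assert gaps == pytest.approx([0.8, 0.4, 0.0])


@given(
    g40=st.floats(0.05, 1.0),
    c40=st.floats(0.05, 1.0),
    floor_40=st.floats(0.1, 1.0),
    g78=st.floats(0.05, 0.9),
)
def test_effect_gap_nonincreasing_for_all_gains(g40, c40, floor_40, g78):
    """Clamping guarantees |effect(40,N) - effect(7.8,N)| never grows
    with N, for every valid parameterization."""
    gains = FrequencyGains(g40=g40, c40=c40, floor_40=floor_40, g78=g78)
    params = StimulusEffectParams(rate=gains, sync=gains, burst=gains)
    pulse_grid = np.unique(np.logspace(2, 5, 25).astype(int))
    gaps = [
        abs(
            stimulus_effect(40.0, int(n), params).rate_mult
            - stimulus_effect(7.8, int(n), params).rate_mult
        )
        for n in pulse_grid
    ]
    assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))


def test_null_coupling_poisson_counts_and_no_synchrony():
    """With zero coupling, channels are independent Poisson: MFR matches
    the base rate, count dispersion is Poisson-like and mean pairwise
    correlation vanishes."""
    gt = generate_ground_truth(a_within=0.0, a_global=0.0, base_rate_hz=1.0, seed=0)
    rec = simulate_trial(gt, StimCondition("control"), duration_s=180.0, seed=42)
    counts = np.array([t.n_spikes for t in rec.trains])
    expected = 180.0
    se = np.sqrt(expected * 60) / 60
    assert abs(counts.mean() - expected) < 3 * se
    fano = counts.var(ddof=1) / counts.mean()
    assert 0.5 < fano < 1.6  # Poisson dispersion, 60 channels
    m = pearson_matrix(bin_spikes(rec, 0.1))
    iu = np.triu_indices(m.n_channels, k=1)
    assert abs(np.nanmean(m.r[iu])) < 0.02


def test_tiny_duration_yields_no_spikes():
    gt = generate_ground_truth(seed=0)
    rec = simulate_trial(gt, StimCondition("control"), duration_s=0.001, seed=3)
    assert rec.total_spikes <= 1


def test_rate_calibration_constant_modulator():
    """Realized MFR within 3 SE of the analytic expectation."""
    gt = generate_ground_truth(base_rate_hz=2.0, a_within=4.0, a_global=1.0, seed=0)
    rec = simulate_trial(gt, StimCondition("control"), duration_s=180.0, seed=11)
    mu = expected_rate(gt)
    total = rec.total_spikes
    n_expected = mu * 180.0 * 60
    # modulator fluctuations widen the variance beyond Poisson; a
    # conservative inflation factor covers the on/off covariance
    se = np.sqrt(n_expected) * 6
    assert abs(total - n_expected) < 3 * se


def test_within_community_synchrony_exceeds_between():
    hits = 0
    for s in range(20):
        gt = generate_ground_truth(a_within=1.5, a_global=0.0, seed=s)
        rec = simulate_trial(gt, StimCondition("control"), seed=500 + s)
        m = pearson_matrix(bin_spikes(rec, 0.1))
        com = [gt.community_of[c] for c in m.channel_ids]
        within, between = [], []
        for i in range(len(com)):
            for j in range(i + 1, len(com)):
                (within if com[i] == com[j] else between).append(m.r[i, j])
        hits += np.nanmean(within) > np.nanmean(between)
    assert hits >= 19


def test_simulation_deterministic_given_seed(tmp_path):
    from meanet import write_spike_table

    gt = generate_ground_truth(seed=5)
    a = simulate_trial(gt, StimCondition("control"), seed=7)
    b = simulate_trial(gt, StimCondition("control"), seed=7)
    c = simulate_trial(gt, StimCondition("control"), seed=8)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_spike_table(a, pa)
    write_spike_table(b, pb)
    assert pa.read_bytes() == pb.read_bytes()
    assert any(
        not np.array_equal(x.times, y.times) for x, y in zip(a.trains, c.trains)
    )


def test_series_structure():
    gt = generate_ground_truth(seed=2)
    trials = generate_disrupt_stabilize_series(gt, seeds=range(8), duration_s=20.0)
    assert [t.condition.paradigm for t in trials] == (
        ["control"] + ["disrupt"] * 3 + ["stabilize"] * 3 + ["control"]
    )
    with pytest.raises(ValidationError):
        generate_disrupt_stabilize_series(gt, seeds=range(5))


def test_rhythmic_series_structure():
    gt = generate_ground_truth(seed=2)
    trials = synthetic.generate_rhythmic_series(gt, seeds=range(7), duration_s=20.0)
    conds = [(t.condition.frequency_hz, t.condition.n_pulses) for t in trials]
    assert conds == [(0.0, 0), (40.0, 100), (7.8, 100), (40.0, 1000), (7.8, 1000),
                     (40.0, 10000), (7.8, 10000)]
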