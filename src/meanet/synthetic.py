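"""Synthetic multichannel spike trains with planted network structure.

No public recordings accompany the experiments this package analyses,
so every analysis stage is exercised against a doubly-stochastic
generator that emulates their key features: ~60 channels, 3-minute
trials, community structure in pairwise synchrony, burst firing, and
frequency-dependent stimulation effects.

Model
-----
Channels are grouped into K communities.  Each community c carries a
two-state (on/off) continuous-time Markov modulator m_c(t), and one
global modulator g(t) is shared by all channels.  Channel i fires as an
inhomogeneous Poisson process with rate

    r_i(t) = base * rate_mult * (1 + a_within * sync_mult * m_c(i)(t)
                                   + a_global * g(t))

sampled exactly by thinning against the analytic maximum rate.  The
on/off modulators produce both bursts (high-rate epochs) and tunable
pairwise synchrony (channels sharing a modulator co-fluctuate), with a
closed-form expected rate for calibration checks.

Stimulation effects enter as multipliers on the base rate
(``rate_mult``), the within-community coupling (``sync_mult``) and the
modulator on-rate (``burst_mult``).  40 Hz stimulation is excitatory at
low pulse counts and its multiplier decays log-linearly with pulse
repetitions down to a floor; 7.8 Hz stimulation is uniformly
suppressive.  The floor is clamped to never undershoot the 7.8 Hz
level, which makes the 40-vs-7.8 Hz effect gap non-increasing in the
pulse count by construction — the "adaptive convergence" the rhythmic
workflow quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import SpikeTrain, StimCondition, TrialRecording

DEFAULT_DURATION_S = 180.0


@dataclass(frozen=True)
class NetworkGroundTruth:
    """Planted network used to simulate one culture."""

    n_channels: int = 60
    community_of: dict = field(default_factory=dict)  # channel id -> community
    base_rate_hz: float = 1.0
    a_within: float = 12.0
    a_global: float = 0.5
    modulator_rates: tuple = (0.2, 2.0)  # (lambda_on, lambda_off) per second
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate_hz <= 0:
            raise ValidationError("base_rate_hz must be > 0")
        if self.a_within < 0 or self.a_global < 0:
            raise ValidationError("coupling strengths must be >= 0")
        lam_on, lam_off = self.modulator_rates
        if lam_on <= 0 or lam_off <= 0:
            raise ValidationError("modulator rates must be > 0")
        if self.community_of:
            if len(self.community_of) != self.n_channels:
                raise ValidationError("every channel needs a community")

    @property
    def communities(self) -> list:
        return sorted(set(self.community_of.values()))

    @property
    def channel_ids(self) -> list:
        return sorted(self.community_of)


@dataclass(frozen=True)
class EffectMultipliers:
    rate_mult: float = 1.0
    sync_mult: float = 1.0
    burst_mult: float = 1.0

    def __post_init__(self) -> None:
        if min(self.rate_mult, self.sync_mult, self.burst_mult) <= 0:
            raise ValidationError("effect multipliers must be > 0")


@dataclass(frozen=True)
class FrequencyGains:
    """Log-linear pulse-count response for one modulated quantity.

    40 Hz: mult(N) = max(floor_40, 1 - g78, 1 + g40 - c40*log10(N/100))
    7.8 Hz: mult(N) = 1 - g78 (constant in N)

    Clamping the 40 Hz curve at the 7.8 Hz level (in addition to its own
    floor) guarantees the between-frequency gap is non-increasing in N.
    """

    g40: float = 0.5
    c40: float = 0.4
    floor_40: float = 0.7
    g78: float = 0.3

    def mult(self, frequency_hz: float, n_pulses: int) -> float:
        if frequency_hz == 0:
            return 1.0
        low = 1.0 - self.g78
        if math.isclose(frequency_hz, 7.8):
            return low
        if math.isclose(frequency_hz, 40.0):
            raw = 1.0 + self.g40 - self.c40 * math.log10(n_pulses / 100.0)
            return max(self.floor_40, low, raw)
        raise ValidationError(f"unsupported rhythmic frequency {frequency_hz} Hz")


@dataclass(frozen=True)
class StimulusEffectParams:
    rate: FrequencyGains = field(default_factory=FrequencyGains)
    sync: FrequencyGains = field(default_factory=FrequencyGains)
    burst: FrequencyGains = field(default_factory=FrequencyGains)


def generate_ground_truth(
    n_channels: int = 60,
    k_communities: int = 4,
    base_rate_hz: float = 1.0,
    a_within: float = 12.0,
    a_global: float = 0.5,
    modulator_rates: tuple = (0.2, 2.0),
    seed: int = 0,
) -> NetworkGroundTruth:
    """Assign channels to contiguous, near-equal community blocks."""
    if k_communities < 1 or k_communities > n_channels:
        raise ValidationError("need 1 <= k_communities <= n_channels")
    width = len(str(n_channels))
    ids = [f"ch{i + 1:0{width}d}" for i in range(n_channels)]
    sizes = [
        n_channels // k_communities + (1 if i < n_channels % k_communities else 0)
        for i in range(k_communities)
    ]
    community_of = {}
    pos = 0
    for c, size in enumerate(sizes):
        for ch in ids[pos : pos + size]:
            community_of[ch] = c
        pos += size
    return NetworkGroundTruth(
        n_channels=n_channels,
        community_of=community_of,
        base_rate_hz=base_rate_hz,
        a_within=a_within,
        a_global=a_global,
        modulator_rates=modulator_rates,
        seed=seed,
    )


def stimulus_effect(
    frequency_hz: float,
    n_pulses: int,
    params: StimulusEffectParams | None = None,
) -> EffectMultipliers:
    """Effect multipliers for a rhythmic stimulation condition.

    Control (0 Hz, 0 pulses) is the identity.  A nonzero frequency with
    zero pulses is invalid.
    """
    params = params or StimulusEffectParams()
    if frequency_hz == 0:
        return EffectMultipliers()
    if n_pulses <= 0:
        raise ValidationError("stimulation with zero pulses is undefined")
    return EffectMultipliers(
        rate_mult=params.rate.mult(frequency_hz, n_pulses),
        sync_mult=params.sync.mult(frequency_hz, n_pulses),
        burst_mult=params.burst.mult(frequency_hz, n_pulses),
    )


def _simulate_onoff(lam_on: float, lam_off: float, duration: float, rng) -> tuple:
    """Two-state CTMC trajectory: (switch times, state after switch).

    The initial state is drawn from the stationary distribution."""
    p_on = lam_on / (lam_on + lam_off)
    state = bool(rng.random() < p_on)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = lam_off if state else lam_on
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        state = not state
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=float)


def _eval_onoff(times: np.ndarray, states: np.ndarray, at: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(times, at, side="right") - 1
    return states[idx]


def simulate_trial(
    ground_truth: NetworkGroundTruth,
    condition: StimCondition,
    duration_s: float = DEFAULT_DURATION_S,
    seed: int = 0,
    effect_params: StimulusEffectParams | None = None,
) -> TrialRecording:
    """Simulate one trial of the planted network under a condition.

    Rhythmic conditions apply :func:`stimulus_effect`; control,
    disrupt and stabilize trials use identity multipliers (the latter
    two are modelled by modified ground truths, see
    :func:`generate_disrupt_stabilize_series`).  Deterministic given
    ``seed``.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be > 0")
    gt = ground_truth
    if not gt.community_of:
        raise ValidationError("ground truth has no channel/community assignment")
    if condition.paradigm == "rhythmic":
        eff = stimulus_effect(condition.frequency_hz, condition.n_pulses, effect_params)
    else:
        eff = EffectMultipliers()

    lam_on, lam_off = gt.modulator_rates
    ss = np.random.SeedSequence(entropy=int(seed))
    communities = gt.communities
    children = ss.spawn(1 + len(communities) + gt.n_channels)
    rng_global = np.random.default_rng(children[0])
    g_times, g_states = _simulate_onoff(lam_on * eff.burst_mult, lam_off, duration_s, rng_global)
    modulators = {}
    for k, c in enumerate(communities):
        rng_c = np.random.default_rng(children[1 + k])
        modulators[c] = _simulate_onoff(lam_on * eff.burst_mult, lam_off, duration_s, rng_c)

    base = gt.base_rate_hz * eff.rate_mult
    aw = gt.a_within * eff.sync_mult
    ag = gt.a_global
    r_max = base * (1.0 + aw + ag)

    trains = []
    for k, ch in enumerate(gt.channel_ids):
        rng = np.random.default_rng(children[1 + len(communities) + k])
        n_cand = rng.poisson(r_max * duration_s)
        cand = np.sort(rng.random(n_cand) * duration_s)
        m_times, m_states = modulators[gt.community_of[ch]]
        rate = base * (
            1.0
            + aw * _eval_onoff(m_times, m_states, cand)
            + ag * _eval_onoff(g_times, g_states, cand)
        )
        keep = rng.random(n_cand) * r_max < rate
        times = np.unique(cand[keep])
        trains.append(SpikeTrain(channel_id=ch, times=times, duration=duration_s))
    return TrialRecording(
        trial_id=f"{condition.paradigm}_{seed}",
        trains=tuple(trains),
        duration=duration_s,
        condition=condition,
    )


def expected_rate(ground_truth: NetworkGroundTruth, eff: EffectMultipliers | None = None) -> float:
    """Analytic per-channel mean rate under stationary modulators."""
    eff = eff or EffectMultipliers()
    lam_on, lam_off = ground_truth.modulator_rates
    p_on = lam_on * eff.burst_mult / (lam_on * eff.burst_mult + lam_off)
    return (
        ground_truth.base_rate_hz
        * eff.rate_mult
        * (1.0 + ground_truth.a_within * eff.sync_mult * p_on + ground_truth.a_global * p_on)
    )


# ---------------------------------------------------------------------------
# study-series generators


@dataclass(frozen=True)
class SeriesParams:
    """Coupling configurations of the disrupt/stabilize series.

    Disrupt trials lower the within-community coupling and add strong
    uniform cross-channel coupling, producing many weak correlations
    spread over all pairs; stabilize trials raise the within-community
    coupling with no global term, producing fewer but stronger
    correlations.
    """

    disrupt_a_within: float = 4.0
    disrupt_a_global: float = 14.0
    stabilize_a_within: float = 20.0
    stabilize_a_global: float = 0.0


def generate_disrupt_stabilize_series(
    ground_truth: NetworkGroundTruth,
    seeds,
    duration_s: float = DEFAULT_DURATION_S,
    params: SeriesParams | None = None,
) -> list:
    """Eight trials: control, 3x disrupt, 3x stabilize, control."""
    seeds = list(seeds)
    if len(seeds) != 8:
        raise ValidationError("the disrupt/stabilize series needs exactly 8 seeds")
    params = params or SeriesParams()
    disrupt_gt = replace(
        ground_truth, a_within=params.disrupt_a_within, a_global=params.disrupt_a_global
    )
    stabilize_gt = replace(
        ground_truth, a_within=params.stabilize_a_within, a_global=params.stabilize_a_global
    )
    # disrupt: ~3.3 Hz asynchronous paired pulses; stabilize: 100 Hz
    # synchronous bursts; both 100 pulses per trial
    plan = [
        ("control_1", ground_truth, StimCondition("control")),
        ("disrupt_1", disrupt_gt, StimCondition("disrupt", 3.3, 100)),
        ("disrupt_2", disrupt_gt, StimCondition("disrupt", 3.3, 100)),
        ("disrupt_3", disrupt_gt, StimCondition("disrupt", 3.3, 100)),
        ("stabilize_1", stabilize_gt, StimCondition("stabilize", 100.0, 100)),
        ("stabilize_2", stabilize_gt, StimCondition("stabilize", 100.0, 100)),
        ("stabilize_3", stabilize_gt, StimCondition("stabilize", 100.0, 100)),
        ("control_2", ground_truth, StimCondition("control")),
    ]
    out = []
    for (trial_id, gt, cond), seed in zip(plan, seeds):
        rec = simulate_trial(gt, cond, duration_s=duration_s, seed=seed)
        out.append(replace(rec, trial_id=trial_id))
    return out


DEFAULT_PULSE_LEVELS = (100, 1000, 10000)


def generate_rhythmic_series(
    ground_truth: NetworkGroundTruth,
    seeds,
    pulse_levels=DEFAULT_PULSE_LEVELS,
    duration_s: float = DEFAULT_DURATION_S,
    effect_params: StimulusEffectParams | None = None,
) -> list:
    """Control plus (40 Hz, 7.8 Hz) x pulse-level trials.

    ``seeds`` must provide one seed per trial: 1 + 2 * len(pulse_levels).
    """
    seeds = list(seeds)
    n_needed = 1 + 2 * len(pulse_levels)
    if len(seeds) != n_needed:
        raise ValidationError(f"rhythmic series needs exactly {n_needed} seeds")
    plan = [("control", StimCondition("control"))]
    for level_i, n_pulses in enumerate(pulse_levels, start=1):
        for freq in (40.0, 7.8):
            plan.append(
                (
                    f"rhythmic_{freq:g}hz_{n_pulses}p",
                    StimCondition("rhythmic", freq, n_pulses, group_label=f"group{level_i}"),
                )
            )
    out = []
    for (trial_id, cond), seed in zip(plan, seeds):
        rec = simulate_trial(
            ground_truth, cond, duration_s=duration_s, seed=seed, effect_params=effect_params
        )
        out.append(replace(rec, trial_id=trial_id))
    return out
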