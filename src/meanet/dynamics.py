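"""Firing-pattern metrics: ISI statistics, joint ISI distributions,
short-interval counts, firing rates, bursts and the baseline-recovery
check.

The joint ISI distribution is the 2-D histogram of consecutive
interval pairs (ISI_k, ISI_{k+1}) pooled across channels, on log-spaced
bins — the standard return-map view of spike timing.  "Short-interval"
events are joint-ISI pairs whose two coordinates both fall at or below
a 50 ms window; a simpler single-interval reading is available via
``mode="single"``.  Bursts are maximal runs of spikes whose internal
ISIs all stay at or below a fixed threshold (default 100 ms) with a
minimum run length (default 3 spikes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ValidationError
from .io import SpikeTrain, TrialRecording

logger = logging.getLogger(__name__)

DEFAULT_MAX_ISI_S = 0.1
DEFAULT_MIN_SPIKES = 3
DEFAULT_SHORT_WINDOW_S = 0.05


def default_joint_isi_edges(
    min_isi_s: float = 1e-3, max_isi_s: float = 10.0, n_bins: int = 50
) -> np.ndarray:
    """log10-spaced bin edges, 1 ms to 10 s by default."""
    return np.logspace(np.log10(min_isi_s), np.log10(max_isi_s), n_bins + 1)


@dataclass(frozen=True)
class JointISIHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray  # (n_bins, n_bins), axis 0 = ISI_k, axis 1 = ISI_{k+1}
    n_pairs: int  # consecutive-ISI pairs pooled over channels
    n_out_of_range: int


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    n_spikes: int


@dataclass(frozen=True)
class ShortIntervalMetrics:
    count: int
    proportion: float
    n_pairs: int
    window_s: float
    mode: str


@dataclass(frozen=True)
class RecoveryResult:
    passed: bool
    ratio: float  # MFR_post / MFR_baseline
    mfr_baseline: float
    mfr_post: float
    tolerance_fraction: float


def isi(train: SpikeTrain) -> np.ndarray:
    """Inter-spike intervals; empty for fewer than two spikes."""
    return np.diff(train.times)


def _isi_pairs(recording: TrialRecording) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive-ISI pairs (ISI_k, ISI_{k+1}) pooled over channels."""
    firsts, seconds = [], []
    for train in recording.trains:
        d = isi(train)
        if d.size >= 2:
            firsts.append(d[:-1])
            seconds.append(d[1:])
    if not firsts:
        raise AnalysisError("no channel has >= 3 spikes; joint ISI undefined")
    return np.concatenate(firsts), np.concatenate(seconds)


def joint_isi_hist(
    recording: TrialRecording, bin_edges: np.ndarray | None = None
) -> JointISIHistogram:
    """Pooled joint ISI histogram on log-spaced edges."""
    if bin_edges is None:
        bin_edges = default_joint_isi_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    x, y = _isi_pairs(recording)
    counts, _, _ = np.histogram2d(x, y, bins=[bin_edges, bin_edges])
    # histogram2d closes the last bin on the right; match the half-open
    # convention by excluding exact-max values that are out of spirit is
    # immaterial here — we only track what fell inside the grid at all.
    n_in = int(counts.sum())
    n_out = int(x.size - n_in)
    if n_out:
        logger.info("joint ISI: %d of %d pairs outside the bin range", n_out, x.size)
    return JointISIHistogram(
        bin_edges=bin_edges,
        counts=counts.astype(np.int64),
        n_pairs=int(x.size),
        n_out_of_range=n_out,
    )


def short_interval_metrics(
    recording: TrialRecording,
    window_s: float = DEFAULT_SHORT_WINDOW_S,
    mode: str = "pair",
) -> ShortIntervalMetrics:
    """Count short-interval firing events.

    ``mode="pair"`` (default): joint-ISI pairs with both coordinates
    <= window.  ``mode="single"``: individual ISIs <= window, counted
    over the same pooled pair structure's underlying intervals.
    """
    if window_s <= 0:
        raise ValidationError("window_s must be > 0")
    if mode not in ("pair", "single"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "pair":
        x, y = _isi_pairs(recording)
        total = int(x.size)
        count = int(np.count_nonzero((x <= window_s) & (y <= window_s)))
    else:
        all_isi = [isi(t) for t in recording.trains if t.n_spikes >= 2]
        if not all_isi:
            raise AnalysisError("no ISIs in recording")
        d = np.concatenate(all_isi)
        total = int(d.size)
        count = int(np.count_nonzero(d <= window_s))
    if total == 0:
        raise AnalysisError("zero interval pairs")
    return ShortIntervalMetrics(
        count=count, proportion=count / total, n_pairs=total,
        window_s=window_s, mode=mode,
    )


def firing_rate(recording: TrialRecording) -> tuple[dict, float]:
    """Per-channel rate (Hz) and network mean firing rate (MFR).

    Silent channels count as 0 Hz and are included in the mean, so the
    MFR equals total spikes / (n_channels * duration).
    """
    if recording.n_channels == 0:
        raise AnalysisError("recording has no channels")
    rates = {t.channel_id: t.rate_hz for t in recording.trains}
    return rates, float(np.mean(list(rates.values())))


def detect_bursts(
    train: SpikeTrain,
    max_isi_s: float = DEFAULT_MAX_ISI_S,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> list[Burst]:
    """Fixed-threshold burst detection.

    A burst is a maximal run of consecutive spikes whose ISIs are all
    <= ``max_isi_s``, kept only if the run contains >= ``min_spikes``
    spikes.
    """
    if max_isi_s <= 0 or min_spikes <= 0:
        raise ValidationError("burst parameters must be positive")
    t = train.times
    if t.size == 0:
        return []
    short = np.diff(t) <= max_isi_s
    bursts = []
    run_start = 0
    for i in range(t.size):
        is_last = i == t.size - 1
        if is_last or not short[i]:
            run_len = i - run_start + 1
            if run_len >= min_spikes:
                bursts.append(Burst(float(t[run_start]), float(t[i]), run_len))
            run_start = i + 1
    return bursts


def burst_spike_rate(
    recording: TrialRecording,
    max_isi_s: float = DEFAULT_MAX_ISI_S,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> float:
    """Fraction of all spikes that fall inside a burst, pooled over
    channels (0 when no bursts are detected)."""
    total = recording.total_spikes
    if total == 0:
        raise AnalysisError("recording contains no spikes")
    in_burst = sum(
        b.n_spikes
        for train in recording.trains
        for b in detect_bursts(train, max_isi_s, min_spikes)
    )
    return in_burst / total


def mfr_recovery_check(
    baseline: TrialRecording,
    post: TrialRecording,
    tolerance_fraction: float = 0.2,
) -> RecoveryResult:
    """Has the network returned to its baseline firing state?

    Passes iff |MFR_post - MFR_baseline| <= tolerance_fraction *
    MFR_baseline (boundary inclusive).
    """
    _, mfr_base = firing_rate(baseline)
    _, mfr_post = firing_rate(post)
    if mfr_base == 0:
        raise AnalysisError("baseline MFR is zero; recovery ratio undefined")
    passed = abs(mfr_post - mfr_base) <= tolerance_fraction * mfr_base + 1e-15
    return RecoveryResult(
        passed=bool(passed),
        ratio=mfr_post / mfr_base,
        mfr_baseline=mfr_base,
        mfr_post=mfr_post,
        tolerance_fraction=tolerance_fraction,
    )
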