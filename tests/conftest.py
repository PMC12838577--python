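"""Shared fixtures: small hand-made recordings plus the session-scoped
simulation studies reused across module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from meanet import StimCondition, SpikeTrain, TrialRecording, pipeline, synthetic

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: Study sizes for the simulation-based checks.
N_SERIES = 50  # disrupt/stabilize series
N_RHYTHMIC_SEEDS = 30  # paired rhythmic series
N_RECOVERY_RUNS = 50  # planted-partition recovery runs


def make_recording(spikes: dict, duration: float = 3.0, trial_id: str = "t") -> TrialRecording:
    trains = tuple(
        SpikeTrain(ch, np.asarray(ts, dtype=float), duration) for ch, ts in spikes.items()
    )
    return TrialRecording(trial_id=trial_id, trains=trains, duration=duration)


@pytest.fixture(scope="session")
def ds_reports():
    """Per-trial connectivity reports for 50 seeded disrupt/stabilize series."""
    reports = []
    for s in range(N_SERIES):
        gt = synthetic.generate_ground_truth(seed=s)
        trials = synthetic.generate_disrupt_stabilize_series(
            gt, seeds=range(1000 * s, 1000 * s + 8)
        )
        reports.append(pipeline.run_connectivity_series(trials).per_trial)
    return reports


@pytest.fixture(scope="session")
def rhythmic_reports():
    """Rhythmic-series reports for 30 seeded cultures (paired across
    frequency and pulse level within each seed)."""
    reports = []
    for s in range(N_RHYTHMIC_SEEDS):
        gt = synthetic.generate_ground_truth(seed=10_000 + s)
        trials = synthetic.generate_rhythmic_series(gt, seeds=range(7 * s, 7 * s + 7))
        reports.append(pipeline.run_rhythmic_series(trials))
    return reports


@pytest.fixture(scope="session")
def recovery_aris():
    """Adjusted Rand index of Louvain-recovered vs planted communities.

    Weak-coupling regime (a_within = 1.5): recovery is checked on
    10-minute synthetic recordings with 0.5 s bins and a positive-
    correlation graph, so the check isolates algorithmic recovery from
    finite-sample noise in the correlation estimates.
    """
    from sklearn.metrics import adjusted_rand_score

    from meanet import bin_spikes, community, functional_edges, pearson_matrix

    aris = []
    for s in range(N_RECOVERY_RUNS):
        gt = synthetic.generate_ground_truth(a_within=1.5, a_global=0.0, seed=s)
        rec = synthetic.simulate_trial(
            gt, StimCondition("control"), duration_s=600.0, seed=20_000 + s
        )
        matrix = pearson_matrix(bin_spikes(rec, 0.5))
        graph = functional_edges(matrix, threshold=1e-9)
        part = community.louvain(graph, seed=s)
        order = sorted(gt.community_of)
        aris.append(
            adjusted_rand_score(
                [gt.community_of[c] for c in order], [part.membership[c] for c in order]
            )
        )
    return np.asarray(aris)
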