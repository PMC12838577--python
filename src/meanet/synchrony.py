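"""Pairwise spike-train synchrony and the functional connectivity graph.

Synchrony between two channels is the sample Pearson correlation of
their binned spike counts (default 100 ms bins).  Channel pairs whose
correlation meets a threshold become weighted, undirected *functional
connections*; the product of the number of connections and their mean
weight is the network synchronization activity index used to summarise
overall network state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import AnalysisError, ValidationError
from .io import TrialRecording

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_S = 0.1
DEFAULT_MIN_RATE_HZ = 0.1
DEFAULT_EDGE_THRESHOLD = 0.3


@dataclass(frozen=True)
class BinnedCounts:
    """Spike counts on a regular half-open bin grid ``[k*w, (k+1)*w)``."""

    channel_ids: tuple
    counts: np.ndarray  # (n_channels, n_bins) nonnegative ints
    bin_width_s: float
    duration_s: float

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def rows(self, channel_ids: Sequence[str]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.channel_ids)}
        return self.counts[[index[c] for c in channel_ids]]


@dataclass(frozen=True)
class SynchronyMatrix:
    """Symmetric Pearson matrix over active channels.

    Pairs involving a zero-variance channel are undefined and stored as
    NaN — never silently zero.
    """

    channel_ids: tuple
    r: np.ndarray
    bin_width_s: float
    min_rate_hz: float

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)


@dataclass(frozen=True)
class FunctionalGraph:
    """Thresholded synchrony graph (no self-edges, weights >= threshold)."""

    graph: nx.Graph
    threshold: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> tuple:
        return tuple(self.graph.nodes)

    def edge_weights(self) -> np.ndarray:
        return np.array([d["weight"] for _, _, d in self.graph.edges(data=True)])


def bin_spikes(recording: TrialRecording, bin_width_s: float = DEFAULT_BIN_WIDTH_S) -> BinnedCounts:
    """Bin every channel's spikes onto a common grid.

    Only full bins are kept (``n_bins = floor(duration / w)``); spikes
    falling past the last full bin are discarded with a logged count.
    """
    if not bin_width_s > 0:
        raise ValidationError(f"bin_width_s must be > 0, got {bin_width_s}")
    if bin_width_s > recording.duration:
        raise ValidationError("bin_width_s exceeds trial duration")
    # float-tolerant floor so that e.g. 0.3 / 0.1 still gives 3 bins
    n_bins = int(np.floor(recording.duration / bin_width_s + 1e-9))
    t_max = n_bins * bin_width_s
    edges = np.linspace(0.0, t_max, n_bins + 1)
    counts = np.zeros((recording.n_channels, n_bins), dtype=np.int64)
    n_discarded = 0
    for i, train in enumerate(recording.trains):
        idx = np.searchsorted(edges, train.times, side="right") - 1
        in_range = idx < n_bins  # spikes at t >= n_bins * w are dropped
        n_discarded += int(np.count_nonzero(~in_range))
        np.add.at(counts[i], idx[in_range], 1)
    if n_discarded:
        logger.info(
            "trial %s: %d spikes past t=%g discarded during binning",
            recording.trial_id, n_discarded, t_max,
        )
    return BinnedCounts(
        channel_ids=recording.channel_ids,
        counts=counts,
        bin_width_s=bin_width_s,
        duration_s=recording.duration,
    )


def active_channels(recording: TrialRecording, min_rate_hz: float = DEFAULT_MIN_RATE_HZ):
    """Channels whose mean firing rate meets ``min_rate_hz`` (inclusive)."""
    if min_rate_hz < 0:
        raise ValidationError("min_rate_hz must be >= 0")
    return {t.channel_id for t in recording.trains if t.rate_hz >= min_rate_hz}


def pearson_matrix(
    binned: BinnedCounts,
    active_ids: Iterable[str] | None = None,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
) -> SynchronyMatrix:
    """Sample Pearson correlation between binned count vectors.

    ``active_ids`` restricts the matrix to the given channels (sorted);
    by default all binned channels are used.  Zero-variance channels
    yield NaN off-diagonal entries and a warning.
    """
    ids = sorted(active_ids) if active_ids is not None else list(binned.channel_ids)
    if len(ids) < 2:
        raise AnalysisError(f"need >= 2 active channels, got {len(ids)}")
    if binned.n_bins < 2:
        raise AnalysisError("need >= 2 bins to correlate")
    x = binned.rows(ids).astype(float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    r = np.full((len(ids), len(ids)), np.nan)
    ok = ~degenerate
    if np.count_nonzero(ok) >= 2:
        sub = np.corrcoef(x[ok])
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, 1.0)
    if np.any(degenerate):
        warnings.warn(
            f"{int(np.count_nonzero(degenerate))} zero-variance channel(s); "
            "their pairwise synchrony is undefined (NaN)",
            stacklevel=2,
        )
    return SynchronyMatrix(
        channel_ids=tuple(ids), r=r, bin_width_s=binned.bin_width_s, min_rate_hz=min_rate_hz
    )


def functional_edges(
    matrix: SynchronyMatrix, threshold: float = DEFAULT_EDGE_THRESHOLD
) -> FunctionalGraph:
    """Edges for every unordered pair with ``r >= threshold``.

    Negative correlations never qualify under the default threshold;
    undefined (NaN) pairs never become edges.  All active channels are
    graph nodes even when isolated.
    """
    if not (-1 < threshold <= 1):
        raise ValidationError("threshold must lie in (-1, 1]")
    g = nx.Graph()
    g.add_nodes_from(matrix.channel_ids)
    n = matrix.n_channels
    for i in range(n):
        for j in range(i + 1, n):
            w = matrix.r[i, j]
            if np.isfinite(w) and w >= threshold:
                g.add_edge(matrix.channel_ids[i], matrix.channel_ids[j], weight=float(w))
    return FunctionalGraph(graph=g, threshold=threshold)


def mean_synchrony(matrix: SynchronyMatrix) -> float:
    """Mean of all defined off-diagonal pairs (not only edges)."""
    iu = np.triu_indices(matrix.n_channels, k=1)
    vals = matrix.r[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise AnalysisError("no defined channel pairs")
    return float(vals.mean())


def sync_activity_index(graph: FunctionalGraph) -> float:
    """Network synchronization activity index.

    Defined as the number of functional connections times their mean
    synchrony coefficient; zero for an edgeless graph.
    """
    if graph.n_edges == 0:
        return 0.0
    return float(graph.n_edges * graph.edge_weights().mean())
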