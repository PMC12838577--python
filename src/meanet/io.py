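"""Data model and file I/O for multichannel spike-train recordings.

A recording session is organised as one CSV spike table per trial
(columns ``channel,time_s``) plus a YAML manifest listing trials in
acquisition order together with their stimulation condition.  Trial
order is significant: downstream analyses compare each trial with its
immediate predecessor, so loaders never reorder trials.

Spike times are stored in seconds as double-precision floats; the
acquisition sampling rate (30 kHz in the experiments this package
models) is treated as metadata and timestamps are never re-quantized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Stimulation paradigms understood by the analysis pipelines.
PARADIGMS = ("control", "disrupt", "stabilize", "rhythmic")

#: Rhythmic stimulation frequencies used in the study design (theta-band
#: 7.8 Hz and gamma-band 40 Hz).
DEFAULT_RHYTHMIC_FREQS = (7.8, 40.0)

SPIKE_TABLE_HEADER = ("channel", "time_s")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds from trial start) for one channel."""

    channel_id: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValidationError(
                f"duration must be finite and positive, got {self.duration!r}"
            )
        if times.ndim != 1:
            raise ValidationError("spike times must be a 1-D array")
        if times.size:
            if not np.all(np.isfinite(times)):
                raise ValidationError(f"non-finite spike time on {self.channel_id}")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValidationError(
                    f"spike times on {self.channel_id} must satisfy "
                    f"0 <= t < duration={self.duration}"
                )
            if np.any(np.diff(times) <= 0):
                raise ValidationError(
                    f"spike times on {self.channel_id} must be strictly increasing"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class StimCondition:
    """Stimulation condition attached to one trial.

    ``control`` trials carry no stimulation (frequency 0, 0 pulses);
    ``rhythmic`` trials must use one of the declared rhythmic
    frequencies.  ``disrupt``/``stabilize`` carry the paradigm's own
    pulse parameters (e.g. ~3.3 Hz asynchronous pairs vs 100 Hz
    synchronous bursts) but are identified by the paradigm label.
    """

    paradigm: str
    frequency_hz: float = 0.0
    n_pulses: int = 0
    group_label: str = ""
    allowed_rhythmic_freqs: tuple = DEFAULT_RHYTHMIC_FREQS

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValidationError(
                f"unknown paradigm {self.paradigm!r}; expected one of {PARADIGMS}"
            )
        if self.frequency_hz < 0:
            raise ValidationError("frequency_hz must be nonnegative")
        if self.n_pulses < 0:
            raise ValidationError("n_pulses must be nonnegative")
        if self.paradigm == "control" and (self.frequency_hz != 0 or self.n_pulses != 0):
            raise ValidationError(
                "control trials must have frequency_hz = 0 and n_pulses = 0"
            )
        if self.paradigm == "rhythmic" and not any(
            math.isclose(self.frequency_hz, f) for f in self.allowed_rhythmic_freqs
        ):
            raise ValidationError(
                f"rhythmic frequency {self.frequency_hz} Hz not in declared set "
                f"{self.allowed_rhythmic_freqs}"
            )


@dataclass(frozen=True)
class TrialRecording:
    """All channels of one trial plus its condition metadata.

    Trains are kept sorted by channel id; every train shares the trial
    duration.  ``condition`` may be ``None`` for a bare spike table that
    has not yet been joined with a manifest.
    """

    trial_id: str
    trains: tuple
    duration: float
    condition: StimCondition | None = None

    def __post_init__(self) -> None:
        trains = tuple(sorted(self.trains, key=lambda t: t.channel_id))
        object.__setattr__(self, "trains", trains)
        ids = [t.channel_id for t in trains]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate channel ids in trial {self.trial_id}")
        for t in trains:
            if t.duration != self.duration:
                raise ValidationError(
                    f"train {t.channel_id} duration {t.duration} != trial "
                    f"duration {self.duration}"
                )

    @property
    def channel_ids(self) -> tuple:
        return tuple(t.channel_id for t in self.trains)

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    @property
    def total_spikes(self) -> int:
        return sum(t.n_spikes for t in self.trains)

    def train(self, channel_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.channel_id == channel_id:
                return t
        raise KeyError(channel_id)

    def with_condition(self, condition: StimCondition) -> "TrialRecording":
        return replace(self, condition=condition)


@dataclass(frozen=True)
class ManifestEntry:
    trial_id: str
    path: str
    condition: StimCondition


@dataclass(frozen=True)
class TrialManifest:
    """Ordered list of trials with condition metadata.

    ``channels`` optionally declares the full electrode layout so that
    channels silent in a given trial still appear as zero-spike trains.
    """

    entries: tuple
    duration_s: float
    channels: tuple = ()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)


# ---------------------------------------------------------------------------
# spike tables


def read_spike_table(
    path: str | Path,
    duration: float,
    channels: Sequence[str] | None = None,
    trial_id: str | None = None,
) -> TrialRecording:
    """Read a ``channel,time_s`` CSV into a :class:`TrialRecording`.

    The header row is optional.  Rows may appear in any order; trains
    come back time-sorted.  Exact duplicate (channel, time) rows are
    dropped with a logged warning.  ``channels`` declares channels that
    must be present even with zero spikes.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"spike table not found: {path}")
    per_channel: dict[str, list[float]] = {str(c): [] for c in (channels or [])}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            if lineno == 1 and parts[0].lower() == SPIKE_TABLE_HEADER[0]:
                continue
            channel, time_str = parts
            try:
                t = float(time_str)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric spike time {time_str!r}"
                ) from None
            if not (0 <= t < duration):
                raise ValidationError(
                    f"{path}:{lineno}: spike time {t} outside [0, {duration})"
                )
            per_channel.setdefault(channel, []).append(t)

    trains = []
    n_dupes = 0
    for channel, times in per_channel.items():
        arr = np.sort(np.asarray(times, dtype=float))
        uniq = np.unique(arr)
        n_dupes += arr.size - uniq.size
        trains.append(SpikeTrain(channel, uniq, duration))
    if n_dupes:
        logger.warning("%s: dropped %d duplicate (channel, time) rows", path, n_dupes)
    return TrialRecording(
        trial_id=trial_id or path.stem, trains=tuple(trains), duration=duration
    )


def write_spike_table(recording: TrialRecording, path: str | Path) -> Path:
    """Write a recording as a canonical spike table.

    Rows are ordered by channel id (lexicographic) then time, with the
    standard header, so that equal recordings produce byte-identical
    files.
    """
    path = Path(path)
    rows = []
    for train in recording.trains:  # already channel-sorted
        for t in train.times:
            rows.append((train.channel_id, t))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(SPIKE_TABLE_HEADER) + "\n")
        for channel, t in rows:
            fh.write(f"{channel},{float(t)!r}\n")
    return path


# ---------------------------------------------------------------------------
# manifests


def _condition_from_mapping(m: Mapping, context: str) -> StimCondition:
    try:
        return StimCondition(
            paradigm=str(m.get("paradigm", "")),
            frequency_hz=float(m.get("frequency_hz", 0.0)),
            n_pulses=int(m.get("n_pulses", 0)),
            group_label=str(m.get("group_label", "")),
        )
    except ValidationError as exc:
        raise ValidationError(f"{context}: {exc}") from None


def read_manifest(path: str | Path) -> TrialManifest:
    """Read a YAML trial manifest, preserving trial order.

    Expected layout::

        duration_s: 180.0
        channels: [ch01, ch02, ...]   # optional declared channel list
        trials:
          - id: control_1
            path: control_1.csv
            paradigm: control

    Conditions are validated on load; an unknown paradigm or a control
    trial with nonzero pulse parameters is rejected.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "trials" not in doc:
        raise FormatError(f"{path}: manifest must be a mapping with a 'trials' list")
    try:
        duration = float(doc.get("duration_s", 180.0))
    except (TypeError, ValueError):
        raise FormatError(f"{path}: bad duration_s") from None
    channels = tuple(str(c) for c in doc.get("channels", []) or [])
    entries = []
    for i, item in enumerate(doc["trials"]):
        if not isinstance(item, Mapping) or "id" not in item or "path" not in item:
            raise FormatError(f"{path}: trial #{i} must declare 'id' and 'path'")
        cond = _condition_from_mapping(item, f"{path}: trial {item['id']!r}")
        entries.append(ManifestEntry(str(item["id"]), str(item["path"]), cond))
    return TrialManifest(entries=tuple(entries), duration_s=duration, channels=channels)


def write_manifest(manifest: TrialManifest, path: str | Path) -> Path:
    doc = {
        "duration_s": float(manifest.duration_s),
        "channels": list(manifest.channels),
        "trials": [
            {
                "id": e.trial_id,
                "path": e.path,
                "paradigm": e.condition.paradigm,
                "frequency_hz": float(e.condition.frequency_hz),
                "n_pulses": int(e.condition.n_pulses),
                "group_label": e.condition.group_label,
            }
            for e in manifest.entries
        ],
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def load_trials(manifest: TrialManifest, base_dir: str | Path | None = None):
    """Yield condition-tagged recordings in manifest order."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    for entry in manifest:
        p = Path(entry.path)
        if not p.is_absolute():
            p = base / p
        rec = read_spike_table(
            p,
            duration=manifest.duration_s,
            channels=manifest.channels or None,
            trial_id=entry.trial_id,
        )
        yield rec.with_condition(entry.condition)


# ---------------------------------------------------------------------------
# generic CSV writers used by downstream stages


def write_matrix_csv(channel_ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> Path:
    """Square matrix with a channel-id header row and column."""
    df = pd.DataFrame(np.asarray(matrix), index=list(channel_ids), columns=list(channel_ids))
    df.to_csv(path, float_format="%.10g")
    return Path(path)


def write_edges_csv(edges: Iterable[tuple], path: str | Path) -> Path:
    """3-column edge list: source, target, weight."""
    df = pd.DataFrame(sorted(edges), columns=["source", "target", "weight"])
    df.to_csv(path, index=False, float_format="%.10g")
    return Path(path)


def write_partition_csv(membership: Mapping[str, int], path: str | Path) -> Path:
    df = pd.DataFrame(
        sorted(membership.items()), columns=["channel", "community"]
    )
    df.to_csv(path, index=False)
    return Path(path)
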