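"""Statistical fusion of emotion, GSR and pulse traces into 44 features.

Each trial of a sensory experiment yields three time series: per-frame
probabilities of nine facial expressions (nominal 30 fps), galvanic skin
response and cardiac pulse (nominal 8 samples/s, arbitrary sensor units).
Every stream is reduced to four order-invariant statistics — average,
population standard deviation, minimum, maximum — giving
``(9 + 2) * 4 = 44`` features per trial.  No cross-stream resampling is
performed: the four statistics are computed per stream over the trial
window, so the differing sampling rates never need reconciling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .labels import DEFAULT_NINE, EMOTION_LABELS, validate_nine_subset

METRICS = ("avr", "std", "min", "max")
SENSOR_STREAMS = ("gsr", "pulse")


class InsufficientDataError(ValueError):
    """A stream was empty where at least one sample is required."""


class SeriesSummary(NamedTuple):
    avr: float
    std: float
    min: float
    max: float


@dataclass(frozen=True)
class EmotionTrace:
    """Frames-by-expressions probability matrix for one trial.

    ``values`` has one column per label in ``labels`` (nine by default);
    frames where no face was detected have already been dropped.
    """

    values: np.ndarray
    labels: tuple[str, ...] = DEFAULT_NINE

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.labels):
            raise ValueError(f"emotion trace must be (frames, {len(self.labels)}), got {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ExperimentRecord:
    """One (participant, sample) trial: three streams plus the hedonic score."""

    participant_id: str
    sample_id: str
    modality: str  # "taste" | "smell"
    emotion_trace: EmotionTrace
    gsr: np.ndarray
    pulse: np.ndarray
    acceptance: int

    def __post_init__(self):
        if not -3 <= self.acceptance <= 3:
            raise ValueError(f"acceptance must lie in [-3, 3], got {self.acceptance}")
        object.__setattr__(self, "gsr", np.asarray(self.gsr, dtype=float).ravel())
        object.__setattr__(self, "pulse", np.asarray(self.pulse, dtype=float).ravel())


@dataclass(frozen=True)
class FeatureVector44:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != len(self.names):
            raise ValueError("feature values and names disagree in length")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def feature_names(subset: Sequence[str] = DEFAULT_NINE) -> tuple[str, ...]:
    """The 44 fused feature names, ``<stream>_<metric>``.

    Streams are ordered as the nine expressions of *subset* followed by
    ``gsr`` and ``pulse``; within a stream the metrics run avr, std, min,
    max.  The order is fixed so feature matrices are column-stable.
    """
    subset = validate_nine_subset(subset)
    return tuple(f"{stream}_{metric}" for stream in (*subset, *SENSOR_STREAMS) for metric in METRICS)


def emotion_feature_names(subset: Sequence[str] = DEFAULT_NINE) -> tuple[str, ...]:
    return tuple(n for n in feature_names(subset) if not n.startswith(SENSOR_STREAMS))


def sensor_feature_names(channels: Sequence[str] = SENSOR_STREAMS) -> tuple[str, ...]:
    return tuple(f"{c}_{m}" for c in channels for m in METRICS)


def summarize_series(series: Iterable[float]) -> SeriesSummary:
    """Average, population standard deviation, minimum and maximum.

    The population (divide-by-n) standard deviation is used, so a single
    sample summarizes to ``(x, 0, x, x)``.  Raises
    :class:`InsufficientDataError` on an empty series.
    """
    x = np.asarray(list(series) if not isinstance(series, np.ndarray) else series, dtype=float).ravel()
    if x.size == 0:
        raise InsufficientDataError("cannot summarize an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return SeriesSummary(float(x.mean()), float(x.std()), float(x.min()), float(x.max()))


def select_nine_emotions(
    probabilities: np.ndarray,
    subset: Sequence[str] = DEFAULT_NINE,
    face_counts: np.ndarray | None = None,
) -> EmotionTrace:
    """Restrict a frames-by-ten probability series to nine expressions.

    Columns are selected and ordered by *subset*; frames whose
    ``face_count`` is -1 (no face detected) are dropped rather than
    imputed, so downstream statistics only see observed frames.
    """
    subset = validate_nine_subset(subset)
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != len(EMOTION_LABELS):
        raise ValueError(f"expected a (frames, {len(EMOTION_LABELS)}) probability series, got {probs.shape}")
    if face_counts is not None:
        face_counts = np.asarray(face_counts).ravel()
        if face_counts.size != probs.shape[0]:
            raise ValueError("face_counts length must match the number of frames")
        probs = probs[face_counts >= 1]
    cols = [EMOTION_LABELS.index(lab) for lab in subset]
    return EmotionTrace(probs[:, cols], labels=subset)


def fuse_experiment(record: ExperimentRecord) -> FeatureVector44:
    """Reduce one trial to its 44-feature vector.

    Each stream is summarized independently over its own sampling grid.
    A trial with any empty stream (e.g. no frame had a detectable face)
    is unusable and raises :class:`InsufficientDataError`.
    """
    trace = record.emotion_trace
    if trace.n_frames == 0:
        raise InsufficientDataError("emotion trace is empty after no-face filtering")
    if record.gsr.size == 0 or record.pulse.size == 0:
        raise InsufficientDataError("sensor trace is empty")
    values: list[float] = []
    for col in range(trace.values.shape[1]):
        values.extend(summarize_series(trace.values[:, col]))
    values.extend(summarize_series(record.gsr))
    values.extend(summarize_series(record.pulse))
    return FeatureVector44(np.asarray(values), feature_names(trace.labels))


ID_COLUMNS = ("participant_id", "sample_id", "modality")
TARGET_COLUMN = "acceptance"


def fuse_cohort(records: Iterable[ExperimentRecord], on_empty: str = "raise") -> pd.DataFrame:
    """Fuse every record into a tidy feature matrix.

    One row per trial: participant_id, sample_id, modality, the 44
    features, and the reported acceptance.  ``on_empty="skip"`` silently
    drops unusable trials (any empty stream) instead of raising.
    """
    if on_empty not in ("raise", "skip"):
        raise ValueError("on_empty must be 'raise' or 'skip'")
    rows = []
    for rec in records:
        try:
            fv = fuse_experiment(rec)
        except InsufficientDataError:
            if on_empty == "skip":
                continue
            raise
        row = {"participant_id": rec.participant_id, "sample_id": rec.sample_id, "modality": rec.modality}
        row.update(fv.as_dict())
        row[TARGET_COLUMN] = rec.acceptance
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*ID_COLUMNS, *feature_names(), TARGET_COLUMN])
    return pd.DataFrame(rows)


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in (*ID_COLUMNS, TARGET_COLUMN) if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns {missing}")
    return df
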