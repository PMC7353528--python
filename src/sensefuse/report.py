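"""Descriptive analyses of a sensory cohort.

Summaries mirroring a standard sensory-science results section: hedonic
score histograms per sample, per-emotion distributions of per-consumer
mean probabilities, absolute-Pearson correlation matrices between the 44
fused features and acceptance, top-k feature importance, and
cross-participant mean/std curves of the sensor signals per sample
(tagged liked vs disliked).  Plot helpers are optional and headless-safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .forest import ImportanceReport
from .fusion import ExperimentRecord, TARGET_COLUMN

HEDONIC_LEVELS = tuple(range(-3, 4))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Absolute Pearson correlations; symmetric, unit diagonal, in [0, 1]."""

    values: np.ndarray
    labels: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def abs_pearson_matrix(features: pd.DataFrame, acceptance: Sequence[float] | None = None) -> CorrelationMatrix:
    """|Pearson r| between every pair of feature columns (plus acceptance).

    *features* holds numeric columns; an ``acceptance`` column may be
    included directly or passed separately.  Constant columns have an
    undefined correlation and are excluded (reported in ``excluded``).
    Requires at least 3 rows.
    """
    df = features.select_dtypes("number").copy()
    if acceptance is not None:
        df[TARGET_COLUMN] = np.asarray(acceptance, dtype=float)
    if len(df) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    constant = tuple(c for c in df.columns if df[c].nunique() <= 1)
    df = df.drop(columns=list(constant))
    if df.shape[1] == 0:
        raise ValueError("all columns are constant")
    r = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(np.abs(r), tuple(df.columns), constant)


def hedonic_histogram(scores: Iterable[int]) -> pd.Series:
    """Counts of hedonic scores over the seven levels -3..+3."""
    scores = np.asarray(list(scores), dtype=int)
    if scores.size and (scores.min() < -3 or scores.max() > 3):
        raise ValueError("hedonic scores must lie in [-3, 3]")
    counts = pd.Series(0, index=list(HEDONIC_LEVELS), name="count")
    uniq, cnt = np.unique(scores, return_counts=True)
    for u, c in zip(uniq, cnt):
        counts.loc[int(u)] = int(c)
    return counts


def emotion_summary(records: Iterable[ExperimentRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-consumer mean emotion probabilities, with boxplot statistics.

    Every participant's frames are pooled over all their trials; the
    first returned frame has one row per participant and one column per
    expression.  The second gives per-expression quartiles (q1, median,
    q3), mean, min and max over participants.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    labels: tuple[str, ...] | None = None
    for rec in records:
        if labels is None:
            labels = rec.emotion_trace.labels
        elif rec.emotion_trace.labels != labels:
            raise ValueError("records mix different expression subsets")
        s = sums.setdefault(rec.participant_id, np.zeros(len(labels)))
        s += rec.emotion_trace.values.sum(axis=0)
        counts[rec.participant_id] = counts.get(rec.participant_id, 0) + rec.emotion_trace.n_frames
    if not sums:
        raise ValueError("no records supplied")
    per_participant = pd.DataFrame(
        {pid: sums[pid] / counts[pid] for pid in sums}, index=list(labels)
    ).T.rename_axis("participant_id")
    stats = pd.DataFrame({
        "q1": per_participant.quantile(0.25),
        "median": per_participant.quantile(0.5),
        "q3": per_participant.quantile(0.75),
        "mean": per_participant.mean(),
        "min": per_participant.min(),
        "max": per_participant.max(),
    }).rename_axis("emotion")
    return per_participant, stats


@dataclass(frozen=True)
class GroupCurve:
    """Cross-participant mean and std of one sensor channel for one sample."""

    sample_id: str
    channel: str
    grid: np.ndarray       # normalized trial time in [0, 1]
    mean: np.ndarray
    std: np.ndarray
    liked: bool
    n_participants: int


def group_signal_curves(
    records: Iterable[ExperimentRecord],
    channel: str,
    grid_points: int = 100,
) -> list[GroupCurve]:
    """Pointwise cross-participant mean/std curves of GSR or pulse.

    Each participant's trace is linearly resampled onto a common
    ``grid_points``-point grid over normalized trial time (trials may
    differ in duration), then averaged across participants per sample.
    A sample is tagged liked when its mean reported acceptance is
    positive.
    """
    if channel not in ("gsr", "pulse"):
        raise ValueError("channel must be 'gsr' or 'pulse'")
    grid = np.linspace(0.0, 1.0, grid_points)
    traces: dict[str, list[np.ndarray]] = {}
    scores: dict[str, list[int]] = {}
    for rec in records:
        x = getattr(rec, channel)
        if x.size == 0:
            continue
        t = np.linspace(0.0, 1.0, x.size) if x.size > 1 else np.array([0.0])
        traces.setdefault(rec.sample_id, []).append(np.interp(grid, t, x))
        scores.setdefault(rec.sample_id, []).append(rec.acceptance)
    out = []
    for sample_id in sorted(traces):
        stack = np.stack(traces[sample_id])
        out.append(GroupCurve(
            sample_id=sample_id,
            channel=channel,
            grid=grid,
            mean=stack.mean(axis=0),
            std=stack.std(axis=0),
            liked=bool(np.mean(scores[sample_id]) > 0),
            n_participants=stack.shape[0],
        ))
    return out


def top_features(report: ImportanceReport, k: int = 10) -> list[tuple[str, float]]:
    """The k most important features, descending; ties break by name."""
    return report.top(k)


# ---------------------------------------------------------------------------
# optional plotting (headless-safe)


def _axes(ax=None):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_hedonic_histogram(counts: pd.Series, title: str = "", ax=None):
    ax = _axes(ax)
    ax.bar(counts.index, counts.to_numpy())
    ax.set_xlabel("hedonic score")
    ax.set_ylabel("participants")
    ax.set_title(title)
    return ax


def plot_correlation_matrix(matrix: CorrelationMatrix, ax=None):
    ax = _axes(ax)
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90, fontsize=5)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels, fontsize=5)
    ax.figure.colorbar(im, ax=ax, label="|r|")
    return ax


def plot_importance(report: ImportanceReport, k: int = 10, ax=None):
    ax = _axes(ax)
    names, vals = zip(*top_features(report, k))
    ax.barh(range(len(names)), vals)
    ax.set_yticks(range(len(names)), names)
    ax.invert_yaxis()
    ax.set_xlabel("feature importance")
    return ax


def plot_group_curves(curves: list[GroupCurve], statistic: str = "mean", ax=None):
    ax = _axes(ax)
    for c in curves:
        ax.plot(c.grid, getattr(c, statistic),
                color=("tab:green" if c.liked else "tab:blue"),
                label=f"{c.sample_id} ({'liked' if c.liked else 'disliked'})")
    ax.set_xlabel("normalized trial time")
    ax.set_ylabel(f"{curves[0].channel} {statistic}" if curves else statistic)
    ax.legend(fontsize=6)
    return ax
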