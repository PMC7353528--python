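"""On-disk cohort layout shared by the CLI stages.

A cohort directory holds three tidy CSVs plus the manifest:

* ``emotions.csv`` — one row per (trial, frame): participant_id,
  sample_id, modality, frame_index, then one probability column per
  fused expression;
* ``sensors.csv`` — one row per (trial, channel, sample): participant_id,
  sample_id, modality, channel (gsr|pulse), sample_index, value;
* ``scores.csv`` — one row per trial with the reported acceptance;
* ``manifest.json`` — the generator's ground-truth parameters (synthetic
  cohorts only).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .fusion import EmotionTrace, ExperimentRecord
from .labels import DEFAULT_NINE
from .synthetic import Cohort, write_manifest

TRIAL_KEY = ["participant_id", "sample_id", "modality"]


def write_cohort(cohort: Cohort | Sequence[ExperimentRecord], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = cohort.records if isinstance(cohort, Cohort) else tuple(cohort)
    emo_rows, sensor_rows, score_rows = [], [], []
    for rec in records:
        key = (rec.participant_id, rec.sample_id, rec.modality)
        labels = rec.emotion_trace.labels
        for i, row in enumerate(rec.emotion_trace.values):
            emo_rows.append((*key, i, *row))
        for channel in ("gsr", "pulse"):
            for i, v in enumerate(getattr(rec, channel)):
                sensor_rows.append((*key, channel, i, v))
        score_rows.append((*key, rec.acceptance))
    labels = records[0].emotion_trace.labels if records else DEFAULT_NINE
    pd.DataFrame(emo_rows, columns=[*TRIAL_KEY, "frame_index", *labels]).to_csv(
        directory / "emotions.csv", index=False)
    pd.DataFrame(sensor_rows, columns=[*TRIAL_KEY, "channel", "sample_index", "value"]).to_csv(
        directory / "sensors.csv", index=False)
    pd.DataFrame(score_rows, columns=[*TRIAL_KEY, "acceptance"]).to_csv(
        directory / "scores.csv", index=False)
    if isinstance(cohort, Cohort):
        write_manifest(cohort.manifest, directory / "manifest.json")


def read_cohort(directory) -> list[ExperimentRecord]:
    directory = Path(directory)
    emotions = pd.read_csv(directory / "emotions.csv")
    sensors = pd.read_csv(directory / "sensors.csv")
    scores = pd.read_csv(directory / "scores.csv")
    labels = tuple(c for c in emotions.columns if c not in (*TRIAL_KEY, "frame_index"))
    emo_groups = {k: g for k, g in emotions.groupby(TRIAL_KEY, sort=False)}
    sensor_groups = {k: g for k, g in sensors.groupby([*TRIAL_KEY, "channel"], sort=False)}
    records = []
    for _, row in scores.iterrows():
        key = (row.participant_id, row.sample_id, row.modality)
        emo = emo_groups[key].sort_values("frame_index")[list(labels)].to_numpy(dtype=float)
        streams = {}
        for channel in ("gsr", "pulse"):
            g = sensor_groups[(*key, channel)].sort_values("sample_index")
            streams[channel] = g["value"].to_numpy(dtype=float)
        records.append(ExperimentRecord(
            participant_id=row.participant_id,
            sample_id=row.sample_id,
            modality=row.modality,
            emotion_trace=EmotionTrace(emo, labels=labels),
            gsr=streams["gsr"],
            pulse=streams["pulse"],
            acceptance=int(row.acceptance),
        ))
    return records
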