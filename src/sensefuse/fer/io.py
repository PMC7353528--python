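"""Per-trial emotion-recognition CSV files.

One CSV per trial, one row per frame: the frame index, the number of
faces detected (-1 when the detector found none), the source file name,
and — for frames with a face — the classification probability for each
of the ten emotion labels.  Probability cells are left empty on no-face
rows; the reader maps them back to ``probabilities=None`` so the files
round-trip losslessly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ..labels import EMOTION_LABELS, N_EMOTIONS

FER_COLUMNS = ("image_index", "n_faces", "file_name", *EMOTION_LABELS)


@dataclass(frozen=True)
class FerRecord:
    image_index: int
    face_count: int
    file_name: str
    probabilities: np.ndarray | None = None

    def __post_init__(self):
        if self.face_count >= 1:
            if self.probabilities is None:
                raise ValueError("a detected face requires a probability vector")
            p = np.asarray(self.probabilities, dtype=float).ravel()
            if p.size != N_EMOTIONS:
                raise ValueError(f"expected {N_EMOTIONS} probabilities, got {p.size}")
            object.__setattr__(self, "probabilities", p)
        elif self.probabilities is not None:
            raise ValueError("no-face records carry no probabilities")


def write_fer_csv(records: Iterable[FerRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FER_COLUMNS)
        for rec in records:
            probs = ([""] * N_EMOTIONS if rec.probabilities is None
                     else [repr(float(p)) for p in rec.probabilities])
            writer.writerow([rec.image_index, rec.face_count, rec.file_name, *probs])


def read_fer_csv(path) -> list[FerRecord]:
    out: list[FerRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != FER_COLUMNS:
            raise ValueError(f"unexpected FER CSV header: {header}")
        for row in reader:
            idx, n_faces, name = int(row[0]), int(row[1]), row[2]
            cells = row[3:]
            probs = None if all(c == "" for c in cells) else np.array([float(c) for c in cells])
            out.append(FerRecord(idx, n_faces, name, probs))
    return out


def records_to_probability_series(records: Sequence[FerRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(frames x 10 probabilities, face counts); no-face rows are NaN."""
    probs = np.full((len(records), N_EMOTIONS), np.nan)
    counts = np.empty(len(records), dtype=int)
    for i, rec in enumerate(records):
        counts[i] = rec.face_count
        if rec.probabilities is not None:
            probs[i] = rec.probabilities
    return probs, counts
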