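"""Emotion label conventions shared by every stage of the pipeline.

The facial-expression classifier distinguishes ten discrete labels; their
order is fixed here and defines vector positions everywhere downstream
(classifier outputs, CSV columns, fused feature names).
"""

from __future__ import annotations

EMOTION_LABELS: tuple[str, ...] = (
    "neutral",
    "happy",
    "sad",
    "surprise",
    "fear",
    "disgust",
    "anger",
    "contempt",
    "none",
    "uncertain",
)
"""The ten-label set, in canonical order."""

N_EMOTIONS = len(EMOTION_LABELS)

DEFAULT_NINE: tuple[str, ...] = EMOTION_LABELS[:9]
"""Default nine-expression subset used for fusion: the ten labels minus
``uncertain``, which marks annotator indecision rather than an expression."""


def label_index(label: str) -> int:
    """Position of *label* in the canonical order; raises on unknown labels."""
    try:
        return EMOTION_LABELS.index(label)
    except ValueError:
        raise ValueError(f"unknown emotion label {label!r}; expected one of {EMOTION_LABELS}") from None


def validate_nine_subset(subset: tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Check that *subset* is a 9-element subset of the ten labels."""
    subset = tuple(subset)
    if len(subset) != 9:
        raise ValueError(f"expression subset must have exactly 9 labels, got {len(subset)}")
    if len(set(subset)) != 9:
        raise ValueError("expression subset contains duplicates")
    for lab in subset:
        label_index(lab)
    return subset
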