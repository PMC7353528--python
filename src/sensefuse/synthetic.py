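"""Synthetic sensory-experiment cohorts with known ground truth.

The study design being emulated: each of 120 participants evaluates ten
food samples (five flavors tasted, five odors smelled) for about ten
seconds while a camera records the face at 30 fps and finger sensors
record galvanic skin response (GSR) and cardiac pulse at 8 samples/s;
afterwards the participant reports liking on a seven-point hedonic scale
coded -3 (most disliked) to +3 (most liked).

Every distributional choice below is simulation design, not an observed
fact.  The defaults are tuned to the qualitative structure the study
conditions call for:

* facial expressions are dominated by sadness and disgust regardless of
  liking (participants concentrate), with only a weak, strongly
  attenuated valence signal (many participants show almost no facial
  gesture, and how expressive a face is varies per participant);
* GSR carries the strongest acceptance signal: its noise level scales
  with arousal (|valence|) and disliked samples additionally impose a
  drift (slow rise or abrupt fall), so the GSR standard deviation tracks
  the elicited reaction closely;
* pulse carries a weaker signal: its variance grows mildly with emotional
  intensity and its mean dips slightly;
* reported acceptance is the latent valence on the 3-point scale plus
  reporting noise, quantized to the seven levels.

A cohort comes with a manifest recording every latent parameter so
parameter-recovery tests can check the pipeline against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .fusion import ExperimentRecord, select_nine_emotions
from .labels import DEFAULT_NINE, EMOTION_LABELS


def _base_emotion_bias() -> tuple[float, ...]:
    # Dirichlet concentration weights over the ten labels; sadness and
    # disgust dominate, "uncertain" is rare.
    bias = {
        "neutral": 2.0, "happy": 0.5, "sad": 4.0, "surprise": 0.4,
        "fear": 0.3, "disgust": 2.5, "anger": 0.4, "contempt": 0.3,
        "none": 0.6, "uncertain": 0.2,
    }
    return tuple(bias[lab] for lab in EMOTION_LABELS)


@dataclass(frozen=True)
class SampleProfile:
    """Latent description of one food sample's elicited response.

    ``latent_valence`` in [-1, 1] drives both the reported score and the
    physiological effects; ``gsr_drift`` is in sensor units per second
    (positive = slow rise, negative = fall); ``pulse_var_factor`` scales
    how much emotional intensity inflates pulse variance.
    """

    sample_id: str
    modality: str  # "taste" | "smell"
    latent_valence: float
    gsr_drift: float = 0.0
    gsr_noise_sd: float = 0.15
    pulse_var_factor: float = 1.0
    emotion_bias: tuple[float, ...] = field(default_factory=_base_emotion_bias)

    def __post_init__(self):
        if not -1.0 <= self.latent_valence <= 1.0:
            raise ValueError("latent_valence must lie in [-1, 1]")
        if len(self.emotion_bias) != len(EMOTION_LABELS):
            raise ValueError("emotion_bias needs one weight per label")
        if any(w <= 0 for w in self.emotion_bias):
            raise ValueError("emotion concentration weights must be positive")


def default_profiles() -> tuple[SampleProfile, ...]:
    """Five taste and five smell samples mirroring the study's menu.

    Disliked samples get the strong GSR signatures (clam: slow rise;
    Gouda cheese: abrupt fall with a noisy trace; smoke: plunge); liked
    samples stay flat.  Vinegar is reported as disliked but elicits only
    a weak physiological reaction.
    """
    return (
        SampleProfile("1_clam", "taste", -0.6, gsr_drift=0.5, gsr_noise_sd=0.45, pulse_var_factor=1.6),
        SampleProfile("2_strawberry", "taste", 0.8, gsr_noise_sd=0.40, pulse_var_factor=1.2),
        SampleProfile("3_mint", "taste", 0.55, gsr_noise_sd=0.30, pulse_var_factor=1.15),
        SampleProfile("4_pineapple", "taste", 0.7, gsr_noise_sd=0.36, pulse_var_factor=1.2),
        SampleProfile("5_gouda_cheese", "taste", -0.9, gsr_drift=-0.9, gsr_noise_sd=0.55, pulse_var_factor=2.0),
        SampleProfile("1_gouda_cheese", "smell", -0.75, gsr_drift=0.6, gsr_noise_sd=0.48, pulse_var_factor=1.8),
        SampleProfile("2_pineapple", "smell", 0.75, gsr_noise_sd=0.38, pulse_var_factor=1.2),
        SampleProfile("3_mint", "smell", 0.6, gsr_noise_sd=0.32, pulse_var_factor=1.15),
        SampleProfile("4_vinegar", "smell", -0.45, gsr_drift=0.05, gsr_noise_sd=0.24, pulse_var_factor=1.1),
        SampleProfile("5_smoke", "smell", -0.85, gsr_drift=-0.8, gsr_noise_sd=0.52, pulse_var_factor=2.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 120
    samples_per_participant: int = 10
    trial_duration: float = 10.0  # seconds
    frame_rate: float = 30.0      # emotion frames per second
    sensor_rate: float = 8.0      # GSR / pulse samples per second
    face_drop_rate: float = 0.02  # fraction of frames with no detectable face
    seed: int | None = None

    def __post_init__(self):
        if min(self.trial_duration, self.frame_rate, self.sensor_rate) <= 0:
            raise ValueError("rates and duration must be positive")
        if not 0 <= self.face_drop_rate < 1:
            raise ValueError("face_drop_rate must lie in [0, 1)")
        if self.n_participants < 1 or self.samples_per_participant < 1:
            raise ValueError("cohort must contain at least one participant and sample")


@dataclass(frozen=True)
class ParticipantState:
    """Per-participant latent physiology."""

    participant_id: str
    gsr_baseline: float
    pulse_baseline: float
    expressiveness: float  # scales the valence-dependent expression shifts


def draw_participant(participant_id: str, rng: np.random.Generator) -> ParticipantState:
    return ParticipantState(
        participant_id=participant_id,
        gsr_baseline=float(rng.uniform(8.0, 12.0)),
        pulse_baseline=float(rng.uniform(60.0, 80.0)),
        expressiveness=float(rng.uniform(0.3, 1.7)),
    )


# frame-to-frame Dirichlet sharpness: larger = steadier expression traces
_FRAME_CONCENTRATION = 6.0


def simulate_trial(
    profile: SampleProfile,
    participant: ParticipantState,
    rng: np.random.Generator,
    config: CohortConfig = CohortConfig(),
    subset: Sequence[str] = DEFAULT_NINE,
) -> ExperimentRecord:
    """Simulate one (participant, sample) trial.

    Emotion frames are Dirichlet draws around the sample's concentration
    weights, shifted toward happiness (liked) or disgust (disliked) in
    proportion to the participant's expressiveness and a per-trial
    attenuation (faces are often nearly blank during tasting, so the
    shift frequently barely registers).  GSR is baseline + drift * t +
    white noise; pulse is baseline with variance modulated by emotional
    intensity and a slight intensity-dependent mean dip.
    """
    n_frames = int(round(config.trial_duration * config.frame_rate))
    n_sensor = int(round(config.trial_duration * config.sensor_rate))
    valence = profile.latent_valence
    intensity = abs(valence)

    attenuation = rng.beta(1.2, 1.8)
    shift = participant.expressiveness * attenuation
    conc = np.asarray(profile.emotion_bias, dtype=float).copy()
    conc[EMOTION_LABELS.index("happy")] += 0.8 * max(valence, 0.0) * shift
    conc[EMOTION_LABELS.index("disgust")] += 0.6 * max(-valence, 0.0) * shift
    probs = rng.dirichlet(conc * _FRAME_CONCENTRATION, size=n_frames)
    face_counts = np.where(rng.random(n_frames) < config.face_drop_rate, -1, 1)

    t = np.arange(n_sensor) / config.sensor_rate
    gsr = participant.gsr_baseline + profile.gsr_drift * t + rng.normal(0.0, profile.gsr_noise_sd, n_sensor)
    pulse_sd = 0.8 * (1.0 + (profile.pulse_var_factor - 1.0) * intensity)
    pulse = participant.pulse_baseline - 2.0 * intensity + rng.normal(0.0, pulse_sd, n_sensor)

    acceptance = int(np.clip(np.rint(3.0 * valence + rng.normal(0.0, 0.5)), -3, 3))
    trace = select_nine_emotions(probs, subset=subset, face_counts=face_counts)
    if trace.n_frames == 0:  # pathological drop rate; keep the record usable
        trace = select_nine_emotions(probs[:1], subset=subset)
    return ExperimentRecord(
        participant_id=participant.participant_id,
        sample_id=profile.sample_id,
        modality=profile.modality,
        emotion_trace=trace,
        gsr=gsr,
        pulse=pulse,
        acceptance=acceptance,
    )


@dataclass(frozen=True)
class Cohort:
    records: tuple[ExperimentRecord, ...]
    manifest: dict


def simulate_cohort(
    config: CohortConfig = CohortConfig(),
    profiles: Sequence[SampleProfile] | None = None,
    subset: Sequence[str] = DEFAULT_NINE,
) -> Cohort:
    """Simulate the full cohort and its ground-truth manifest.

    Each participant evaluates ``samples_per_participant`` samples taken
    cyclically from *profiles* (defaults: the five-taste + five-smell
    menu, so 120 participants x 10 trials = 1200 records).  The manifest
    records the configuration, every sample's latent parameters and every
    participant's latent physiology for recovery tests.
    """
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(config.seed)
    records: list[ExperimentRecord] = []
    participants: list[ParticipantState] = []
    for i in range(config.n_participants):
        participant = draw_participant(f"P{i + 1:03d}", rng)
        participants.append(participant)
        for j in range(config.samples_per_participant):
            profile = profiles[j % len(profiles)]
            records.append(simulate_trial(profile, participant, rng, config, subset))
    manifest = {
        "config": asdict(config),
        "profiles": [asdict(p) for p in profiles],
        "participants": [asdict(p) for p in participants],
        "n_records": len(records),
    }
    return Cohort(tuple(records), manifest)


def toy_section_dataset(
    n_classes: int = 4,
    n_per_class: int = 10,
    seed: int = 0,
    size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """A tiny labeled section dataset for capacity checks.

    Each class is an oriented sinusoidal grating with a class-specific
    orientation and frequency plus pixel noise — easy to separate, so a
    classifier with adequate capacity should overfit it to near-perfect
    training accuracy.  Labels index the ten-label set (classes beyond
    ``n_classes`` are simply unused).  Images are in [0, 1].
    """
    if not 2 <= n_classes <= len(EMOTION_LABELS):
        raise ValueError("n_classes must lie in [2, 10]")
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:size, 0:size] / size
    images, labels = [], []
    for cls in range(n_classes):
        theta = cls * np.pi / n_classes
        freq = 4 + 3 * cls
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            img = 0.5 + 0.4 * np.sin(2 * np.pi * freq * (xs * np.cos(theta) + ys * np.sin(theta)) + phase)
            img = img + rng.normal(0, 0.05, img.shape)
            images.append(np.clip(img, 0, 1))
            labels.append(cls)
    order = rng.permutation(len(labels))
    return np.stack(images)[order], np.asarray(labels)[order]


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
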