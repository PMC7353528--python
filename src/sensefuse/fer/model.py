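"""The two-stage facial-expression classifier.

Stage 1 is a pair of section networks sharing one architecture: network A
scores the two eye sections (the mirrored right section goes through the
same network as the left), network B the two nose-mouth sections.  Each
takes a 64x64 grayscale section through three blocks of (three 3x3
convolutions + 2x2 max pooling) and four dense layers, the last a 10-way
softmax; every hidden activation is a ReLU.  The four resulting 10-vectors
are concatenated — eye_left, eye_right_flipped, mouth_left,
mouth_right_flipped — into a 40-vector for stage 2, a small dense network
(two hidden ReLU layers, softmax output) that yields the final
classification over the ten labels.

Filter counts, dense widths, optimizer and learning rate are configurable
defaults of this implementation, not fixed facts of the design; the
architecture shape (3 x (3 conv + pool), 4 dense; 40-input stage 2) is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..faceprep import FaceSections, SECTION_SIZE
from ..labels import EMOTION_LABELS, N_EMOTIONS
from . import nn

SECTION_ORDER = ("eye_left", "eye_right_flipped", "mouth_left", "mouth_right_flipped")
STAGE2_WIDTH = 4 * N_EMOTIONS  # 40


@dataclass(frozen=True)
class FerNetworkConfig:
    """Architecture hyperparameters for both stages."""

    conv_filters: tuple[int, int, int] = (32, 64, 128)
    convs_per_block: int = 3
    kernel: int = 3
    dense_widths: tuple[int, int, int] = (256, 128, 64)
    stage2_widths: tuple[int, int] = (32, 16)
    dropout_rate: float = 0.4
    n_labels: int = N_EMOTIONS

    def __post_init__(self):
        if len(self.conv_filters) != 3:
            raise ValueError("three convolution blocks are required")
        if len(self.dense_widths) != 3:
            raise ValueError("three hidden dense widths are required (the 10-way head is the fourth)")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if min(*self.conv_filters, *self.dense_widths, *self.stage2_widths) < 1:
            raise ValueError("layer widths must be positive")


TOY_NETWORK = FerNetworkConfig(conv_filters=(4, 8, 8), dense_widths=(32, 16, 16),
                               stage2_widths=(16, 16), dropout_rate=0.1)
"""A narrow configuration for desk-scale training and tests."""


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters; the two stages differ only in the
    validation fraction (0.20 for the section networks, 0.15 for stage 2)."""

    epochs: int = 50
    batch_size: int = 128
    dropout_rate: float = 0.4
    validation_fraction: float = 0.20
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


def build_section_network(config: FerNetworkConfig = FerNetworkConfig(), seed: int = 0) -> nn.Sequential:
    """Stage-1 section network: 64x64x1 in, 10-way softmax out."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_c = 1
    side = SECTION_SIZE
    for filters in config.conv_filters:
        for _ in range(config.convs_per_block):
            layers.append(nn.Conv2D(in_c, filters, config.kernel, rng))
            layers.append(nn.ReLU())
            in_c = filters
        layers.append(nn.MaxPool2x2())
        side //= 2
    layers.append(nn.Flatten())
    width = in_c * side * side
    for w in config.dense_widths:
        layers.append(nn.Dense(width, w, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_rate))
        width = w
    layers.append(nn.Dense(width, config.n_labels, rng))
    return nn.Sequential(layers)


def build_stage2_network(config: FerNetworkConfig = FerNetworkConfig(), seed: int = 0) -> nn.Sequential:
    """Stage-2 fusion network: 40 in, two dense ReLU layers, softmax out."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    width = STAGE2_WIDTH
    for w in config.stage2_widths:
        layers.append(nn.Dense(width, w, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_rate))
        width = w
    layers.append(nn.Dense(width, config.n_labels, rng))
    return nn.Sequential(layers)


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = np.array([EMOTION_LABELS.index(l) for l in labels])
    labels = labels.astype(np.int64)
    if labels.size and not (0 <= labels.min() and labels.max() < N_EMOTIONS):
        raise ValueError(f"labels must index the {N_EMOTIONS}-label set")
    return labels


def train(
    model: nn.Sequential,
    X: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
) -> dict[str, list[float]]:
    """Train with Adam on softmax cross-entropy; returns the epoch history.

    The last ``validation_fraction`` of a seeded shuffle is held out; the
    history records per-epoch mean training loss/accuracy and validation
    loss/accuracy.  Fully reproducible from (model init, data, seed).
    """
    X = np.asarray(X, dtype=nn.DTYPE)
    labels = _validate_labels(labels)
    rng = np.random.default_rng(config.seed)
    n = labels.size
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, train_idx = perm[n - n_val:], perm[: n - n_val]
    if train_idx.size == 0:
        raise ValueError("validation split leaves no training data")
    opt = nn.Adam(lr=config.learning_rate)
    history: dict[str, list[float]] = {k: [] for k in
                                       ("train_loss", "train_acc", "val_loss", "val_acc")}
    for _ in range(config.epochs):
        order = rng.permutation(train_idx.size)
        losses, accs = [], []
        for i in range(0, order.size, config.batch_size):
            batch = train_idx[order[i:i + config.batch_size]]
            loss, acc = model.train_step(X[batch], labels[batch], opt, rng)
            losses.append(loss)
            accs.append(acc)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(float(np.mean(accs)))
        if val_idx.size:
            probs = model.predict_proba(X[val_idx])
            history["val_loss"].append(nn.cross_entropy(probs, labels[val_idx]))
            history["val_acc"].append(float((probs.argmax(axis=1) == labels[val_idx]).mean()))
    return history


def train_section_networks(
    eye_dataset: tuple[np.ndarray, np.ndarray],
    mouth_dataset: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig = TrainingConfig(),
    network_config: FerNetworkConfig = FerNetworkConfig(),
) -> tuple[nn.Sequential, nn.Sequential, dict]:
    """Train network A on eye sections and network B on nose-mouth sections.

    Each dataset is (images, labels) with images (n, 64, 64) in [0, 1] —
    the eye set containing left plus mirrored-right sections so one
    network serves both sides.  Returns (network_a, network_b, histories).
    """
    histories = {}
    nets = []
    for name, (imgs, labs) in (("A", eye_dataset), ("B", mouth_dataset)):
        imgs = np.asarray(imgs, dtype=nn.DTYPE)
        if imgs.ndim == 3:
            imgs = imgs[:, None, :, :]
        cfg = FerNetworkConfig(**{**asdict(network_config), "dropout_rate": config.dropout_rate})
        net = build_section_network(cfg, seed=config.seed + (0 if name == "A" else 1))
        histories[name] = train(net, imgs, labs, config)
        nets.append(net)
    return nets[0], nets[1], histories


def section_outputs(sections: FaceSections, network_a: nn.Sequential, network_b: nn.Sequential) -> list[np.ndarray]:
    """Stage-1 probability vectors for one face, in the canonical order."""
    out = []
    for name in SECTION_ORDER:
        net = network_a if name.startswith("eye") else network_b
        img = getattr(sections, name)[None, None, :, :]
        out.append(net.predict_proba(img)[0])
    return out


def assemble_stage2_input(stage1: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    """Concatenate the four stage-1 vectors into the 40-number stage-2 input."""
    if len(stage1) != 4:
        raise ValueError("stage-2 input is assembled from exactly four vectors")
    vecs = [np.asarray(v, dtype=float).ravel() for v in stage1]
    for v in vecs:
        if v.size != N_EMOTIONS:
            raise ValueError(f"each stage-1 vector must have {N_EMOTIONS} entries, got {v.size}")
    return np.concatenate(vecs)


def train_stage2(
    vectors: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig = TrainingConfig(validation_fraction=0.15),
    network_config: FerNetworkConfig = FerNetworkConfig(),
) -> tuple[nn.Sequential, dict]:
    """Train the 40-input fusion stage on assembled stage-1 vectors."""
    vectors = np.asarray(vectors, dtype=nn.DTYPE)
    if vectors.ndim != 2 or vectors.shape[1] != STAGE2_WIDTH:
        raise ValueError(f"stage-2 training vectors must be (n, {STAGE2_WIDTH})")
    cfg = FerNetworkConfig(**{**asdict(network_config), "dropout_rate": config.dropout_rate})
    net = build_stage2_network(cfg, seed=config.seed + 2)
    history = train(net, vectors, labels, config)
    return net, history


@dataclass
class TwoStageClassifier:
    """The full emotion classifier: two section networks plus the fusion stage."""

    network_a: nn.Sequential
    network_b: nn.Sequential
    stage2: nn.Sequential
    network_config: FerNetworkConfig = field(default_factory=FerNetworkConfig)

    def classify_sections(self, sections: FaceSections) -> np.ndarray:
        """Probability vector over the ten labels for one face."""
        vec = assemble_stage2_input(section_outputs(sections, self.network_a, self.network_b))
        return self.stage2.predict_proba(vec[None, :].astype(nn.DTYPE))[0]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, net in (("network_a", self.network_a), ("network_b", self.network_b),
                          ("stage2", self.stage2)):
            np.savez(directory / f"{name}.npz", *net.state())
        (directory / "config.json").write_text(json.dumps(asdict(self.network_config)))

    @classmethod
    def load(cls, directory) -> "TwoStageClassifier":
        directory = Path(directory)
        cfg_dict = json.loads((directory / "config.json").read_text())
        cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
        cfg_dict["dense_widths"] = tuple(cfg_dict["dense_widths"])
        cfg_dict["stage2_widths"] = tuple(cfg_dict["stage2_widths"])
        cfg = FerNetworkConfig(**cfg_dict)
        nets = {}
        for name, builder in (("network_a", build_section_network),
                              ("network_b", build_section_network),
                              ("stage2", build_stage2_network)):
            net = builder(cfg)
            with np.load(directory / f"{name}.npz") as data:
                net.load_state([data[k] for k in data.files])
            nets[name] = net
        return cls(nets["network_a"], nets["network_b"], nets["stage2"], cfg)


def classify_frame(sections: FaceSections | None, classifier: TwoStageClassifier) -> np.ndarray | None:
    """Emotion probabilities for one preprocessed frame (None if no face)."""
    if sections is None:
        return None
    return classifier.classify_sections(sections)
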