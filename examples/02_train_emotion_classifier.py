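"""Train the two-stage emotion classifier at toy scale.

Builds a 40-image labeled section dataset (oriented gratings standing in
for face sections), trains the two section networks and the 40-input
fusion stage, and prints the training accuracy — a capacity check: a
classifier of adequate capacity should overfit this tiny set.
"""

import numpy as np

from sensefuse.fer import model as fer_model
from sensefuse.synthetic import toy_section_dataset

imgs, labels = toy_section_dataset(n_classes=4, n_per_class=10, seed=1)
print(f"toy dataset: {imgs.shape[0]} images, {len(set(labels.tolist()))} classes")

tc = fer_model.TrainingConfig(epochs=100, batch_size=16, dropout_rate=0.0,
                              validation_fraction=0.2, learning_rate=2e-3, seed=0)
net_a, net_b, hist = fer_model.train_section_networks(
    (imgs, labels), (imgs, labels), tc, fer_model.TOY_NETWORK)
print(f"network A final training accuracy: {hist['A']['train_acc'][-1]:.2f}")

x = imgs[:, None].astype(np.float32)
pa, pb = net_a.predict_proba(x), net_b.predict_proba(x)
vectors = np.concatenate([pa, pa, pb, pb], axis=1)  # the 40-number stage-2 input
tc2 = fer_model.TrainingConfig(epochs=120, batch_size=16, dropout_rate=0.0,
                               validation_fraction=0.15, learning_rate=2e-3, seed=0)
stage2, _ = fer_model.train_stage2(vectors, labels, tc2, fer_model.TOY_NETWORK)

probs = stage2.predict_proba(vectors.astype(np.float32))
acc = (probs.argmax(axis=1) == labels).mean()
print(f"two-stage training accuracy: {acc:.2f} "
      f"(probability rows sum to 1 within {np.abs(probs.sum(axis=1) - 1).max():.1e})")
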