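"""Supervised pretraining of the state-to-action network.

Emits a balanced 4-class feature table at the valence/arousal quadrant
corners (a synthetic stand-in for a public affect dataset, including
inter-subject gain shift), then trains the 152-80-4 tanh/softmax
network as a classifier. The resulting weights seed the speed policy
before reinforcement learning.
"""

import numpy as np

from psa.operator import make_deap_like_dataset
from psa.policy import PolicyParameters, policy_forward, pretrain

rng = np.random.default_rng(0)
X, y = make_deap_like_dataset(50, rng)
print(f"dataset: {X.shape[0]} labeled vectors of dim {X.shape[1]}, "
      f"{np.bincount(y).tolist()} per class")

# min-max normalize exactly as the closed loop does
span = X.max(0) - X.min(0)
Xn = (X - X.min(0)) / np.where(span > 0, span, 1.0)
theta = PolicyParameters.init(rng)
theta, history = pretrain(theta, Xn, y, epochs=500, rng=rng)

acc = np.mean(np.argmax(policy_forward(theta, Xn), axis=1) == y)
print(f"cross-entropy loss: {history[0]:.3f} (epoch 1) -> {history[-1]:.4f} (epoch 500)")
print(f"training accuracy: {acc:.2%} (chance = 25%)")
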