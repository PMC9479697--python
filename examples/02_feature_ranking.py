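"""Rank candidate EEG feature kinds by mutual information with affect labels.

Builds a labeled window set from the four valence/arousal quadrant
states and scores differential entropy (DE), band power (BP) and band
energy (BE) by plug-in MI against the labels. DE's log scale spreads
the heavy-tailed band amplitudes across the histogram bins, so it
carries the most usable mental-state information — it is the feature
the speed-adaptation policy consumes.
"""

import numpy as np

from psa.features import rank_features
from psa.operator import QUADRANTS, OperatorProfile, emit_signals, quadrant_state
from psa.signals import preprocess, slide_windows

rng = np.random.default_rng(0)
profile = OperatorProfile.conservative()
windows, valence, arousal = [], [], []
n_per_quadrant = 30
for v, a in QUADRANTS:
    rec = emit_signals(quadrant_state(v, a), profile, 2.0 + 1.2 * n_per_quadrant, rng)
    eeg, _ = preprocess(rec)
    windows.append(slide_windows(eeg, n_windows=n_per_quadrant).windows)
    valence += [v] * n_per_quadrant
    arousal += [a] * n_per_quadrant

ranking = rank_features(
    np.concatenate(windows),
    {"valence": np.array(valence), "arousal": np.array(arousal)},
    kinds=("DE", "BP", "BE"),
)
print("mean MI (nats) per feature kind, all channels/bands pooled:")
print(ranking.mean_by_kind().round(3).to_string())
print(f"selected EEG feature kind: {ranking.best_kind()}")
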