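"""From raw multimodal signals to the 152-dim mental-state vector.

Emits 60 s of synthetic EEG/EOG from a fatigued operator state, runs the
preprocessing chain (baseline removal, Butterworth band-pass, polyphase
down-sampling), cuts the 50 sliding windows, and extracts one state
vector per window.
"""

import numpy as np

from psa import extract_state_vector, preprocess, slide_windows
from psa.operator import LatentOperatorState, OperatorProfile, emit_signals

rng = np.random.default_rng(0)
state = LatentOperatorState(arousal=0.4, fatigue=0.7)
rec = emit_signals(state, OperatorProfile.conservative(), duration=60.0, rng=rng)
print(f"device recording: {rec.n_channels} channels, {rec.duration:.0f} s @ {rec.fs:.0f} Hz")

eeg, eog = preprocess(rec)
print(f"preprocessed: EEG {eeg.samples.shape} @ {eeg.fs:.0f} Hz, "
      f"EOG {eog.samples.shape} @ {eog.fs:.0f} Hz")

eeg_windows = slide_windows(eeg, window_ms=2000, n_windows=50)
eog_windows = slide_windows(eog, window_ms=2000, n_windows=50)
print(f"windowing: {eeg_windows.n_windows} windows of {eeg_windows.windows.shape[1]} "
      f"samples, stride {eeg_windows.stride_ms:.0f} ms")

fv = extract_state_vector(eeg_windows.windows[0], eog_windows.windows[0])
print(f"state vector: {fv.values.shape[0]} dims "
      f"({150} EEG differential entropies + {2} EOG power ratios)")
print(f"  first EEG channel DE by band (delta..gamma): "
      f"{np.round(fv.values[:5], 2)}")
print(f"  EOG power ratios: {np.round(fv.values[150:], 2)} "
      f"(high at this low arousal: slow eye components dominate)")
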