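"""Synthetic operator: latent mental state, signal generation, control noise.

Stands in for the human in the loop. A latent state (arousal, valence,
fatigue, stress, all in [0, 1]) evolves under task load and timed
stimulation events, and drives three observable surfaces:

* EEG/EOG emission — band-limited noise whose per-channel variances are
  modulated by the latent state. Encoded directional links: fatigue
  lowers broadband EEG variance (hence DE), most strongly over
  occipital/parietal/prefrontal electrodes; stress raises variance over
  the temporal electrodes; low arousal raises the EOG low/high power
  ratio; valence modulates beta-band variance (an invented link that
  makes the four valence/arousal quadrants separable for pretraining).
* control intent — aims along the task guidance vector with Gaussian
  noise whose scale grows with fatigue and with the mismatch between
  the applied and the operator's preferred speed level. This mismatch
  penalty is what makes personalized speed adaptation improve
  operational quality.
* a preferred speed level — higher for aggressive profiles, reduced
  under fatigue/stress — that the adaptation must discover.

Effect sizes are simulator calibration knobs (see the gains below), not
empirical claims; only the directions of the links are grounded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .errors import InvalidInputError
from .features import FeatureVector, extract_state_vector
from .signals import (
    CHANNEL_GROUPS,
    DEVICE_FS,
    EEG_CHANNELS,
    EOG_CHANNELS,
    MultichannelRecording,
    preprocess,
    slide_windows,
)

#: Generation band edges (Hz), dyadically aligned with the wavelet mapping.
GEN_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 45.0),
}
#: Baseline per-band EEG amplitude (µV std) before state modulation.
BASE_BAND_STD: dict[str, float] = {
    "delta": 8.0,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 5.0,
    "gamma": 3.0,
}


@dataclass
class LatentOperatorState:
    """Hidden mental state driving signals and control noise."""

    arousal: float = 0.8
    valence: float = 0.6
    fatigue: float = 0.1
    stress: float = 0.1
    time_on_task: float = 0.0

    def clipped(self) -> "LatentOperatorState":
        return LatentOperatorState(
            float(np.clip(self.arousal, 0, 1)),
            float(np.clip(self.valence, 0, 1)),
            float(np.clip(self.fatigue, 0, 1)),
            float(np.clip(self.stress, 0, 1)),
            max(self.time_on_task, 0.0),
        )


@dataclass
class OperatorProfile:
    """Per-operator style, preference and simulator gains."""

    style: str = "conservative"  # or "aggressive"
    base_level: int = 1  # preferred speed level when fresh
    intent_rate: float = 1.05  # desired path progress per step (units)
    intent_var: float = 0.15  # relative spread of intent magnitude
    base_noise: float = 0.08  # control noise floor (units/step)
    mismatch_gain: float = 1.2  # noise growth per level of mismatch
    fatigue_noise_gain: float = 1.0
    fatigue_rate: float = 0.004  # 1/s saturating fatigue growth
    rest_recovery: float = 0.5  # fractional fatigue drop per rest event
    stress_jump: float = 0.4
    stress_half_life: float = 30.0  # s
    valence_step: float = 0.2
    arousal_base: float = 0.9
    round_start_fatigue: float = 0.12  # between-round micro-rest baseline
    fatigue_gains: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in ("aggressive", "conservative"):
            raise InvalidInputError(f"unknown style {self.style!r}")

    @classmethod
    def aggressive(cls, seed: int = 0) -> "OperatorProfile":
        return cls(
            style="aggressive",
            base_level=3,
            intent_rate=1.15,
            intent_var=0.45,
            base_noise=0.09,
            seed=seed,
        )

    @classmethod
    def conservative(cls, seed: int = 0) -> "OperatorProfile":
        return cls(style="conservative", base_level=1, seed=seed)

    def preferred_level(self, state: LatentOperatorState) -> int:
        """Speed level the operator is comfortable with right now."""
        level = self.base_level
        if state.fatigue > 0.6:
            level -= 1
        if state.stress > 0.7:
            level -= 1
        return int(np.clip(level, 0, 3))

    def noise_scale(self, state: LatentOperatorState, mismatch: int) -> float:
        """Control-noise std; strictly increasing in |applied - preferred|."""
        return (
            self.base_noise
            * (1.0 + self.fatigue_noise_gain * state.fatigue)
            * (1.0 + self.mismatch_gain * abs(mismatch))
        )

    def to_yaml(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as f:
            yaml.safe_dump(d, f)

    @classmethod
    def from_yaml(cls, path) -> "OperatorProfile":
        with open(path) as f:
            return cls(**yaml.safe_load(f))


def step_latent(
    state: LatentOperatorState,
    profile: OperatorProfile,
    events: tuple[str, ...] = (),
    dt: float = 2.0,
    rng: np.random.Generator | None = None,
) -> LatentOperatorState:
    """First-order latent update with saturating growth and event jumps.

    Fatigue grows toward 1 with time on task and drops on rest events;
    stress jumps on "nervous" events and decays exponentially; valence
    jumps up/down on positive/negative prompts and mean-reverts;
    arousal declines with fatigue around the profile's baseline.
    """
    if dt <= 0:
        raise InvalidInputError(f"dt must be positive, got {dt}")
    f = state.fatigue + (1.0 - state.fatigue) * profile.fatigue_rate * dt
    s = state.stress * float(np.exp(-np.log(2.0) * dt / profile.stress_half_life))
    v = state.valence + 0.02 * (0.5 - state.valence) * dt
    for ev in events:
        if ev == "rest":
            f *= 1.0 - profile.rest_recovery
        elif ev == "nervous":
            s = min(1.0, s + profile.stress_jump)
        elif ev == "positive":
            v += profile.valence_step
        elif ev == "negative":
            v -= profile.valence_step
    noise = 0.0 if rng is None else float(rng.uniform(-0.02, 0.02))
    a = profile.arousal_base - 0.7 * f + noise
    return LatentOperatorState(a, v, f, s, state.time_on_task + dt).clipped()


def _accumulate_band(
    spec: np.ndarray,
    rng: np.random.Generator,
    mask: np.ndarray,
    n: int,
    scale: np.ndarray | float,
) -> None:
    """Add band-limited Gaussian noise of target std into a spectrum.

    Complex Gaussian coefficients on the band's frequency bins; the
    time-domain variance of each column is known exactly from Parseval
    ((2/n^2) * sum |Z_k|^2 for interior bins), so the band is pinned to
    its target standard deviation without an extra inverse FFT.
    """
    nb = int(mask.sum())
    n_ch = spec.shape[1]
    Z = rng.standard_normal((nb, n_ch)) + 1j * rng.standard_normal((nb, n_ch))
    var = 2.0 * np.sum(np.abs(Z) ** 2, axis=0) / n**2
    spec[mask] += Z * (np.asarray(scale) / np.maximum(np.sqrt(var), 1e-15))


def _band_noise(
    rng: np.random.Generator,
    n: int,
    n_ch: int,
    lo: float,
    hi: float,
    fs: float,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi) Hz."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros((f.size, n_ch), dtype=complex)
    _accumulate_band(spec, rng, (f >= lo) & (f < hi), n, 1.0)
    return np.fft.irfft(spec, n=n, axis=0)


def _channel_band_std(state: LatentOperatorState) -> np.ndarray:
    """Target std per (band, EEG channel) under the latent modulation."""
    n_ch = len(EEG_CHANNELS)
    grouped = np.zeros(n_ch, dtype=bool)  # fatigue-sensitive group
    temporal = np.zeros(n_ch, dtype=bool)
    for i, ch in enumerate(EEG_CHANNELS):
        if ch in CHANNEL_GROUPS["occipital"] or ch in CHANNEL_GROUPS["parietal"] \
                or ch in CHANNEL_GROUPS["prefrontal"]:
            grouped[i] = True
        if ch in CHANNEL_GROUPS["temporal"]:
            temporal[i] = True
    fatigue_factor = (1.0 - 0.45 * state.fatigue) * np.where(
        grouped, 1.0 - 0.30 * state.fatigue, 1.0
    )
    stress_factor = np.where(temporal, 1.0 + 0.8 * state.stress, 1.0)
    out = np.empty((len(GEN_BANDS), n_ch))
    for b, band in enumerate(GEN_BANDS):
        base = BASE_BAND_STD[band]
        valence_factor = (
            1.0 + 0.6 * (state.valence - 0.5) if band == "beta" else 1.0
        )
        out[b] = base * fatigue_factor * stress_factor * valence_factor
    return out


def emit_signals(
    state: LatentOperatorState,
    profile: OperatorProfile,
    duration: float,
    rng: np.random.Generator,
    fs: float = DEVICE_FS,
) -> MultichannelRecording:
    """Emit a 30-EEG + 2-EOG recording at the device rate.

    Each EEG channel is a sum of five band-limited noise processes whose
    standard deviations carry the latent-state modulation; each EOG
    channel is a low-frequency component (power grows as arousal falls)
    plus a fixed high-frequency component. Column-wise renormalization
    pins the realized band variances to their targets, so the encoded
    monotone links survive the downstream feature pipeline.
    """
    if duration < 2.0:
        raise InvalidInputError(f"duration must be >= 2 s, got {duration}")
    n = int(round(duration * fs))
    n_ch = len(EEG_CHANNELS)
    stds = _channel_band_std(state)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros((f.size, n_ch), dtype=complex)
    for b, (band, (lo, hi)) in enumerate(GEN_BANDS.items()):
        _accumulate_band(spec, rng, (f >= lo) & (f < hi), n, stds[b])
    eeg = np.fft.irfft(spec, n=n, axis=0)

    lo_std = 12.0 * (1.0 + 3.0 * (1.0 - state.arousal))
    hi_std = 8.0
    espec = np.zeros((f.size, 2), dtype=complex)
    _accumulate_band(espec, rng, (f >= 0.1) & (f < 1.5), n, lo_std)
    _accumulate_band(espec, rng, (f >= 1.5) & (f < 30.0), n, hi_std)
    eog = np.fft.irfft(espec, n=n, axis=0)

    return MultichannelRecording(
        np.hstack([eeg, eog]),
        fs,
        EEG_CHANNELS + EOG_CHANNELS,
        ("EEG",) * n_ch + ("EOG",) * len(EOG_CHANNELS),
    )


def control_intent(
    state: LatentOperatorState,
    profile: OperatorProfile,
    env,
    applied_level: int,
    rng: np.random.Generator,
):
    """Operator's 2-D displacement intent for one control step.

    Aims along the environment's guidance vector at a rate that partly
    compensates the applied speed multiplier (progress still grows with
    the multiplier as sqrt(m)), with additive Gaussian noise scaled by
    fatigue and the applied-vs-preferred level mismatch.
    """
    from .policy import DEFAULT_MULTIPLIERS
    from .tasks import ControlCommand

    direction = env.guidance()
    m = DEFAULT_MULTIPLIERS[int(applied_level)]
    # partial gain compensation: both aim and tremor shrink as the control
    # gain rises, so realized progress and noise grow like sqrt(m)
    mag = profile.intent_rate / np.sqrt(m)
    mag *= max(0.1, 1.0 + profile.intent_var * float(rng.standard_normal()))
    mismatch = int(applied_level) - profile.preferred_level(state)
    sd = profile.noise_scale(state, mismatch) / np.sqrt(m)
    intent = direction * mag + rng.normal(0.0, sd, size=2)
    return ControlCommand(float(intent[0]), float(intent[1]))


class SyntheticOperator:
    """Stateful wrapper binding a profile to seeded random substreams."""

    def __init__(self, profile: OperatorProfile, seed: int | None = None) -> None:
        self.profile = profile
        seed = profile.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        s_signal, s_control, s_latent = ss.spawn(3)
        self.signal_rng = np.random.default_rng(s_signal)
        self.control_rng = np.random.default_rng(s_control)
        self.latent_rng = np.random.default_rng(s_latent)
        self.state = LatentOperatorState(arousal=profile.arousal_base)

    def reset_round(self) -> None:
        """Start-of-round re-baseline (a between-round micro-rest).

        Fatigue returns to the profile's round-start baseline, stress
        and valence revert most of the way toward neutral, so rounds
        start from a stationary latent state: within-round dynamics
        (fatigue growth, event responses) carry all the variation.
        """
        self.state = replace(
            self.state,
            fatigue=self.profile.round_start_fatigue,
            stress=self.state.stress * 0.3,
            valence=0.5 + (self.state.valence - 0.5) * 0.3,
        ).clipped()

    def step(self, events: tuple[str, ...] = (), dt: float = 2.0) -> None:
        self.state = step_latent(
            self.state, self.profile, events, dt, rng=self.latent_rng
        )

    def emit_window(self, duration: float = 2.0) -> MultichannelRecording:
        return emit_signals(self.state, self.profile, duration, self.signal_rng)

    def intent(self, env, applied_level: int):
        return control_intent(
            self.state, self.profile, env, applied_level, self.control_rng
        )

    def preferred_level(self) -> int:
        return self.profile.preferred_level(self.state)


def default_cohort(seed: int = 0) -> list[OperatorProfile]:
    """The six-operator simulated cohort: 2 aggressive, 4 conservative.

    Preferred speed levels vary across the conservative operators
    (individual differences); one of them prefers the unadjusted speed,
    so a fixed non-personalized strategy matches exactly one cohort
    member.
    """
    profiles = [
        OperatorProfile.aggressive(seed=seed + 1),
        OperatorProfile.aggressive(seed=seed + 2),
        OperatorProfile.conservative(seed=seed + 3),
        OperatorProfile.conservative(seed=seed + 4),
        OperatorProfile.conservative(seed=seed + 5),
        OperatorProfile.conservative(seed=seed + 6),
    ]
    for p, base in zip(profiles[2:], (2, 2, 2, 1)):
        p.base_level = base
    return profiles


#: (valence, arousal) corner per pretraining class, in the conventional
#: DEAP quadrant enumeration: HVHA=0, HVLA=1, LVHA=2, LVLA=3. The class
#: index maps directly onto the action index; no quadrant-to-speed
#: semantics is assumed — discovering the individually right mapping is
#: the reinforcement phase's job.
QUADRANTS: tuple[tuple[float, float], ...] = (
    (0.85, 0.85),
    (0.85, 0.15),
    (0.15, 0.85),
    (0.15, 0.15),
)


def quadrant_state(valence: float, arousal: float) -> LatentOperatorState:
    """Latent state at a valence/arousal corner (fatigue/stress implied)."""
    return LatentOperatorState(
        arousal=arousal,
        valence=valence,
        fatigue=0.8 * (1.0 - arousal),
        stress=0.4 * (1.0 - valence),
    )


def make_deap_like_dataset(
    n_per_class: int,
    rng: np.random.Generator,
    profile: OperatorProfile | None = None,
    eeg_feature_kind: str = "DE",
    subject_shift: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced 4-class labeled feature set emulating a DEAP-style table.

    Signals are emitted at the four valence/arousal corner states, run
    through the real preprocessing (band-pass, down-sample) and the
    sliding-window + feature pipeline, then labeled by corner. Returns
    (X, y) with X of shape (4*n_per_class, 152).

    ``subject_shift`` applies a fixed per-channel log-normal gain jitter
    to the emitted signals, emulating the inter-subject domain shift of
    a public affect dataset relative to the operator at hand: a network
    pre-trained on this set is an informative but imperfect prior.
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    profile = profile or OperatorProfile.conservative()
    X: list[np.ndarray] = []
    y: list[int] = []
    duration = max(4.0, 2.0 + 1.2 * n_per_class)
    n_ch = len(EEG_CHANNELS) + len(EOG_CHANNELS)
    gains = np.exp(rng.normal(0.0, subject_shift, size=n_ch))
    for cls, (valence, arousal) in enumerate(QUADRANTS):
        state = quadrant_state(valence, arousal)
        rec = emit_signals(state, profile, duration, rng)
        rec = MultichannelRecording(
            rec.samples * gains, rec.fs, rec.channel_labels, rec.modality
        )
        eeg, eog = preprocess(rec)
        eeg_w = slide_windows(eeg, n_windows=n_per_class)
        eog_w = slide_windows(eog, n_windows=n_per_class)
        for w in range(n_per_class):
            fv: FeatureVector = extract_state_vector(
                eeg_w.windows[w], eog_w.windows[w], eeg_feature_kind
            )
            X.append(fv.values)
            y.append(cls)
    return np.asarray(X), np.asarray(y)
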