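"""Multichannel EEG/EOG recordings and the preprocessing pipeline.

The device model is a 32-channel cap: 30 EEG electrodes in the
international 10-20 layout plus 2 EOG electrodes, sampled at 1000 Hz.
Preprocessing runs three steps per channel — least-squares baseline
removal, 4th-order Butterworth band-pass (0.5-45 Hz for EEG, 0.1-30 Hz
for EOG), and polyphase down-sampling (EEG to 256 Hz, EOG to 128 Hz) —
followed by sliding-window sampling (2000 ms windows, 50 per minute).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

#: 10-20 montage order used throughout the package (fixed ordering contract).
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4", "O1", "O2",
)
EOG_CHANNELS: tuple[str, ...] = ("HEOG", "VEOG")

#: Channel groups by 10-20 label prefix, used by the synthetic operator to
#: localize fatigue (occipital/parietal/prefrontal) and stress (temporal).
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "occipital": tuple(c for c in EEG_CHANNELS if c.startswith("O")),
    "parietal": tuple(c for c in EEG_CHANNELS if c.startswith("P")),
    "prefrontal": tuple(c for c in EEG_CHANNELS if c.startswith("Fp")),
    "temporal": tuple(c for c in EEG_CHANNELS if c.startswith("T")),
}

DEVICE_FS = 1000.0
EEG_BANDPASS = (0.5, 45.0)
EOG_BANDPASS = (0.1, 30.0)
EEG_FS_OUT = 256.0
EOG_FS_OUT = 128.0
WINDOW_MS = 2000.0
WINDOWS_PER_MINUTE = 50


@dataclass
class MultichannelRecording:
    """Time-major amplitude matrix (µV) with channel metadata.

    ``samples`` has shape ``(n_samples, n_channels)``; ``modality`` tags
    each channel as ``"EEG"`` or ``"EOG"`` so the two streams can be
    separated for their different filter bands and target rates.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    modality: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidInputError("samples must be 2-D (n_samples, n_channels)")
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        self.channel_labels = tuple(self.channel_labels)
        self.modality = tuple(self.modality)
        n = self.samples.shape[1]
        if len(self.channel_labels) != n or len(self.modality) != n:
            raise InvalidInputError(
                f"{n} channels but {len(self.channel_labels)} labels / "
                f"{len(self.modality)} modality tags"
            )
        bad = set(self.modality) - {"EEG", "EOG"}
        if bad:
            raise InvalidInputError(f"unknown modality tags: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def select(self, modality: str) -> "MultichannelRecording":
        """Sub-recording of all channels with the given modality tag."""
        idx = [i for i, m in enumerate(self.modality) if m == modality]
        if not idx:
            raise InvalidInputError(f"no channels with modality {modality!r}")
        return MultichannelRecording(
            self.samples[:, idx],
            self.fs,
            tuple(self.channel_labels[i] for i in idx),
            tuple(self.modality[i] for i in idx),
        )


@dataclass
class WindowBatch:
    """Fixed-length windows cut from one recording.

    ``windows`` has shape ``(n_windows, window_samples, n_channels)``;
    start times are strictly increasing and every window has the same
    sample count ``round(window_ms * fs / 1000)``.
    """

    windows: np.ndarray
    window_ms: float
    stride_ms: float
    source_fs: float
    channel_labels: tuple[str, ...] = field(default_factory=tuple)
    modality: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@lru_cache(maxsize=32)
def _butter_cached(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=16)
def _trend_basis(n: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    V = np.vander(np.arange(n, dtype=float), degree + 1)
    return V, np.linalg.pinv(V)


@lru_cache(maxsize=16)
def _resample_fir(up: int, down: int) -> np.ndarray:
    # mirror of scipy's default resample_poly kaiser design, cached
    max_rate = max(up, down)
    half_len = 10 * max_rate
    return sps.firwin(2 * half_len + 1, 1.0 / max_rate, window=("kaiser", 5.0))


def detrend_baseline(x: np.ndarray, degree: int = 1) -> np.ndarray:
    """Remove the least-squares polynomial trend (baseline drift).

    Default is a linear (degree-1) trend; the degree is configurable.
    Works on a 1-D series or a time-major 2-D array (per column).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise InvalidInputError(f"need at least 2 samples to detrend, got {n}")
    V, P = _trend_basis(n, degree)
    return x - V @ (P @ x)


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass filter.

    Zero-phase (forward-backward) by default, which doubles the effective
    order of the magnitude response but removes group delay; set
    ``zero_phase=False`` for a causal single pass (online mode).
    """
    x = np.asarray(x, dtype=float)
    if not (0 < low < high < fs / 2):
        raise InvalidParameterError(
            f"band edges must satisfy 0 < low < high < fs/2; got "
            f"low={low}, high={high}, fs={fs}"
        )
    if order < 1:
        raise InvalidParameterError(f"order must be >= 1, got {order}")
    sos = _butter_cached(order, float(low), float(high), float(fs))
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling from ``fs_in`` to ``fs_out``.

    The caller is expected to have band-limited the signal below
    ``fs_out / 2`` already (the preceding band-pass does this); the
    polyphase filter provides the remaining anti-aliasing.
    """
    x = np.asarray(x, dtype=float)
    if fs_out >= fs_in:
        raise InvalidParameterError(
            f"fs_out must be < fs_in, got {fs_out} >= {fs_in}"
        )
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    return sps.resample_poly(x, up, down, axis=0, window=_resample_fir(up, down))


def slide_windows(
    recording: MultichannelRecording,
    window_ms: float = WINDOW_MS,
    n_windows: int = WINDOWS_PER_MINUTE,
) -> WindowBatch:
    """Cut ``n_windows`` uniformly spaced windows from a recording.

    The stride is ``floor((L - W) / (n_windows - 1))`` samples so the
    windows tile the buffer uniformly (about 1183 ms hop for a 60 s
    buffer at 256 Hz with 50 windows of 2000 ms); the last window ends
    at or before the end of the recording.
    """
    if n_windows < 1:
        raise InvalidParameterError(f"n_windows must be >= 1, got {n_windows}")
    fs = recording.fs
    W = int(round(window_ms * fs / 1000.0))
    L = recording.n_samples
    if L < W:
        raise InsufficientDataError(
            f"recording of {L} samples shorter than window of {W} samples"
        )
    if n_windows == 1:
        stride = 0
        starts = [0]
    else:
        stride = (L - W) // (n_windows - 1)
        if stride < 1:
            raise InsufficientDataError(
                f"{L} samples cannot host {n_windows} distinct windows of {W}"
            )
        starts = [i * stride for i in range(n_windows)]
    windows = np.stack([recording.samples[s : s + W] for s in starts])
    return WindowBatch(
        windows=windows,
        window_ms=window_ms,
        stride_ms=stride / fs * 1000.0,
        source_fs=fs,
        channel_labels=recording.channel_labels,
        modality=recording.modality,
    )


def preprocess(
    recording: MultichannelRecording,
    detrend_degree: int = 1,
    zero_phase: bool = True,
) -> tuple[MultichannelRecording, MultichannelRecording]:
    """Run the three preprocessing steps; returns (EEG @256 Hz, EOG @128 Hz).

    Order: detrend -> band-pass -> down-sample, applied separately to the
    EEG channels (0.5-45 Hz, 256 Hz) and EOG channels (0.1-30 Hz, 128 Hz).
    """
    out = []
    for modality, band, fs_out in (
        ("EEG", EEG_BANDPASS, EEG_FS_OUT),
        ("EOG", EOG_BANDPASS, EOG_FS_OUT),
    ):
        sub = recording.select(modality)
        x = detrend_baseline(sub.samples, degree=detrend_degree)
        x = bandpass(x, sub.fs, *band, zero_phase=zero_phase)
        x = downsample(x, sub.fs, fs_out)
        out.append(
            MultichannelRecording(x, fs_out, sub.channel_labels, sub.modality)
        )
    return out[0], out[1]
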