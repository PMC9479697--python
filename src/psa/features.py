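"""Mental-state feature extraction from preprocessed EEG/EOG windows.

EEG windows (256 Hz) are decomposed into the five rhythm bands
(delta 0.5-4, theta 4-8, alpha 8-16, beta 16-32, gamma >32 Hz in the
dyadic approximation) by a 5-level Daubechies-5 wavelet decomposition
with per-level reconstruction. Four candidate per-band features are
implemented — sample entropy (SE), differential entropy (DE), band
power (BP) and band energy (BE) — together with a plug-in mutual
information ranking of the candidates against arousal/valence labels.
EOG windows (128 Hz) yield the low/high frequency power ratio (PR),
which rises as arousal falls.

The state vector consumed by the policy is 152-dimensional: 30 EEG
channels x 5 bands of the selected EEG feature (DE by default, the
top-ranked kind), followed by one PR per EOG channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .errors import (
    DegenerateInputError,
    DegenerateLabelsError,
    InvalidInputError,
    SchemaError,
)
from .signals import EEG_CHANNELS, EOG_CHANNELS

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
FEATURE_KINDS: tuple[str, ...] = ("SE", "DE", "BP", "BE")
STATE_DIM = len(EEG_CHANNELS) * len(BAND_ORDER) + len(EOG_CHANNELS)  # 152

WAVELET = "db5"
DECOMP_LEVEL = 5

#: Saturation cap for the EOG power ratio when the high band is empty.
PR_CAP = 1e12


# ------------------------------------------------------------ rhythm bands

def wavelet_rhythms(window: np.ndarray) -> dict[str, np.ndarray]:
    """Split a 256 Hz window into the five rhythm-band series.

    5-level db5 decomposition; per-level reconstruction maps
    A5 (0-4 Hz) -> delta, D5 (4-8) -> theta, D4 (8-16) -> alpha,
    D3 (16-32) -> beta, and D2+D1 (>32 Hz) -> gamma. The five band
    series sum back to the window exactly (perfect reconstruction).

    Accepts a 1-D series or a time-major 2-D array (shared decomposition
    across columns).
    """
    window = np.asarray(window, dtype=float)
    if window.shape[0] < 2**DECOMP_LEVEL:
        raise InvalidInputError(
            f"window of {window.shape[0]} samples too short for "
            f"{DECOMP_LEVEL}-level decomposition (need >= {2**DECOMP_LEVEL})"
        )
    coeffs = pywt.wavedec(window, WAVELET, level=DECOMP_LEVEL, axis=0)
    # coeffs = [A5, D5, D4, D3, D2, D1]
    def recon(keep: int) -> np.ndarray:
        parts = [c if i == keep else np.zeros_like(c) for i, c in enumerate(coeffs)]
        r = pywt.waverec(parts, WAVELET, axis=0)
        return r[: window.shape[0]]

    bands = {
        "delta": recon(0),
        "theta": recon(1),
        "alpha": recon(2),
        "beta": recon(3),
    }
    # gamma (D2 + D1, >32 Hz) by subtraction: the five bands then sum back
    # to the window exactly (perfect reconstruction by construction)
    bands["gamma"] = window - sum(bands.values())
    return bands


# ------------------------------------------------------------ entropies

def sample_entropy(
    x: np.ndarray, v: int = 2, eta: float | None = None
) -> float:
    """Sample entropy -ln(B^{v+1} / B^v) of a series.

    Template matching uses Chebyshev distance with self-matches
    excluded (Richman-Moorman convention). Defaults follow the standard
    choice v = 2, eta = 0.2 * std(x). Returns ``inf`` (saturated) when
    no template pair matches at length v+1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= v + 1:
        raise InvalidInputError(f"series of length {n} too short for v={v}")
    if eta is None:
        sd = float(np.std(x))
        if sd == 0.0:
            raise DegenerateInputError(
                "zero-variance series with relative tolerance"
            )
        eta = 0.2 * sd

    def count_matches(m: int) -> int:
        # templates x[i:i+m], i = 0..n-m-1 (same count for m and m+1)
        nt = n - v  # common template count so the ratio is a probability
        idx = np.arange(nt)[:, None] + np.arange(m)[None, :]
        T = x[idx]  # (nt, m)
        d = np.max(np.abs(T[:, None, :] - T[None, :, :]), axis=2)
        within = d <= eta
        np.fill_diagonal(within, False)
        return int(within.sum()) // 2

    b_v = count_matches(v)
    b_v1 = count_matches(v + 1)
    if b_v == 0 or b_v1 == 0:
        return float("inf")
    return float(-np.log(b_v1 / b_v))


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian differential entropy 0.5*ln(2*pi*e*sigma^2) of a series.

    sigma^2 is the mean squared deviation from the sample mean. For a
    band-limited EEG segment this is the closed-form entropy under the
    Gaussian approximation; it grows by ln(c) when the series is scaled
    by c and is invariant to shifts.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples")
    sigma2 = float(np.mean((x - x.mean()) ** 2))
    if sigma2 <= 0.0:
        raise DegenerateInputError("zero variance: differential entropy undefined")
    return 0.5 * np.log(2.0 * np.pi * np.e * sigma2)


def band_power(x: np.ndarray) -> float:
    """Mean of squared samples of a band-reconstructed series."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty series")
    return float(np.mean(x**2))


def band_energy(x: np.ndarray) -> float:
    """Sum of squared samples; equals band_power * len(x)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty series")
    return float(np.sum(x**2))


# ------------------------------------------------------------ mutual information

def discretize(x: np.ndarray, n_bins: int = 8, strategy: str = "width") -> np.ndarray:
    """Bin a continuous series into integer codes.

    Default is equal-width bins over the observed range. Equal-width
    binning is deliberately scale-sensitive: a monotone transform of a
    feature (e.g. log-compressing band power into differential entropy)
    changes the partition and hence the plug-in MI, which is what makes
    the feature-kind ranking informative. ``strategy="frequency"``
    selects equal-frequency (quantile) bins instead, which are
    invariant to monotone transforms.
    """
    x = np.asarray(x, dtype=float)
    if strategy == "width":
        lo, hi = x.min(), x.max()
        if hi <= lo:
            return np.zeros(x.shape, dtype=int)
        edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    elif strategy == "frequency":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    else:
        raise InvalidInputError(f"unknown binning strategy {strategy!r}")
    return np.digitize(x, edges)


def mutual_information(
    xf: np.ndarray, yl: np.ndarray, n_bins: int = 8, discretize_x: bool = True
) -> float:
    """Plug-in mutual information (nats) of a feature against labels.

    Continuous features are binned into ``n_bins`` equal-width bins;
    labels are taken as discrete. MI is the double sum of
    p(x,y) * ln(p(x,y) / (p(x) p(y))) over the empirical joint table.
    """
    xf = np.asarray(xf)
    yl = np.asarray(yl)
    if xf.shape[0] != yl.shape[0]:
        raise InvalidInputError(
            f"length mismatch: {xf.shape[0]} features vs {yl.shape[0]} labels"
        )
    if xf.shape[0] < 2:
        raise InvalidInputError("need at least 2 observations")
    xc = discretize(xf, n_bins) if discretize_x else xf
    _, xi = np.unique(xc, return_inverse=True)
    _, yi = np.unique(yl, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


# ------------------------------------------------------------ EOG power ratio

def eog_power_ratio(
    x: np.ndarray,
    fs: float = 128.0,
    split_hz: float = 1.5,
    high_hz: float = 30.0,
    eps: float = 1e-12,
) -> float:
    """Low/high frequency power ratio PR of an EOG window.

    Welch PSD with 2 s Hann segments (clipped to the window length) at
    50% overlap — the segment must be at least 2 s for the estimator to
    resolve the 0-1.5 Hz low band at all. PR is the integrated power
    over (0, 1.5] Hz divided by that over (1.5, 30] Hz. A vanishing
    high band yields the saturation cap rather than a division error.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < int(fs):
        raise InvalidInputError(
            f"EOG window of {x.shape[0]} samples shorter than 1 s ({int(fs)})"
        )
    nperseg = min(int(2 * fs), x.shape[0])
    f, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    low = np.trapezoid(pxx[f <= split_hz], f[f <= split_hz])
    band = (f > split_hz) & (f <= high_hz)
    high = np.trapezoid(pxx[band], f[band])
    return float(min(low / max(high, eps), PR_CAP))


# ------------------------------------------------------------ state vector

@dataclass
class FeatureVector:
    """The 152-dim mental-state vector s_i consumed by the policy.

    Ordering contract: EEG channels in montage order, bands in
    delta/theta/alpha/beta/gamma order (channel-major), then the two
    EOG PR values.
    """

    values: np.ndarray
    eeg_feature_kind: str = "DE"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (STATE_DIM,):
            raise SchemaError(
                f"feature vector must have length {STATE_DIM}, got {self.values.shape}"
            )


_KIND_FN = {
    "SE": sample_entropy,
    "DE": differential_entropy,
    "BP": band_power,
    "BE": band_energy,
}


def assemble_features(
    rhythms: dict[str, dict[str, np.ndarray]],
    eog_windows: dict[str, np.ndarray],
    eeg_feature_kind: str = "DE",
    eog_fs: float = 128.0,
) -> FeatureVector:
    """Build the raw 152-dim state vector from per-channel band series.

    ``rhythms`` maps EEG channel label -> band name -> series; the 30
    montage channels with all 5 bands must be present. ``eog_windows``
    maps each EOG channel label to its 128 Hz window.
    """
    if eeg_feature_kind not in _KIND_FN:
        raise SchemaError(f"unknown EEG feature kind {eeg_feature_kind!r}")
    fn = _KIND_FN[eeg_feature_kind]
    values = np.empty(STATE_DIM)
    i = 0
    for ch in EEG_CHANNELS:
        if ch not in rhythms:
            raise SchemaError(f"missing EEG channel {ch!r}")
        for band in BAND_ORDER:
            if band not in rhythms[ch]:
                raise SchemaError(f"missing band {band!r} for channel {ch!r}")
            values[i] = fn(rhythms[ch][band])
            i += 1
    for ch in EOG_CHANNELS:
        if ch not in eog_windows:
            raise SchemaError(f"missing EOG channel {ch!r}")
        values[i] = eog_power_ratio(eog_windows[ch], fs=eog_fs)
        i += 1
    return FeatureVector(values, eeg_feature_kind=eeg_feature_kind)


def extract_state_vector(
    eeg_window: np.ndarray,
    eog_window: np.ndarray,
    eeg_feature_kind: str = "DE",
    eog_fs: float = 128.0,
) -> FeatureVector:
    """Raw state vector from one EEG window (n, 30) and EOG window (m, 2).

    Equivalent to :func:`assemble_features` on the per-channel band
    series; the default DE path is vectorized across channels/bands for
    the closed-loop hot path.
    """
    bands = wavelet_rhythms(eeg_window)  # each (n, 30)
    if eeg_feature_kind == "DE":
        values = np.empty(STATE_DIM)
        stacked = np.stack([bands[b] for b in BAND_ORDER])  # (5, n, 30)
        var = np.var(stacked, axis=1)  # (5, 30)
        if np.any(var <= 0):
            raise DegenerateInputError("zero-variance band series")
        # channel-major ordering: (30, 5) flattened
        values[: 5 * len(EEG_CHANNELS)] = (
            0.5 * np.log(2.0 * np.pi * np.e * var.T)
        ).ravel()
        for j, _ in enumerate(EOG_CHANNELS):
            values[150 + j] = eog_power_ratio(eog_window[:, j], fs=eog_fs)
        return FeatureVector(values, eeg_feature_kind="DE")
    rhythms = {
        ch: {b: bands[b][:, j] for b in BAND_ORDER}
        for j, ch in enumerate(EEG_CHANNELS)
    }
    eog = {ch: eog_window[:, j] for j, ch in enumerate(EOG_CHANNELS)}
    return assemble_features(rhythms, eog, eeg_feature_kind, eog_fs=eog_fs)


class FeatureNormalizer:
    """Per-dimension running min-max normalization to [0, 1].

    Statistics accumulate during the training session (practice rounds
    included) and are frozen before testing/control so all sessions see
    an identical mapping. Unseen values outside the frozen range clip
    to [0, 1]; a dimension with zero observed range maps to 0.5.
    """

    def __init__(self, dim: int = STATE_DIM) -> None:
        self.lo = np.full(dim, np.inf)
        self.hi = np.full(dim, -np.inf)
        self.frozen = False

    def update(self, vec: FeatureVector | np.ndarray) -> None:
        if self.frozen:
            raise InvalidInputError("normalizer is frozen")
        v = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec)
        np.minimum(self.lo, v, out=self.lo)
        np.maximum(self.hi, v, out=self.hi)

    def freeze(self) -> None:
        self.frozen = True

    def transform(self, vec: FeatureVector) -> FeatureVector:
        span = self.hi - self.lo
        ok = np.isfinite(span) & (span > 0)
        out = np.full_like(vec.values, 0.5)
        out[ok] = np.clip((vec.values[ok] - self.lo[ok]) / span[ok], 0.0, 1.0)
        return FeatureVector(out, vec.eeg_feature_kind, normalized=True)


# ------------------------------------------------------------ feature ranking

@dataclass
class FeatureRanking:
    """MI of every (kind, channel, band) feature against each label axis."""

    table: pd.DataFrame = field(repr=False)

    def mean_by_kind(self, label_dim: str | None = None) -> pd.Series:
        t = self.table
        if label_dim is not None:
            t = t[t["label_dim"] == label_dim]
        return t.groupby("kind")["mi"].mean().sort_values(ascending=False)

    def best_kind(self) -> str:
        return str(self.mean_by_kind().index[0])


def rank_features(
    eeg_windows: np.ndarray,
    labels: dict[str, np.ndarray],
    kinds: tuple[str, ...] = FEATURE_KINDS,
    channels: tuple[str, ...] = EEG_CHANNELS,
    n_bins: int = 8,
) -> FeatureRanking:
    """Rank candidate EEG feature kinds by mutual information with labels.

    ``eeg_windows`` has shape (n_windows, n_samples, n_channels) at
    256 Hz; ``labels`` maps a label axis name (e.g. "valence",
    "arousal") to a discrete label per window. Continuous label vectors
    are binarized at their midpoint (high/low split).
    """
    n_windows = eeg_windows.shape[0]
    disc_labels = {}
    for name, y in labels.items():
        y = np.asarray(y)
        if y.shape[0] != n_windows:
            raise InvalidInputError(
                f"label {name!r} has {y.shape[0]} entries for {n_windows} windows"
            )
        if np.issubdtype(y.dtype, np.floating):
            y = (y > (y.min() + y.max()) / 2).astype(int)
        if np.unique(y).size < 2:
            raise DegenerateLabelsError(f"label {name!r} has a single class")
        disc_labels[name] = y

    # band series for all windows/channels in one pass per window
    feats: dict[tuple[str, str, str], np.ndarray] = {}
    per_band = [wavelet_rhythms(eeg_windows[w]) for w in range(n_windows)]
    for kind in kinds:
        fn = _KIND_FN[kind]
        for j, ch in enumerate(channels):
            cj = list(EEG_CHANNELS).index(ch)
            for band in BAND_ORDER:
                vals = np.array(
                    [fn(per_band[w][band][:, cj]) for w in range(n_windows)]
                )
                feats[(kind, ch, band)] = vals

    rows = []
    for (kind, ch, band), vals in feats.items():
        finite = np.isfinite(vals)
        for name, y in disc_labels.items():
            mi = mutual_information(vals[finite], y[finite], n_bins=n_bins)
            rows.append(
                {"kind": kind, "channel": ch, "band": band, "label_dim": name, "mi": mi}
            )
    return FeatureRanking(pd.DataFrame(rows))
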