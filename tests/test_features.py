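"""Feature extractors against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psa.errors import (
    DegenerateInputError,
    DegenerateLabelsError,
    InvalidInputError,
    SchemaError,
)
from psa.features import (
    BAND_ORDER,
    STATE_DIM,
    FeatureNormalizer,
    assemble_features,
    band_energy,
    band_power,
    differential_entropy,
    discretize,
    eog_power_ratio,
    extract_state_vector,
    mutual_information,
    rank_features,
    sample_entropy,
    wavelet_rhythms,
)
from psa.signals import EEG_CHANNELS, EOG_CHANNELS


# ---------------------------------------------------------------- oracles

def sample_entropy_bruteforce(x, v=2, eta=None):
    """O(n^2) loop implementation: Chebyshev templates, no self-matches."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if eta is None:
        eta = 0.2 * np.std(x)

    def count(m):
        nt = n - v
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                d = max(abs(x[i + k] - x[j + k]) for k in range(m))
                if d <= eta:
                    c += 1
        return c

    b_v, b_v1 = count(v), count(v + 1)
    if b_v == 0 or b_v1 == 0:
        return float("inf")
    return -math.log(b_v1 / b_v)


def mi_by_hand(table):
    """Direct double summation of the plug-in MI over a contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p = table / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return mi


def table_to_samples(table):
    xs, ys = [], []
    for i, row in enumerate(table):
        for j, c in enumerate(row):
            xs += [i] * c
            ys += [j] * c
    return np.array(xs), np.array(ys)


# ---------------------------------------------------------------- rhythms

class TestWaveletRhythms:
    def test_zero_window_gives_zero_bands(self):
        bands = wavelet_rhythms(np.zeros(512))
        assert set(bands) == set(BAND_ORDER)
        for b in bands.values():
            assert np.allclose(b, 0.0)

    @pytest.mark.parametrize("n", [64, 200, 512])
    def test_perfect_reconstruction(self, rng, n):
        w = rng.standard_normal(n) * 10
        bands = wavelet_rhythms(w)
        recon = sum(bands.values())
        rel = np.sqrt(np.mean((recon - w) ** 2)) / np.sqrt(np.mean(w**2))
        assert rel < 1e-6
        assert all(v.shape == w.shape for v in bands.values())

    def test_10hz_tone_energy_in_alpha(self):
        t = np.arange(512) / 256.0
        w = np.sin(2 * np.pi * 10 * t)
        bands = wavelet_rhythms(w)
        energies = {k: np.sum(v**2) for k, v in bands.items()}
        assert energies["alpha"] / sum(energies.values()) >= 0.70

    def test_too_short_window_raises(self):
        with pytest.raises(InvalidInputError):
            wavelet_rhythms(np.zeros(16))


# ---------------------------------------------------------------- entropies

class TestSampleEntropy:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(100)
        assert sample_entropy(x) == pytest.approx(sample_entropy_bruteforce(x))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(-5, 5), min_size=10, max_size=60),
        v=st.integers(1, 3),
    )
    def test_oracle_equivalence_property(self, data, v):
        x = np.asarray(data)
        if np.std(x) == 0:
            return
        eta = 0.25 * np.std(x)
        ours = sample_entropy(x, v=v, eta=eta)
        theirs = sample_entropy_bruteforce(x, v=v, eta=eta)
        if math.isinf(theirs):
            assert math.isinf(ours)
        else:
            assert ours == pytest.approx(theirs)

    def test_regular_series_below_shuffled(self):
        rng = np.random.default_rng(3)
        periodic = np.tile([1.0, 2.0, 3.0], 33)
        shuffled = rng.permutation(periodic)
        eta = 0.2 * np.std(periodic)
        se_p = sample_entropy_bruteforce(periodic, eta=eta)
        se_s = sample_entropy_bruteforce(shuffled, eta=eta)
        assert sample_entropy(periodic, eta=eta) == pytest.approx(se_p)
        assert sample_entropy(shuffled, eta=eta) == pytest.approx(se_s)
        assert se_p < se_s

    def test_default_tolerance_is_point2_std(self, rng):
        x = rng.standard_normal(80)
        assert sample_entropy(x) == sample_entropy(x, v=2, eta=0.2 * np.std(x))

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            sample_entropy(np.ones(50))

    def test_too_short_raises(self):
        with pytest.raises(InvalidInputError):
            sample_entropy(np.arange(3.0), v=2)


class TestDifferentialEntropy:
    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, size=10_000)
        expected = 0.5 * math.log(2 * math.pi * math.e * 4.0)
        assert differential_entropy(x) == pytest.approx(expected, abs=0.05)

    def test_scaling_adds_log_factor(self, rng):
        x = rng.standard_normal(500)
        assert differential_entropy(2 * x) - differential_entropy(x) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_constructed_zero_entropy(self):
        # two-point series with sigma^2 exactly 1/(2*pi*e)
        s = math.sqrt(1.0 / (2 * math.pi * math.e))
        x = np.array([-s, s])
        assert differential_entropy(x) == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance_exact(self, rng):
        x = rng.standard_normal(300)
        assert differential_entropy(x + 17.3) == pytest.approx(
            differential_entropy(x), abs=1e-9
        )

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            differential_entropy(np.full(10, 2.0))


class TestBandPowerEnergy:
    def test_unit_sine_power_half(self):
        t = np.arange(512) / 256.0
        x = np.sin(2 * np.pi * 8 * t)  # integer periods in the window
        assert band_power(x) == pytest.approx(0.5, abs=1e-3)

    def test_zeros(self):
        assert band_power(np.zeros(10)) == 0.0
        assert band_energy(np.zeros(10)) == 0.0

    def test_energy_power_identity(self, rng):
        x = rng.standard_normal(333)
        assert band_energy(x) == pytest.approx(band_power(x) * len(x), rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            band_power(np.array([]))


# ---------------------------------------------------------------- MI

class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        x = rng.standard_normal(400)
        codes = discretize(x, 8)
        _, counts = np.unique(codes, return_counts=True)
        p = counts / counts.sum()
        entropy = -np.sum(p * np.log(p))
        assert mutual_information(x, codes) == pytest.approx(entropy, abs=1e-9)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        y = rng.integers(0, 2, size=10_000)
        assert mutual_information(x, y) < 0.01

    def test_contingency_table_matches_hand_summation(self):
        table = [[40, 10], [10, 40]]
        xs, ys = table_to_samples(table)
        ours = mutual_information(xs, ys, discretize_x=False)
        assert ours == pytest.approx(mi_by_hand(table), abs=1e-12)

    def test_symmetry_on_discrete_inputs(self, rng):
        x = rng.integers(0, 4, size=500)
        y = (x + rng.integers(0, 2, size=500)) % 4
        assert mutual_information(x, y, discretize_x=False) == pytest.approx(
            mutual_information(y, x, discretize_x=False), abs=1e-12
        )

    def test_nonnegative(self, rng):
        for _ in range(10):
            x = rng.standard_normal(100)
            y = rng.integers(0, 3, size=100)
            assert mutual_information(x, y) >= 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(InvalidInputError):
            mutual_information(np.zeros(10), np.zeros(9))


# ---------------------------------------------------------------- EOG PR

class TestEogPowerRatio:
    def test_fast_tone_low_ratio(self):
        t = np.arange(256) / 128.0
        assert eog_power_ratio(np.sin(2 * np.pi * 10 * t)) < 0.05

    def test_slow_dominant_high_ratio(self):
        t = np.arange(512) / 128.0
        x = np.sin(2 * np.pi * 0.5 * t) + 0.01 * np.sin(2 * np.pi * 10 * t)
        assert eog_power_ratio(x) > 100

    def test_equal_tones_near_unity(self):
        t = np.arange(512) / 128.0
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 10 * t)
        assert 0.5 <= eog_power_ratio(x) <= 2.0

    def test_short_window_raises(self):
        with pytest.raises(InvalidInputError):
            eog_power_ratio(np.zeros(64))


# ---------------------------------------------------------------- assembly

def _rhythms_and_eog(rng):
    rhythms = {
        ch: {b: rng.standard_normal(512) for b in BAND_ORDER}
        for ch in EEG_CHANNELS
    }
    eog = {ch: rng.standard_normal(256) for ch in EOG_CHANNELS}
    return rhythms, eog


class TestAssemble:
    def test_dimensions(self, rng):
        rhythms, eog = _rhythms_and_eog(rng)
        fv = assemble_features(rhythms, eog)
        assert fv.values.shape == (STATE_DIM,) == (152,)
        # EEG block is channels x bands = 150, EOG block is 2
        assert 5 * len(EEG_CHANNELS) == 150
        assert len(EOG_CHANNELS) == 2

    def test_deterministic(self, rng):
        rhythms, eog = _rhythms_and_eog(rng)
        a = assemble_features(rhythms, eog)
        b = assemble_features(rhythms, eog)
        assert np.array_equal(a.values, b.values)

    def test_missing_channel_named_in_error(self, rng):
        rhythms, eog = _rhythms_and_eog(rng)
        del rhythms["Cz"]
        with pytest.raises(SchemaError, match="Cz"):
            assemble_features(rhythms, eog)

    def test_missing_band_named_in_error(self, rng):
        rhythms, eog = _rhythms_and_eog(rng)
        del rhythms["O1"]["alpha"]
        with pytest.raises(SchemaError, match="alpha"):
            assemble_features(rhythms, eog)

    def test_fast_de_path_matches_generic_assembly(self, rng):
        eeg = rng.standard_normal((512, 30)) * 10
        eog = rng.standard_normal((256, 2)) * 20
        fast = extract_state_vector(eeg, eog, "DE")
        bands = wavelet_rhythms(eeg)
        rhythms = {
            ch: {b: bands[b][:, j] for b in BAND_ORDER}
            for j, ch in enumerate(EEG_CHANNELS)
        }
        generic = assemble_features(
            rhythms, {ch: eog[:, j] for j, ch in enumerate(EOG_CHANNELS)}, "DE"
        )
        assert np.allclose(fast.values, generic.values, atol=1e-10)


class TestNormalizer:
    def test_maps_to_unit_interval_and_freezes(self, rng):
        norm = FeatureNormalizer(dim=4)
        from psa.features import FeatureVector  # noqa: PLC0415

        vecs = [rng.standard_normal(152) for _ in range(20)]
        norm = FeatureNormalizer()
        for v in vecs:
            norm.update(v)
        out = norm.transform(FeatureVector(vecs[3]))
        assert out.normalized
        assert np.all(out.values >= 0) and np.all(out.values <= 1)
        norm.freeze()
        with pytest.raises(InvalidInputError):
            norm.update(vecs[0])


# ---------------------------------------------------------------- ranking

class TestRankFeatures:
    def _labeled_windows(self, n_per_class=40, n=64, seed=0):
        """Heavy-tailed amplitude classes: log-variance (DE) separates the
        labels cleanly while raw power (BP/BE) is outlier-dominated."""
        rng = np.random.default_rng(seed)
        windows, labels = [], []
        for cls, mu in enumerate((0.0, 2.0)):
            for _ in range(n_per_class):
                sigma = np.exp(rng.normal(mu, 1.5) / 2)
                windows.append(rng.standard_normal((n, 30)) * sigma)
                labels.append(cls)
        return np.asarray(windows), np.asarray(labels)

    def test_de_outranks_power_features(self):
        windows, labels = self._labeled_windows()
        ranking = rank_features(
            windows,
            {"valence": labels},
            kinds=("DE", "BP", "BE"),
            channels=("Fp1", "Cz", "O1"),
        )
        means = ranking.mean_by_kind()
        assert means["DE"] > means["BP"]
        assert means["DE"] > means["BE"]
        assert ranking.best_kind() == "DE"

    def test_independent_labels_low_mi(self):
        windows, labels = self._labeled_windows(n_per_class=60, seed=1)
        rng = np.random.default_rng(2)
        shuffled = rng.permutation(labels)
        ranking = rank_features(
            windows, {"valence": shuffled}, kinds=("DE",), channels=("Cz",)
        )
        assert ranking.table["mi"].mean() < 0.1

    def test_all_mi_nonnegative(self):
        windows, labels = self._labeled_windows(n_per_class=20)
        ranking = rank_features(
            windows, {"valence": labels}, kinds=("DE", "BP"), channels=("Pz",)
        )
        assert (ranking.table["mi"] >= 0).all()

    def test_single_class_labels_raise(self):
        windows, labels = self._labeled_windows(n_per_class=10)
        with pytest.raises(DegenerateLabelsError):
            rank_features(windows, {"valence": np.zeros(len(windows))})
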