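"""EEG feature families against brute-force and closed-form oracles."""

import numpy as np
import pytest
import pywt
from scipy import stats as sstats

from neurofuse.containers import EEG, Epoch, FeatureLabel
from neurofuse.eeg_features import (
    DEFAULT_BANDS,
    DEFAULT_MONTAGE,
    DEFAULT_PAIRS,
    BandDefinition,
    band_power,
    differential_entropy,
    extract_eeg_features,
    periodogram_psd,
    rasm_features,
    time_domain_stats,
    wavelet_entropy,
)


def brute_force_stats(x):
    """Direct loop evaluation of the six time-domain statistics."""
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    d1 = sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1)
    d2 = sum(abs(x[i + 2] - x[i]) for i in range(n - 2)) / (n - 2)
    sd = var ** 0.5
    return mu, var, d1, d1 / sd if sd else 0.0, d2, d2 / sd if sd else 0.0


class TestTimeDomainStats:
    def test_constant_signal(self):
        with pytest.warns(UserWarning, match="zero variance"):
            s = time_domain_stats(np.full(50, 3.5))
        assert s.as_array() == pytest.approx([3.5, 0, 0, 0, 0, 0])

    def test_alternating_signal(self):
        x = np.tile([0.0, 1.0], 50)
        s = time_domain_stats(x)
        assert s.d1 == pytest.approx(1.0)
        assert s.d2 == pytest.approx(0.0)

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(1000)
        s = time_domain_stats(x)
        assert s.as_array() == pytest.approx(brute_force_stats(list(x)),
                                             rel=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_domain_stats(np.array([1.0, 2.0]))


class TestPeriodogram:
    def test_pure_tone_concentrated(self):
        fs, f0 = 500.0, 10.0
        t = np.arange(int(fs)) / fs
        freqs, psd = periodogram_psd(np.sin(2 * np.pi * f0 * t), fs)
        peak = freqs[np.argmax(psd)]
        assert peak == pytest.approx(f0)
        df = freqs[1] - freqs[0]
        near = np.abs(freqs - f0) <= 1.5 * df
        assert psd[near].sum() / psd.sum() >= 0.95

    def test_parseval(self, rng):
        fs = 500.0
        x = rng.standard_normal(1000)
        freqs, psd = periodogram_psd(x, fs)
        df = freqs[1] - freqs[0]
        total = psd.sum() * df
        assert total == pytest.approx(np.mean(x ** 2), rel=1e-6)

    def test_zero_signal(self):
        _, psd = periodogram_psd(np.zeros(256), 500.0)
        assert np.all(psd == 0)


class TestBandPower:
    def test_tone_lands_in_alpha(self):
        fs = 500.0
        t = np.arange(int(fs)) / fs
        freqs, psd = periodogram_psd(np.sin(2 * np.pi * 10.0 * t), fs)
        bp = band_power(freqs, psd)
        assert bp[2] / bp.sum() >= 0.95  # alpha is the third band

    def test_subadditivity(self, rng):
        freqs, psd = periodogram_psd(rng.standard_normal(1000), 500.0)
        df = freqs[1] - freqs[0]
        assert band_power(freqs, psd).sum() <= psd.sum() * df + 1e-12

    def test_flat_psd_gives_bandwidth(self):
        freqs = np.arange(0, 250, 0.5)
        psd = np.full_like(freqs, 2.0)
        bp = band_power(freqs, psd)
        widths = [b.hi_hz - b.lo_hz for b in DEFAULT_BANDS]
        assert bp == pytest.approx([2.0 * w for w in widths])

    def test_band_beyond_nyquist_rejected(self):
        freqs = np.arange(0, 10, 0.5)
        with pytest.raises(ValueError, match="exceeds"):
            band_power(freqs, np.ones_like(freqs),
                       (BandDefinition("gamma", 30, 50),))


class TestDifferentialEntropy:
    def test_gaussian_closed_form(self, rng):
        x = rng.standard_normal(100_000)
        de = differential_entropy(x, band=None, fs=500.0)
        assert de == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=0.02)
        assert de == pytest.approx(1.4189, abs=0.03)

    def test_doubling_amplitude_adds_ln2(self, rng):
        x = rng.standard_normal(5000)
        d1 = differential_entropy(x, band=None, fs=500.0)
        d2 = differential_entropy(2 * x, band=None, fs=500.0)
        assert d2 - d1 == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_nonparametric_estimator(self, rng):
        # independent oracle: scipy's nonparametric entropy estimate of the
        # band-limited signal
        from neurofuse.io_preprocess import design_bandpass
        from scipy.signal import sosfiltfilt

        fs = 500.0
        x = rng.standard_normal(10_000)
        band = DEFAULT_BANDS[2]
        de = differential_entropy(x, band=band, fs=fs)
        sos = design_bandpass(band.lo_hz, band.hi_hz, 4, fs)
        xf = sosfiltfilt(sos, x)
        ref = sstats.differential_entropy(xf, method="vasicek")
        assert de == pytest.approx(ref, abs=0.1)

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="sentinel"):
            de = differential_entropy(np.zeros(1000), band=None, fs=500.0)
        assert de < -100


class TestWaveletEntropy:
    def test_single_level_energy_is_zero(self):
        # synthesize a signal from coefficients living on one level only
        n = 256
        coeffs = pywt.wavedec(np.zeros(n), "db4", level=5, mode="periodization")
        coeffs[2] = np.ones_like(coeffs[2])
        x = pywt.waverec(coeffs, "db4", mode="periodization")
        w = wavelet_entropy(x, "db4", 5)
        assert w.swt == pytest.approx(0.0, abs=1e-8)

    def test_equal_energy_reaches_ln_j(self):
        n = 512
        coeffs = pywt.wavedec(np.zeros(n), "db4", level=5, mode="periodization")
        for i, c in enumerate(coeffs):
            c[:] = 0.0
            c[len(c) // 2] = 1.0  # unit energy on every level
        x = pywt.waverec(coeffs, "db4", mode="periodization")
        w = wavelet_entropy(x, "db4", 5)
        assert w.swt == pytest.approx(np.log(6), abs=1e-6)
        assert w.level_probs.sum() == pytest.approx(1.0)

    def test_self_consistent_with_level_probs(self, rng):
        w = wavelet_entropy(rng.standard_normal(1000), "db4", 5)
        p = w.level_probs
        manual = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert w.swt == pytest.approx(manual, rel=1e-12)
        assert 0 <= w.swt <= np.log(len(p))

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError, match="zero total energy"):
            wavelet_entropy(np.zeros(256))


class TestRASM:
    def test_identical_features_give_ones(self):
        v = np.array([1.0, 2.0, 3.0])
        assert rasm_features(v, v) == pytest.approx([1.0, 1.0, 1.0])

    def test_simple_ratio(self):
        assert rasm_features(np.array([2.0]), np.array([4.0]))[0] == 0.5

    def test_zero_denominator_guard(self):
        out = rasm_features(np.array([1.0]), np.array([0.0]))
        assert out[0] == pytest.approx(1e12)

    def test_mirroring_inverts_ratios(self, rng):
        left, right = rng.uniform(0.5, 2.0, 10), rng.uniform(0.5, 2.0, 10)
        assert rasm_features(right, left) == pytest.approx(
            1.0 / rasm_features(left, right)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            rasm_features(np.ones(3), np.ones(4))


def _epoch_from(data, fs=500.0, condition="neutral"):
    names = list(DEFAULT_MONTAGE)[: data.shape[0]]
    return Epoch(data, fs, condition, (5.0, 205.0), names, EEG, onset_s=120.0)


@pytest.fixture(scope="module")
def fm():
    rng = np.random.default_rng(42)
    data = rng.standard_normal((32, 200 * 500))
    return extract_eeg_features(_epoch_from(data))


class TestExtractEEGFeatures:

    def test_row_count(self, fm):
        assert fm.n_samples == 200

    def test_column_count_from_families(self, fm):
        # 32 channels x (6 stats + 5 band powers + 5 DE + 1 SWT) + 15 pairs x 17
        assert fm.n_features == 32 * 17 + 15 * 17 == 799

    def test_labels_unique_and_parseable(self, fm):
        names = fm.column_names()
        assert len(set(names)) == len(names)
        for name in names:
            lab = FeatureLabel.parse(name)
            assert lab.modality == "eeg"
            assert lab.family in {"statistic", "psd", "de", "swt", "rasm"}

    def test_deterministic_bit_exact(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((32, 10 * 500))
        a = extract_eeg_features(_epoch_from(data))
        b = extract_eeg_features(_epoch_from(data.copy()))
        assert np.array_equal(a.values, b.values)

    def test_alpha_tone_raises_only_alpha_band_power(self, rng):
        n = 20 * 500
        base = rng.standard_normal((32, n))
        t = np.arange(n) / 500.0
        boosted = base.copy()
        boosted[0] += 20 * np.sin(2 * np.pi * 10.0 * t)
        fm0 = extract_eeg_features(_epoch_from(base))
        fm1 = extract_eeg_features(_epoch_from(boosted))
        cols = {l.band: i for i, l in enumerate(fm0.labels)
                if l.family == "psd" and l.channel == DEFAULT_MONTAGE[0]}
        p0 = {b: fm0.values[:, i].mean() for b, i in cols.items()}
        p1 = {b: fm1.values[:, i].mean() for b, i in cols.items()}
        assert p1["alpha"] > 10 * p0["alpha"]
        for b in ("delta", "theta", "beta", "gamma"):
            assert abs(p1[b] - p0[b]) / p0[b] < 0.05

    def test_de_monotone_in_band_variance(self, rng):
        # same band, increasing amplitude across epochs -> increasing DE
        n = 5 * 500
        base = rng.standard_normal((32, n))
        des = []
        for scale in (1.0, 2.0, 4.0):
            fm = extract_eeg_features(_epoch_from(scale * base))
            idx = [i for i, l in enumerate(fm.labels)
                   if l.family == "de" and l.band == "alpha"]
            des.append(fm.values[:, idx].mean())
        assert des[0] < des[1] < des[2]

    def test_missing_pair_channel_rejected(self, rng):
        data = np.random.default_rng(0).standard_normal((4, 2 * 500))
        ep = Epoch(data, 500.0, "neutral", (5.0, 205.0),
                   ["a", "b", "c", "d"], EEG, onset_s=0.0)
        with pytest.raises(ValueError, match="montage"):
            extract_eeg_features(ep, pairs=DEFAULT_PAIRS)

    def test_empty_epoch_rejected(self):
        ep = Epoch(np.empty((2, 0)), 500.0, "neutral", (5.0, 205.0),
                   ["a", "b"], EEG, onset_s=0.0)
        with pytest.raises(ValueError, match="empty"):
            extract_eeg_features(ep, pairs=())
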