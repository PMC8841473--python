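"""EEG feature families computed per channel per 1 s packaged window.

Five families are extracted from each stimulus epoch:

* time-domain statistics — mean, population variance, and the mean absolute
  first/second differences, raw and variance-normalized;
* periodogram band power — one-sided windowed periodogram integrated over the
  five canonical bands (δ 0.5-3, θ 4-7, α 8-13, β 14-30, γ 30-50 Hz);
* differential entropy — for a band-limited Gaussian signal the closed form
  ``DE = ½ ln(2πe σ²)`` in nats, with σ² the band-limited sample variance;
* wavelet entropy — Shannon entropy of the per-level energy distribution of a
  discrete wavelet decomposition;
* RASM — the left/right ratio of each of the above features over the 15
  symmetric electrode pairs of the 32-channel montage.

Packaging uses non-overlapping windows (default 1 s), so a 200 s epoch yields
200 rows at a 1 Hz row rate, directly fusable with the fNIRS feature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .containers import EEG, Epoch, FeatureLabel, FeatureMatrix
from .io_preprocess import design_bandpass

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "DEFAULT_PAIRS",
    "DEFAULT_MONTAGE",
    "TimeStatVector",
    "WaveletEntropyValue",
    "time_domain_stats",
    "periodogram_psd",
    "band_power",
    "differential_entropy",
    "wavelet_entropy",
    "rasm_features",
    "extract_eeg_features",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)

# 15 anatomically mirrored left-right electrode pairs (midline Cz/Pz excluded)
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("AFp1", "AFp2"),
    ("AFF1h", "AFF2h"),
    ("AFF5h", "AFF6h"),
    ("F7", "F8"),
    ("FFC1h", "FFC2h"),
    ("FFC5h", "FFC6h"),
    ("FCC3h", "FCC4h"),
    ("FCC5h", "FCC6h"),
    ("FTT7h", "FTT8h"),
    ("CCP3h", "CCP4h"),
    ("CCP5h", "CCP6h"),
    ("TTP7h", "TTP8h"),
    ("CPP3h", "CPP4h"),
    ("TPP7h", "TPP8h"),
    ("PO3", "PO4"),
)

DEFAULT_MONTAGE: tuple[str, ...] = tuple(
    ch for pair in DEFAULT_PAIRS for ch in pair
) + ("Cz", "Pz")

STAT_COMPONENTS = ("mu", "var", "d1", "d1n", "d2", "d2n")

_DE_SENTINEL = -745.0  # returned when the band-limited variance underflows to 0


@dataclass(frozen=True)
class TimeStatVector:
    mu: float
    var: float
    d1: float
    d1n: float
    d2: float
    d2n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.var, self.d1, self.d1n, self.d2, self.d2n])


@dataclass(frozen=True)
class WaveletEntropyValue:
    swt: float
    level_probs: np.ndarray


def time_domain_stats(x: np.ndarray) -> TimeStatVector:
    """Six centralized time-domain statistics of a 1-D signal.

    The variance is the population form (divide by N).  The normalized
    difference statistics divide by the standard deviation; they are set to 0
    with a warning when the variance vanishes.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D signal of length >= 3")
    mu = x.mean()
    var = np.mean((x - mu) ** 2)
    d1 = np.mean(np.abs(np.diff(x)))
    d2 = np.mean(np.abs(x[2:] - x[:-2]))
    if var > 0:
        sd = np.sqrt(var)
        d1n, d2n = d1 / sd, d2 / sd
    else:
        warnings.warn("zero variance: normalized difference statistics set to 0",
                      stacklevel=2)
        d1n = d2n = 0.0
    return TimeStatVector(float(mu), float(var), float(d1), float(d1n),
                          float(d2), float(d2n))


def periodogram_psd(
    x: np.ndarray, fs: float, window: str = "boxcar"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided windowed periodogram on the grid f = k·Fs/N.

    Density scaling: the rectangle-rule integral of the PSD over frequency
    equals the windowed signal's mean square (Parseval).
    Returns ``(freqs, psd)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 8:
        raise ValueError("need at least 8 samples for a periodogram")
    freqs, psd = sps.periodogram(x, fs=fs, window=window, detrend=False,
                                 scaling="density")
    return freqs, psd


def band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Rectangle-rule integral of the PSD over each band's [lo, hi).

    ``psd`` may have leading axes; the band powers are computed along the
    last (frequency) axis and returned stacked on a new last axis.
    """
    freqs = np.asarray(freqs)
    df = freqs[1] - freqs[0]
    nyquist = freqs[-1]
    out = []
    for band in bands:
        if band.hi_hz > nyquist + df / 2:
            raise ValueError(
                f"band {band.name} [{band.lo_hz}, {band.hi_hz}) Hz exceeds the "
                f"PSD grid (top {nyquist} Hz)"
            )
        mask = (freqs >= band.lo_hz) & (freqs < band.hi_hz)
        out.append(np.asarray(psd)[..., mask].sum(axis=-1) * df)
    return np.stack(out, axis=-1)


def _gaussian_de(var: np.ndarray | float) -> np.ndarray | float:
    var = np.asarray(var, dtype=np.float64)
    out = np.full(var.shape, _DE_SENTINEL)
    pos = var > 0
    out[pos] = 0.5 * np.log(2 * np.pi * np.e * var[pos])
    return out if out.ndim else float(out)


def differential_entropy(
    x: np.ndarray,
    band: BandDefinition | None,
    fs: float,
    filter_order: int = 4,
) -> float:
    """Differential entropy (nats) of a band-limited window.

    Band-passes the window to ``band`` (``None`` skips filtering) and applies
    the Gaussian closed form ``½ ln(2πe σ̂²)`` with σ̂² the band-limited
    population variance — the standard estimator for EEG differential entropy.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < fs * 0.5:
        raise ValueError("window shorter than 0.5 s")
    if band is not None:
        sos = design_bandpass(band.lo_hz, band.hi_hz, filter_order, fs)
        x = sps.sosfiltfilt(sos, x)
    var = np.mean((x - x.mean()) ** 2)
    if var <= 0:
        warnings.warn("zero band-limited variance: DE sentinel returned",
                      stacklevel=2)
    return float(_gaussian_de(var))


def _wavelet_level_energies(
    x: np.ndarray, wavelet: str, levels: int
) -> np.ndarray:
    """Energies of the detail levels 1..J and the final approximation.

    ``x`` may have leading axes; returns energies stacked on a new last axis
    (approximation last).
    """
    # periodized orthonormal DWT: level energies sum exactly to signal energy
    coeffs = pywt.wavedec(x, wavelet, level=levels, axis=-1,
                          mode="periodization")
    # wavedec returns [cA_J, cD_J, ..., cD_1]; order as D1..DJ then A
    details = coeffs[:0:-1]
    ordered = list(details) + [coeffs[0]]
    return np.stack([(c ** 2).sum(axis=-1) for c in ordered], axis=-1)


def wavelet_entropy(
    x: np.ndarray, wavelet: str = "db4", levels: int = 5
) -> WaveletEntropyValue:
    """Shannon entropy of the wavelet decomposition's energy distribution.

    ``p_i`` is level i's share of the total energy over the ``levels`` detail
    levels plus the final approximation; ``swt = -Σ p_i ln p_i`` with 0·ln 0
    taken as 0, so 0 ≤ swt ≤ ln(levels + 1).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2 ** levels:
        raise ValueError(f"need at least 2^{levels} samples")
    energies = _wavelet_level_energies(x, wavelet, levels)
    total = energies.sum()
    if total <= 0:
        raise ValueError("zero total energy: wavelet entropy undefined")
    p = energies / total
    return WaveletEntropyValue(float(_entropy(p)), p)


def _entropy(p: np.ndarray) -> np.ndarray:
    """-Σ p ln p along the last axis, with 0 ln 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def rasm_features(
    left: np.ndarray, right: np.ndarray, eps: float = 1e-12
) -> np.ndarray:
    """Rational asymmetry: elementwise left / right with an ε-guarded divisor."""
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if left.shape != right.shape:
        raise ValueError(f"shape mismatch: {left.shape} vs {right.shape}")
    sign = np.where(right < 0, -1.0, 1.0)
    denom = sign * np.maximum(np.abs(right), eps)
    return left / denom


def extract_eeg_features(
    epoch: Epoch,
    window_s: float = 1.0,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    wavelet: str = "db4",
    wavelet_levels: int = 5,
    rasm: bool = True,
    filter_order: int = 4,
) -> FeatureMatrix:
    """Package an EEG epoch into the per-second feature table.

    One row per non-overlapping ``window_s`` window.  Per channel: 6
    time-domain statistics, 5 band powers, 5 band differential entropies and
    1 wavelet entropy; per symmetric pair, the RASM ratio of each of those 17
    features.  With the default 32-channel montage this is
    32·(6+5+5+1) + 15·17 = 544 + 255 = 831 columns total.

    Band-limiting for the DE family filters the whole epoch once per band
    (avoiding per-window edge transients), then takes per-window variances.
    """
    if epoch.modality != EEG:
        raise ValueError("expected an EEG epoch")
    if epoch.n_samples == 0:
        raise ValueError("empty epoch")
    win = int(np.floor(window_s * epoch.fs))
    # nominal epoch length bounds the row count so that both modalities
    # package a given epoch window to the same number of rows
    nominal_s = epoch.window_s[1] - epoch.window_s[0]
    n_win = min(epoch.n_samples // win,
                int(np.floor(nominal_s / window_s + 1e-9)))
    if n_win < 1:
        raise ValueError("epoch shorter than one packaging window")
    n_ch = len(epoch.channel_names)
    wins = epoch.data[:, : n_win * win].reshape(n_ch, n_win, win)

    # -- time-domain statistics (vectorized Eqs: population variance) -------
    mu = wins.mean(axis=-1)
    var = wins.var(axis=-1)
    d1 = np.abs(np.diff(wins, axis=-1)).mean(axis=-1)
    d2 = np.abs(wins[..., 2:] - wins[..., :-2]).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(var)
        d1n = np.where(var > 0, d1 / np.where(sd > 0, sd, 1.0), 0.0)
        d2n = np.where(var > 0, d2 / np.where(sd > 0, sd, 1.0), 0.0)
    stats = np.stack([mu, var, d1, d1n, d2, d2n], axis=-1)  # ch x win x 6

    # -- band power from the per-window periodogram --------------------------
    freqs, psd = periodogram_psd(wins, epoch.fs)
    bp = band_power(freqs, psd, bands)  # ch x win x n_bands

    # -- differential entropy: filter whole epoch per band, window variances -
    de = np.empty((n_ch, n_win, len(bands)))
    for b, band in enumerate(bands):
        sos = design_bandpass(band.lo_hz, band.hi_hz, filter_order, epoch.fs)
        filt = sps.sosfiltfilt(sos, epoch.data, axis=1)
        fw = filt[:, : n_win * win].reshape(n_ch, n_win, win)
        de[:, :, b] = _gaussian_de(fw.var(axis=-1))

    # -- wavelet entropy ------------------------------------------------------
    energies = _wavelet_level_energies(wins, wavelet, wavelet_levels)
    totals = energies.sum(axis=-1, keepdims=True)
    p = np.divide(energies, totals, out=np.zeros_like(energies),
                  where=totals > 0)
    swt = _entropy(p)  # ch x win

    per_channel = np.concatenate([stats, bp, de, swt[..., None]], axis=-1)
    per_channel_keys = (
        [("statistic", c) for c in STAT_COMPONENTS]
        + [("psd", b.name) for b in bands]
        + [("de", b.name) for b in bands]
        + [("swt", "")]
    )

    blocks: list[np.ndarray] = []
    labels: list[FeatureLabel] = []
    for fi, (family, comp) in enumerate(per_channel_keys):
        blocks.append(per_channel[:, :, fi].T)  # win x ch
        labels.extend(
            FeatureLabel(EEG, ch, family, comp) for ch in epoch.channel_names
        )

    if rasm and pairs:
        name_to_idx = {n: i for i, n in enumerate(epoch.channel_names)}
        for lch, rch in pairs:
            if lch not in name_to_idx or rch not in name_to_idx:
                raise ValueError(f"pair ({lch}, {rch}) not in the montage")
        li = [name_to_idx[p[0]] for p in pairs]
        ri = [name_to_idx[p[1]] for p in pairs]
        ratios = rasm_features(per_channel[li], per_channel[ri])  # pair x win x f
        for fi, (family, comp) in enumerate(per_channel_keys):
            blocks.append(ratios[:, :, fi].T)
            key = f"{family}.{comp}" if comp else family
            labels.extend(
                FeatureLabel(EEG, f"{l}-{r}", "rasm", key) for l, r in pairs
            )

    values = np.concatenate(blocks, axis=1)
    y = np.repeat(epoch.condition, n_win)
    return FeatureMatrix(values, labels, y=y, rate_hz=1.0 / window_s)
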