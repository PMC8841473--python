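"""Synthetic two-condition EEG + fNIRS sessions with known ground truth.

The generator emulates the structure of a music-listening session: a
rest / neutral-music / rest / preferred-music / rest paradigm (2-4-2-4-2
minutes) recorded simultaneously by a 32-channel 500 Hz EEG montage and a
44-channel 3.91 Hz dual-wavelength fNIRS probe, with a shared trigger table.

EEG channels are sums of band-limited noise processes, one per canonical
band, whose amplitudes are modulated per condition on frontal and occipital
channel groups (strongest in δ), plus broadband white noise.  fNIRS ground
truth is an HRF-convolved boxcar activation in ΔHbO (stronger for preferred
music on "active" sites) with anticorrelated activation ΔHb = −ΔHbO/3,
contaminated by in-phase cardiac (~1 Hz), respiratory (~0.2 Hz) and
Mayer-wave (~0.1 Hz) systemic oscillations and white noise, and pushed
through the modified Beer-Lambert forward model
to dual-wavelength raw intensities so the inverse conversion is exercised
end-to-end.

Everything is a pure function of the :class:`SimConfig` (same seed, same
bits).  What the generator does *not* emulate: 1/f EEG background spectra,
volume conduction and channel covariance, eye-blink or motion artifacts,
and optode-specific gain drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EEG, FNIRS_RAW, EventMarker, Recording
from .eeg_features import DEFAULT_MONTAGE
from .fnirs_features import double_gamma_hrf
from .io_preprocess import DEFAULT_DPF, mbll_forward

__all__ = [
    "SimConfig",
    "simulate_eeg",
    "simulate_fnirs",
    "simulate_session",
    "simulate_feature_tables",
]

# rest / neutral / rest / preferred / rest block durations, seconds
DEFAULT_PARADIGM: tuple[tuple[str, float], ...] = (
    ("rest", 120.0),
    ("neutral", 240.0),
    ("rest", 120.0),
    ("preferred", 240.0),
    ("rest", 120.0),
)

# per-band RMS amplitudes (µV) of the background band-limited processes
DEFAULT_BAND_AMPLITUDE = {
    "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 5.0, "gamma": 2.0,
}

# condition-dependent amplitude multipliers; strongest contrast in δ, echoing
# low-band dominance of music-evoked activity
DEFAULT_EEG_EFFECT = {
    "delta": {"neutral": 1.2, "preferred": 1.5},
    "theta": {"neutral": 1.1, "preferred": 1.3},
    "alpha": {"neutral": 1.15, "preferred": 1.3},
    "beta": {"neutral": 1.05, "preferred": 1.1},
}

# frontal + occipital electrodes carry the condition effect by default
DEFAULT_EFFECT_CHANNELS = (
    "AFp1", "AFp2", "AFF1h", "AFF2h", "AFF5h", "AFF6h", "F7", "F8",
    "PO3", "PO4",
)

# µM peak ΔHbO activation amplitude per condition on active sites
DEFAULT_FNIRS_EFFECT = {"neutral": 0.6, "preferred": 1.0}

_BAND_EDGES = {
    "delta": (0.5, 3.0), "theta": (4.0, 7.0), "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0), "gamma": (30.0, 50.0),
}


@dataclass
class SimConfig:
    """All knobs of the synthetic session generator."""

    seed: int = 0
    n_eeg_channels: int = 32
    n_fnirs_channels: int = 44
    fs_eeg: float = 500.0
    fs_fnirs: float = 3.91
    paradigm: tuple[tuple[str, float], ...] = DEFAULT_PARADIGM
    band_amplitude: dict = field(default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDE))
    eeg_effect: dict = field(
        default_factory=lambda: {b: dict(m) for b, m in DEFAULT_EEG_EFFECT.items()}
    )
    eeg_effect_channels: tuple[str, ...] = DEFAULT_EFFECT_CHANNELS
    eeg_noise_sd: float = 5.0  # µV broadband
    fnirs_effect: dict = field(default_factory=lambda: dict(DEFAULT_FNIRS_EFFECT))
    n_active_sites: int = 20  # leading sites carry the hemodynamic effect
    cardiac_hz: float = 1.0
    resp_hz: float = 0.2
    mayer_hz: float = 0.1
    cardiac_amp: float = 0.3  # µM-equivalent oscillation amplitudes
    resp_amp: float = 0.2
    mayer_amp: float = 0.2
    fnirs_noise_sd: float = 0.2  # µM white noise on ΔHbO
    hb_ratio: float = -1.0 / 3.0  # ΔHb coupling to ΔHbO
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    sd_distance_cm: float = 3.0
    dpf: float = DEFAULT_DPF

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.paradigm):
            raise ValueError("paradigm block durations must be positive")
        if self.fs_eeg <= 0 or self.fs_fnirs <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.paradigm)

    def events(self) -> list[EventMarker]:
        out, t = [], 0.0
        for label, dur in self.paradigm:
            if label != "rest":
                out.append(EventMarker(t, label, dur))
            t += dur
        return out

    def eeg_channel_names(self) -> list[str]:
        base = list(DEFAULT_MONTAGE)
        if self.n_eeg_channels <= len(base):
            return base[: self.n_eeg_channels]
        return base + [f"EEG{i}" for i in range(len(base), self.n_eeg_channels)]


def _condition_envelope(cfg: SimConfig, fs: float, n: int,
                        multipliers: dict[str, float]) -> np.ndarray:
    """Per-sample amplitude multiplier from the paradigm blocks."""
    env = np.ones(n)
    t0 = 0.0
    idx = np.arange(n) / fs
    for label, dur in cfg.paradigm:
        if label in multipliers:
            env[(idx >= t0) & (idx < t0 + dur)] = multipliers[label]
        t0 += dur
    return env


def simulate_eeg(cfg: SimConfig) -> Recording:
    """Condition-modulated band-limited noise EEG (µV, channels x samples)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    n = int(np.floor(cfg.duration_s * cfg.fs_eeg))
    names = cfg.eeg_channel_names()
    affected = np.array([c in cfg.eeg_effect_channels for c in names])
    data = rng.normal(0.0, cfg.eeg_noise_sd, size=(cfg.n_eeg_channels, n))
    for band, (lo, hi) in _BAND_EDGES.items():
        amp = cfg.band_amplitude.get(band, 0.0)
        if amp <= 0:
            continue
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=cfg.fs_eeg,
                         output="sos")
        proc = sps.sosfiltfilt(sos, rng.standard_normal((cfg.n_eeg_channels, n)),
                               axis=1)
        proc *= amp / proc.std(axis=1, keepdims=True)
        mult = cfg.eeg_effect.get(band, {})
        if mult:
            env = _condition_envelope(cfg, cfg.fs_eeg, n, mult)
            proc[affected] *= env[None, :]
        data += proc
    return Recording(
        data=data, fs=cfg.fs_eeg, channel_names=names, modality=EEG,
        events=cfg.events(),
    )


def _ground_truth_hbo(cfg: SimConfig, n: int) -> np.ndarray:
    """Noise-free activation component of ΔHbO (µM, sites x samples)."""
    t = np.arange(n) / cfg.fs_fnirs
    hrf = double_gamma_hrf(cfg.fs_fnirs)
    box = {}
    t0 = 0.0
    for label, dur in cfg.paradigm:
        if label in cfg.fnirs_effect:
            box.setdefault(label, np.zeros(n))
            box[label][(t >= t0) & (t < t0 + dur)] = 1.0
        t0 += dur
    response = np.zeros(n)
    for label, b in box.items():
        response += cfg.fnirs_effect[label] * np.convolve(b, hrf)[:n]
    site_gain = np.zeros(cfg.n_fnirs_channels)
    site_gain[: cfg.n_active_sites] = 1.0
    return site_gain[:, None] * response[None, :]


def simulate_fnirs(cfg: SimConfig) -> Recording:
    """Raw dual-wavelength fNIRS intensities from an HRF + physiology model."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    n = int(np.floor(cfg.duration_s * cfg.fs_fnirs))
    t = np.arange(n) / cfg.fs_fnirs
    n_sites = cfg.n_fnirs_channels

    activation = _ground_truth_hbo(cfg, n)
    # systemic oscillations are in phase across chromophores (at reduced
    # amplitude in Hb); only the neuronal activation is anticorrelated
    osc = np.zeros((n_sites, n))
    for freq, amp in ((cfg.cardiac_hz, cfg.cardiac_amp),
                      (cfg.resp_hz, cfg.resp_amp),
                      (cfg.mayer_hz, cfg.mayer_amp)):
        phase = rng.uniform(0, 2 * np.pi, size=n_sites)
        osc += amp * np.sin(2 * np.pi * freq * t[None, :] + phase[:, None])
    hbo = activation + osc + rng.normal(0.0, cfg.fnirs_noise_sd,
                                        size=(n_sites, n))
    hb = (cfg.hb_ratio * activation + abs(cfg.hb_ratio) * osc
          + rng.normal(0.0, cfg.fnirs_noise_sd / 3, size=(n_sites, n)))

    distances = np.full(n_sites, cfg.sd_distance_cm)
    intensities = mbll_forward(
        hbo, hb, cfg.wavelengths_nm, distances, dpf=cfg.dpf
    )
    names = [
        f"CH{i + 1:02d}_{wl:.0f}nm"
        for wl in cfg.wavelengths_nm
        for i in range(n_sites)
    ]
    return Recording(
        data=intensities, fs=cfg.fs_fnirs, channel_names=names,
        modality=FNIRS_RAW, events=cfg.events(),
        wavelengths_nm=cfg.wavelengths_nm, sd_distance_cm=distances,
    )


def simulate_session(cfg: SimConfig) -> tuple[Recording, Recording, dict]:
    """Both modalities with a shared event table, plus the ground truth.

    The ground-truth record carries the configured effects and the noise-free
    ΔHbO activation component, enabling parameter-recovery checks.
    """
    eeg = simulate_eeg(cfg)
    fnirs = simulate_fnirs(cfg)
    n = int(np.floor(cfg.duration_s * cfg.fs_fnirs))
    truth = {
        "seed": cfg.seed,
        "eeg_effect": cfg.eeg_effect,
        "fnirs_effect": cfg.fnirs_effect,
        "n_active_sites": cfg.n_active_sites,
        "hbo_activation": _ground_truth_hbo(cfg, n),
        "events": cfg.events(),
    }
    return eeg, fnirs, truth


def simulate_feature_tables(
    seed: int = 0,
    n_samples: int = 400,
    n_informative: int = 10,
    n_noise: int = 90,
    shift: float = 2.0,
    fnirs_scale: float = 1.0,
    informative_split: float = 0.5,
) -> tuple["FeatureMatrix", "FeatureMatrix"]:
    """Directly simulated feature tables with planted class structure.

    Informative columns are unit-variance Gaussians whose class means differ
    by ``shift`` standard deviations (a strong condition effect, matching the
    high separability the session generator produces); noise columns carry no
    class information.  Columns are split between a nominal "EEG" and a
    nominal "fNIRS" table (fraction ``informative_split`` of informative
    features to EEG), and the fNIRS table is multiplied by ``fnirs_scale`` to
    emulate the raw scale mismatch between modalities.
    """
    from .containers import FeatureLabel, FeatureMatrix

    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    half = n_samples // 2
    y = np.array(["neutral"] * half + ["preferred"] * (n_samples - half))
    cls = (y == "preferred").astype(float)

    p = n_informative + n_noise
    values = rng.standard_normal((n_samples, p))
    values[:, :n_informative] += shift * cls[:, None]
    perm = rng.permutation(n_samples)
    values, y = values[perm], y[perm]

    n_inf_eeg = int(round(n_informative * informative_split))
    n_noise_eeg = (p // 2) - n_inf_eeg
    eeg_cols = list(range(n_inf_eeg)) + list(
        range(n_informative, n_informative + n_noise_eeg)
    )
    fnirs_cols = [j for j in range(p) if j not in set(eeg_cols)]

    def table(cols, modality, scale):
        labels = [
            FeatureLabel(
                modality, f"ch{j}",
                "informative" if j < n_informative else "noise", str(j),
            )
            for j in cols
        ]
        return FeatureMatrix(values[:, cols] * scale, labels, y=y)

    return table(eeg_cols, "eeg", 1.0), table(fnirs_cols, "fnirs", fnirs_scale)
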