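"""fNIRS feature extraction: window statistics, GLM activation betas, and
channel-wise condition contrasts.

Two feature families are computed per channel and chromophore (HbO / Hb):

* window statistics — the mean absolute concentration change and the variance
  over each packaged window;
* GLM beta — the least-squares coefficient of the stimulus regressor, the
  standard activation magnitude for hemodynamic data.  For per-second
  packaging the beta is fitted on a causal sliding context (default 20 s)
  ending at the window, so every packaged row carries an activation estimate;
  a whole-epoch fit replicated across rows is available via ``design="whole"``.

The condition contrast is a channel-wise two-sample t-test between the
per-window values of the two music conditions, the basis of an activation
difference map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gamma as _gamma_fn
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import FNIRS_HEMO, Epoch, EventMarker, FeatureLabel, FeatureMatrix

__all__ = [
    "HemoStatVector",
    "DesignMatrix",
    "GLMResult",
    "ContrastMap",
    "hemo_window_stats",
    "double_gamma_hrf",
    "build_design_matrix",
    "glm_beta",
    "extract_fnirs_features",
    "channel_contrast",
]


@dataclass(frozen=True)
class HemoStatVector:
    """Mean absolute level and variance of a hemodynamic window."""

    mu_f: float
    var_f: float


@dataclass
class DesignMatrix:
    """Time x regressors design with named columns (intercept last)."""

    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X must be time x regressors, one name per column")


@dataclass
class GLMResult:
    B: np.ndarray  # regressors x channels
    E: np.ndarray  # residuals, time x channels
    regressor_names: list[str] = field(default_factory=list)


@dataclass
class ContrastMap:
    """Per-channel two-condition t statistics with significance mask."""

    channels: list[str]
    t: np.ndarray
    p: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channels,
                "t": self.t,
                "p": self.p,
                "significant": self.significant,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hemo_window_stats(
    x: np.ndarray, t1: float, t2: float, fs: float
) -> HemoStatVector:
    """Statistics of a hemodynamic signal over the window [t1, t2) seconds.

    The mean is of the *absolute* signal, normalized by the nominal sample
    count ``fs·(t2-t1)``; the variance is the ordinary population variance
    about the window mean.
    """
    if t2 <= t1:
        raise ValueError("need t2 > t1")
    x = np.asarray(x, dtype=np.float64)
    i0, i1 = int(np.floor(t1 * fs)), int(np.floor(t2 * fs))
    if i0 < 0 or i1 > x.shape[-1] or i1 <= i0:
        raise ValueError(f"window [{t1}, {t2}) s outside the signal")
    w = x[..., i0:i1]
    mu_f = np.abs(w).sum() / (fs * (t2 - t1))
    var_f = w.var()
    return HemoStatVector(float(mu_f), float(var_f))


def double_gamma_hrf(fs: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~5-6 s), unit peak."""
    t = np.arange(0, duration_s, 1.0 / fs)
    a1, b1, a2, b2, c = 6.0, 1.0, 16.0, 1.0, 1.0 / 6.0
    h = (
        t ** (a1 - 1) * b1 ** a1 * np.exp(-b1 * t) / _gamma_fn(a1)
        - c * t ** (a2 - 1) * b2 ** a2 * np.exp(-b2 * t) / _gamma_fn(a2)
    )
    return h / h.max()


def build_design_matrix(
    events: list[EventMarker],
    n_samples: int,
    fs: float,
    hrf: str = "none",
) -> DesignMatrix:
    """One regressor per stimulus condition plus an intercept.

    Each non-rest condition contributes a boxcar (1 while its events are on)
    convolved with the configured HRF kernel (``"none"`` keeps plain boxcars;
    ``"double_gamma"`` uses the canonical double-gamma response).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    t_max = n_samples / fs
    for e in events:
        if e.onset_s >= t_max:
            raise ValueError(
                f"event {e.label} at {e.onset_s} s lies beyond the "
                f"{t_max:.1f} s design window"
            )
    t = np.arange(n_samples) / fs
    conditions = sorted({e.label for e in events if e.label != "rest"})
    cols, names = [], []
    kernel = None
    if hrf == "double_gamma":
        kernel = double_gamma_hrf(fs)
    elif hrf != "none":
        raise ValueError(f"unknown HRF kernel {hrf!r}")
    for cond in conditions:
        box = np.zeros(n_samples)
        for e in events:
            if e.label == cond:
                box[(t >= e.onset_s) & (t < e.end_s)] = 1.0
        if kernel is not None:
            box = np.convolve(box, kernel)[:n_samples]
        cols.append(box)
        names.append(cond)
    cols.append(np.ones(n_samples))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names)


def glm_beta(Y: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares via the normal equations, B = (XᵀX)⁻¹XᵀY.

    Residual columns are orthogonal to the design columns.  A rank-deficient
    design raises, naming the collinear regressors.
    """
    X = design.X
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"Y has {Y.shape[0]} rows but the design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [design.names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear regressors: {bad or design.names}"
        )
    xtx = X.T @ X
    B = np.linalg.solve(xtx, X.T @ Y)
    E = Y - X @ B
    return GLMResult(B=B, E=E, regressor_names=list(design.names))


def _chromophore_blocks(epoch: Epoch) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = epoch.channel_names
    hbo_idx = [i for i, n in enumerate(names) if n.endswith("_hbo")]
    hbr_idx = [i for i, n in enumerate(names) if n.endswith("_hbr")]
    if not hbo_idx or len(hbo_idx) != len(hbr_idx):
        raise ValueError("epoch must contain matching HbO and Hb channel blocks")
    sites = [names[i].rsplit("_", 1)[0] for i in hbo_idx]
    return sites, epoch.data[hbo_idx], epoch.data[hbr_idx]


def extract_fnirs_features(
    epoch: Epoch,
    window_s: float = 1.0,
    context_s: float = 20.0,
    hrf: str = "none",
    design: str = "sliding",
) -> FeatureMatrix:
    """Package a hemodynamic epoch into the per-second feature table.

    Per window and per channel/chromophore: the window statistics (mean
    absolute level, variance) and a GLM activation beta.  With
    ``design="sliding"`` the beta is the least-squares fit of the stimulus
    regressor on the causal ``context_s`` context ending at the window; the
    epoch lies wholly inside the stimulus and is baseline-corrected against
    the pre-stimulus interval, so the sliding design carries the stimulus
    regressor alone (an intercept would be collinear with a plain boxcar).
    ``design="whole"`` fits once on the full epoch and replicates the beta.
    """
    if epoch.modality != FNIRS_HEMO:
        raise ValueError("expected a hemoglobin-converted fNIRS epoch")
    win_n = int(np.floor(window_s * epoch.fs))
    if win_n < 1 or epoch.n_samples < win_n:
        raise ValueError("packaging window longer than the epoch")
    # row count comes from the nominal epoch length so that modalities with
    # different sampling rates package to identical row counts
    nominal_s = epoch.window_s[1] - epoch.window_s[0]
    target = int(np.floor(nominal_s / window_s + 1e-9))
    edges = np.floor(np.arange(target + 1) * window_s * epoch.fs).astype(int)
    n_win = int(np.searchsorted(edges, epoch.n_samples, side="right")) - 1
    n_win = min(n_win, target)
    if n_win < 1:
        raise ValueError("packaging window longer than the epoch")
    sites, hbo, hbr = _chromophore_blocks(epoch)
    chrom = {"hbo": hbo, "hbr": hbr}

    # stimulus regressor over the epoch timeline (stimulus on throughout,
    # starting window_s[0] before the epoch's first sample)
    onset_in_epoch = -epoch.window_s[0]
    reg_events = [
        EventMarker(max(onset_in_epoch, 0.0), epoch.condition
                    if epoch.condition != "rest" else "neutral",
                    epoch.duration_s + max(-onset_in_epoch, 0.0))
    ]
    if hrf == "double_gamma":
        # build on an extended timeline so the rise since true onset is kept
        pad = int(np.floor(epoch.window_s[0] * epoch.fs))
        dm = build_design_matrix(
            [EventMarker(0.0, reg_events[0].label,
                         epoch.duration_s + epoch.window_s[0])],
            epoch.n_samples + pad, epoch.fs, hrf="double_gamma",
        )
        regressor = dm.X[pad:, 0]
    else:
        dm = build_design_matrix(reg_events, epoch.n_samples, epoch.fs, hrf=hrf)
        regressor = dm.X[:, 0]

    bounds = edges[: n_win + 1]
    ctx_n = max(int(np.floor(context_s * epoch.fs)), 2)

    stat_blocks: dict[str, np.ndarray] = {}
    beta_blocks: dict[str, np.ndarray] = {}
    for key, block in chrom.items():
        n_sites = block.shape[0]
        mu = np.empty((n_win, n_sites))
        var = np.empty((n_win, n_sites))
        beta = np.empty((n_win, n_sites))
        if design == "whole":
            x = regressor
            denom = float(x @ x)
            whole_beta = (block @ x) / denom if denom > 0 else np.zeros(n_sites)
        for i in range(n_win):
            i0, i1 = bounds[i], bounds[i + 1]
            w = block[:, i0:i1]
            mu[i] = np.abs(w).sum(axis=1) / (epoch.fs * window_s)
            var[i] = w.var(axis=1)
            if design == "sliding":
                c0 = max(0, i1 - ctx_n)
                x = regressor[c0:i1]
                denom = float(x @ x)
                beta[i] = (block[:, c0:i1] @ x) / denom if denom > 0 else 0.0
            else:
                beta[i] = whole_beta
        stat_blocks[key] = np.concatenate([mu, var], axis=1)
        beta_blocks[key] = beta

    blocks, labels = [], []
    for key in ("hbo", "hbr"):
        blocks.append(stat_blocks[key])
        labels.extend(
            FeatureLabel("fnirs", s, "hemo_stat", f"{key}.mu") for s in sites
        )
        labels.extend(
            FeatureLabel("fnirs", s, "hemo_stat", f"{key}.var") for s in sites
        )
    for key in ("hbo", "hbr"):
        blocks.append(beta_blocks[key])
        labels.extend(
            FeatureLabel("fnirs", s, "glm_beta", key) for s in sites
        )
    values = np.concatenate(blocks, axis=1)
    y = np.repeat(epoch.condition, n_win)
    return FeatureMatrix(values, labels, y=y, rate_hz=1.0 / window_s)


def channel_contrast(
    feats_a: np.ndarray,
    feats_b: np.ndarray,
    channels: list[str] | None = None,
    alpha: float = 0.05,
) -> ContrastMap:
    """Channel-wise two-sample t-test between two conditions.

    ``feats_a``/``feats_b`` are windows x channels value arrays (e.g. HbO
    means per packaged window).  Pooled-variance (Student) t, two-sided p.
    """
    a = np.atleast_2d(np.asarray(feats_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(feats_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("condition blocks have different channel counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 windows per condition")
    t, p = sstats.ttest_ind(a, b, axis=0, equal_var=True)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} channel(s) with zero variance in both "
            "groups: t set to 0, p to 1",
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    if channels is None:
        channels = [f"ch{i}" for i in range(a.shape[1])]
    return ContrastMap(list(channels), t, p, alpha=alpha)
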