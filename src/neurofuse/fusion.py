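"""Feature-level multimodal fusion: the Normalized-ReliefF method.

EEG and fNIRS features live on wildly different scales (µV² band powers vs
µM concentration changes), so direct concatenation ("splicing") lets one
modality dominate distance-based learners.  The fusion method here
min-max-normalizes each modality's feature table to [0, 1], concatenates them
row-wise at the shared 1 Hz packaged rate, weights every column with the
ReliefF relevance score ω(x), and drops columns below a selection threshold.

ReliefF scores a feature by contrasting its separation of each probe sample
from its k nearest same-class *hits* (which should be close → subtracts) and
its k nearest other-class *misses* (which should be far → adds, weighted by
the miss class's prior):

    ω(x) ← ω(x) − Σⱼ diff(x, S, NHⱼ)/(m·k)
                + Σ_{C≠cl(S)} P(C)/(1−P(cl(S))) · Σⱼ diff(x, S, NM(C)ⱼ)/(m·k)

with diff(x, a, b) = |a[x] − b[x]| / (max(x) − min(x)) for continuous
features, so ω is bounded in [−1, 1].  Neighbor search uses the Manhattan
distance over all diff-normalized features; constant features contribute
nothing and receive weight exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .containers import FeatureMatrix

__all__ = [
    "ReliefFConfig",
    "FeatureWeights",
    "minmax_normalize",
    "fuse_concat",
    "relieff_weights",
    "select_features",
    "normalized_relieff",
    "NormalizedReliefFResult",
]


@dataclass
class ReliefFConfig:
    """ReliefF weighting / selection settings.

    ``m="all"`` performs one deterministic pass visiting every sample in
    index order; an integer m draws that many probe samples from the seeded
    RNG.  ``threshold`` mode keeps features whose weight strictly exceeds
    the threshold (default 0: non-positive-weight features are dropped);
    ``top_n`` keeps the ``n_keep`` largest-weight features.
    """

    k: int = 10
    m: int | str = "all"
    seed: int = 0
    threshold: float = 0.0
    mode: str = "threshold"
    n_keep: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m != "all" and (not isinstance(self.m, int) or self.m < 1):
            raise ValueError('m must be a positive integer or "all"')
        if self.mode not in ("threshold", "top_n"):
            raise ValueError(f"unknown selection mode {self.mode!r}")


@dataclass
class FeatureWeights:
    """Per-column ReliefF weights with the class priors used in the update."""

    omega: np.ndarray
    priors: dict[str, float]
    labels: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"feature": [str(l) for l in self.labels], "omega": self.omega}
        )


def minmax_normalize(
    fm: FeatureMatrix,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Scale each column to [0, 1] by its (min, max).

    Without ``stats`` the per-column extrema are fitted from ``fm`` itself and
    stored on the result as ``minmax_stats`` for reuse on held-out folds.
    Constant columns map to 0 with a warning.  Idempotent on already
    normalized data.
    """
    if fm.n_samples < 2 and stats is None:
        raise ValueError("need at least 2 rows to fit normalization statistics")
    if stats is None:
        mins = fm.values.min(axis=0)
        maxs = fm.values.max(axis=0)
    else:
        mins, maxs = stats
    span = maxs - mins
    constant = span <= 0
    if constant.any() and stats is None:
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) mapped to 0",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, span)
    values = (fm.values - mins) / safe
    values[:, constant] = 0.0
    out = FeatureMatrix(values, fm.labels, y=fm.y, rate_hz=fm.rate_hz)
    out.minmax_stats = (mins, maxs)
    return out


def fuse_concat(eeg_fm: FeatureMatrix, fnirs_fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of the two modality tables (EEG first).

    Rows must align one-to-one: same count, same condition label sequence.
    An empty second table passes the first through unchanged.
    """
    if fnirs_fm.n_features == 0:
        return eeg_fm
    if eeg_fm.n_features == 0:
        return fnirs_fm
    if eeg_fm.n_samples != fnirs_fm.n_samples:
        raise ValueError(
            f"row mismatch: EEG has {eeg_fm.n_samples} packaged samples, "
            f"fNIRS has {fnirs_fm.n_samples}"
        )
    if eeg_fm.y is not None and fnirs_fm.y is not None:
        if not np.array_equal(eeg_fm.y, fnirs_fm.y):
            raise ValueError("row condition labels disagree between modalities")
    collisions = set(eeg_fm.column_names()) & set(fnirs_fm.column_names())
    if collisions:
        raise ValueError(f"column label collision: {sorted(collisions)[:5]}")
    return FeatureMatrix(
        np.concatenate([eeg_fm.values, fnirs_fm.values], axis=1),
        eeg_fm.labels + fnirs_fm.labels,
        y=eeg_fm.y if eeg_fm.y is not None else fnirs_fm.y,
        rate_hz=eeg_fm.rate_hz,
    )


def _feature_ranges(values: np.ndarray) -> np.ndarray:
    """max - min per column; constant columns get inf so their diff is 0."""
    span = values.max(axis=0) - values.min(axis=0)
    return np.where(span > 0, span, np.inf)


def relieff_weights(fm: FeatureMatrix, cfg: ReliefFConfig) -> FeatureWeights:
    """ReliefF relevance weight ω(x) for every feature column.

    Deterministic given ``cfg.seed`` (and fully deterministic for
    ``m="all"``).  Neighbor ties are broken by lowest sample index.
    """
    if fm.y is None:
        raise ValueError("class labels required for ReliefF")
    values = fm.values
    y = np.asarray(fm.y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    too_small = classes[counts <= cfg.k]
    if len(too_small):
        raise ValueError(
            f"class(es) {list(too_small)} have <= k={cfg.k} samples; "
            "use a smaller k"
        )
    n = values.shape[0]
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    span = _feature_ranges(values)
    z = values / span  # constant columns become 0 via inf span
    dist = cdist(z, z, metric="cityblock")
    np.fill_diagonal(dist, np.inf)

    if cfg.m == "all":
        probes = np.arange(n)
    else:
        rng = np.random.default_rng(cfg.seed)
        probes = rng.choice(n, size=cfg.m, replace=cfg.m > n)
    m = len(probes)

    class_idx = {c: np.where(y == c)[0] for c in classes}
    omega = np.zeros(values.shape[1])
    for s in probes:
        cl = y[s]
        zdiff = np.abs(z - z[s])  # n x p, diff of every sample vs the probe
        for c in classes:
            members = class_idx[c]
            if c == cl:
                members = members[members != s]
            # nearest first, ties broken by lowest sample index
            order = members[np.lexsort((members, dist[s, members]))][: cfg.k]
            contrib = zdiff[order].sum(axis=0)
            if c == cl:
                omega -= contrib  # k nearest hits should be close
            else:
                omega += priors[c] / (1.0 - priors[cl]) * contrib
    omega /= m * cfg.k
    return FeatureWeights(omega=omega, priors={str(c): p for c, p in priors.items()},
                          labels=list(fm.labels))


def select_features(
    fm: FeatureMatrix, w: FeatureWeights, cfg: ReliefFConfig
) -> FeatureMatrix:
    """Keep columns by weight: strict threshold or the n largest.

    Threshold mode keeps ω > threshold (so irrelevant features at exactly the
    default threshold 0 are dropped); if nothing clears it, the single
    best-weighted column is kept so downstream classifiers always see input.
    Top-n ties are broken by column order.
    """
    if len(w.omega) != fm.n_features:
        raise ValueError("weights are not aligned to the feature columns")
    if cfg.mode == "top_n":
        if cfg.n_keep is None or cfg.n_keep > fm.n_features:
            raise ValueError(
                f"n_keep={cfg.n_keep} invalid for {fm.n_features} features"
            )
        order = np.lexsort((np.arange(len(w.omega)), -w.omega))[: cfg.n_keep]
        keep = np.sort(order)
    else:
        mask = w.omega > cfg.threshold
        if not mask.any():
            warnings.warn(
                "no feature weight exceeds the threshold; keeping the best one",
                stacklevel=2,
            )
            mask[int(np.argmax(w.omega))] = True
        keep = np.where(mask)[0]
    return fm.select_columns(keep)


@dataclass
class NormalizedReliefFResult:
    """Selected feature table plus the intermediate fusion artifacts."""

    selected: FeatureMatrix
    weights: FeatureWeights
    fused: FeatureMatrix
    kept: np.ndarray  # boolean mask over the fused columns


def normalized_relieff(
    eeg_fm: FeatureMatrix,
    fnirs_fm: FeatureMatrix,
    cfg: ReliefFConfig | None = None,
) -> NormalizedReliefFResult:
    """The full fusion method: normalize → concatenate → ReliefF → select."""
    cfg = cfg or ReliefFConfig()
    fused = fuse_concat(minmax_normalize(eeg_fm), minmax_normalize(fnirs_fm))
    weights = relieff_weights(fused, cfg)
    selected = select_features(fused, weights, cfg)
    kept_names = set(selected.column_names())
    kept = np.array([name in kept_names for name in fused.column_names()])
    return NormalizedReliefFResult(selected=selected, weights=weights,
                                   fused=fused, kept=kept)
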