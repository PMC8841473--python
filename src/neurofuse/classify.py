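"""Cross-validated two-condition classification and the fusion ablation.

Six off-the-shelf classifiers (SVM, KNN, random forest, AdaBoost, Gaussian
naive Bayes, and a linear discriminant-analysis classifier) are evaluated
with stratified 5-fold cross-validation on the packaged 1 Hz feature rows.
All data-dependent preprocessing — min-max normalization statistics and
ReliefF weights — is fitted on the training folds only and applied to the
held-out fold, so reported accuracies are leakage-free.

``ablation_compare`` reproduces the four-method comparison grid (direct
splicing, normalization only, ReliefF only, Normalized-ReliefF) across all
six classifiers, with row and column averages.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import FeatureMatrix
from .fusion import (
    ReliefFConfig,
    fuse_concat,
    minmax_normalize,
    relieff_weights,
    select_features,
)

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "DEFAULT_CLASSIFIERS",
    "FUSION_METHODS",
    "build_classifier",
    "crossval_classify",
    "crossval_multimodal",
    "ablation_compare",
    "feature_set_table",
]

CLASSIFIER_NAMES = ("svm", "knn", "random_forest", "adaboost", "naive_bayes", "dac")
FUSION_METHODS = ("splicing", "normalize_only", "relieff_only", "normalized_relieff")

METHOD_DISPLAY = {
    "splicing": "Splicing",
    "normalize_only": "Only normalization",
    "relieff_only": "Only ReliefF",
    "normalized_relieff": "Normalized-ReliefF",
}
CLASSIFIER_DISPLAY = {
    "svm": "SVM",
    "knn": "KNN",
    "random_forest": "Random forest",
    "adaboost": "AdaBoosting",
    "naive_bayes": "Naive bayesian",
    "dac": "DAC",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the six classifiers with its hyperparameters."""

    name: str
    hyperparameters: tuple = ()  # (key, value) pairs; hashable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"classifier must be one of {CLASSIFIER_NAMES}, got {self.name!r}"
            )


DEFAULT_CLASSIFIERS: tuple[ClassifierSpec, ...] = tuple(
    ClassifierSpec(name) for name in CLASSIFIER_NAMES
)


def build_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    hp = dict(spec.hyperparameters)
    if spec.name == "svm":
        return SVC(C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
                   kernel=hp.get("kernel", "rbf"), random_state=spec.seed)
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    if spec.name == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=spec.seed,
            n_jobs=1,
        )
    if spec.name == "adaboost":
        return AdaBoostClassifier(
            n_estimators=hp.get("n_estimators", 50), random_state=spec.seed
        )
    if spec.name == "naive_bayes":
        return GaussianNB()
    if spec.name == "dac":
        return LinearDiscriminantAnalysis()
    raise AssertionError(spec.name)


@dataclass
class CVResult:
    """Per-fold and mean accuracies for one classifier under one method."""

    classifier: str
    method: str
    fold_accuracies: np.ndarray
    fold_assignment: np.ndarray  # fold index per row
    confusions: list[np.ndarray] = field(default_factory=list)
    wall_time_s: float = 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


class _FoldTransform:
    """Fits one fusion method on the training fold, applies it to any fold."""

    def __init__(self, method: str, relieff_cfg: ReliefFConfig | None):
        if method not in FUSION_METHODS + ("none",):
            raise ValueError(f"unknown fusion method {method!r}")
        self.method = method
        self.cfg = relieff_cfg or ReliefFConfig()

    def fit(self, eeg_tr: FeatureMatrix, fnirs_tr: FeatureMatrix | None):
        self._norm_stats = []
        parts = [p for p in (eeg_tr, fnirs_tr) if p is not None]
        if self.method in ("normalize_only", "normalized_relieff"):
            normed = []
            for p in parts:
                np_ = minmax_normalize(p)
                self._norm_stats.append(np_.minmax_stats)
                normed.append(np_)
            fused = _concat_all(normed)
        else:
            fused = _concat_all(parts)
            self._train_ranges = (fused.values.min(axis=0),
                                  fused.values.max(axis=0))
        if self.method in ("relieff_only", "normalized_relieff"):
            self._weights = relieff_weights(fused, self.cfg)
            selected = select_features(fused, self._weights, self.cfg)
            kept_names = set(selected.column_names())
            self._kept = np.array(
                [n in kept_names for n in fused.column_names()]
            )
        return self

    def transform(
        self, eeg: FeatureMatrix, fnirs: FeatureMatrix | None
    ) -> np.ndarray:
        parts = [p for p in (eeg, fnirs) if p is not None]
        if self.method in ("normalize_only", "normalized_relieff"):
            parts = [
                minmax_normalize(p, stats=s)
                for p, s in zip(parts, self._norm_stats)
            ]
        X = _concat_all(parts).values
        if self.method in ("relieff_only", "normalized_relieff"):
            X = X[:, self._kept]
        return X


def _concat_all(parts: list[FeatureMatrix]) -> FeatureMatrix:
    out = parts[0]
    for p in parts[1:]:
        out = fuse_concat(out, p)
    return out


def _row_subset(fm: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        fm.values[idx], fm.labels,
        y=fm.y[idx] if fm.y is not None else None, rate_hz=fm.rate_hz,
    )


def _run_cv(
    eeg_fm: FeatureMatrix,
    fnirs_fm: FeatureMatrix | None,
    spec: ClassifierSpec,
    method: str,
    folds: int,
    seed: int,
    relieff_cfg: ReliefFConfig | None,
) -> CVResult:
    y = np.asarray(eeg_fm.y)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    accs, confusions = [], []
    t0 = time.perf_counter()
    for f, (tr, te) in enumerate(skf.split(eeg_fm.values, y)):
        assignment[te] = f
        ft = _FoldTransform(method, relieff_cfg)
        ft.fit(_row_subset(eeg_fm, tr),
               _row_subset(fnirs_fm, tr) if fnirs_fm is not None else None)
        X_tr = ft.transform(
            _row_subset(eeg_fm, tr),
            _row_subset(fnirs_fm, tr) if fnirs_fm is not None else None)
        X_te = ft.transform(
            _row_subset(eeg_fm, te),
            _row_subset(fnirs_fm, te) if fnirs_fm is not None else None)
        clf = build_classifier(spec)
        clf.fit(X_tr, y[tr])
        pred = clf.predict(X_te)
        accs.append(float(np.mean(pred == y[te])))
        confusions.append(confusion_matrix(y[te], pred))
    return CVResult(
        classifier=spec.name,
        method=method,
        fold_accuracies=np.array(accs),
        fold_assignment=assignment,
        confusions=confusions,
        wall_time_s=time.perf_counter() - t0,
    )


def crossval_classify(
    fm: FeatureMatrix,
    spec: ClassifierSpec,
    folds: int = 5,
    seed: int = 0,
    method: str = "none",
    relieff_cfg: ReliefFConfig | None = None,
) -> CVResult:
    """Stratified k-fold CV of one classifier on a single feature table.

    ``method`` optionally applies a fusion/selection step fitted per training
    fold ("none" uses the table as-is).
    """
    return _run_cv(fm, None, spec, method, folds, seed, relieff_cfg)


def crossval_multimodal(
    eeg_fm: FeatureMatrix,
    fnirs_fm: FeatureMatrix,
    spec: ClassifierSpec,
    method: str = "normalized_relieff",
    folds: int = 5,
    seed: int = 0,
    relieff_cfg: ReliefFConfig | None = None,
) -> CVResult:
    """Stratified k-fold CV with a two-modality fusion method per fold."""
    return _run_cv(eeg_fm, fnirs_fm, spec, method, folds, seed, relieff_cfg)


def _with_averages(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["Averaged accuracy"] = out.mean(axis=1)
    out.loc["Averaged accuracy"] = out.mean(axis=0)
    return out


def ablation_compare(
    eeg_fm: FeatureMatrix,
    fnirs_fm: FeatureMatrix,
    methods: tuple[str, ...] = FUSION_METHODS,
    specs: tuple[ClassifierSpec, ...] = DEFAULT_CLASSIFIERS,
    folds: int = 5,
    seed: int = 0,
    relieff_cfg: ReliefFConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """The methods x classifiers mean-accuracy grid with averages.

    Returns ``(table, details)``: the table has one row per classifier and
    one column per fusion method plus "Averaged accuracy" row and column;
    ``details`` maps (method, classifier) to the full CVResult (including
    per-method wall time).
    """
    cells: dict[str, dict[str, float]] = {}
    details: dict[tuple[str, str], CVResult] = {}
    for method in methods:
        col = METHOD_DISPLAY.get(method, method)
        cells[col] = {}
        for spec in specs:
            res = crossval_multimodal(
                eeg_fm, fnirs_fm, spec, method=method, folds=folds, seed=seed,
                relieff_cfg=relieff_cfg,
            )
            cells[col][CLASSIFIER_DISPLAY.get(spec.name, spec.name)] = (
                res.mean_accuracy
            )
            details[(method, spec.name)] = res
    rows = [CLASSIFIER_DISPLAY.get(s.name, s.name) for s in specs]
    df = pd.DataFrame(cells).loc[rows]
    return _with_averages(df), details


def feature_set_table(
    fm: FeatureMatrix,
    feature_sets: dict[str, np.ndarray],
    specs: tuple[ClassifierSpec, ...] = DEFAULT_CLASSIFIERS,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Classifiers x feature-subset mean-accuracy grid with averages.

    ``feature_sets`` maps a display name to a boolean column mask over
    ``fm``'s columns (e.g. the per-family EEG subsets, or the per-chromophore
    fNIRS subsets).  Features are min-max normalized per training fold.
    """
    cells: dict[str, dict[str, float]] = {}
    for set_name, mask in feature_sets.items():
        sub = fm.select_columns(np.where(mask)[0])
        cells[set_name] = {}
        for spec in specs:
            res = crossval_classify(
                sub, spec, folds=folds, seed=seed, method="normalize_only"
            )
            cells[set_name][CLASSIFIER_DISPLAY.get(spec.name, spec.name)] = (
                res.mean_accuracy
            )
    rows = [CLASSIFIER_DISPLAY.get(s.name, s.name) for s in specs]
    return _with_averages(pd.DataFrame(cells).loc[rows])


def eeg_feature_sets(fm: FeatureMatrix) -> dict[str, np.ndarray]:
    """The six EEG column subsets: DE, PSD, Statistic, Wavelet entropy, RASM,
    and all EEG features combined."""
    fams = np.array([l.family for l in fm.labels])
    return {
        "DE": fams == "de",
        "PSD": fams == "psd",
        "Statistic": fams == "statistic",
        "Wavelet entropy": fams == "swt",
        "RASM": fams == "rasm",
        "Combined features": np.ones(len(fams), dtype=bool),
    }


def fnirs_feature_sets(fm: FeatureMatrix) -> dict[str, np.ndarray]:
    """The four fNIRS column subsets by family and chromophore."""
    fams = np.array([l.family for l in fm.labels])
    chrom = np.array([l.band.split(".")[0] for l in fm.labels])
    return {
        "Statistic (HbO)": (fams == "hemo_stat") & (chrom == "hbo"),
        "GLM (HbO)": (fams == "glm_beta") & (chrom == "hbo"),
        "Statistic (Hb)": (fams == "hemo_stat") & (chrom == "hbr"),
        "GLM (Hb)": (fams == "glm_beta") & (chrom == "hbr"),
    }
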