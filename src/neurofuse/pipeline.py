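"""End-to-end orchestration: simulate/load → preprocess → features → fuse →
classify, driven by a single TOML config, with a JSON run report.

The pipeline reproduces the full study workflow on one session: both
modalities are preprocessed, the two stimulus epochs are packaged into 1 Hz
feature tables, the channel-wise HbO condition contrast is computed, and the
three results grids are written — EEG feature sets x classifiers, fNIRS
feature sets x classifiers, and fusion methods x classifiers — each with row
and column averages.  Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify as clf
from .containers import EEG, FeatureMatrix, Recording, write_events_tsv
from .eeg_features import extract_eeg_features
from .fnirs_features import channel_contrast, extract_fnirs_features
from .fusion import ReliefFConfig, normalized_relieff
from .io_preprocess import (
    bandpass_filter,
    baseline_correct,
    common_average_reference,
    load_recording,
    mbll_convert,
    save_recording,
    segment_epoch,
)
from .synthetic import SimConfig, simulate_session

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("neurofuse")


@dataclass
class RunConfig:
    """Validated pipeline configuration (one TOML file, per-stage sections)."""

    seed: int = 0
    out_dir: str = "neurofuse_out"
    # input
    mode: str = "simulate"  # or "load"
    eeg_path: str | None = None
    eeg_format: str = "internal"
    fnirs_path: str | None = None
    fnirs_format: str = "internal"
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    # preprocessing
    eeg_band: tuple[float, float] = (0.5, 50.0)
    fnirs_band: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 4
    epoch_window: tuple[float, float] = (5.0, 205.0)
    baseline_s: float = 10.0
    # features
    window_s: float = 1.0
    glm_context_s: float = 20.0
    hrf: str = "none"
    glm_design: str = "sliding"
    # fusion
    relieff: dict = field(default_factory=dict)  # ReliefFConfig overrides
    # classification
    classifiers: tuple[str, ...] = clf.CLASSIFIER_NAMES
    folds: int = 5
    modalities: tuple[str, ...] = ("eeg", "fnirs")

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        bad = [c for c in self.classifiers if c not in clf.CLASSIFIER_NAMES]
        if bad:
            raise ValueError(f"unknown classifiers {bad}")
        bad = [m for m in self.modalities if m not in ("eeg", "fnirs")]
        if bad:
            raise ValueError(f"unknown modalities {bad}")
        if self.mode == "load":
            for name, path in (("eeg", self.eeg_path), ("fnirs", self.fnirs_path)):
                if name in self.modalities and (path is None or not Path(path).exists()):
                    raise ValueError(f"{name} input path missing: {path}")
        # fail on typos inside the nested sections
        sim_keys = set(SimConfig.__dataclass_fields__)
        unknown = set(self.simulate) - sim_keys
        if unknown:
            raise ValueError(f"unknown [simulate] keys: {sorted(unknown)}")
        rf_keys = set(ReliefFConfig.__dataclass_fields__)
        unknown = set(self.relieff) - rf_keys
        if unknown:
            raise ValueError(f"unknown [relieff] keys: {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a TOML config; any unrecognized key is an error."""
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    flat: dict = {}
    known = set(RunConfig.__dataclass_fields__)
    for key, value in raw.items():
        if isinstance(value, dict) and key not in ("simulate", "relieff"):
            for k, v in value.items():
                if k not in known:
                    raise ValueError(f"unknown config key [{key}].{k}")
                flat[k] = tuple(v) if isinstance(v, list) else v
        else:
            if key not in known:
                raise ValueError(f"unknown config key {key}")
            flat[key] = tuple(value) if isinstance(value, list) and key in (
                "classifiers", "modalities") else value
    for tup_key in ("eeg_band", "fnirs_band", "epoch_window"):
        if tup_key in flat and isinstance(flat[tup_key], list):
            flat[tup_key] = tuple(flat[tup_key])
    return RunConfig(**flat)


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def preprocess_eeg(rec: Recording, cfg: RunConfig) -> list:
    """CAR → 0.5-50 Hz zero-phase band-pass → epoch → baseline-correct."""
    rec = common_average_reference(rec)
    rec = bandpass_filter(rec, *cfg.eeg_band, order=cfg.filter_order)
    epochs = []
    for ev in rec.events:
        ep = segment_epoch(rec, ev, *cfg.epoch_window)
        epochs.append(baseline_correct(ep, rec, cfg.baseline_s))
    return epochs


def preprocess_fnirs(rec: Recording, cfg: RunConfig) -> list:
    """0.01-0.1 Hz band-pass (about the mean) → MBLL → epoch → baseline."""
    rec = bandpass_filter(rec, *cfg.fnirs_band, order=cfg.filter_order,
                          keep_mean=True)
    hemo = mbll_convert(rec)
    epochs = []
    for ev in hemo.events:
        ep = segment_epoch(hemo, ev, *cfg.epoch_window)
        epochs.append(baseline_correct(ep, hemo, cfg.baseline_s))
    return epochs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write all artifacts; returns the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(asdict(cfg)), "stages": {}}
    rng_seed = int(cfg.seed)

    t0 = _stage("input")
    if cfg.mode == "simulate":
        sim = SimConfig(seed=rng_seed, **cfg.simulate)
        eeg_rec, fnirs_rec, _truth = simulate_session(sim)
    else:
        eeg_rec = (load_recording(cfg.eeg_path, cfg.eeg_format)
                   if "eeg" in cfg.modalities else None)
        fnirs_rec = (load_recording(cfg.fnirs_path, cfg.fnirs_format)
                     if "fnirs" in cfg.modalities else None)
    if "eeg" in cfg.modalities:
        save_recording(eeg_rec, out / "eeg_recording")
        write_events_tsv(eeg_rec.events, out / "events.tsv")
    if "fnirs" in cfg.modalities:
        save_recording(fnirs_rec, out / "fnirs_recording")
        if "eeg" not in cfg.modalities:
            write_events_tsv(fnirs_rec.events, out / "events.tsv")
    report["stages"]["input"] = {"seconds": time.perf_counter() - t0}

    eeg_fm = fnirs_fm = None
    try:
        if "eeg" in cfg.modalities:
            t0 = _stage("eeg features")
            eeg_epochs = preprocess_eeg(eeg_rec, cfg)
            eeg_fm = FeatureMatrix.vstack(
                [extract_eeg_features(ep, window_s=cfg.window_s)
                 for ep in eeg_epochs]
            )
            eeg_fm.save(out / "eeg_features.tsv")
            report["stages"]["eeg_features"] = {
                "seconds": time.perf_counter() - t0,
                "shape": list(eeg_fm.shape),
            }
        if "fnirs" in cfg.modalities:
            t0 = _stage("fnirs features")
            fnirs_epochs = preprocess_fnirs(fnirs_rec, cfg)
            fnirs_fm = FeatureMatrix.vstack(
                [extract_fnirs_features(
                    ep, window_s=cfg.window_s, context_s=cfg.glm_context_s,
                    hrf=cfg.hrf, design=cfg.glm_design)
                 for ep in fnirs_epochs]
            )
            fnirs_fm.save(out / "fnirs_features.tsv")
            report["stages"]["fnirs_features"] = {
                "seconds": time.perf_counter() - t0,
                "shape": list(fnirs_fm.shape),
            }
            # channel-wise HbO condition contrast over packaged window means
            sets = clf.fnirs_feature_sets(fnirs_fm)
            hbo_mu = np.where(
                sets["Statistic (HbO)"]
                & np.array([l.band.endswith(".mu") for l in fnirs_fm.labels])
            )[0]
            conds = np.unique(fnirs_fm.y)
            if len(conds) == 2:
                a = fnirs_fm.values[fnirs_fm.y == conds[1]][:, hbo_mu]
                b = fnirs_fm.values[fnirs_fm.y == conds[0]][:, hbo_mu]
                cmap = channel_contrast(
                    a, b, channels=[fnirs_fm.labels[i].channel for i in hbo_mu]
                )
                cmap.save(out / "hbo_contrast.tsv")
                report["stages"]["hbo_contrast"] = {
                    "n_significant": int(cmap.significant.sum()),
                    "comparison": f"{conds[1]} - {conds[0]}",
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during feature stage: {exc}") from exc

    specs = tuple(
        clf.ClassifierSpec(name, seed=rng_seed) for name in cfg.classifiers
    )
    rf_cfg = ReliefFConfig(**{"seed": rng_seed, **cfg.relieff})
    tables: dict[str, object] = {}

    if eeg_fm is not None:
        t0 = _stage("table 1 (EEG feature sets)")
        tables["eeg_feature_sets"] = clf.feature_set_table(
            eeg_fm, clf.eeg_feature_sets(eeg_fm), specs, cfg.folds, rng_seed
        )
    if fnirs_fm is not None:
        t0 = _stage("table 2 (fNIRS feature sets)")
        tables["fnirs_feature_sets"] = clf.feature_set_table(
            fnirs_fm, clf.fnirs_feature_sets(fnirs_fm), specs, cfg.folds,
            rng_seed,
        )
    if eeg_fm is not None and fnirs_fm is not None:
        t0 = _stage("table 3 (fusion ablation)")
        table3, details = clf.ablation_compare(
            eeg_fm, fnirs_fm, specs=specs, folds=cfg.folds, seed=rng_seed,
            relieff_cfg=rf_cfg,
        )
        tables["fusion_methods"] = table3
        report["stages"]["ablation"] = {
            "wall_time_s": {
                m: sum(r.wall_time_s for (mm, _), r in details.items() if mm == m)
                for m in clf.FUSION_METHODS
            }
        }
        # pooled fusion artifacts for inspection
        fused = normalized_relieff(eeg_fm, fnirs_fm, rf_cfg)
        wf = fused.weights.to_frame()
        wf["kept"] = fused.kept
        wf.to_csv(out / "relieff_weights.tsv", sep="\t", index=False)
        report["fusion"] = {
            "n_fused_features": fused.fused.n_features,
            "n_selected_features": fused.selected.n_features,
        }

    for name, df in tables.items():
        df.to_csv(out / f"table_{name}.tsv", sep="\t")
        report.setdefault("tables", {})[name] = json.loads(
            df.to_json(orient="split")
        )

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("report written to %s", report_path)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
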