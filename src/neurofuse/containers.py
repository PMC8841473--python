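"""Shared in-memory containers for multimodal recordings and feature tables.

A :class:`Recording` holds one modality's continuous data (EEG in µV, fNIRS
either as raw dual-wavelength intensities or as chromophore concentrations in
µM) together with its sampling rate, channel names and event markers.  An
:class:`Epoch` is a condition-labelled stimulus window cut from a recording.
A :class:`FeatureMatrix` is the 1 Hz sample-packaged feature table that the
fusion and classification stages operate on: rows are packaged samples,
columns carry a structured (modality, channel, family, band) label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EEG = "eeg"
FNIRS_RAW = "fnirs_raw"
FNIRS_HEMO = "fnirs_hemo"
MODALITIES = (EEG, FNIRS_RAW, FNIRS_HEMO)

CONDITIONS = ("rest", "neutral", "preferred")

LABEL_SEP = "|"


@dataclass(frozen=True)
class EventMarker:
    """A stimulus/rest block: onset and duration in seconds from recording start."""

    onset_s: float
    label: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration_s}")
        if self.label not in CONDITIONS:
            raise ValueError(
                f"event label must be one of {CONDITIONS}, got {self.label!r}"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def check_events_nonoverlapping(events: Sequence[EventMarker]) -> None:
    ordered = sorted(events, key=lambda e: e.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if a.end_s > b.onset_s + 1e-9:
            raise ValueError(
                f"events overlap: {a.label} [{a.onset_s}, {a.end_s}) and "
                f"{b.label} starting at {b.onset_s}"
            )


@dataclass
class Recording:
    """Continuous multichannel time series of one modality.

    ``data`` is channels x samples.  For ``fnirs_raw`` the two wavelengths are
    stored as two stacked blocks of ``n_sites`` channels each (channel names
    carry the wavelength suffix) and ``wavelengths_nm`` / ``sd_distance_cm``
    are populated.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    modality: str
    events: list[EventMarker] = field(default_factory=list)
    wavelengths_nm: tuple[float, float] | None = None
    sd_distance_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples (2-D)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == FNIRS_RAW:
            if self.wavelengths_nm is None or len(self.wavelengths_nm) != 2:
                raise ValueError("fnirs_raw requires exactly 2 wavelengths")
        check_events_nonoverlapping(self.events)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        out = replace(self, **kw)
        return out


@dataclass
class Epoch:
    """A condition-labelled stimulus window.

    ``window_s`` is (t_start, t_end) relative to the stimulus onset;
    ``onset_s`` keeps the absolute onset so baseline correction can find the
    pre-stimulus interval in the parent recording.
    """

    data: np.ndarray
    fs: float
    condition: str
    window_s: tuple[float, float]
    channel_names: list[str]
    modality: str
    onset_s: float
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels x samples")
        if self.condition not in ("neutral", "preferred", "rest"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class FeatureLabel:
    """Structured column label: (modality, channel-or-pair, family, band).

    ``band`` doubles as the component slot: a frequency band for psd/de,
    a statistic name (mu, var, d1, ...) for the time-domain family, a
    chromophore (hbo/hbr) prefix for fNIRS families, and the underlying
    feature key for RASM ratios.
    """

    modality: str
    channel: str
    family: str
    band: str = ""

    def __str__(self) -> str:
        return LABEL_SEP.join((self.modality, self.channel, self.family, self.band))

    @classmethod
    def parse(cls, s: str) -> "FeatureLabel":
        parts = s.split(LABEL_SEP)
        if len(parts) != 4:
            raise ValueError(f"not a feature label: {s!r}")
        return cls(*parts)


class FeatureMatrix:
    """Sample-packaged feature table: rows at a common rate, labelled columns."""

    def __init__(
        self,
        values: np.ndarray,
        labels: Sequence[FeatureLabel],
        y: Sequence[str] | None = None,
        rate_hz: float = 1.0,
    ) -> None:
        self.values = np.asarray(values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be samples x features")
        self.labels = list(labels)
        if self.values.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.labels)} labels"
            )
        names = [str(l) for l in self.labels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate column labels: {dupes[:5]}")
        if y is not None:
            y = np.asarray(y, dtype=object)
            if y.shape[0] != self.values.shape[0]:
                raise ValueError("y length does not match row count")
        self.y = y
        self.rate_hz = float(rate_hz)
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    # -- basic protocol ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_names(self) -> list[str]:
        return [str(l) for l in self.labels]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names())
        if self.y is not None:
            df.insert(0, "condition", self.y)
        return df

    @classmethod
    def vstack(cls, parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Stack tables row-wise (e.g. the two conditions' epochs).

        All parts must share the same column labels in the same order.
        """
        if not parts:
            raise ValueError("nothing to stack")
        first = parts[0]
        for p in parts[1:]:
            if p.column_names() != first.column_names():
                raise ValueError("cannot stack tables with different columns")
        ys = [p.y for p in parts]
        y = np.concatenate(ys) if all(v is not None for v in ys) else None
        return cls(
            np.concatenate([p.values for p in parts], axis=0),
            first.labels,
            y=y,
            rate_hz=first.rate_hz,
        )

    def select_columns(self, idx: Iterable[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            self.values[:, idx],
            [self.labels[i] for i in idx],
            y=self.y,
            rate_hz=self.rate_hz,
        )

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a TSV of values (+condition column) and a JSON label sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        sidecar = {
            "rate_hz": self.rate_hz,
            "labels": [vars(l) for l in self.labels],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        labels = [FeatureLabel(**d) for d in meta["labels"]]
        y = df["condition"].to_numpy() if "condition" in df.columns else None
        vals = df[[str(l) for l in labels]].to_numpy(dtype=np.float64)
        return cls(vals, labels, y=y, rate_hz=meta["rate_hz"])


# ---------------------------------------------------------------------------
# event-table TSV (onset_s, duration_s, label)
# ---------------------------------------------------------------------------

def write_events_tsv(events: Sequence[EventMarker], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "label": [e.label for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[EventMarker]:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    return [
        EventMarker(float(r.onset_s), str(r.label), float(r.duration_s))
        for r in df.itertuples()
    ]
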