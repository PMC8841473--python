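"""Readers, the internal container format, and the preprocessing chain.

The preprocessing chain mirrors standard multimodal practice for a
two-condition music-listening session: EEG is re-referenced to the common
average and band-passed 0.5-50 Hz; fNIRS raw intensities are band-passed
0.01-0.1 Hz (removing cardiac ~1 Hz, respiratory ~0.2 Hz and Mayer-wave
~0.1 Hz physiological oscillations), converted to oxy-/deoxy-hemoglobin
concentration changes through the modified Beer-Lambert law, and baseline
corrected against the 10 s preceding each stimulus.  Both modalities are
segmented to the 5-205 s post-onset stimulus window.

All filters are applied forward-backward (zero phase) so that filtering never
shifts event latencies relative to the marker table.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy import signal

from .containers import (
    EEG,
    FNIRS_HEMO,
    FNIRS_RAW,
    CONDITIONS,
    Epoch,
    EventMarker,
    Recording,
)

__all__ = [
    "load_recording",
    "save_recording",
    "common_average_reference",
    "bandpass_filter",
    "mbll_convert",
    "mbll_forward",
    "segment_epoch",
    "baseline_correct",
    "DEFAULT_EXTINCTION",
    "DEFAULT_DPF",
]

# Molar extinction coefficients, cm^-1 M^-1 (compiled in vivo hemoglobin
# spectra; overridable wherever they are consumed).
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    # wavelength_nm: (eps_HbO, eps_Hb)
    690.0: (276.0, 2051.96),
    760.0: (586.0, 1548.52),
    800.0: (816.0, 761.72),
    830.0: (974.0, 693.04),
    850.0: (1058.0, 691.32),
}

# Differential pathlength factor, dimensionless, same at both wavelengths by
# default (adult head, typical literature value).
DEFAULT_DPF: float = 6.0


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write the internal single-file container (bit-exact round trip)."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "modality": rec.modality,
        "events": [
            {"onset_s": e.onset_s, "label": e.label, "duration_s": e.duration_s}
            for e in rec.events
        ],
        "wavelengths_nm": list(rec.wavelengths_nm) if rec.wavelengths_nm else None,
    }
    arrays = {"data": rec.data, "meta_json": np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)}
    if rec.sd_distance_cm is not None:
        arrays["sd_distance_cm"] = np.asarray(rec.sd_distance_cm, dtype=np.float64)
    np.savez(path, **arrays)
    # np.savez appends .npz when missing
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _load_internal(path: Path) -> Recording:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        data = npz["data"]
        sd = npz["sd_distance_cm"] if "sd_distance_cm" in npz.files else None
    return Recording(
        data=data,
        fs=meta["fs"],
        channel_names=list(meta["channel_names"]),
        modality=meta["modality"],
        events=[EventMarker(e["onset_s"], e["label"], e["duration_s"])
                for e in meta["events"]],
        wavelengths_nm=tuple(meta["wavelengths_nm"]) if meta["wavelengths_nm"] else None,
        sd_distance_cm=sd,
    )


def _events_from_annotations(onsets, durations, descriptions) -> list[EventMarker]:
    events = []
    for onset, dur, desc in zip(onsets, durations, descriptions):
        # BrainVision markers arrive as "Stimulus/<label>"
        label = str(desc).split("/")[-1].strip().lower()
        if label in CONDITIONS and dur > 0:
            events.append(EventMarker(float(onset), label, float(dur)))
    return events


def _load_mne(path: Path, fmt: str) -> Recording:
    import mne

    readers = {
        "brainvision": mne.io.read_raw_brainvision,
        "edf": mne.io.read_raw_edf,
    }
    try:
        raw = readers[fmt](path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalized error contract
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns SI volts
    events = _events_from_annotations(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    )
    if not events:
        warnings.warn(f"no condition events found in {path.name}", stacklevel=3)
    return Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        modality=EEG,
        events=events,
    )


def _load_snirf(path: Path) -> Recording:
    """Minimal SNIRF (HDF5 layout) reader for raw dual-wavelength intensity."""
    import h5py

    def _scalar(x):
        x = np.asarray(x)
        return x.item() if x.size == 1 else x

    try:
        with h5py.File(path, "r") as f:
            nirs = f["/nirs1"] if "nirs1" in f else f["/nirs"]
            d1 = nirs["data1"]
            ts = np.asarray(d1["dataTimeSeries"], dtype=np.float64)  # time x ch
            time = np.asarray(d1["time"], dtype=np.float64)
            wavelengths = np.asarray(nirs["probe"]["wavelengths"], dtype=np.float64)
            n_ch = ts.shape[1]
            wl_index = np.empty(n_ch, dtype=int)
            src = np.empty(n_ch, dtype=int)
            det = np.empty(n_ch, dtype=int)
            for j in range(n_ch):
                ml = d1[f"measurementList{j + 1}"]
                wl_index[j] = int(_scalar(ml["wavelengthIndex"][()]))
                src[j] = int(_scalar(ml["sourceIndex"][()]))
                det[j] = int(_scalar(ml["detectorIndex"][()]))
            events = []
            for key in sorted(k for k in nirs if k.startswith("stim")):
                stim = nirs[key]
                name = stim["name"][()]
                if isinstance(name, bytes):
                    name = name.decode()
                name = str(name).strip().lower()
                sdata = np.atleast_2d(np.asarray(stim["data"], dtype=np.float64))
                for row in sdata:
                    if name in CONDITIONS and row[1] > 0:
                        events.append(EventMarker(float(row[0]), name, float(row[1])))
    except (OSError, KeyError) as exc:
        raise ValueError(f"cannot parse {path} as SNIRF: {exc}") from exc

    if len(time) == 2:  # SNIRF start/step shorthand
        fs = 1.0 / time[1]
    else:
        fs = 1.0 / float(np.median(np.diff(time)))
    if len(wavelengths) != 2:
        raise ValueError(f"expected 2 wavelengths, found {len(wavelengths)}")
    # order channels as [wavelength-1 block, wavelength-2 block], each block
    # sorted by (source, detector) so both blocks align site-for-site
    order = np.lexsort((det, src, wl_index))
    names = [
        f"S{src[j]}-D{det[j]}_{wavelengths[wl_index[j] - 1]:.0f}nm" for j in order
    ]
    if not events:
        warnings.warn(f"no condition events found in {path.name}", stacklevel=3)
    return Recording(
        data=ts.T[order],
        fs=fs,
        channel_names=names,
        modality=FNIRS_RAW,
        events=events,
        wavelengths_nm=(float(wavelengths[0]), float(wavelengths[1])),
        sd_distance_cm=np.full(n_ch // 2, 3.0),
    )


def load_recording(path: str | Path, format: str) -> Recording:
    """Read a recording from disk.

    ``format`` is one of ``brainvision``, ``edf``, ``snirf``, ``internal``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "internal":
        return _load_internal(path)
    if format in ("brainvision", "edf"):
        return _load_mne(path, format)
    if format == "snirf":
        return _load_snirf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def common_average_reference(rec: Recording) -> Recording:
    """Re-reference EEG to the common average (per-sample channel mean = 0)."""
    if rec.modality != EEG:
        raise ValueError("CAR applies to EEG recordings")
    if rec.n_channels < 2:
        raise ValueError("CAR undefined for a single channel")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def design_bandpass(low_hz: float, high_hz: float, order: int, fs: float):
    """Butterworth band-pass as second-order sections (shared with tests)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={fs} (Nyquist {fs / 2})"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_filter(
    rec: Recording,
    low_hz: float,
    high_hz: float,
    order: int = 4,
    keep_mean: bool = False,
) -> Recording:
    """Zero-phase Butterworth band-pass applied along time.

    With ``keep_mean`` the per-channel mean is re-added after filtering, i.e.
    fluctuations around the mean are band-passed.  This is how the 0.01-0.1 Hz
    filter is applied to raw fNIRS intensities, which must stay positive for
    the Beer-Lambert log that follows.
    """
    sos = design_bandpass(low_hz, high_hz, order, rec.fs)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if keep_mean:
        data = data + rec.data.mean(axis=1, keepdims=True)
    return rec.copy_with(data=np.ascontiguousarray(data))


def _extinction_at(wavelength_nm: float,
                   table: dict[float, tuple[float, float]]) -> tuple[float, float]:
    """(eps_HbO, eps_Hb) at a wavelength, linearly interpolated in the table."""
    wl = sorted(table)
    if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside extinction table "
            f"[{wl[0]}, {wl[-1]}]"
        )
    eps_hbo = np.interp(wavelength_nm, wl, [table[w][0] for w in wl])
    eps_hb = np.interp(wavelength_nm, wl, [table[w][1] for w in wl])
    return float(eps_hbo), float(eps_hb)


def _mbll_matrix(wavelengths, dpf, distances_cm, extinction):
    """Per-site 2x2 systems mapping (dHbO, dHb) in µM to dOD at the 2 λ."""
    if np.isscalar(dpf):
        dpf = (float(dpf), float(dpf))
    eps = np.array([_extinction_at(w, extinction) for w in wavelengths])  # 2x2
    # rows: wavelength; cols: chromophore.  1e-6: µM -> M.
    a = eps * np.asarray(dpf)[:, None] * 1e-6  # 2x2, per unit distance
    if abs(np.linalg.det(a)) < 1e-12 * np.abs(a).max() ** 2:
        raise ValueError(
            f"extinction system singular for wavelengths {tuple(wavelengths)}; "
            "choose more separated wavelengths"
        )
    return a, np.asarray(distances_cm, dtype=np.float64)


def mbll_forward(
    hbo: np.ndarray,
    hb: np.ndarray,
    wavelengths_nm: tuple[float, float],
    sd_distance_cm: np.ndarray,
    dpf: float | tuple[float, float] = DEFAULT_DPF,
    extinction: dict | None = None,
    i_ref: float = 1.0,
) -> np.ndarray:
    """Chromophore concentrations (µM, sites x time) -> raw intensities.

    Returns a (2*n_sites) x time array ordered [λ1 block, λ2 block], the
    modified Beer-Lambert forward model ``I = I_ref * 10**(-ΔOD)``.
    """
    extinction = extinction or DEFAULT_EXTINCTION
    a, d = _mbll_matrix(wavelengths_nm, dpf, sd_distance_cm, extinction)
    conc = np.stack([hbo, hb])  # 2 x sites x time
    dod = np.einsum("wc,cst->wst", a, conc) * d[None, :, None]
    intensity = i_ref * 10.0 ** (-dod)
    return intensity.reshape(-1, hbo.shape[1])


def mbll_convert(
    rec: Recording,
    dpf: float | tuple[float, float] = DEFAULT_DPF,
    extinction: dict | None = None,
    i_ref: str | float | np.ndarray = "mean",
) -> Recording:
    """Raw dual-wavelength intensities -> ΔHbO/ΔHb concentration changes (µM).

    The reference intensity defaults to each channel's mean over the full
    recording (``i_ref="mean"``); a scalar or per-channel array pins it
    explicitly.  Output channels are ordered [HbO block, Hb block] over the
    same sites.
    """
    if rec.modality != FNIRS_RAW:
        raise ValueError("mbll_convert expects a raw fNIRS recording")
    if np.any(rec.data <= 0):
        raise ValueError("non-positive light intensity; cannot take log")
    n_sites = rec.n_channels // 2
    if rec.sd_distance_cm is None:
        raise ValueError("source-detector distances required for MBLL")
    extinction = extinction or DEFAULT_EXTINCTION
    a, d = _mbll_matrix(rec.wavelengths_nm, dpf, rec.sd_distance_cm, extinction)

    if isinstance(i_ref, str):
        if i_ref != "mean":
            raise ValueError(f"unknown i_ref {i_ref!r}")
        ref = rec.data.mean(axis=1, keepdims=True)
    else:
        ref = np.asarray(i_ref, dtype=np.float64).reshape(-1, 1)
        if ref.shape[0] == 1:
            ref = np.broadcast_to(ref, (rec.n_channels, 1))
    dod = -np.log10(rec.data / ref)  # (2*sites) x time
    dod = dod.reshape(2, n_sites, -1)
    a_inv = np.linalg.inv(a)
    conc = np.einsum("cw,wst->cst", a_inv, dod) / d[None, :, None]  # µM

    site_names = [n.rsplit("_", 1)[0] for n in rec.channel_names[:n_sites]]
    names = [f"{n}_hbo" for n in site_names] + [f"{n}_hbr" for n in site_names]
    return Recording(
        data=conc.reshape(-1, rec.n_samples),
        fs=rec.fs,
        channel_names=names,
        modality=FNIRS_HEMO,
        events=list(rec.events),
        sd_distance_cm=rec.sd_distance_cm,
    )


def segment_epoch(
    rec: Recording,
    event: EventMarker,
    t_start: float = 5.0,
    t_end: float = 205.0,
) -> Epoch:
    """Cut the [onset+t_start, onset+t_end) stimulus window.

    Sample count is floor((t_end - t_start) * fs); windows are half-open with
    0-based sample indexing, the single rounding convention used at both the
    500 Hz EEG and 3.91 Hz fNIRS rates.
    """
    start = int(np.floor((event.onset_s + t_start) * rec.fs))
    n = int(np.floor((t_end - t_start) * rec.fs))
    if start + n > rec.n_samples:
        short = (start + n - rec.n_samples) / rec.fs
        raise ValueError(
            f"epoch window [{event.onset_s + t_start}, {event.onset_s + t_end}) s "
            f"exceeds the {rec.duration_s:.1f} s recording by {short:.2f} s"
        )
    return Epoch(
        data=rec.data[:, start:start + n].copy(),
        fs=rec.fs,
        condition=event.label,
        window_s=(t_start, t_end),
        channel_names=list(rec.channel_names),
        modality=rec.modality,
        onset_s=event.onset_s,
    )


def baseline_correct(
    epoch: Epoch, rec: Recording, baseline_s: float = 10.0
) -> Epoch:
    """Subtract each channel's mean over the ``baseline_s`` pre-onset interval.

    Not generally idempotent: the baseline interval lies outside the epoch, so
    re-application subtracts the (unchanged) pre-onset mean again.
    """
    if epoch.onset_s < baseline_s:
        raise ValueError(
            f"need {baseline_s} s before onset at {epoch.onset_s} s for baseline"
        )
    b0 = int(np.floor((epoch.onset_s - baseline_s) * rec.fs))
    b1 = int(np.floor(epoch.onset_s * rec.fs))
    baseline = rec.data[:, b0:b1].mean(axis=1, keepdims=True)
    return Epoch(
        data=epoch.data - baseline,
        fs=epoch.fs,
        condition=epoch.condition,
        window_s=epoch.window_s,
        channel_names=list(epoch.channel_names),
        modality=epoch.modality,
        onset_s=epoch.onset_s,
        baseline_corrected=True,
    )
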