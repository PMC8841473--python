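"""Minimal on-the-fly writers for the external recording formats.

These exist only to build reader fixtures at test time (the deliverable
carries no binary files); they write just enough of each standard for the
package's readers to parse.
"""

from pathlib import Path

import numpy as np


def write_edf(path: Path, data_uv: np.ndarray, fs: int,
              channel_names: list[str]) -> Path:
    """Write a minimal EDF file (1 s data records, int16 samples)."""
    n_ch, n_samp = data_uv.shape
    n_records = n_samp // fs
    phys_min, phys_max = -3200.0, 3200.0
    dig_min, dig_max = -32768, 32767

    def pad(s, width):
        return str(s)[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("12.00.00", 8),
        pad(256 + 256 * n_ch, 8), pad("", 44),
        pad(n_records, 8), pad(1, 8), pad(n_ch, 4),
    ])
    fields = [
        [pad(name, 16) for name in channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(phys_min, 8)] * n_ch,
        [pad(phys_max, 8)] * n_ch,
        [pad(dig_min, 8)] * n_ch,
        [pad(dig_max, 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(fs, 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data_uv - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for field in fields:
            f.write(b"".join(field))
        for r in range(n_records):
            for ch in range(n_ch):
                f.write(digital[ch, r * fs:(r + 1) * fs].tobytes())
    return path


def write_brainvision(
    stem: Path,
    data_uv: np.ndarray,
    fs: float,
    channel_names: list[str],
    markers: list[tuple[float, str, float]] = (),
) -> Path:
    """Write a .vhdr/.vmrk/.eeg triplet (IEEE float32, multiplexed).

    ``markers`` are (onset_s, label, duration_s) stimulus markers.
    """
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = data_uv.shape[0]
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    lines += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(channel_names)]
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20200101120000000000",
    ]
    for i, (onset, label, dur) in enumerate(markers, start=2):
        pos = int(round(onset * fs)) + 1
        size = int(round(dur * fs))
        mlines.append(f"Mk{i}=Stimulus,{label},{pos},{size},0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    data_uv.astype("<f4").T.tofile(eeg)
    return vhdr


def write_snirf(
    path: Path,
    intensities: np.ndarray,
    fs: float,
    wavelengths: tuple[float, float],
    stims: list[tuple[float, str, float]] = (),
) -> Path:
    """Write a minimal SNIRF (HDF5) raw-intensity file.

    ``intensities`` is (2*n_sites) x time ordered [λ1 block, λ2 block]; each
    site i becomes source i+1 / detector i+1.
    """
    import h5py

    n_ch, n_t = intensities.shape
    n_sites = n_ch // 2
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=intensities.T)
        d1.create_dataset("time", data=np.arange(n_t) / fs)
        for j in range(n_ch):
            ml = d1.create_group(f"measurementList{j + 1}")
            site = j % n_sites
            ml.create_dataset("sourceIndex", data=site + 1)
            ml.create_dataset("detectorIndex", data=site + 1)
            ml.create_dataset("wavelengthIndex", data=j // n_sites + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths))
        for s, (onset, label, dur) in enumerate(stims, start=1):
            stim = nirs.create_group(f"stim{s}")
            stim.create_dataset("name", data=label)
            stim.create_dataset("data", data=np.array([[onset, dur, 1.0]]))
    return path
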