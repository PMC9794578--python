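"""Test-only helpers: a minimal BrainVision fixture writer.

The package deliberately does not write vendor formats; tests need real
triplets on disk to exercise the reader, so a restricted writer lives here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_brainvision_fixture(directory: Path, name: str, data: np.ndarray,
                              channel_labels: list[str], sampling_rate: float,
                              binary_format: str = "INT_16",
                              resolution: float = 0.1,
                              markers: list[tuple[str, int]] = ()) -> Path:
    """Write a .vhdr/.vmrk/.eeg triplet; returns the header path.

    ``data`` is channels x samples in microvolts.  ``markers`` is a list of
    ``(description, sample_index)`` pairs written as Stimulus markers
    (positions are 1-based in the file format).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_ch = data.shape[0]
    vhdr = directory / f"{name}.vhdr"
    vmrk = directory / f"{name}.vmrk"
    eeg = directory / f"{name}.eeg"

    res_field = f"{resolution:g}" if binary_format == "INT_16" else "1"
    chan_lines = [f"Ch{i+1}={lab},,{res_field},µV"
                  for i, lab in enumerate(channel_labels)]
    vhdr.write_text("\n".join([
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Data created by the averp test suite (synthetic fixture)",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / sampling_rate:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
        *chan_lines,
    ]) + "\n", encoding="utf-8")

    marker_lines = ["Mk1=New Segment,,1,1,0"]
    for j, (desc, sample) in enumerate(markers, start=2):
        marker_lines.append(f"Mk{j}=Stimulus,{desc},{sample + 1},1,0")
    vmrk.write_text("\n".join([
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        *marker_lines,
    ]) + "\n", encoding="utf-8")

    if binary_format == "INT_16":
        raw = np.round(data / resolution).astype("<i2")
    elif binary_format == "IEEE_FLOAT_32":
        raw = data.astype("<f4")
    else:
        raise ValueError(binary_format)
    raw.T.reshape(-1).tofile(eeg)
    return vhdr
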