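"""Readers and writers for the plain formats the pipeline exchanges.

Continuous EEG comes in as a restricted BrainVision triplet
(``.vhdr``/``.vmrk``/``.eeg``): multiplexed channel order, INT_16 or
IEEE_FLOAT_32 samples, microvolt scaling via the per-channel resolution.
Behavioral trial logs are tab-separated text.  Derived results travel as a
TSV file with a JSON sidecar declaring the column schema, so every artifact
on disk is self-describing text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

MODALITIES = ("V", "A", "AV")
ROLES = ("target", "standard")
INTENSITIES = ("high", "low")
GROUPS = ("older", "younger")

MISSING_TOKEN = "NA"


class BrainVisionError(IOError):
    """A BrainVision triplet is missing a file or is internally inconsistent."""


class UnsupportedDialectError(BrainVisionError):
    """The file uses a BrainVision feature outside the supported subset."""


class TrialLogError(ValueError):
    """A behavioral trial log row failed validation."""


class SchemaError(ValueError):
    """A results table disagrees with its declared column schema."""


@dataclass
class Event:
    """One stimulus presentation, optionally with the subject's response.

    ``sample`` indexes into a recording; ``onset_ms`` is the experiment-clock
    onset used by trial logs.  Either may be absent depending on provenance.
    """

    modality: str
    role: str
    intensity: str
    sample: Optional[int] = None
    onset_ms: Optional[float] = None
    response_time_ms: Optional[float] = None
    block: Optional[int] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}; expected one of {INTENSITIES}")
        if self.response_time_ms is not None and self.response_time_ms < 0:
            raise ValueError("response_time_ms must be nonnegative")

    @property
    def responded(self) -> bool:
        return self.response_time_ms is not None


@dataclass
class ContinuousRecording:
    """Multichannel EEG in microvolts with its event markers."""

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray  # channels x samples, microvolts
    events: list[Event] = field(default_factory=list)
    subject_id: str = ""
    group: str = "younger"
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"for {len(self.channel_labels)} channel labels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        n = self.data.shape[1]
        for ev in self.events:
            if ev.sample is not None and not (0 <= ev.sample < n):
                raise ValueError(f"event sample {ev.sample} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


def _parse_vhdr_sections(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: Optional[str] = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            key, val = line.split("=", 1)
            sections[current][key.strip()] = val.strip()
    return sections


def read_brainvision(
    header_path: str | Path,
    marker_map: Optional[dict[str, tuple[str, str, str]]] = None,
    subject_id: str = "",
    group: str = "younger",
) -> ContinuousRecording:
    """Read a BrainVision triplet into a :class:`ContinuousRecording`.

    Supports the multiplexed INT_16 / IEEE_FLOAT_32 dialect.  INT_16 samples
    are scaled by the per-channel resolution so the returned data is in
    microvolts.  ``marker_map`` translates "Stimulus" marker descriptions
    (e.g. ``"S 11"``) to ``(modality, role, intensity)``; markers with codes
    absent from the map are skipped and listed in the recording history under
    a ``skipped_markers`` entry.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise BrainVisionError(f"header file not found: {header_path}")
    sections = _parse_vhdr_sections(header_path.read_text(encoding="utf-8", errors="replace"))
    common = sections.get("Common Infos", {})
    binfo = sections.get("Binary Infos", {})

    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise UnsupportedDialectError(f"DataOrientation {orientation} not supported (MULTIPLEXED only)")
    binary_format = binfo.get("BinaryFormat", "INT_16").upper()
    if binary_format not in ("INT_16", "IEEE_FLOAT_32"):
        raise UnsupportedDialectError(f"BinaryFormat {binary_format} not supported")

    n_channels = int(common["NumberOfChannels"])
    # SamplingInterval is in microseconds
    sampling_rate = 1e6 / float(common["SamplingInterval"])

    data_file = header_path.parent / common["DataFile"]
    marker_file = header_path.parent / common["MarkerFile"] if "MarkerFile" in common else None
    if not data_file.exists():
        raise BrainVisionError(f"data file referenced by header not found: {data_file}")
    if marker_file is not None and not marker_file.exists():
        raise BrainVisionError(f"marker file referenced by header not found: {marker_file}")

    labels: list[str] = []
    resolutions: list[float] = []
    chan_section = sections.get("Channel Infos", {})
    for i in range(1, n_channels + 1):
        entry = chan_section.get(f"Ch{i}")
        if entry is None:
            raise BrainVisionError(f"header missing Channel Infos entry Ch{i}")
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 else ""
        if res == "":
            if binary_format == "INT_16":
                raise UnsupportedDialectError(f"channel {parts[0]}: INT_16 data requires a resolution")
            resolutions.append(1.0)
        else:
            resolutions.append(float(res))

    raw = np.fromfile(data_file, dtype="<i2" if binary_format == "INT_16" else "<f4")
    if raw.size % n_channels:
        raise BrainVisionError(
            f"data file length {raw.size} not divisible by {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(float)
    if binary_format == "INT_16":
        data *= np.asarray(resolutions)[:, None]

    events: list[Event] = []
    skipped: list[str] = []
    if marker_file is not None:
        msec = _parse_vhdr_sections(marker_file.read_text(encoding="utf-8", errors="replace"))
        for key in sorted(msec.get("Marker Infos", {}), key=lambda k: int(k[2:])):
            parts = msec["Marker Infos"][key].split(",")
            mtype, desc = parts[0], parts[1]
            if mtype != "Stimulus":
                continue
            # BrainVision marker positions are 1-based sample numbers
            sample = int(parts[2]) - 1
            if marker_map is None or desc not in marker_map:
                skipped.append(desc)
                continue
            modality, role, intensity = marker_map[desc]
            events.append(Event(modality=modality, role=role, intensity=intensity, sample=sample))

    rec = ContinuousRecording(
        channel_labels=labels,
        sampling_rate=sampling_rate,
        data=data,
        events=events,
        subject_id=subject_id,
        group=group,
    )
    rec.history.append({"step": "read_brainvision", "path": str(header_path), "skipped_markers": skipped})
    return rec


TRIAL_LOG_COLUMNS = ["subject", "block", "trial", "modality", "role", "intensity", "onset_ms", "rt_ms"]


def read_trial_log(path: str | Path) -> list[Event]:
    """Read a behavioral trial log TSV into a list of events.

    Empty ``rt_ms`` cells mean "no response".  Enumeration violations raise
    :class:`TrialLogError` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"trial log {path} missing columns: {missing}")
    events: list[Event] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        try:
            rt = row.rt_ms.strip()
            events.append(
                Event(
                    modality=row.modality,
                    role=row.role,
                    intensity=row.intensity,
                    onset_ms=float(row.onset_ms),
                    response_time_ms=float(rt) if rt else None,
                    block=int(row.block),
                    subject_id=row.subject,
                )
            )
        except ValueError as exc:
            raise TrialLogError(f"{path} line {i}: {exc}") from exc
    return events


def write_trial_log(events: list[Event], path: str | Path) -> None:
    rows = []
    for i, ev in enumerate(events, start=1):
        rows.append(
            {
                "subject": ev.subject_id or "",
                "block": ev.block if ev.block is not None else 1,
                "trial": i,
                "modality": ev.modality,
                "role": ev.role,
                "intensity": ev.intensity,
                "onset_ms": "" if ev.onset_ms is None else f"{ev.onset_ms:.6g}",
                "rt_ms": "" if ev.response_time_ms is None else f"{ev.response_time_ms:.6g}",
            }
        )
    pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class ResultsTable:
    """A tabular result with an explicit column schema.

    ``schema`` maps column name to one of ``{"string", "integer", "real"}``.
    Real columns may hold NaN, which serializes to the ``NA`` token.
    """

    data: pd.DataFrame
    schema: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cols = list(self.data.columns)
        if cols != list(self.schema):
            raise SchemaError(f"columns {cols} do not match schema {list(self.schema)}")
        for name, kind in self.schema.items():
            if kind not in ("string", "integer", "real"):
                raise SchemaError(f"column {name}: unknown type {kind!r}")
            col = self.data[name]
            if kind == "integer":
                if len(col) and not np.issubdtype(np.asarray(col).dtype, np.integer):
                    raise SchemaError(f"column {name} declared integer but holds {col.dtype}")
            elif kind == "real":
                arr = np.asarray(col, dtype=float)
                if np.any(np.isinf(arr)):
                    raise SchemaError(f"column {name} contains non-finite values other than NaN")


def write_results(table: ResultsTable, path: str | Path) -> None:
    """Write a TSV with a ``<path>.schema.json`` sidecar."""
    path = Path(path)
    table.validate()
    out = table.data.copy()
    for name, kind in table.schema.items():
        if kind == "real":
            out[name] = [
                MISSING_TOKEN if (isinstance(v, float) and math.isnan(v)) else f"{float(v):.12g}"
                for v in out[name]
            ]
    out.to_csv(path, sep="\t", index=False)
    sidecar = {"columns": [{"name": n, "type": t} for n, t in table.schema.items()]}
    Path(str(path) + ".schema.json").write_text(json.dumps(sidecar, indent=1), encoding="utf-8")


def read_results(path: str | Path) -> ResultsTable:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".schema.json").read_text(encoding="utf-8"))
    schema = {c["name"]: c["type"] for c in sidecar["columns"]}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(schema):
        raise SchemaError(f"{path}: TSV columns {list(df.columns)} do not match sidecar")
    for name, kind in schema.items():
        if kind == "integer":
            df[name] = df[name].astype(int)
        elif kind == "real":
            df[name] = [float("nan") if v == MISSING_TOKEN else float(v) for v in df[name]]
    return ResultsTable(data=df, schema=schema)
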