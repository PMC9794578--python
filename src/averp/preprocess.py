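"""Continuous EEG to clean per-subject condition-average ERPs.

The canonical order is: re-reference to the mastoids (TP9/TP10), band-pass
0.01-60 Hz on the continuous data, cut -100..400 ms epochs around standard
stimuli, baseline-correct on -100..0 ms, reject trials exceeding +-100 uV,
average per condition (subjects with fewer than 30 surviving epochs are
flagged excluded), band-pass the averages 0.1-30 Hz, then grand-average
across subjects.  Each step appends to the object's history and refuses to
run if its prerequisites are missing (pass ``strict=False`` to lift the
check when processing data of external provenance).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .io_formats import ContinuousRecording, Event

DEFAULT_REFERENCE = ("TP9", "TP10")
#: channels never scanned by artifact rejection
NON_EEG_CHANNELS = ("TP9", "TP10", "EOGh", "EOGv", "HEOG", "VEOG")


class PipelineOrderError(RuntimeError):
    """A preprocessing step was called before its prerequisites."""


@dataclass
class EpochSet:
    """Trials x channels x time for one subject and condition, in microvolts."""

    subject_id: str
    group: str
    modality: str
    intensity: str
    data: np.ndarray
    times_ms: np.ndarray
    channel_labels: list[str]
    roles: tuple[str, ...] = ("standard",)
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    history: list[dict] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        dt = np.diff(self.times_ms)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("times_ms must be uniformly spaced")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def has_step(self, step: str) -> bool:
        return any(h.get("step") == step for h in self.history)


@dataclass
class SubjectERP:
    subject_id: str
    group: str
    modality: str
    intensity: str
    mean_wave: np.ndarray        # channels x time
    times_ms: np.ndarray
    channel_labels: list[str]
    n_epochs: int
    included: bool
    history: list[dict] = field(default_factory=list)


def _require(history: list[dict], step: str, strict: bool) -> None:
    if strict and not any(h.get("step") == step for h in history):
        raise PipelineOrderError(f"step {step!r} must run first (history: "
                                 f"{[h.get('step') for h in history]})")


def rereference(obj: ContinuousRecording | EpochSet,
                ref_channels: Sequence[str] = DEFAULT_REFERENCE):
    """Subtract the mean of the reference channels from every channel."""
    missing = [ch for ch in ref_channels if ch not in obj.channel_labels]
    if missing:
        raise ValueError(f"reference channels missing from data: {missing}")
    idx = [obj.channel_labels.index(ch) for ch in ref_channels]
    out = dataclasses.replace(obj)
    out.data = obj.data.copy()
    out.history = list(obj.history)
    ref = out.data[..., idx, :].mean(axis=-2, keepdims=True)
    out.data = out.data - ref
    out.history.append({"step": "rereference", "ref_channels": list(ref_channels)})
    return out


def bandpass(obj, low_hz: float, high_hz: float,
             sampling_rate: Optional[float] = None, order: int = 4):
    """Zero-phase Butterworth band-pass (forward-backward, ``sosfiltfilt``).

    Accepts a :class:`ContinuousRecording`, :class:`EpochSet`,
    :class:`SubjectERP` or a bare array (then ``sampling_rate`` is required).
    """
    if isinstance(obj, np.ndarray):
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
        return _bandpass_array(obj, low_hz, high_hz, sampling_rate, order)
    fs = getattr(obj, "sampling_rate", None)
    if fs is None:
        dt = float(obj.times_ms[1] - obj.times_ms[0])
        fs = 1000.0 / dt
    out = dataclasses.replace(obj)
    out.history = list(obj.history)
    if isinstance(obj, SubjectERP):
        out.mean_wave = _bandpass_array(obj.mean_wave, low_hz, high_hz, fs, order)
    else:
        out.data = _bandpass_array(obj.data, low_hz, high_hz, fs, order)
    out.history.append({"step": "bandpass", "low_hz": low_hz, "high_hz": high_hz, "order": order})
    return out


def _bandpass_array(data: np.ndarray, low_hz: float, high_hz: float,
                    fs: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(f"invalid band {low_hz}-{high_hz} Hz at fs={fs}")
    if low_hz == 0:
        sos = signal.butter(order, high_hz / nyq, btype="low", output="sos")
    else:
        sos = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def extract_epochs(recording: ContinuousRecording,
                   events: Optional[list[Event]] = None,
                   tmin_ms: float = -100.0, tmax_ms: float = 400.0,
                   roles: Sequence[str] = ("standard",),
                   strict: bool = True) -> dict[tuple[str, str], EpochSet]:
    """Cut epochs around events, one :class:`EpochSet` per (modality, intensity).

    The epoch window is a closed interval: both the ``tmin`` and ``tmax``
    samples are included (126 samples for -100..400 ms at 250 Hz); the sample
    at t=0 is the marker sample.  Events whose window would cross a recording
    edge are dropped and logged.  Conditions with no surviving events yield
    an empty, flagged EpochSet.
    """
    _require(recording.history, "rereference", strict)
    _require(recording.history, "bandpass", strict)
    if events is None:
        events = recording.events
    fs = recording.sampling_rate
    pre = int(round(-tmin_ms * fs / 1000.0))
    post = int(round(tmax_ms * fs / 1000.0))
    n_t = pre + post + 1
    times = (np.arange(n_t) - pre) * 1000.0 / fs
    n_samples = recording.n_samples

    grouped: dict[tuple[str, str], list[np.ndarray]] = {}
    dropped: dict[tuple[str, str], list[dict]] = {}
    for ev in events:
        if ev.role not in roles or ev.sample is None:
            continue
        key = (ev.modality, ev.intensity)
        grouped.setdefault(key, [])
        dropped.setdefault(key, [])
        start = ev.sample - pre
        if start < 0 or start + n_t > n_samples:
            dropped[key].append({"sample": ev.sample, "reason": "window outside recording"})
            continue
        grouped[key].append(recording.data[:, start:start + n_t])

    out = {}
    for key, chunks in grouped.items():
        data = np.stack(chunks) if chunks else np.empty((0, len(recording.channel_labels), n_t))
        es = EpochSet(subject_id=recording.subject_id, group=recording.group,
                      modality=key[0], intensity=key[1], data=data, times_ms=times,
                      channel_labels=list(recording.channel_labels), roles=tuple(roles),
                      history=list(recording.history), dropped=dropped[key])
        es.history.append({"step": "extract_epochs", "tmin_ms": tmin_ms, "tmax_ms": tmax_ms,
                           "roles": list(roles), "n_dropped_boundary": len(dropped[key]),
                           "empty": data.shape[0] == 0})
        out[key] = es
    return out


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract the per-trial per-channel mean over the baseline window.

    Idempotent: re-applying changes nothing beyond float round-off.
    """
    mask = (epochs.times_ms >= window_ms[0]) & (epochs.times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    out = dataclasses.replace(epochs)
    out.history = list(epochs.history)
    out.data = epochs.data - epochs.data[..., mask].mean(axis=-1, keepdims=True)
    out.baseline_window_ms = window_ms
    out.history.append({"step": "baseline_correct", "window_ms": list(window_ms)})
    return out


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0,
                     channels: Optional[Sequence[str]] = None,
                     drop_trials: Sequence[int] = (),
                     strict: bool = True) -> tuple[EpochSet, list[dict]]:
    """Drop trials whose absolute amplitude strictly exceeds the threshold.

    Only EEG channels are scanned (mastoid references and EOG channels are
    skipped unless ``channels`` names them explicitly).  A value exactly at
    the threshold is retained.  ``drop_trials`` adds a user-supplied manual
    drop list.  Returns the reduced EpochSet and the rejection log.
    """
    if not threshold_uv > 0:
        raise ValueError("threshold must be positive")
    _require(epochs.history, "baseline_correct", strict)
    if channels is None:
        scan = [i for i, ch in enumerate(epochs.channel_labels) if ch not in NON_EEG_CHANNELS]
    else:
        scan = [epochs.channel_labels.index(ch) for ch in channels]
    log = []
    keep = []
    manual = set(drop_trials)
    for t in range(epochs.n_epochs):
        if t in manual:
            log.append({"trial": t, "channel": None, "peak_uv": None, "reason": "manual"})
            continue
        absdata = np.abs(epochs.data[t][scan])
        peak = absdata.max() if absdata.size else 0.0
        if peak > threshold_uv:
            ch = epochs.channel_labels[scan[int(np.unravel_index(absdata.argmax(), absdata.shape)[0])]]
            log.append({"trial": t, "channel": ch, "peak_uv": float(peak), "reason": "amplitude"})
        else:
            keep.append(t)
    out = dataclasses.replace(epochs)
    out.history = list(epochs.history)
    out.data = epochs.data[keep] if keep else epochs.data[:0]
    out.history.append({"step": "reject_artifacts", "threshold_uv": threshold_uv,
                        "n_rejected": len(log), "n_kept": len(keep),
                        "retention": len(keep) / epochs.n_epochs if epochs.n_epochs else 1.0})
    return out, log


def subject_average(epochs: EpochSet, min_epochs: int = 30, strict: bool = True) -> SubjectERP:
    """Average across trials; fewer than ``min_epochs`` trials flags exclusion."""
    _require(epochs.history, "baseline_correct", strict)
    n = epochs.n_epochs
    mean_wave = epochs.data.mean(axis=0) if n else np.zeros(epochs.data.shape[1:])
    erp = SubjectERP(subject_id=epochs.subject_id, group=epochs.group,
                     modality=epochs.modality, intensity=epochs.intensity,
                     mean_wave=mean_wave, times_ms=epochs.times_ms.copy(),
                     channel_labels=list(epochs.channel_labels),
                     n_epochs=n, included=n >= min_epochs,
                     history=list(epochs.history))
    erp.history.append({"step": "subject_average", "n_epochs": n, "min_epochs": min_epochs})
    return erp


def grand_average(erps: list[SubjectERP]) -> np.ndarray:
    """Unweighted mean wave over included subjects (channels x time)."""
    included = [e for e in erps if e.included]
    if not included:
        raise ValueError("no included subjects to average")
    ref = included[0]
    for e in included[1:]:
        if e.channel_labels != ref.channel_labels or not np.array_equal(e.times_ms, ref.times_ms):
            raise ValueError(f"subject {e.subject_id}: channel set or time axis mismatch")
    return np.mean([e.mean_wave for e in included], axis=0)
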