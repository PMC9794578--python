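"""Additive-model audiovisual integration statistics.

The integration quantity is the per-subject difference wave
``ERP(AV) - [ERP(A) + ERP(V)]``: zero everywhere under the additive null,
negative-going where the multisensory response exceeds the summed unimodal
responses.  Pointwise one-sample t-tests against zero over 0-400 ms, with a
run-length criterion (12 or more consecutive samples at p < .05), localize
integration windows; electrode-cluster (ROI) averages and closed-interval
window means feed the mixed ANOVA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SubjectERP

#: The five analysis ROIs over the 32-channel montage.
DEFAULT_ROIS = {
    "left_anterior": ["F3", "FC5", "FC1"],
    "right_anterior": ["F4", "FC6", "FC2"],
    "central": ["C3", "Cz", "C4"],
    "left_posterior": ["P3", "CP5", "CP1"],
    "right_posterior": ["P4", "CP6", "CP2"],
}

#: The four analysis windows (ms) located by the running t-tests.
DEFAULT_WINDOWS = [(60.0, 100.0), (120.0, 160.0), (220.0, 260.0), (340.0, 380.0)]


@dataclass
class DifferenceWave:
    """AV - (A + V) for one subject and intensity, channels x time in uV."""

    subject_id: str
    group: str
    intensity: str
    wave: np.ndarray
    times_ms: np.ndarray
    channel_labels: list[str]

    def channel(self, label: str) -> np.ndarray:
        return self.wave[self.channel_labels.index(label)]


@dataclass
class PointwiseTestSeries:
    electrode: str
    group: str
    intensity: str
    times_ms: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    n_subjects: int
    degenerate: list[int] = field(default_factory=list)  # zero-variance samples


@dataclass
class IntegrationWindow:
    electrode: str
    start_ms: float
    end_ms: float
    n_samples: int
    mean_t: float
    direction: str  # "super-additive negative" | "super-additive positive"


def additive_difference(av: SubjectERP, a: SubjectERP, v: SubjectERP) -> DifferenceWave:
    """``wave = AV - (A + V)`` sample-wise, after axis/identity validation."""
    for x, name in ((a, "A"), (v, "V")):
        if x.subject_id != av.subject_id or x.intensity != av.intensity:
            raise ValueError(f"{name} ERP belongs to a different subject/intensity than AV")
        if x.channel_labels != av.channel_labels or not np.array_equal(x.times_ms, av.times_ms):
            raise ValueError(f"{name} ERP channel set or time axis differs from AV")
    for x, name in ((av, "AV"), (a, "A"), (v, "V")):
        if not x.included:
            raise ValueError(f"{name} ERP of subject {x.subject_id} is excluded "
                             f"(n_epochs={x.n_epochs}); skip this subject")
    return DifferenceWave(subject_id=av.subject_id, group=av.group, intensity=av.intensity,
                          wave=av.mean_wave - (a.mean_wave + v.mean_wave),
                          times_ms=av.times_ms.copy(), channel_labels=list(av.channel_labels))


def difference_waves(erps: dict[tuple[str, str], SubjectERP]) -> dict[str, DifferenceWave]:
    """Per-intensity difference waves from a subject's condition dict."""
    out = {}
    for intensity in {k[1] for k in erps}:
        out[intensity] = additive_difference(erps[("AV", intensity)],
                                             erps[("A", intensity)],
                                             erps[("V", intensity)])
    return out


def pointwise_ttest(diffs: list[DifferenceWave], electrode: str,
                    window_ms: tuple[float, float] = (0.0, 400.0)) -> PointwiseTestSeries:
    """One-sample two-sided t-test of the subject difference waves against 0
    at every sample of the analysis window (closed interval), df = n - 1.

    Zero-variance samples get the degenerate rule: p = 0 when the mean is
    nonzero, p = 1 when it is zero; their indices are recorded.
    """
    if len(diffs) < 2:
        raise ValueError("need at least 2 subjects for a t-test")
    g = {d.group for d in diffs}
    it = {d.intensity for d in diffs}
    if len(g) > 1 or len(it) > 1:
        raise ValueError(f"difference waves mix groups {g} or intensities {it}")
    times = diffs[0].times_ms
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    X = np.stack([d.channel(electrode)[mask] for d in diffs])  # subjects x time
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    for i in degenerate:
        t[i] = np.inf if mean[i] > 0 else (-np.inf if mean[i] < 0 else 0.0)
        p[i] = 1.0 if mean[i] == 0 else 0.0
    return PointwiseTestSeries(electrode=electrode, group=diffs[0].group,
                               intensity=diffs[0].intensity, times_ms=times[mask],
                               t_values=t, p_values=p, n_subjects=n,
                               degenerate=list(map(int, degenerate)))


def detect_windows(series: PointwiseTestSeries, alpha: float = 0.05,
                   min_run: int = 12) -> list[IntegrationWindow]:
    """Maximal runs of >= ``min_run`` consecutive significant samples.

    Significance is strict (p < alpha); runs shorter than ``min_run`` are
    discarded and adjacent runs separated by even one nonsignificant sample
    stay separate.  Window direction follows the sign of the mean t in the run.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    sig = series.p_values < alpha
    out = []
    i = 0
    n = len(sig)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < n and sig[j]:
            j += 1
        if j - i >= min_run:
            mean_t = float(np.mean(series.t_values[i:j]))
            out.append(IntegrationWindow(
                electrode=series.electrode,
                start_ms=float(series.times_ms[i]), end_ms=float(series.times_ms[j - 1]),
                n_samples=j - i, mean_t=mean_t,
                direction="super-additive negative" if mean_t < 0 else "super-additive positive"))
        i = j
    return out


def roi_average(wave_obj, rois: dict[str, list[str]] = DEFAULT_ROIS):
    """Replace channels by ROI pseudo-channels (mean over each ROI's electrodes).

    Works on :class:`DifferenceWave` and :class:`SubjectERP` alike; returns
    the same type with ``channel_labels`` set to the ROI names.
    """
    labels = wave_obj.channel_labels
    for name, chans in rois.items():
        missing = [ch for ch in chans if ch not in labels]
        if missing:
            raise ValueError(f"ROI {name!r}: electrodes {missing} not in data")
        if not chans:
            raise ValueError(f"ROI {name!r} has no electrodes")
    arr = wave_obj.wave if isinstance(wave_obj, DifferenceWave) else wave_obj.mean_wave
    rows = [arr[[labels.index(ch) for ch in chans]].mean(axis=0) for chans in rois.values()]
    out = dataclasses.replace(wave_obj)
    stacked = np.stack(rows)
    if isinstance(wave_obj, DifferenceWave):
        out.wave = stacked
    else:
        out.mean_wave = stacked
    out.channel_labels = list(rois)
    return out


def window_mean_amplitude(wave_obj, electrode: str,
                          window_ms: tuple[float, float]) -> float:
    """Mean amplitude over ``start <= t <= end`` (closed interval), in uV."""
    times = wave_obj.times_ms
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    arr = wave_obj.wave if isinstance(wave_obj, DifferenceWave) else wave_obj.mean_wave
    return float(arr[wave_obj.channel_labels.index(electrode), mask].mean())


def window_amplitude_table(diffs: list[DifferenceWave],
                           rois: dict[str, list[str]] = DEFAULT_ROIS,
                           windows: list[tuple[float, float]] = DEFAULT_WINDOWS) -> pd.DataFrame:
    """Long table of subject x intensity x ROI x window mean amplitudes.

    One row per combination, ready for :func:`averp.anova_stats.mixed_anova`
    with ``between=["group"]``, ``within=["intensity", "roi"]`` per window.
    """
    rows = []
    for d in diffs:
        r = roi_average(d, rois)
        for roi in rois:
            for (lo, hi) in windows:
                rows.append({
                    "subject": d.subject_id, "group": d.group, "intensity": d.intensity,
                    "roi": roi, "window": f"{lo:g}-{hi:g}",
                    "amplitude_uv": window_mean_amplitude(r, roi, (lo, hi)),
                })
    return pd.DataFrame(rows)
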