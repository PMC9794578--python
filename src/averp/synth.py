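"""Synthetic audiovisual oddball experiments with controllable integration.

The generator emulates a two-block (high/low intensity) design in which
visual (V), auditory (A) and audiovisual (AV) stimuli are presented in random
order — 150 trials per modality per block, 30 targets and 120 standards —
with an 800 ms stimulus and a uniform 1200-1500 ms interstimulus interval,
recorded at 250 Hz on a 32-channel mastoid-referenced montage.

ERP components are Gaussian-windowed bumps (FWHM parameterization) with
per-channel scalp weights.  The AV response is constructed as the exact sum
of the A and V templates — the additive null — plus any configured
integration effects: Gaussian bumps confined to a latency window and a set of
ROI channels, whose amplitude is the ground truth that downstream analysis
should recover.  Background activity is white plus 1/f ("pink") noise;
blinks are Poisson-scheduled frontal deflections large enough to trip a
+-100 uV rejection criterion.  Behavioral responses follow per-cell hit and
false-alarm probabilities with ex-Gaussian response times.

Everything is a pure function of the configuration seed: the same
:class:`SimConfig` always yields byte-identical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import Event, ContinuousRecording, GROUPS, INTENSITIES, MODALITIES

#: Standard 32-channel actiCAP-style montage (includes TP9/TP10 mastoids and
#: every electrode of the five analysis ROIs).
DEFAULT_MONTAGE = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]

#: Channels that receive the blink artifact kernel.
BLINK_CHANNELS = ("Fp1", "Fp2", "F7", "F8")


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class ComponentSpec:
    """One Gaussian-windowed ERP component of a unimodal response."""

    modality: str                     # "V" or "A"
    intensity: str                    # "high" or "low"
    scalp_weights: dict[str, float]   # channel -> weight in [-1, 1]
    latency_ms: float
    width_ms: float                   # FWHM
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.modality not in ("V", "A"):
            raise ConfigError("component modality must be V or A (AV is built additively)")
        if self.intensity not in INTENSITIES:
            raise ConfigError(f"unknown intensity {self.intensity!r}")
        if not self.width_ms > 0:
            raise ConfigError("width_ms must be positive")


@dataclass
class IntegrationEffectSpec:
    """A super-additive deviation injected into AV trials only.

    ``amplitude_uv`` is the peak deviation of AV - (A+V); negative values are
    the super-additive negativity the analysis looks for.
    """

    window_ms: tuple[float, float]
    roi_channels: list[str]
    amplitude_uv: float
    group: str = "both"               # older / younger / both
    intensity: str = "both"           # high / low / both

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not lo < hi:
            raise ConfigError("integration window start must precede end")
        if not (0 <= lo and hi <= 400):
            raise ConfigError("integration window must lie within 0-400 ms")
        if self.group not in (*GROUPS, "both"):
            raise ConfigError(f"unknown group {self.group!r}")
        if self.intensity not in (*INTENSITIES, "both"):
            raise ConfigError(f"unknown intensity {self.intensity!r}")

    def applies(self, group: str, intensity: str) -> bool:
        return self.group in ("both", group) and self.intensity in ("both", intensity)


@dataclass
class NoiseSpec:
    white_sd_uv: float = 5.0
    pink_sd_uv: float = 10.0
    blink_rate_per_min: float = 4.0
    blink_amplitude_uv: float = 150.0
    # multiplicative between-subject variability of component / integration
    # amplitudes (SD of a unit-mean Gaussian factor)
    subject_amp_sd: float = 0.15
    subject_effect_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.white_sd_uv < 0 or self.pink_sd_uv < 0:
            raise ConfigError("noise SDs must be nonnegative")
        if self.blink_rate_per_min < 0:
            raise ConfigError("blink rate must be nonnegative")


@dataclass
class BehaviorCellSpec:
    """Ex-Gaussian RT and response probabilities for one design cell."""

    rt_mu_ms: float
    rt_sigma_ms: float
    rt_tau_ms: float
    hit_p: float
    fa_p: float

    def __post_init__(self) -> None:
        if not (0 <= self.hit_p <= 1 and 0 <= self.fa_p <= 1):
            raise ConfigError("hit_p and fa_p must lie in [0, 1]")


@dataclass
class DesignSpec:
    targets_per_modality: int = 30
    standards_per_modality: int = 120
    blocks: tuple[str, ...] = ("high", "low")
    isi_ms_range: tuple[float, float] = (1200.0, 1500.0)
    fixation_ms: float = 2000.0
    stimulus_ms: float = 800.0

    def __post_init__(self) -> None:
        if self.targets_per_modality < 0 or self.standards_per_modality <= 0:
            raise ConfigError("trial counts must be positive")
        if not self.isi_ms_range[0] <= self.isi_ms_range[1]:
            raise ConfigError("ISI range reversed")

    @property
    def trials_per_modality(self) -> int:
        return self.targets_per_modality + self.standards_per_modality


def _default_behavior() -> dict[tuple[str, str, str], BehaviorCellSpec]:
    """Default behavioral parameters per (group, intensity, modality).

    Means and SDs follow the observed response-time / hit-rate / false-alarm
    pattern: AV fastest, then V, then A, and slower older-adult responses.
    Ex-Gaussian parameters are chosen so the distribution's mean and SD equal
    the tabulated values (tau = 0.6 SD, sigma = 0.8 SD, mu = mean - tau).
    """
    raw = {
        # (group, intensity, modality): (rt_mean, rt_sd, hit%, fa%)
        ("older", "low", "V"): (655, 111, 97, 0.14),
        ("older", "low", "A"): (673, 116, 95, 1.39),
        ("older", "low", "AV"): (575, 93, 98, 0.48),
        ("older", "high", "V"): (590, 104, 97, 0.76),
        ("older", "high", "A"): (662, 74, 96, 1.73),
        ("older", "high", "AV"): (562, 71, 99, 0.97),
        ("younger", "low", "V"): (521, 67, 98, 0.17),
        ("younger", "low", "A"): (584, 71, 97, 0.71),
        ("younger", "low", "AV"): (502, 62, 99, 0.25),
        ("younger", "high", "V"): (543, 55, 99, 0.21),
        ("younger", "high", "A"): (573, 65, 97, 1.74),
        ("younger", "high", "AV"): (468, 62, 99, 0.38),
    }
    out = {}
    for key, (mean, sd, ht, fa) in raw.items():
        tau = 0.6 * sd
        out[key] = BehaviorCellSpec(
            rt_mu_ms=mean - tau, rt_sigma_ms=0.8 * sd, rt_tau_ms=tau,
            hit_p=ht / 100.0, fa_p=fa / 100.0,
        )
    return out


def default_components(low_gain: float = 0.6) -> list[ComponentSpec]:
    """A minimal visual P1/N1 and auditory N1/P2 component set.

    Low-intensity stimuli evoke the same components scaled by ``low_gain``,
    the generative stand-in for the contrast / sound-level manipulation.
    """
    specs = []
    bases = [
        # (modality, weights, latency, FWHM, amplitude)
        ("V", {"O1": 1.0, "Oz": 1.0, "O2": 1.0, "P3": 0.6, "Pz": 0.7, "P4": 0.6,
               "PO9": 0.8, "PO10": 0.8}, 110.0, 60.0, 4.0),
        ("V", {"O1": 0.8, "Oz": 0.9, "O2": 0.8, "P7": 0.6, "P8": 0.6}, 170.0, 70.0, -3.0),
        ("A", {"Fz": 0.9, "Cz": 1.0, "FC1": 0.8, "FC2": 0.8, "C3": 0.7, "C4": 0.7,
               "F3": 0.6, "F4": 0.6}, 100.0, 60.0, -5.0),
        ("A", {"Cz": 1.0, "Fz": 0.8, "CP1": 0.6, "CP2": 0.6}, 200.0, 90.0, 3.5),
    ]
    for modality, w, lat, width, amp in bases:
        for intensity, gain in (("high", 1.0), ("low", low_gain)):
            specs.append(ComponentSpec(modality, intensity, dict(w), lat, width, amp * gain))
    return specs


@dataclass
class SimConfig:
    """Complete generative specification of a synthetic experiment."""

    n_older: int = 18
    n_younger: int = 20
    sampling_rate: float = 250.0
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    components: list[ComponentSpec] = field(default_factory=default_components)
    integration_effects: list[IntegrationEffectSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    behavior: dict[tuple[str, str, str], BehaviorCellSpec] = field(default_factory=_default_behavior)
    #: SD of the per-subject response-speed intercept shared across cells;
    #: group-level RT SDs are of this order, trial-level spread comes from the
    #: per-cell ex-Gaussian parameters
    rt_subject_sd_ms: float = 60.0
    design: DesignSpec = field(default_factory=DesignSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_older < 0 or self.n_younger < 0 or self.n_older + self.n_younger == 0:
            raise ConfigError("need at least one subject")
        if not self.sampling_rate > 0:
            raise ConfigError("sampling_rate must be positive")
        for comp in self.components:
            for ch in comp.scalp_weights:
                if ch not in self.channel_labels:
                    raise ConfigError(f"component references unknown channel {ch!r}")
        for eff in self.integration_effects:
            for ch in eff.roi_channels:
                if ch not in self.channel_labels:
                    raise ConfigError(f"integration effect references unknown channel {ch!r}")

    def subjects(self) -> list[tuple[str, str]]:
        return [(f"older{i+1:02d}", "older") for i in range(self.n_older)] + \
               [(f"younger{i+1:02d}", "younger") for i in range(self.n_younger)]


def inverse_effectiveness_effect(amplitude_uv: float = -1.5) -> list[IntegrationEffectSpec]:
    """An early left-anterior super-additive effect restricted to the
    older / low-intensity cell — the inverse-effectiveness scenario."""
    return [IntegrationEffectSpec(window_ms=(60.0, 100.0),
                                  roi_channels=["F3", "FC5", "FC1"],
                                  amplitude_uv=amplitude_uv,
                                  group="older", intensity="low")]


# ---------------------------------------------------------------------------
# deterministic sub-stream derivation

def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed & 0x7FFFFFFF, *key]))


_STREAM_DESIGN, _STREAM_EEG, _STREAM_BEHAV, _STREAM_SUBJ = 1, 2, 3, 4


def _subject_index(config: SimConfig, subject_id: str) -> int:
    ids = [sid for sid, _ in config.subjects()]
    try:
        return ids.index(subject_id)
    except ValueError:
        # foreign id: stable hash into the stream space
        return 10_000 + sum(ord(c) * (i + 1) for i, c in enumerate(subject_id)) % 100_000


# ---------------------------------------------------------------------------
# design

def make_design(design: DesignSpec, seed: int, intensity: str = "high",
                block: int = 1, subject_id: str = "") -> list[Event]:
    """Random trial sequence for one block.

    Exactly ``targets + standards`` trials per modality in uniformly random
    order; successive onsets are separated by the stimulus duration plus a
    uniform ISI draw; the first onset follows the fixation period.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, _STREAM_DESIGN, block]))
    roles = ["target"] * design.targets_per_modality + ["standard"] * design.standards_per_modality
    trials = [(m, r) for m in MODALITIES for r in roles]
    order = rng.permutation(len(trials))
    lo, hi = design.isi_ms_range
    onset = design.fixation_ms
    events = []
    for idx in order:
        m, r = trials[idx]
        events.append(Event(modality=m, role=r, intensity=intensity,
                            onset_ms=float(onset), block=block, subject_id=subject_id))
        onset += design.stimulus_ms + rng.uniform(lo, hi)
    return events


# ---------------------------------------------------------------------------
# templates and noise

def _gauss_bump(times_ms: np.ndarray, latency_ms: float, width_ms: float) -> np.ndarray:
    sigma = width_ms / 2.355  # FWHM -> SD
    return np.exp(-0.5 * ((times_ms - latency_ms) / sigma) ** 2)


def erp_template(components: list[ComponentSpec], channel_labels: list[str],
                 sampling_rate: float, window_ms: tuple[float, float] = (-100.0, 400.0),
                 amp_scale: Optional[dict[int, float]] = None) -> tuple[np.ndarray, np.ndarray]:
    """Sum the Gaussian components into a channels x time template.

    Returns ``(template, times_ms)``.  ``amp_scale`` optionally scales each
    component (by list position) — the hook for per-subject variability.
    """
    if not channel_labels:
        raise ConfigError("channel list must be nonempty")
    n_t = int(round((window_ms[1] - window_ms[0]) * sampling_rate / 1000.0)) + 1
    times = window_ms[0] + np.arange(n_t) * 1000.0 / sampling_rate
    out = np.zeros((len(channel_labels), n_t))
    index = {ch: i for i, ch in enumerate(channel_labels)}
    for ci, comp in enumerate(components):
        for ch, w in comp.scalp_weights.items():
            if ch not in index:
                raise ConfigError(f"scalp weight references unknown channel {ch!r}")
        scale = 1.0 if amp_scale is None else amp_scale.get(ci, 1.0)
        bump = comp.amplitude_uv * scale * _gauss_bump(times, comp.latency_ms, comp.width_ms)
        for ch, w in comp.scalp_weights.items():
            out[index[ch]] += w * bump
    return out, times


def integration_bump(effect: IntegrationEffectSpec, channel_labels: list[str],
                     times_ms: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """The injected super-additive deviation as a channels x time array.

    A Gaussian centered on the window midpoint with SD equal to half the
    window length, applied with weight 1 on each ROI channel.  The width
    makes the deviation sustained enough to support a consecutive-significance
    run of the detector's length, matching the kind of effect the running
    t-test analysis reports; the bump is calibrated so its MEAN over the
    window's samples equals ``amplitude_uv``, so a closed-interval
    window-mean readout recovers the injected amplitude directly.
    """
    lo, hi = effect.window_ms
    shape = _gauss_bump(times_ms, (lo + hi) / 2.0, 2.355 * (hi - lo) / 2.0)
    in_win = (times_ms >= lo) & (times_ms <= hi)
    norm = shape[in_win].mean() if in_win.any() else shape.max()
    bump = effect.amplitude_uv * scale * shape / norm
    out = np.zeros((len(channel_labels), len(times_ms)))
    for ch in effect.roi_channels:
        out[channel_labels.index(ch)] = bump
    return out


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-power noise along the last axis, standardized to the given SD.

    White Gaussian noise is shaped in the frequency domain with amplitude
    proportional to 1/sqrt(f); the DC bin is zeroed.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    if sd == 0 or n < 2:
        return np.zeros(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2))
    return x * (sd / rms) if rms > 0 else x


def _subject_scales(config: SimConfig, subject_idx: int):
    """Per-subject unit-mean amplitude factors (components and effects)."""
    rng = _rng(config.seed, _STREAM_SUBJ, subject_idx)
    comp = {i: max(0.1, 1.0 + rng.standard_normal() * config.noise.subject_amp_sd)
            for i in range(len(config.components))}
    eff = {i: 1.0 + rng.standard_normal() * config.noise.subject_effect_sd
           for i in range(len(config.integration_effects))}
    return comp, eff


def _condition_signal(config: SimConfig, modality: str, intensity: str, group: str,
                      times_ms: np.ndarray, comp_scale, eff_scale) -> np.ndarray:
    """Noise-free single-trial signal for one condition (channels x time)."""
    if modality == "AV":
        comps = [c for c in config.components if c.intensity == intensity]
    else:
        comps = [c for c in config.components
                 if c.modality == modality and c.intensity == intensity]
    idx = [i for i, c in enumerate(config.components) if c in comps]
    scale = {j: comp_scale[i] for j, i in enumerate(idx)}
    sig, _ = erp_template(comps, config.channel_labels, config.sampling_rate,
                          (times_ms[0], times_ms[-1]), amp_scale=scale)
    if modality == "AV":
        for i, eff in enumerate(config.integration_effects):
            if eff.applies(group, intensity):
                sig += integration_bump(eff, config.channel_labels, times_ms, eff_scale[i])
    return sig


# ---------------------------------------------------------------------------
# trial-level epoch generation (honest path)

def simulate_epochs(config: SimConfig, subject_id: str, group: str,
                    modality: str, intensity: str, n_trials: int,
                    window_ms: tuple[float, float] = (-100.0, 400.0)) -> tuple[np.ndarray, np.ndarray]:
    """Generate single-trial epochs (trials x channels x time) plus time axis.

    Each trial is the condition's noise-free signal plus independent white and
    pink noise.  No blinks: this path feeds statistical tests that assume
    artifact-free epochs; use :func:`simulate_subject` for continuous data
    with artifacts.
    """
    s_idx = _subject_index(config, subject_id)
    comp_scale, eff_scale = _subject_scales(config, s_idx)
    n_t = int(round((window_ms[1] - window_ms[0]) * config.sampling_rate / 1000.0)) + 1
    times = window_ms[0] + np.arange(n_t) * 1000.0 / config.sampling_rate
    sig = _condition_signal(config, modality, intensity, group, times, comp_scale, eff_scale)
    mstream = {"V": 0, "A": 1, "AV": 2}[modality] + (3 if intensity == "low" else 0)
    rng = _rng(config.seed, _STREAM_EEG, s_idx, mstream)
    n_ch = len(config.channel_labels)
    epochs = np.empty((n_trials, n_ch, n_t))
    for t in range(n_trials):
        noise = rng.standard_normal((n_ch, n_t)) * config.noise.white_sd_uv
        noise += pink_noise(rng, (n_ch, n_t), config.noise.pink_sd_uv)
        epochs[t] = sig + noise
    return epochs, times


def simulate_subject_erps(config: SimConfig, subject_id: str, group: str,
                          n_trials: Optional[int] = None,
                          window_ms: tuple[float, float] = (-100.0, 400.0),
                          ) -> dict[tuple[str, str], np.ndarray]:
    """Subject condition-average ERPs via the variance-equivalent fast path.

    The average of ``n`` i.i.d. Gaussian noise epochs has the same
    distribution as a single noise epoch scaled by ``1/sqrt(n)``, so the
    condition average is generated directly: signal plus one noise draw at
    ``sd/sqrt(n_trials)``.  Returns ``{(modality, intensity): channels x time}``
    and stores the time axis under the ``"times_ms"`` key of the returned
    dict's ``.times`` attribute-free convention — callers use
    :func:`erp_times` for the axis.
    """
    if n_trials is None:
        n_trials = config.design.standards_per_modality
    s_idx = _subject_index(config, subject_id)
    comp_scale, eff_scale = _subject_scales(config, s_idx)
    n_t = int(round((window_ms[1] - window_ms[0]) * config.sampling_rate / 1000.0)) + 1
    times = window_ms[0] + np.arange(n_t) * 1000.0 / config.sampling_rate
    shrink = 1.0 / np.sqrt(n_trials)
    out = {}
    for intensity in INTENSITIES:
        for mi, modality in enumerate(MODALITIES):
            sig = _condition_signal(config, modality, intensity, group, times, comp_scale, eff_scale)
            rng = _rng(config.seed, _STREAM_EEG, s_idx, mi + (3 if intensity == "low" else 0), 7)
            n_ch = len(config.channel_labels)
            noise = rng.standard_normal((n_ch, n_t)) * config.noise.white_sd_uv
            noise += pink_noise(rng, (n_ch, n_t), config.noise.pink_sd_uv)
            out[(modality, intensity)] = sig + shrink * noise
    return out


def erp_times(config: SimConfig, window_ms: tuple[float, float] = (-100.0, 400.0)) -> np.ndarray:
    n_t = int(round((window_ms[1] - window_ms[0]) * config.sampling_rate / 1000.0)) + 1
    return window_ms[0] + np.arange(n_t) * 1000.0 / config.sampling_rate


# ---------------------------------------------------------------------------
# continuous recording

def simulate_subject(config: SimConfig, subject_id: str, group: str,
                     intensities: tuple[str, ...] | None = None,
                     ) -> tuple[ContinuousRecording, list[Event]]:
    """Continuous EEG for one subject plus the responded trial events.

    One concatenated timeline per requested block (default: the design's
    blocks).  Each trial adds its condition signal at the marker sample;
    white + pink noise span the whole recording and Poisson-scheduled blinks
    land on the frontal channels.  Behavioral responses are attached to the
    returned events by :func:`simulate_behavior`.
    """
    if intensities is None:
        intensities = config.design.blocks
    s_idx = _subject_index(config, subject_id)
    comp_scale, eff_scale = _subject_scales(config, s_idx)
    fs = config.sampling_rate
    n_ch = len(config.channel_labels)
    tpl_window = (-100.0, 400.0)
    times = erp_times(config, tpl_window)
    pre = int(round(-tpl_window[0] * fs / 1000.0))

    all_events: list[Event] = []
    blocks_data = []
    for b, intensity in enumerate(intensities, start=1):
        events = make_design(config.design, config.seed + 1000 * s_idx, intensity, b, subject_id)
        last_onset = events[-1].onset_ms
        n_samp = int(round((last_onset + 1000.0) * fs / 1000.0)) + len(times)
        rng = _rng(config.seed, _STREAM_EEG, s_idx, 100 + b)
        data = rng.standard_normal((n_ch, n_samp)) * config.noise.white_sd_uv
        data += pink_noise(rng, (n_ch, n_samp), config.noise.pink_sd_uv)
        sig_cache = {}
        for ev in events:
            key = (ev.modality, intensity)
            if key not in sig_cache:
                sig_cache[key] = _condition_signal(config, ev.modality, intensity, group,
                                                   times, comp_scale, eff_scale)
            sample = int(round(ev.onset_ms * fs / 1000.0))
            ev.sample = sample + sum(d.shape[1] for d in blocks_data)
            start = sample - pre
            data[:, start:start + len(times)] += sig_cache[key]
        # blinks: Poisson count over the block, raised-cosine kernel
        if config.noise.blink_rate_per_min > 0 and config.noise.blink_amplitude_uv != 0:
            minutes = n_samp / fs / 60.0
            n_blinks = rng.poisson(config.noise.blink_rate_per_min * minutes)
            k_len = int(round(0.3 * fs))
            kernel = config.noise.blink_amplitude_uv * 0.5 * (1 - np.cos(2 * np.pi * np.arange(k_len) / k_len))
            blink_rows = [i for i, ch in enumerate(config.channel_labels) if ch in BLINK_CHANNELS]
            for _ in range(n_blinks):
                at = rng.integers(0, max(1, n_samp - k_len))
                for row in blink_rows:
                    data[row, at:at + k_len] += kernel
        blocks_data.append(data)
        all_events.extend(events)

    recording = ContinuousRecording(
        channel_labels=list(config.channel_labels), sampling_rate=fs,
        data=np.hstack(blocks_data), events=all_events,
        subject_id=subject_id, group=group,
    )
    recording.history.append({"step": "simulate", "seed": config.seed, "subject": subject_id})
    responded = simulate_behavior(config, all_events, group,
                                  seed=np.random.SeedSequence([config.seed & 0x7FFFFFFF,
                                                               _STREAM_BEHAV, s_idx]))
    return recording, responded


def simulate_behavior(config: SimConfig, events: list[Event], group: str,
                      seed=None) -> list[Event]:
    """Attach responses: hits on targets with probability ``hit_p`` at an
    ex-Gaussian RT; false alarms on standards with probability ``fa_p``.

    A subject-level speed intercept (one Gaussian draw per call, SD
    ``config.rt_subject_sd_ms``) shifts every RT, giving the across-subject
    spread that group-level summaries show.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    subject_shift = rng.standard_normal() * config.rt_subject_sd_ms
    out = []
    for ev in events:
        cell = config.behavior[(group, ev.intensity, ev.modality)]
        p = cell.hit_p if ev.role == "target" else cell.fa_p
        rt = None
        if rng.uniform() < p:
            rt = cell.rt_mu_ms + subject_shift + rng.standard_normal() * cell.rt_sigma_ms
            if cell.rt_tau_ms > 0:
                rt += rng.exponential(cell.rt_tau_ms)
            rt = max(rt, 100.0)
        out.append(dataclasses.replace(ev, response_time_ms=rt))
    return out


@dataclass
class CohortBundle:
    """In-memory output of a whole-cohort simulation."""

    config: SimConfig
    subjects: list[tuple[str, str]]                      # (subject_id, group)
    erps: dict[str, dict[tuple[str, str], np.ndarray]]   # subject -> condition -> ch x time
    times_ms: np.ndarray
    logs: dict[str, list[Event]]                         # subject -> responded events

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_older": self.config.n_older,
            "n_younger": self.config.n_younger,
            "subjects": [{"id": sid, "group": g} for sid, g in self.subjects],
        }


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None,
                    mode: str = "erp") -> CohortBundle:
    """Simulate every subject of the configured cohort.

    ``mode="erp"`` uses the fast subject-average path;
    ``mode="trials"`` averages honestly generated single-trial epochs.
    Behavioral logs always come from the full trial design.  If ``out_dir``
    is given, trial logs and a manifest JSON are written there.
    """
    from .io_formats import write_trial_log

    subjects = config.subjects()
    erps: dict[str, dict] = {}
    logs: dict[str, list[Event]] = {}
    times = erp_times(config)
    for s_idx, (sid, group) in enumerate(subjects):
        if mode == "erp":
            erps[sid] = simulate_subject_erps(config, sid, group)
        elif mode == "trials":
            d = {}
            for intensity in INTENSITIES:
                for modality in MODALITIES:
                    ep, _ = simulate_epochs(config, sid, group, modality, intensity,
                                            config.design.standards_per_modality)
                    d[(modality, intensity)] = ep.mean(axis=0)
            erps[sid] = d
        else:
            raise ConfigError(f"unknown cohort mode {mode!r}")
        events = []
        for b, intensity in enumerate(config.design.blocks, start=1):
            events.extend(make_design(config.design, config.seed + 1000 * s_idx,
                                      intensity, b, sid))
        logs[sid] = simulate_behavior(config, events, group,
                                      seed=np.random.SeedSequence([config.seed & 0x7FFFFFFF,
                                                                   _STREAM_BEHAV, s_idx]))
    bundle = CohortBundle(config=config, subjects=subjects, erps=erps,
                          times_ms=times, logs=logs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, _ in subjects:
            write_trial_log(logs[sid], out_dir / f"{sid}_log.tsv")
        (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest(), indent=1))
    return bundle
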