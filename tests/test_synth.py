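from collections import Counter

import numpy as np
import pytest

from averp import synth
from averp.io_formats import MODALITIES
from averp.synth import (
    ComponentSpec, ConfigError, DesignSpec, IntegrationEffectSpec, NoiseSpec,
    SimConfig, erp_template, make_design, inverse_effectiveness_effect, pink_noise,
    simulate_behavior, simulate_cohort, simulate_epochs, simulate_subject,
    simulate_subject_erps,
)


class TestDesign:
    def test_default_block_counts(self):
        events = make_design(DesignSpec(), seed=0, intensity="high")
        assert len(events) == 450
        counts = Counter((e.modality, e.role) for e in events)
        for m in MODALITIES:
            assert counts[(m, "standard")] == 120
            assert counts[(m, "target")] == 30

    def test_deterministic_under_seed(self):
        a = make_design(DesignSpec(), seed=5)
        b = make_design(DesignSpec(), seed=5)
        assert [(e.modality, e.role, e.onset_ms) for e in a] == \
               [(e.modality, e.role, e.onset_ms) for e in b]

    def test_isi_bounds_over_many_trials(self):
        """Gaps between consecutive onsets stay inside stimulus + ISI range."""
        spec = DesignSpec()
        gaps = []
        for seed in range(25):  # 25 x 450 > 10^4 trials
            events = make_design(spec, seed=seed)
            onsets = np.array([e.onset_ms for e in events])
            gaps.append(np.diff(onsets))
        gaps = np.concatenate(gaps)
        assert gaps.size > 10_000
        assert gaps.min() >= spec.stimulus_ms + spec.isi_ms_range[0]
        assert gaps.max() <= spec.stimulus_ms + spec.isi_ms_range[1]

    def test_first_onset_after_fixation(self):
        events = make_design(DesignSpec(), seed=1)
        assert events[0].onset_ms == pytest.approx(2000.0)


class TestErpTemplate:
    def test_empty_component_list_all_zero(self):
        tpl, times = erp_template([], ["Cz", "Pz"], 250.0)
        assert tpl.shape == (2, 126)
        assert np.all(tpl == 0)

    def test_single_component_peak_at_latency(self):
        comp = ComponentSpec("A", "high", {"Cz": 1.0}, latency_ms=100.0,
                             width_ms=60.0, amplitude_uv=5.0)
        tpl, times = erp_template([comp], ["Cz"], 250.0)
        peak_idx = np.argmax(tpl[0])
        assert times[peak_idx] == pytest.approx(100.0)
        assert tpl[0, peak_idx] == pytest.approx(5.0)

    def test_linearity_two_identical_components(self):
        comp = ComponentSpec("V", "low", {"Oz": 0.8}, 120.0, 50.0, -3.0)
        single, _ = erp_template([comp], ["Oz"], 250.0)
        double, _ = erp_template([comp, comp], ["Oz"], 250.0)
        np.testing.assert_allclose(double, 2 * single)

    def test_unknown_channel_rejected(self):
        comp = ComponentSpec("V", "high", {"Nope": 1.0}, 100.0, 50.0, 1.0)
        with pytest.raises(ConfigError, match="Nope"):
            erp_template([comp], ["Cz"], 250.0)


class TestPinkNoise:
    def test_target_sd_and_zero_mean_spectrum(self, rng):
        x = pink_noise(rng, (4, 2048), sd=3.0)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(3.0, rel=1e-6)

    def test_low_frequencies_dominate(self, rng):
        x = pink_noise(rng, (1, 4096), sd=1.0)[0]
        spec = np.abs(np.fft.rfft(x)) ** 2
        lo = spec[1:50].mean()
        hi = spec[-50:].mean()
        assert lo > 10 * hi


class TestAdditiveNull:
    def test_noise_free_no_effect_difference_is_zero(self, quiet_config):
        erps = simulate_subject_erps(quiet_config, "older01", "older")
        for intensity in ("high", "low"):
            diff = erps[("AV", intensity)] - (erps[("A", intensity)] + erps[("V", intensity)])
            np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_injected_effect_recovered_at_subject_level(self):
        """ROI/window mean of the difference equals the injected amplitude."""
        cfg = SimConfig(
            n_older=1, n_younger=0, seed=3,
            integration_effects=inverse_effectiveness_effect(-1.5),
            noise=NoiseSpec(white_sd_uv=0, pink_sd_uv=0, blink_rate_per_min=0,
                            subject_amp_sd=0, subject_effect_sd=0))
        erps = simulate_subject_erps(cfg, "older01", "older")
        times = synth.erp_times(cfg)
        diff = erps[("AV", "low")] - (erps[("A", "low")] + erps[("V", "low")])
        rows = [cfg.channel_labels.index(ch) for ch in ("F3", "FC5", "FC1")]
        mask = (times >= 60) & (times <= 100)
        assert diff[rows][:, mask].mean() == pytest.approx(-1.5, rel=1e-9)
        # effect confined to its cell: high intensity stays additive
        diff_high = erps[("AV", "high")] - (erps[("A", "high")] + erps[("V", "high")])
        np.testing.assert_allclose(diff_high, 0.0, atol=1e-12)

    def test_trial_average_converges_to_fast_path_signal(self):
        cfg = SimConfig(n_older=1, n_younger=0, seed=9,
                        noise=NoiseSpec(white_sd_uv=2.0, pink_sd_uv=0.0,
                                        blink_rate_per_min=0,
                                        subject_amp_sd=0, subject_effect_sd=0))
        epochs, times = simulate_epochs(cfg, "older01", "older", "A", "high", 400)
        avg = epochs.mean(axis=0)
        tpl = [c for c in cfg.components if c.modality == "A" and c.intensity == "high"]
        sig, _ = erp_template(tpl, cfg.channel_labels, cfg.sampling_rate)
        resid = avg - sig
        assert np.abs(resid).mean() < 3 * 2.0 / np.sqrt(400)


class TestContinuousRecording:
    def test_blinks_exceed_rejection_threshold(self, small_design):
        cfg = SimConfig(n_older=1, n_younger=0, seed=4, design=small_design,
                        noise=NoiseSpec(white_sd_uv=1.0, pink_sd_uv=1.0,
                                        blink_rate_per_min=10.0,
                                        blink_amplitude_uv=150.0))
        rec, _ = simulate_subject(cfg, "older01", "older")
        fp1 = rec.data[rec.channel_index("Fp1")]
        assert np.abs(fp1).max() > 100.0

    def test_events_have_samples_within_bounds(self, small_design):
        cfg = SimConfig(n_older=1, n_younger=0, seed=5, design=small_design)
        rec, events = simulate_subject(cfg, "older01", "older")
        assert all(0 <= e.sample < rec.n_samples for e in rec.events)
        assert len(events) == len(rec.events)

    def test_deterministic(self, small_design):
        cfg = SimConfig(n_older=1, n_younger=0, seed=6, design=small_design)
        r1, _ = simulate_subject(cfg, "older01", "older")
        r2, _ = simulate_subject(cfg, "older01", "older")
        np.testing.assert_array_equal(r1.data, r2.data)


class TestBehavior:
    def _events(self, cfg, n=200):
        return make_design(cfg.design, seed=1, intensity="low")

    def test_degenerate_probabilities(self, quiet_config):
        cfg = quiet_config
        for cell in cfg.behavior.values():
            cell.hit_p, cell.fa_p = 1.0, 0.0
        events = simulate_behavior(cfg, self._events(cfg), "older", seed=0)
        targets = [e for e in events if e.role == "target"]
        standards = [e for e in events if e.role == "standard"]
        assert all(e.responded for e in targets)
        assert not any(e.responded for e in standards)

    def test_rt_mean_recovers_parameter(self):
        """Pure-Gaussian cell: sample mean within 3 SE of mu = 502."""
        cfg = SimConfig(seed=2, rt_subject_sd_ms=0.0)
        cell = cfg.behavior[("younger", "low", "AV")]
        cell.rt_mu_ms, cell.rt_sigma_ms, cell.rt_tau_ms = 502.0, 62.0, 0.0
        cell.hit_p = 1.0
        rng_events = []
        for s in range(30):
            rng_events.extend(make_design(cfg.design, seed=s, intensity="low"))
        events = simulate_behavior(cfg, rng_events, "younger", seed=11)
        rts = [e.response_time_ms for e in events
               if e.modality == "AV" and e.role == "target" and e.responded]
        se = 62.0 / np.sqrt(len(rts))
        assert abs(np.mean(rts) - 502.0) < 3 * se

    def test_hit_rate_within_binomial_ci(self):
        cfg = SimConfig(seed=3)
        for cell in cfg.behavior.values():
            cell.hit_p = 0.5
        events = []
        for s in range(80):  # 80 blocks x 90 targets > 10^3 per modality
            events.extend(make_design(cfg.design, seed=100 + s, intensity="high"))
        out = simulate_behavior(cfg, events, "older", seed=12)
        targets = [e for e in out if e.role == "target"]
        ht = np.mean([e.responded for e in targets])
        half = 2.576 * np.sqrt(0.25 / len(targets))
        assert abs(ht - 0.5) < half

    def test_rt_ordering_av_v_a_in_defaults(self):
        beh = synth._default_behavior()
        for group in ("older", "younger"):
            for intensity in ("high", "low"):
                means = {m: beh[(group, intensity, m)].rt_mu_ms + beh[(group, intensity, m)].rt_tau_ms
                         for m in MODALITIES}
                assert means["AV"] < means["V"] < means["A"]


class TestCohort:
    def test_default_cohort_is_38_subjects(self):
        cfg = SimConfig(seed=0, n_older=18, n_younger=20)
        assert len(cfg.subjects()) == 38

    def test_two_subject_cohort_manifest(self, tmp_path, quiet_config):
        bundle = simulate_cohort(quiet_config, out_dir=tmp_path)
        manifest = bundle.manifest()
        assert len(manifest["subjects"]) == 2
        assert (tmp_path / "manifest.json").exists()
        assert sorted(p.name for p in tmp_path.glob("*_log.tsv")) == \
            ["older01_log.tsv", "younger01_log.tsv"]

    def test_same_seed_identical_output(self, quiet_config):
        b1 = simulate_cohort(quiet_config)
        b2 = simulate_cohort(quiet_config)
        for sid in b1.erps:
            for key in b1.erps[sid]:
                np.testing.assert_array_equal(b1.erps[sid][key], b2.erps[sid][key])
        assert [(e.onset_ms, e.response_time_ms) for e in b1.logs["older01"]] == \
               [(e.onset_ms, e.response_time_ms) for e in b2.logs["older01"]]


class TestConfigValidation:
    def test_unknown_roi_channel_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(integration_effects=[IntegrationEffectSpec(
                (60, 100), ["NotAChannel"], -1.5)])

    def test_window_outside_analysis_range_rejected(self):
        with pytest.raises(ConfigError):
            IntegrationEffectSpec((350, 450), ["F3"], -1.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            NoiseSpec(white_sd_uv=-1.0)
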