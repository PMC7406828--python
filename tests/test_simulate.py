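"""Synthetic cohort: event layout, determinism and effect recovery."""

import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import ttest_ind

from expmse_decode.errors import ConfigError
from expmse_decode.simulate import (DK_REGIONS, EffectSpec, REGION_GROUPS,
                                    SimulationConfig, generate_cohort,
                                    generate_events, generate_recording)


def small_config(**overrides):
    params = dict(
        n_subjects=1, n_regions=2,
        region_labels=("lateraloccipital-lh", "precentral-lh"),
        n_sessions=1, trials_per_task=2, tasks=("VP", "ME"),
        master_seed=7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


class TestEvents:
    def test_default_layout_has_one_row_per_session_task_trial(self):
        events = generate_events(SimulationConfig())
        assert len(events) == 3 * 12 * 8 == 288
        # fixed task order within each session
        session1 = events[events["session"] == 1]
        order = session1["task"].drop_duplicates().tolist()
        assert tuple(order) == SimulationConfig().tasks

    def test_trials_are_back_to_back(self):
        cfg = small_config(tasks=("VP",), trials_per_task=2)
        events = generate_events(cfg)
        assert len(events) == 2
        assert events.loc[1, "rest_onset"] == events.loc[0, "task_offset"]

    def test_total_duration_matches_arithmetic(self):
        cfg = SimulationConfig()
        events = generate_events(cfg)
        expected = 3 * 12 * 8 * int((6 + 6) * 400)
        assert events["task_offset"].iloc[-1] == expected == cfg.n_samples

    def test_windows_non_overlapping_and_increasing(self):
        events = generate_events(small_config())
        assert (events["task_onset"] > events["rest_onset"]).all()
        assert (events["task_offset"] > events["task_onset"]).all()
        assert (events["rest_onset"].iloc[1:].to_numpy()
                >= events["task_offset"].iloc[:-1].to_numpy()).all()


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"trials_per_task": 1},
        {"tasks": ()},
        {"tasks": ("VP", "VP")},
        {"rest_s": 0.0},
        {"n_subjects": 0},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            SimulationConfig(**bad)

    def test_unknown_effect_region_rejected(self):
        cfg = small_config()
        eff = EffectSpec("VP", ("bananas-lh",), "gamma", 2.0, 1.0)
        with pytest.raises(ConfigError):
            generate_recording(cfg, [eff], subject_seed=0)

    def test_unknown_effect_task_rejected(self):
        cfg = small_config()
        eff = EffectSpec("XX", cfg.region_labels[:1], "gamma", 2.0, 1.0)
        with pytest.raises(ConfigError):
            generate_recording(cfg, [eff], subject_seed=0)

    def test_default_region_labels_are_desikan_killiany(self):
        assert len(DK_REGIONS) == 68
        cfg = SimulationConfig()
        assert cfg.region_labels == DK_REGIONS
        for group, members in REGION_GROUPS.items():
            assert set(members) <= set(DK_REGIONS), group


class TestRecording:
    def test_same_seed_is_bit_identical(self):
        cfg = small_config()
        eff = [EffectSpec("VP", cfg.region_labels[:1], "gamma", 2.0, 2.0)]
        rec1, _ = generate_recording(cfg, eff, subject_seed=3)
        rec2, _ = generate_recording(cfg, eff, subject_seed=3)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        rec3, _ = generate_recording(cfg, eff, subject_seed=4)
        assert not np.array_equal(rec1.data, rec3.data)

    def test_spectral_slope_of_background(self):
        """Background-only log-log spectral slope ~ -noise_exponent."""
        cfg = small_config(tasks=("VP",), trials_per_task=30,
                           noise_exponent=1.0)
        # no oscillation contrast: amplitude/regularity gains of 1
        rec, _ = generate_recording(cfg, [], subject_seed=11)
        # oscillations ride on the background; fit away from band peaks
        f, p = welch(rec.data[0], fs=cfg.fs, nperseg=4096)
        sel = (f >= 1) & (f <= 80) & ~((f > 7) & (f < 50))
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert abs(slope - (-1.0)) < 0.3

    def _band_power(self, x, fs, lo, hi):
        f, p = welch(x, fs=fs, nperseg=1024)
        return p[(f >= lo) & (f <= hi)].mean()

    def test_null_effects_leave_task_and_rest_indistinguishable(self):
        cfg = small_config(tasks=("VP",), trials_per_task=60)
        eff = [EffectSpec("VP", cfg.region_labels, "gamma", 1.0, 1.0)]
        rec, events = generate_recording(cfg, eff, subject_seed=5)
        task_p, rest_p = [], []
        for row in events.itertuples(index=False):
            task_p.append(self._band_power(
                rec.data[0][row.task_onset:row.task_offset], cfg.fs, 35, 45))
            rest_p.append(self._band_power(
                rec.data[0][row.rest_onset:row.task_onset], cfg.fs, 35, 45))
        assert ttest_ind(task_p, rest_p).pvalue > 0.01

    def test_amplitude_gain_recovered_from_band_power(self):
        """Occipital gamma amplitude gain 2 recovered within 20 percent."""
        cfg = small_config(tasks=("VP",), trials_per_task=60)
        gain = 2.0
        eff = [EffectSpec("VP", ("lateraloccipital-lh",), "gamma",
                          gain, 1.0)]
        rec, events = generate_recording(cfg, eff, subject_seed=5)
        x = rec.data[0]
        task_p, rest_p, task_n, rest_n = [], [], [], []
        for row in events.itertuples(index=False):
            t, r = (x[row.task_onset:row.task_offset],
                    x[row.rest_onset:row.task_onset])
            task_p.append(self._band_power(t, cfg.fs, 35, 45))
            rest_p.append(self._band_power(r, cfg.fs, 35, 45))
            # flanking bands estimate the 1/f noise floor under the peak
            task_n.append(np.mean([self._band_power(t, cfg.fs, 25, 32),
                                   self._band_power(t, cfg.fs, 48, 55)]))
            rest_n.append(np.mean([self._band_power(r, cfg.fs, 25, 32),
                                   self._band_power(r, cfg.fs, 48, 55)]))
        excess_task = np.mean(task_p) - np.mean(task_n)
        excess_rest = np.mean(rest_p) - np.mean(rest_n)
        assert np.mean(task_p) > np.mean(rest_p)
        est = np.sqrt(excess_task / excess_rest)
        assert abs(est - gain) / gain < 0.20


class TestCohort:
    def test_cohort_has_distinct_reproducible_subjects(self):
        cfg = small_config(n_subjects=3)
        cohort1 = generate_cohort(cfg)
        cohort2 = generate_cohort(cfg)
        assert len(cohort1) == 3
        for (r1, _), (r2, _) in zip(cohort1, cohort2):
            np.testing.assert_array_equal(r1.data, r2.data)
        assert not np.array_equal(cohort1[0][0].data, cohort1[1][0].data)

    def test_zero_jitter_shares_effect_magnitudes(self):
        cfg = small_config(n_subjects=2, effect_jitter_sd=0.0)
        eff = [EffectSpec("VP", cfg.region_labels[:1], "gamma", 2.0, 1.0)]
        cohort = generate_cohort(cfg, eff)
        # same effect scale, different noise seeds: recordings differ but
        # both realize the unjittered gain; regenerate per-subject with
        # explicit seeds to confirm scales were not jittered
        base0, _ = generate_recording(
            cfg, eff, subject_seed=cohort[0][0].subject)
        # subject field is overwritten by cohort index; rebuild from seeds
        master = np.random.SeedSequence(cfg.master_seed)
        seeds = master.generate_state(2, dtype=np.uint32)
        for s, (rec, _) in enumerate(cohort):
            ref, _ = generate_recording(cfg, eff, int(seeds[s]))
            np.testing.assert_array_equal(rec.data, ref.data)
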