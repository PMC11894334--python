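"""Synthetic-cohort generator: ground-truth contracts and determinism."""

import numpy as np
import pytest

from heartscales import (ChannelScalarMap, CohortSpec, EventTrain,
                         heartbeat_acw, simulate_acw_maps,
                         simulate_behavioural_table, simulate_ecg,
                         simulate_eeg, simulate_taps)
from heartscales.acw import acf
from heartscales.behav import welch_t_from_summary
from heartscales.io import ConfigError
from heartscales.synth import SCORE_RANGES, channel_tau, subject_ids


class TestSimulateEEG:
    def test_ou_autocorrelation_matches_closed_form(self):
        """Sample ACF of a tau=0.05 channel tracks exp(-k/(fs*tau))."""
        spec = CohortSpec(n_per_group=2, n_channels=8, block_duration=120.0,
                          tau_background=0.05, channel_tau_jitter=0.0,
                          subject_tau_jitter=0.0, snr_db=40.0, seed=5)
        rec = simulate_eeg(spec, "sub-HC-00", "exteroception")
        curve = acf(rec.data[0], max_lag=50, fs=spec.fs)
        k = np.arange(51)
        expected = np.exp(-k / (spec.fs * 0.05))
        assert np.max(np.abs(curve.values - expected)) < 0.05

    def test_deterministic_given_seed(self, tiny_spec):
        a = simulate_eeg(tiny_spec, "sub-HC-00", "interoception")
        b = simulate_eeg(tiny_spec, "sub-HC-00", "interoception")
        assert np.array_equal(a.data, b.data)

    def test_effect_added_only_for_patient_interoception(self, tiny_spec):
        labels = tiny_spec.montage[0]
        eff = [labels.index(ch) for ch in tiny_spec.effect_electrodes]
        t_hc = channel_tau(tiny_spec, "sub-HC-00", "interoception")
        t_pat_int = channel_tau(tiny_spec, "sub-bvFTD-00", "interoception")
        t_pat_ext = channel_tau(tiny_spec, "sub-bvFTD-00", "exteroception")
        assert np.all(t_pat_int[eff] > t_hc[eff].max())
        assert np.allclose(t_pat_ext[eff], t_pat_int[eff]
                           - tiny_spec.tau_effect)

    def test_no_effect_spec_gives_equal_groups(self):
        """With tau_effect=0 the patient group is statistically identical."""
        from scipy import stats

        spec = CohortSpec(n_per_group=4, n_channels=8, block_duration=20.0,
                          tau_effect=0.0, seed=17)
        vals = {g: [] for g in spec.groups}
        for sub in subject_ids(spec):
            _, truth = simulate_ecg(spec, sub)
            rec = simulate_eeg(spec, sub, "interoception")
            m = heartbeat_acw(rec, truth)
            vals[spec.subject_group(sub)].append(np.nanmean(m.values))
        p = stats.mannwhitneyu(vals["HC"], vals["bvFTD"]).pvalue
        assert p > 0.01

    def test_unknown_subject_or_condition_rejected(self, tiny_spec):
        with pytest.raises(ConfigError):
            simulate_eeg(tiny_spec, "sub-XX-00", "interoception")
        with pytest.raises(ConfigError):
            simulate_eeg(tiny_spec, "sub-HC-00", "nope")


class TestSimulateECG:
    def test_zero_variance_rr_gives_exact_beats(self):
        spec = CohortSpec(n_per_group=2, n_channels=8, block_duration=60.0,
                          mean_hr=60.0, sdnn=0.0, seed=1)
        _, truth = simulate_ecg(spec, "sub-HC-00", duration=120.0)
        assert len(truth) == 120
        assert np.allclose(np.diff(truth.times), 1.0)

    def test_sdnn_recovered_from_truth_train(self):
        spec = CohortSpec(n_per_group=2, n_channels=8, block_duration=120.0,
                          mean_hr=60.0, sdnn=0.05, seed=2)
        _, truth = simulate_ecg(spec, "sub-HC-00", duration=240.0)
        sdnn = np.diff(truth.times).std()
        assert abs(sdnn - 0.05) < 0.2 * 0.05

    def test_truth_strictly_increasing_min_gap(self, tiny_spec):
        _, truth = simulate_ecg(tiny_spec, "sub-HC-01")
        gaps = np.diff(truth.times)
        assert np.all(gaps >= 0.3 - 1e-12)

    def test_negative_sdnn_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(n_per_group=2, n_channels=8, sdnn=-0.1)


class TestSimulateTaps:
    def test_noiseless_taps_are_shifted_beats(self):
        beats = EventTrain(np.arange(1.0, 50.0, 1.0))
        taps = simulate_taps(beats, tap_noise=0.0, miss_rate=0.0, seed=0,
                             latency=0.2)
        assert np.allclose(taps.times, beats.times + 0.2)

    def test_miss_rate_thins_binomially(self):
        beats = EventTrain(np.arange(1.0, 201.0, 1.0))
        counts = [len(simulate_taps(beats, 0.0, 0.5, seed=s))
                  for s in range(10)]
        assert all(86 <= c <= 114 for c in counts)

    def test_heavy_jitter_output_strictly_increasing(self):
        beats = EventTrain(np.arange(1.0, 101.0, 1.0))
        taps = simulate_taps(beats, tap_noise=1.5, miss_rate=0.0, seed=3)
        assert np.all(np.diff(taps.times) > 0)


class TestBehaviouralTable:
    def test_complete_when_no_missingness(self):
        spec = CohortSpec(n_per_group=5, n_channels=8, missing_rate=0.0,
                          seed=4)
        df = simulate_behavioural_table(spec)
        assert not df.isna().any().any()
        assert len(df) == 10

    def test_scores_respect_scale_ranges(self):
        spec = CohortSpec(n_per_group=20, n_channels=8, missing_rate=0.0,
                          seed=5)
        df = simulate_behavioural_table(spec)
        for score, (lo, hi) in SCORE_RANGES.items():
            assert df[score].between(lo, hi).all()

    def test_group_effect_detectable_by_welch_t(self):
        """A -2.8 point cognitive deficit at n=20/20 yields t > 2 reliably."""
        hits = 0
        for s in range(30):
            spec = CohortSpec(n_per_group=20, n_channels=8,
                              missing_rate=0.0, seed=s)
            df = simulate_behavioural_table(spec)
            hc = df[df.diagnosis == "HC"]["mmse"]
            pat = df[df.diagnosis == "bvFTD"]["mmse"]
            t, _, _ = welch_t_from_summary(
                hc.mean(), hc.std(), len(hc), pat.mean(), pat.std(), len(pat))
            hits += t > 2
        assert hits >= 29

    def test_out_of_range_effect_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(n_per_group=2, n_channels=8,
                       behav_effects={"mmse": -40.0})


class TestAcwMaps:
    def test_shapes_and_determinism(self):
        tau = np.full(16, 0.05)
        m1 = simulate_acw_maps(5, {"A": tau, "B": tau}, seed=9)
        m2 = simulate_acw_maps(5, {"A": tau, "B": tau}, seed=9)
        assert m1["A"].shape == (5, 16)
        assert np.array_equal(m1["B"], m2["B"])

    def test_injected_effect_localises_to_patch(self):
        """The group-difference map peaks on the injected electrodes."""
        tau = np.full(16, 0.05)
        tau2 = tau.copy()
        patch = [3, 4, 5]
        tau2[patch] *= 2
        hits = 0
        for s in range(10):
            m = simulate_acw_maps(15, {"HC": tau, "P": tau2}, seed=s)
            diff = m["P"].mean(axis=0) - m["HC"].mean(axis=0)
            hits += int(np.argmax(diff)) in patch
        assert hits >= 9
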