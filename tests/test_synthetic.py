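"""Generator contracts: rates, determinism, ground-truth consistency."""

import dataclasses

import numpy as np
import pytest

from neurodish import mea
from neurodish import synthetic as syn


class TestSpikeTrains:
    def test_background_rate_matches_poisson_expectation(self):
        """Mean total count over 20 seeds ~ n_el * T * rate (Poisson)."""
        expected = 8 * 600 * 1.0
        counts = []
        for seed in range(20):
            prof = syn.SimulationProfile(
                n_electrodes=8, duration_s=600.0, base_rate_hz=1.0,
                burst_rate_per_min=0.0, seed=seed)
            spikes, bursts = syn.simulate_spike_trains(prof)
            assert bursts == []
            counts.append(sum(t.size for t in spikes.spikes))
        se = np.sqrt(expected / 20)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_burst_count_matches_onset_process(self):
        """Mean ground-truth burst count over 20 seeds ~ rate * duration."""
        expected = 6.0 * 10.0  # 6/min for 600 s
        counts = []
        for seed in range(20):
            prof = syn.SimulationProfile(
                n_electrodes=8, duration_s=600.0, base_rate_hz=0.0,
                burst_rate_per_min=6.0, burst_participation=1.0, seed=seed)
            _, bursts = syn.simulate_spike_trains(prof)
            counts.append(len(bursts))
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 20)

    def test_no_sources_means_no_spikes(self):
        prof = syn.SimulationProfile(base_rate_hz=0.0, burst_rate_per_min=0.0,
                                     duration_s=60.0)
        spikes, bursts = syn.simulate_spike_trains(prof)
        assert sum(t.size for t in spikes.spikes) == 0
        assert bursts == []

    @pytest.mark.parametrize("bad", [
        {"base_rate_hz": -1.0}, {"duration_s": 0.0},
        {"burst_participation": 1.5}, {"synchrony_coupling": -0.1},
        {"base_rate_hz": np.nan},
    ])
    def test_invalid_profiles_rejected(self, bad):
        with pytest.raises(ValueError):
            syn.SimulationProfile(**bad)

    def test_seed_determinism(self):
        prof = syn.SimulationProfile(duration_s=120.0, seed=5)
        s1, b1 = syn.simulate_spike_trains(prof)
        s2, b2 = syn.simulate_spike_trains(prof)
        for a, b in zip(s1.spikes, s2.spikes):
            np.testing.assert_array_equal(a, b)
        assert b1 == b2

    def test_ground_truth_consistent_with_emitted_spikes(self, burst_well):
        """Every realized electrode of every burst fired in its interval."""
        _, spikes, bursts = burst_well
        for b in bursts:
            for el in b.realized:
                t = spikes.spikes[el]
                in_win = (t >= b.onset_s) & (t <= b.onset_s + b.duration_s)
                assert in_win.any()


class TestRawSynthesis:
    def test_pure_tone_dominates_psd(self):
        from neurodish import lfp

        empty = mea.SpikeTrainSet(spikes=[np.array([])], duration_s=20.0)
        raw = syn.synthesize_raw(empty, fs_hz=1000.0,
                                 oscillations=[(5.0, 20.0)],
                                 noise_sd_uV=0.0, seed=0)
        series = lfp.LFPSeries(samples_uV=raw.voltage_uV[0], fs_hz=1000.0)
        psd = lfp.compute_psd(series)
        assert abs(psd.freqs_hz[np.argmax(psd.psd_uV2_per_hz)] - 5.0) < 0.5

    def test_noise_sigma_estimator_consistent(self):
        empty = mea.SpikeTrainSet(spikes=[np.array([])], duration_s=10.0)
        raw = syn.synthesize_raw(empty, fs_hz=10000.0, noise_sd_uV=10.0,
                                 one_over_f_exponent=0.0, seed=1)
        est = mea.estimate_noise_sigma(raw.voltage_uV[0])
        assert abs(est - 10.0) / 10.0 < 0.05

    def test_zero_amplitude_spikes_not_detected(self):
        """TTX emulation: spikes rendered at zero amplitude vanish."""
        t = np.sort(np.random.default_rng(2).uniform(0, 10, 50))
        spikes = mea.SpikeTrainSet(spikes=[t], duration_s=10.0)
        raw = syn.synthesize_raw(spikes, fs_hz=10000.0, spike_amp_sigma=0.0,
                                 noise_sd_uV=5.0, one_over_f_exponent=0.0,
                                 seed=3)
        detected = mea.detect_spikes(raw)
        assert detected.spikes[0].size == 0

    def test_aliasing_rejected(self):
        empty = mea.SpikeTrainSet(spikes=[np.array([])], duration_s=1.0)
        with pytest.raises(ValueError, match="alias"):
            syn.synthesize_raw(empty, fs_hz=1000.0,
                               oscillations=[(600.0, 1.0)])

    def test_one_over_f_noise_slopes_down(self):
        empty = mea.SpikeTrainSet(spikes=[np.array([])], duration_s=60.0)
        raw = syn.synthesize_raw(empty, fs_hz=1000.0, noise_sd_uV=5.0,
                                 one_over_f_exponent=1.0, seed=4)
        from neurodish import lfp

        psd = lfp.compute_psd(lfp.LFPSeries(raw.voltage_uV[0], 1000.0))
        low = psd.psd_uV2_per_hz[(psd.freqs_hz >= 1) & (psd.freqs_hz < 10)]
        high = psd.psd_uV2_per_hz[(psd.freqs_hz >= 100) &
                                  (psd.freqs_hz < 110)]
        assert low.mean() > 5 * high.mean()


class TestCalciumSim:
    def test_full_coupling_no_noise_gives_identical_traces(self):
        prof = syn.CalciumSimProfile(
            n_cells=5, duration_s=200.0, coupling_per_cell=1.0,
            noise_sd=0.0, private_event_rate_per_min=0.0, seed=0)
        traces, _ = syn.simulate_calcium(prof, drive_event_rate_per_min=6.0)
        corr = np.corrcoef(traces.F)
        assert np.allclose(corr, 1.0)

    def test_uncoupled_cells_uncorrelated(self):
        prof = syn.CalciumSimProfile(
            n_cells=6, duration_s=600.0, fs_hz=10.0,
            coupling_per_cell=0.0, noise_sd=0.01,
            private_event_rate_per_min=6.0, seed=1)
        traces, _ = syn.simulate_calcium(prof, drive_event_rate_per_min=6.0)
        assert traces.n_samples >= 5000
        corr = np.corrcoef(traces.F)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.all(np.abs(off) < 0.1)

    def test_zero_event_rates_flat_baseline(self):
        prof = syn.CalciumSimProfile(n_cells=3, duration_s=60.0,
                                     noise_sd=0.0,
                                     private_event_rate_per_min=0.0, seed=2)
        traces, _ = syn.simulate_calcium(prof, drive_event_rate_per_min=0.0)
        assert np.allclose(traces.F, prof.baseline)

    def test_undersampled_kernel_rejected(self):
        with pytest.raises(ValueError, match="[Ss]ampling"):
            syn.CalciumSimProfile(fs_hz=2.0, tau_rise_s=0.2)


class TestMorphologyGen:
    def test_total_length_within_contract(self):
        m = syn.generate_morphology(
            syn.MorphologyParams(target_total_length_um=848.0, seed=3))
        from neurodish.morphometry import morpho_summary

        out = morpho_summary(m)["total_outgrowth_um"]
        assert 763.0 <= out <= 933.0

    def test_primary_neurite_count(self):
        from neurodish.morphometry import morpho_summary

        m = syn.generate_morphology(
            syn.MorphologyParams(n_primary_neurites=3, seed=4))
        assert morpho_summary(m)["n_primary_neurites"] == 3

    def test_same_seed_byte_identical_swc(self, tmp_path):
        from neurodish.morphometry import write_swc

        params = syn.MorphologyParams(seed=5)
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        write_swc(syn.generate_morphology(params), p1)
        write_swc(syn.generate_morphology(params), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_impossible_target_rejected(self):
        with pytest.raises(ValueError):
            syn.MorphologyParams(target_total_length_um=5.0,
                                 mean_segment_um=10.0)


class TestPunctaGen:
    def test_full_colocalization_zero_jitter_coincident(self):
        params = syn.PunctaParams(colocalization_fraction=1.0, jitter_um=0.0,
                                  post_density_per_um=0.0, seed=6)
        field, truth = syn.generate_puncta(params)
        assert truth["n_colocalized"] == len(field.pre_points_um)
        # every pre punctum has an exactly coincident post partner
        for p in field.pre_points_um:
            d = np.linalg.norm(field.post_points_um - p, axis=1)
            assert d.min() < 1e-9

    def test_zero_fraction_only_chance_pairs(self):
        from neurodish.morphometry import colocalize_and_density

        params = syn.PunctaParams(colocalization_fraction=0.0,
                                  pre_density_per_um=0.05,
                                  post_density_per_um=0.05,
                                  neurite_length_um=200.0,
                                  image_shape=(128, 2100), seed=7)
        field, _ = syn.generate_puncta(params)
        n, _, _ = colocalize_and_density(field.pre_points_um,
                                         field.post_points_um,
                                         field.neurite_length_um,
                                         max_dist_um=0.5)
        # chance pairs ~ n_pre * n_post * pi r^2 / field area
        area = 200.0 * 2.0
        expect = (len(field.pre_points_um) * len(field.post_points_um)
                  * np.pi * 0.25 / area)
        assert n <= expect + 3 * np.sqrt(expect + 1) + 1

    def test_zero_density_empty_field(self):
        params = syn.PunctaParams(pre_density_per_um=0.0,
                                  post_density_per_um=0.0,
                                  colocalization_fraction=0.0, seed=8)
        field, truth = syn.generate_puncta(params)
        assert len(field.pre_points_um) == 0
        assert len(field.post_points_um) == 0
        assert truth["n_colocalized"] == 0

    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            syn.PunctaParams(neurite_length_um=100.0, image_shape=(64, 64),
                             pixel_size_um=0.1)

    def test_generators_deterministic(self):
        """Identical seeds reproduce calcium and puncta outputs exactly."""
        cp = syn.CalciumSimProfile(n_cells=4, duration_s=60.0, seed=9)
        (t1, _), (t2, _) = (syn.simulate_calcium(cp) for _ in range(2))
        np.testing.assert_array_equal(t1.F, t2.F)
        pp = syn.PunctaParams(seed=10)
        (f1, _), (f2, _) = (syn.generate_puncta(pp) for _ in range(2))
        np.testing.assert_array_equal(f1.pre_points_um, f2.pre_points_um)
        np.testing.assert_array_equal(f1.post_points_um, f2.post_points_um)
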