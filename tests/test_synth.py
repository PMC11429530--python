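import numpy as np
import pandas as pd
import pytest

from gonogo import behaviour, linkage, montage, spectra, synth
from gonogo.errors import InvalidConfigError


class TestSpecs:
    def test_oscillator_invariants(self):
        with pytest.raises(InvalidConfigError):
            synth.OscillatorSpec(0, 5.0)
        with pytest.raises(InvalidConfigError):
            synth.OscillatorSpec(10, -1.0)
        with pytest.raises(InvalidConfigError):
            synth.OscillatorSpec(10, 5.0, topography=0.5 * np.ones(19))

    def test_erp_invariants(self):
        with pytest.raises(InvalidConfigError):
            synth.ErpTemplateSpec(latency=700.0, width=20.0, amplitude=5.0,
                                  topography=np.ones(19))
        with pytest.raises(InvalidConfigError):
            synth.ErpTemplateSpec(latency=100.0, width=20.0, amplitude=5.0,
                                  topography=np.ones(19),
                                  condition_gain={"Go": -1.0})

    def test_link_invariants(self):
        with pytest.raises(InvalidConfigError):
            synth.BehaviourLinkSpec("osc_9Hz", "bogus", 0.5)
        with pytest.raises(InvalidConfigError):
            synth.BehaviourLinkSpec("osc_9Hz", "mean_rt", 1.5)


class TestScheduleEvents:
    def test_counts_and_spacing(self):
        ev = synth.schedule_events(2, 75, 1100.0, seed=7)
        assert len(ev) == 300
        assert (ev["condition"] == "Go").sum() == 150
        np.testing.assert_allclose(np.diff(ev["onset_ms"]), 1100.0)
        for b in (0, 1):
            block = ev[ev["block"] == b]
            assert (block["condition"] == "Go").sum() == 75
            assert (block["condition"] == "NoGo").sum() == 75

    def test_minimal_case(self):
        ev = synth.schedule_events(1, 1, 1100.0, seed=0)
        assert len(ev) == 2
        assert ev["onset_ms"].iloc[1] - ev["onset_ms"].iloc[0] == 1100.0

    def test_seed_determinism(self):
        a = synth.schedule_events(1, 10, 1100.0, seed=5)
        b = synth.schedule_events(1, 10, 1100.0, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_config(self):
        with pytest.raises(InvalidConfigError):
            synth.schedule_events(0, 10, 1100.0, seed=0)
        with pytest.raises(InvalidConfigError):
            synth.schedule_events(1, 10, -5.0, seed=0)


class TestSynthBackground:
    def test_single_oscillator_peak_amplitude(self):
        topo = montage.gaussian_topography("Pz", 0.9)
        osc = synth.OscillatorSpec(9, 6.0, 2.5, topo)
        sig = synth.synth_background(60.0, 512.0, [osc], 0.0, seed=3)
        ch = int(np.argmax(topo))
        segs = sig[ch, : (sig.shape[1] // 256) * 256].reshape(-1, 256)
        est = spectra.amplitude_spectrum(segs)[:, 9].mean()
        assert est == pytest.approx(6.0, rel=0.05)

    def test_no_sources_zero_signal(self):
        sig = synth.synth_background(5.0, 512.0, [], 0.0, seed=0)
        assert np.all(sig == 0)

    def test_two_oscillators_two_local_maxima(self):
        oscs = [synth.OscillatorSpec(2, 7.0, 2.0, np.ones(19)),
                synth.OscillatorSpec(9, 6.0, 2.0, np.ones(19))]
        sig = synth.synth_background(60.0, 512.0, oscs, 0.0, seed=1)
        segs = sig[0, : (sig.shape[1] // 256) * 256].reshape(-1, 256)
        mean_amp = spectra.amplitude_spectrum(segs).mean(axis=0)
        for peak in (2, 9):
            assert mean_amp[peak] > mean_amp[peak - 2]
            assert mean_amp[peak] > mean_amp[peak + 2]

    def test_one_over_f_declines(self):
        sig = synth.synth_background(60.0, 512.0, [], 3.0, seed=2)
        segs = sig[0, : (sig.shape[1] // 256) * 256].reshape(-1, 256)
        mean_amp = spectra.amplitude_spectrum(segs).mean(axis=0)
        assert mean_amp[2] > mean_amp[8] > mean_amp[25]

    def test_duration_must_cover_schedule(self):
        with pytest.raises(InvalidConfigError):
            synth.synth_background(1.0, 512.0, [], 0.0, seed=0,
                                   events_samples=np.array([5000]))

    def test_bit_reproducible(self):
        osc = synth.OscillatorSpec(9, 6.0, 2.5, np.ones(19))
        a = synth.synth_background(5.0, 512.0, [osc], 2.0, seed=9,
                                   sensor_noise_sd=1.0)
        b = synth.synth_background(5.0, 512.0, [osc], 2.0, seed=9,
                                   sensor_noise_sd=1.0)
        np.testing.assert_array_equal(a, b)


class TestInjectErp:
    def _events(self, n=40, fs=512.0):
        onsets = (2000 + np.arange(n) * 1100.0) * fs / 1000.0
        cond = ["Go", "NoGo"] * (n // 2)
        return pd.DataFrame({"onset_sample": np.round(onsets).astype(int),
                             "condition": cond})

    def test_condition_gated_template_recovered_by_averaging(self):
        fs = 512.0
        events = self._events()
        n_samples = int(events["onset_sample"].max() + 1000)
        topo = montage.gaussian_topography("Cz", 0.9)
        erp = synth.ErpTemplateSpec(100.0, 20.0, 5.0, topo,
                                    {"Go": 1.0, "NoGo": 0.0})
        sig = synth.inject_erp(np.zeros((19, n_samples)), events, [erp], fs)
        cz = montage.EEG_CHANNELS.index("Cz")
        lat = int(round(100 * fs / 1000.0))
        go = events[events.condition == "Go"]["onset_sample"].to_numpy()
        nogo = events[events.condition == "NoGo"]["onset_sample"].to_numpy()
        go_peak = np.mean([sig[cz, o + lat] for o in go])
        nogo_peak = np.mean([sig[cz, o + lat] for o in nogo])
        # nearest grid sample sits 0.4 ms off the 100 ms peak
        assert go_peak == pytest.approx(5.0, rel=1e-3)
        assert nogo_peak == 0.0

    def test_empty_template_list_identity(self, rng):
        sig = rng.standard_normal((19, 5000))
        out = synth.inject_erp(sig, self._events(4), [], 512.0)
        np.testing.assert_array_equal(out, sig)

    def test_gain_linearity(self):
        events = self._events(4)
        n = int(events["onset_sample"].max() + 1000)
        topo = np.ones(19)
        e1 = synth.ErpTemplateSpec(100.0, 20.0, 5.0, topo, {"Go": 1.0, "NoGo": 1.0})
        e2 = synth.ErpTemplateSpec(100.0, 20.0, 5.0, topo, {"Go": 2.0, "NoGo": 2.0})
        s1 = synth.inject_erp(np.zeros((19, n)), events, [e1], 512.0)
        s2 = synth.inject_erp(np.zeros((19, n)), events, [e2], 512.0)
        np.testing.assert_allclose(s2, 2 * s1, atol=1e-12)

    def test_template_beyond_soa_rejected(self):
        erp = synth.ErpTemplateSpec(550.0, 300.0, 5.0, np.ones(19))
        with pytest.raises(InvalidConfigError):
            synth.inject_erp(np.zeros((19, 100)), self._events(2), [erp], 512.0)


class TestInjectEog:
    def test_zero_propagation_identity(self, rng):
        sig = rng.standard_normal((19, 20000))
        out, eog, _ = synth.inject_eog(sig, 512.0, 10.0, np.zeros((4, 19)), seed=1)
        np.testing.assert_array_equal(out, sig)

    def test_propagation_linearity(self):
        prop = np.zeros((4, 19))
        prop[0, 0] = 0.4  # VEOGU -> Fp1
        sig = np.zeros((19, 30000))
        out, eog, intervals = synth.inject_eog(sig, 512.0, 10.0, prop, seed=2,
                                               eog_noise_sd=0.0,
                                               saccade_rate_per_min=0.0)
        assert len(intervals) > 0
        np.testing.assert_allclose(out[0], 0.4 * eog[0], atol=1e-12)
        assert np.all(out[1:] == 0)

    def test_seed_determinism(self, rng):
        sig = rng.standard_normal((19, 20000))
        a = synth.inject_eog(sig, 512.0, 8.0, synth.default_propagation(), seed=5)
        b = synth.inject_eog(sig, 512.0, 8.0, synth.default_propagation(), seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]


class TestSynthBehaviour:
    def test_degenerate_all_rts_equal(self):
        ev = synth.schedule_events(1, 20, 1100.0, seed=0)
        resp = synth.synth_behaviour(ev, None, [], 350.0, seed=1)
        go = ev["condition"] == "Go"
        rts = resp["press_ms"][go].to_numpy() - ev["onset_ms"][go].to_numpy()
        assert np.all(rts == 350.0)
        assert resp["press_ms"][~go].isna().all()

    def test_zero_commission_rate(self):
        ev = synth.schedule_events(1, 30, 1100.0, seed=0)
        params = synth.BehaviourParams(mean_rt=350.0, p_commission=0.0)
        resp = synth.synth_behaviour(ev, None, [], 350.0, seed=2, params=params)
        nogo = ev["condition"] == "NoGo"
        assert resp["press_ms"][nogo].isna().all()

    def test_invalid_strength_rejected(self):
        with pytest.raises(InvalidConfigError):
            synth.BehaviourLinkSpec("osc_9Hz", "mean_rt", -2.0)

    def test_planted_subject_level_rho_recovered(self):
        cfg = synth.default_config(
            n_subjects=40,
            links=[synth.BehaviourLinkSpec("osc_9Hz", "rt_variability", 0.8)])
        recs, truth = synth.simulate_group(cfg, seed=5, with_signal=False)
        rt_vars = []
        for s, rec in recs.items():
            classes = behaviour.classify_trials(rec.events, rec.responses,
                                                cfg.soa_ms, cfg.fs)
            rts = [c.rt_ms for c in classes if c.category == "valid_go"]
            rt_vars.append(behaviour.summarise(classes, rts).rt_variability)
        rho = linkage.spearman_rho(
            truth.subject_amplitudes["osc_9Hz"].to_numpy(), np.array(rt_vars))
        lo, hi = linkage.spearman_ci(0.8, 40)
        assert lo <= rho <= hi

    def test_double_linked_target_rejected(self):
        cfg = synth.default_config(
            links=[synth.BehaviourLinkSpec("osc_9Hz", "mean_rt", 0.5),
                   synth.BehaviourLinkSpec("osc_2Hz", "mean_rt", 0.5)])
        with pytest.raises(InvalidConfigError):
            synth.simulate_group(cfg, seed=0, with_signal=False)


class TestSimulateGroup:
    def test_bit_reproducible(self):
        cfg = synth.default_config(n_subjects=2, n_blocks=1, per_condition=10)
        a_recs, a_truth = synth.simulate_group(cfg, seed=11)
        b_recs, b_truth = synth.simulate_group(cfg, seed=11)
        for s in a_recs:
            np.testing.assert_array_equal(a_recs[s].data, b_recs[s].data)
            pd.testing.assert_frame_equal(a_recs[s].events, b_recs[s].events)
            pd.testing.assert_frame_equal(a_recs[s].responses, b_recs[s].responses)
        pd.testing.assert_frame_equal(a_truth.subject_amplitudes,
                                      b_truth.subject_amplitudes)

    def test_truth_round_trips_to_json(self, tmp_path):
        cfg = synth.default_config(n_subjects=1, n_blocks=1, per_condition=5)
        _, truth = synth.simulate_group(cfg, seed=3)
        path = truth.to_json(tmp_path / "truth.json")
        import json
        doc = json.loads(path.read_text())
        assert doc["seed"] == 3
        assert len(doc["oscillators"]) == 3
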