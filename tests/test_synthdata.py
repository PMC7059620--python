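import numpy as np
import pytest

from surfspike.synthdata import (GROUP_TARGETS, make_stimulus_envelope,
                                 render_waveform_snippets, simulate_session,
                                 simulate_unit_population, waveform_template)
from surfspike.types import ElectrodeGeometry, SessionConfig, UnitSpec
from surfspike.unit_metrics import waveform_features


class TestStimulusEnvelope:
    def test_zero_syllables_all_zero(self):
        env = make_stimulus_envelope(n_syllables=0)
        assert env.values.size == 0 or np.all(env.values == 0)

    def test_layout_matches_closed_form(self):
        # 3 syllables of 0.1 s, 0.2 s gaps, no amplitude jitter: samples above
        # half-max occupy (dur - ramp) per (dur + gap) of the total
        env = make_stimulus_envelope(3, 0.1, 0.2, seed=0, amp_jitter=0.0)
        assert env.values.size == int(np.ceil(0.9 * 200))
        frac = np.mean(env.values > 0.5 * env.values.max())
        ramp = 0.25 * 0.1
        assert frac == pytest.approx((0.1 - ramp) / 0.3, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_nonnegative_for_any_seed(self, seed):
        env = make_stimulus_envelope(seed=seed)
        assert env.values.min() >= 0.0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            make_stimulus_envelope(3, -0.1, 0.2)


class TestUnitPopulation:
    def test_empty_population(self):
        assert simulate_unit_population(0, 0) == []

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            simulate_unit_population(1, 1, feature_targets={"cortex": {}})

    def test_group_medians_converge_to_targets(self):
        pop = simulate_unit_population(200, 200, seed=3)
        for group in ("surface", "depth"):
            units = [u for u in pop if u.group == group]
            tg = GROUP_TARGETS[group]
            durs = np.median([u.waveform_params[2] for u in units])
            amps = np.median([u.waveform_params[1] - u.waveform_params[0] for u in units])
            assert abs(durs - tg["duration_s"]) / tg["duration_s"] < 0.2
            assert abs(amps - tg["amplitude_uv"]) / tg["amplitude_uv"] < 0.2

    def test_bursting_fraction_planted(self):
        pop = simulate_unit_population(23, 46, seed=0)
        surf = [u for u in pop if u.group == "surface"]
        dep = [u for u in pop if u.group == "depth"]
        assert sum(u.bursting for u in surf) == 14
        assert sum(u.bursting for u in dep) == 34

    def test_electrodes_match_probe(self):
        g = ElectrodeGeometry.default()
        pop = simulate_unit_population(5, 5, seed=0, geometry=g)
        for u in pop:
            assert u.electrode_id.startswith("S" if u.group == "surface" else "D")

    def test_deterministic_under_seed(self):
        a = simulate_unit_population(5, 5, seed=42)
        b = simulate_unit_population(5, 5, seed=42)
        assert a == b


class TestWaveformRendering:
    UNIT = UnitSpec("u0", "depth", 2.0, 0.0, 0.05, False, 0.004, 1.0,
                    (-40.0, 20.0, 5e-4), "D00")

    def test_noiseless_average_equals_template(self):
        w = render_waveform_snippets(self.UNIT, n_snippets=3, noise_sd=0.0)
        np.testing.assert_array_equal(w.samples, waveform_template(self.UNIT, 30000.0))

    def test_feature_round_trip(self):
        w = render_waveform_snippets(self.UNIT, noise_sd=0.0)
        f = waveform_features(w)
        assert f.amplitude == pytest.approx(60.0, rel=0.1)
        assert f.trough_peak_ratio == pytest.approx(-0.5, rel=0.1)

    def test_averaging_reduces_noise_per_clt(self):
        template = waveform_template(self.UNIT, 30000.0)
        w = render_waveform_snippets(self.UNIT, n_snippets=50, noise_sd=10.0, seed=5)
        rms = np.sqrt(np.mean((w.samples - template) ** 2))
        assert rms < 3 * 10.0 / np.sqrt(50)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            render_waveform_snippets(self.UNIT, noise_sd=-1.0)


class TestSessionSimulation:
    def test_silent_unit_emits_no_spikes(self):
        u = UnitSpec("u0", "depth", 0.0, 0.0, 0.0, False, 0.004, 0.0,
                     (-40.0, 20.0, 5e-4), "D00")
        sess = simulate_session([u], SessionConfig(n_trials=2, seed=0))
        assert sess.trains["u0"].n_spikes == 0

    def test_empty_population_allowed(self):
        sess = simulate_session([], SessionConfig(n_trials=2, seed=0))
        assert sess.trains == {} and sess.stimulus.onsets.size == 2

    def test_poisson_count_statistics(self):
        u = UnitSpec("u0", "depth", 5.0, 0.0, 0.0, False, 0.004, 1.0,
                     (-40.0, 20.0, 5e-4), "D00")
        cfg = SessionConfig(n_trials=1, seed=11, coupling_strength=0.0, lead_in=100.0)
        sess = simulate_session([u], cfg)
        expected = 5.0 * sess.duration
        assert abs(sess.trains["u0"].n_spikes - expected) < 3 * np.sqrt(expected)

    def test_spike_times_strictly_increasing(self):
        pop = simulate_unit_population(3, 3, seed=2)
        sess = simulate_session(pop, SessionConfig(n_trials=5, seed=2))
        for tr in sess.trains.values():
            assert np.all(np.diff(tr.times) > 0)

    def test_schedule_respects_isi_bounds(self):
        sess = simulate_session([], SessionConfig(n_trials=20, seed=4))
        stim_dur = sess.stimulus.envelopes["BOS"].duration
        gaps = np.diff(sess.stimulus.onsets) - stim_dur
        assert np.all(gaps >= 7.0) and np.all(gaps <= 15.0)

    def test_bit_identical_under_seed_and_stable_to_population_edits(self):
        pop = simulate_unit_population(2, 2, seed=9)
        cfg = SessionConfig(n_trials=3, seed=9)
        s1 = simulate_session(pop, cfg)
        s2 = simulate_session(pop, cfg)
        for uid in s1.trains:
            np.testing.assert_array_equal(s1.trains[uid].times, s2.trains[uid].times)
        # dropping other units leaves a unit's private stream untouched
        kept = pop[0]
        s3 = simulate_session([kept], cfg)
        np.testing.assert_array_equal(s3.trains[kept.unit_id].times,
                                      s1.trains[kept.unit_id].times)

    def test_bursting_unit_has_short_isi_mode(self):
        u = UnitSpec("b0", "depth", 2.0, 0.0, 0.0, True, 0.004, 1.0,
                     (-40.0, 20.0, 5e-4), "D00")
        cfg = SessionConfig(n_trials=1, seed=3, coupling_strength=0.0, lead_in=200.0)
        sess = simulate_session([u], cfg)
        isis = np.diff(sess.trains["b0"].times)
        assert np.mean(isis < 0.01) > 0.2  # intra-burst intervals present
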