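"""Generator determinism, calibration and distributional checks."""

import numpy as np
import pytest

from gustnet import synth
from gustnet.behavior import modal_ili
from gustnet.core import StimulusPanel, ValidationError
from gustnet.optotag import pulse_metrics
from gustnet.responses import compute_profile, lightm_net_response


@pytest.fixture
def suc_only_panel():
    return StimulusPanel(labels=("SUC", "NaCl"))


class TestSimulateSession:
    def test_same_seed_identical_output(self, panel_a):
        specs = synth.default_population(panel_a, 3, 1, 1, seed=4)
        plan = synth.standard_plan(panel_a, n_reps=1)
        a = synth.simulate_session(specs, panel_a, plan, seed=11)
        b = synth.simulate_session(specs, panel_a, plan, seed=11)
        for uid in a.spikes:
            assert np.array_equal(a.spikes[uid].timestamps, b.spikes[uid].timestamps)

    def test_adding_a_neuron_does_not_perturb_others(self, panel_a):
        specs = synth.default_population(panel_a, 2, 0, 0, seed=4)
        plan = synth.standard_plan(panel_a, n_reps=1)
        small = synth.simulate_session(specs, panel_a, plan, seed=11)
        bigger = synth.simulate_session(
            specs + [synth.gplus_unr("extra")], panel_a, plan, seed=11
        )
        uid = specs[0].unit_id
        assert np.array_equal(
            small.spikes[uid].timestamps, bigger.spikes[uid].timestamps
        )

    def test_silent_chr2_unit_emits_binomial_pulse_locked_spikes(self):
        spec = synth.gplus_unr("u", spont=0.0, follow_prob=0.95)
        counts = []
        for seed in range(30):
            spikes, trains = synth.simulate_optotag_block(
                spec, seed=seed, frequencies=(10.0,), n_pulses=100
            )
            counts.append(len(spikes))
        # Binomial(100, 0.95): mean 95, sd ~2.2; 30-seed mean within 99% CI
        assert abs(np.mean(counts) - 95.0) < 3 * 2.2 / np.sqrt(30)
        m = pulse_metrics(spikes, trains)[0]
        assert m.latency_mean_ms == pytest.approx(5.9, abs=1.0)

    def test_mean_stimulus_count_matches_poisson_rate(self, suc_only_panel):
        spec = synth.gminus_taste("u", {"SUC": 4.0}, spont=3.0, g=1.0)
        plan = [("SUC", "control")] * 200
        res = synth.simulate_session([spec], suc_only_panel, plan, seed=5)
        spikes, trials = res.spikes["u"], res.trials["u"]
        counts = [spikes.count_between(*t.stim_window) for t in trials]
        # rate 7 Hz x 10 s = 70; SE = sqrt(70/200) ~ 0.6
        assert np.mean(counts) == pytest.approx(70.0, abs=3 * 0.6 + 1.0)

    def test_unity_gain_means_identical_rate_parameters(self, suc_only_panel):
        spec = synth.gminus_taste("u", {"SUC": 5.0}, spont=2.0, g=1.0, beta=0.0)
        plan = synth.standard_plan(suc_only_panel, n_reps=30)
        res = synth.simulate_session([spec], suc_only_panel, plan, seed=9)
        prof = compute_profile(res.spikes["u"], res.trials["u"], suc_only_panel)
        ctrl = prof.get("SUC", "control").net
        light = prof.get("SUC", "light_br").net
        # both ~50 net spikes; equal in expectation under g=1, beta=0
        assert light == pytest.approx(ctrl, abs=12.0)

    def test_suppressed_evoked_rate_clamps_with_warning(self, suc_only_panel):
        spec = synth.gminus_taste("u", {"SUC": 1.0}, spont=0.0, g=0.5, beta=3.0)
        with pytest.warns(UserWarning, match="clamped"):
            synth.simulate_session(
                [spec], suc_only_panel, [("SUC", "light_br")], seed=1
            )

    def test_generated_tables_pass_validation_round_trip(self, panel_a, tmp_path):
        from gustnet import io

        specs = synth.default_population(panel_a, 3, 1, 1, seed=0)
        res = synth.simulate_session(
            specs, panel_a, synth.standard_plan(panel_a, 1), seed=3
        )
        io.write_spikes(res.spikes, tmp_path / "s.csv")
        io.write_trials(res.trials, tmp_path / "t.csv")
        io.write_pulses(res.pulses, tmp_path / "p.csv")
        assert set(io.read_spikes(tmp_path / "s.csv")) == set(res.spikes)
        assert len(io.read_pulses(tmp_path / "p.csv")) == len(res.pulses)

    def test_ground_truth_serializes(self, panel_a):
        specs = synth.default_population(panel_a, 2, 0, 0, seed=0)
        res = synth.simulate_session(
            specs, panel_a, synth.standard_plan(panel_a, 1), seed=3
        )
        gt = synth.GroundTruth.from_json(res.ground_truth.to_json())
        assert gt.seed == 3
        assert len(gt.neurons) == 2


class TestLightM:
    def test_low_frequency_counts_nondecreasing(self):
        spec = synth.gminus_taste("u", {}, spont=0.5, g=0.5)
        means = {f: [] for f in (2.0, 5.0, 10.0)}
        for seed in range(40):
            spikes, trains = synth.simulate_lightm_series(
                spec, seed=seed, frequencies=(2.0, 5.0, 10.0), conditions=("control",)
            )
            for tr in trains:
                nr = lightm_net_response(spikes, [tr])
                means[tr.nominal_frequency].append(nr.net)
        m = [np.mean(means[f]) for f in (2.0, 5.0, 10.0)]
        assert m[0] < m[1] < m[2]

    def test_brain_light_suppresses_entrainment(self):
        spec = synth.gminus_taste("u", {}, spont=0.0, g=0.4)
        totals = {"control": 0, "light_br": 0}
        for seed in range(20):
            spikes, trains = synth.simulate_lightm_series(
                spec, seed=seed, frequencies=(10.0,)
            )
            for tr in trains:
                t0 = tr.pulse_onsets[0]
                totals[tr.light_condition] += spikes.count_between(t0, t0 + 2.0)
        assert totals["light_br"] < 0.6 * totals["control"]

    def test_same_seed_identical(self):
        spec = synth.gminus_taste("u", {}, spont=1.0)
        a, _ = synth.simulate_lightm_series(spec, seed=2)
        b, _ = synth.simulate_lightm_series(spec, seed=2)
        assert np.array_equal(a.timestamps, b.timestamps)

    def test_empty_frequency_list_rejected(self):
        with pytest.raises(ValidationError):
            synth.simulate_lightm_series(synth.gplus_unr("u"), seed=0, frequencies=())


class TestLickStudy:
    def test_flat_logistic_gives_concentration_independent_slr(self):
        spec = synth.LickSpec(
            "m1",
            logistic_params={"saline": (0.8, 0.8, 2.0, 1.0), "CNO": (0.8, 0.8, 2.0, 1.0)},
            slr_sigma=0.0,
        )
        sessions, _ = synth.simulate_lick_study(
            [spec], "SUC", [30, 100, 300, 1000], "mM", seed=0, n_trials=2
        )
        counts = {t.n_licks for s in sessions for t in s.trials}
        assert len(counts) == 1

    def test_unit_slr_target_gives_about_43_licks(self):
        spec = synth.LickSpec(
            "m1",
            logistic_params={"saline": (1.0, 1.0, 2.0, 1.0), "CNO": (1.0, 1.0, 2.0, 1.0)},
            modal_ili_ms=115.0,
            slr_sigma=0.0,
        )
        sessions, _ = synth.simulate_lick_study(
            [spec], "SUC", [300], "mM", seed=0, n_trials=4
        )
        for s in sessions:
            for t in s.trials:
                assert t.n_licks == round(5.0 / 0.115)  # = 43

    def test_recovered_modal_ili_matches_spec(self):
        spec = synth.sucrose_lick_spec("m1", modal_ili_ms=115.5, ili_sd_ms=8.0)
        sessions, _ = synth.simulate_lick_study(
            [spec], "SUC", [100, 200, 300, 600, 1000], "mM", seed=1, n_trials=4
        )
        ili = modal_ili(sessions[0])
        assert ili == pytest.approx(115.5, abs=5.0)

    def test_determinism(self):
        spec = synth.sucrose_lick_spec("m1")
        a, _ = synth.simulate_lick_study([spec], "SUC", [100, 300], "mM", seed=7)
        b, _ = synth.simulate_lick_study([spec], "SUC", [100, 300], "mM", seed=7)
        for sa, sb in zip(a, b):
            for ta, tb in zip(sa.trials, sb.trials):
                assert np.array_equal(ta.lick_times, tb.lick_times)

    def test_water_trials_included_for_aversive_testing(self):
        spec = synth.LickSpec(
            "m1",
            logistic_params={"saline": (0.1, 0.9, 2.0, -1.0), "CNO": (0.1, 0.9, 2.3, -1.0)},
        )
        sessions, _ = synth.simulate_lick_study(
            [spec], "QUI", [30, 100, 1000, 3000], "uM", seed=0, include_water=True
        )
        assert all("WATER" in s.stimuli for s in sessions)
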