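"""Generator tests: schedules, behavior, and photometry phantoms."""

import numpy as np
import pytest

from fiberpit import simulate as sim
from fiberpit.config import SimConfig
from fiberpit.core import CSTrial, SessionSchedule


class TestContingency:
    def test_first_counterbalance_cell(self):
        c = sim.make_contingency(0)
        assert c.cs_to_outcome == {"tone": "sucrose", "noise": "pellet"}
        assert c.lever_to_outcome == {"left": "sucrose", "right": "pellet"}

    def test_alternation(self):
        c = sim.make_contingency(1)
        assert c.cs_to_outcome == {"tone": "pellet", "noise": "sucrose"}

    def test_even_cohort_is_balanced(self):
        maps = [sim.make_contingency(i).cs_to_outcome["tone"] for i in range(8)]
        assert maps.count("sucrose") == 4
        levers = [sim.make_contingency(i).lever_to_outcome["left"] for i in range(8)]
        assert levers.count("sucrose") == 4

    def test_lever_counterbalanced_independently(self):
        cells = {
            (
                sim.make_contingency(i).cs_to_outcome["tone"],
                sim.make_contingency(i).lever_to_outcome["left"],
            )
            for i in range(4)
        }
        assert len(cells) == 4

    def test_negative_subject_rejected(self):
        with pytest.raises(ValueError):
            sim.make_contingency(-1)


class TestRandomTimeSchedule:
    def test_empty_window(self):
        assert sim.generate_rt_schedule(0.0, 30.0, 0.0, np.random.default_rng(0)) == []

    def test_negative_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sim.generate_rt_schedule(-1.0, 30.0, 0.0, rng)
        with pytest.raises(ValueError):
            sim.generate_rt_schedule(120.0, -30.0, 0.0, rng)

    def test_seed_determinism(self):
        a = sim.generate_rt_schedule(120, 30, 0, np.random.default_rng(42))
        b = sim.generate_rt_schedule(120, 30, 0, np.random.default_rng(42))
        assert a == b

    def test_probe_period_respected(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            times = sim.generate_rt_schedule(120, 30, 15, rng)
            assert all(t > 15 for t in times)
            assert all(t <= 120 for t in times)
            assert times == sorted(times)

    def test_mean_count_matches_rate(self):
        rng = np.random.default_rng(7)
        counts = [len(sim.generate_rt_schedule(120, 30, 0, rng)) for _ in range(4000)]
        assert np.mean(counts) == pytest.approx(4.0, abs=0.1)


class TestConditioningSession:
    def test_standard_trial_counts(self):
        cfg = SimConfig()
        sch = sim.generate_conditioning_session(
            cfg, sim.make_contingency(0), 1, np.random.default_rng(0)
        )
        ids = [t.cs_id for t in sch.trials]
        assert ids.count("tone") == 8 and ids.count("noise") == 8

    def test_photometry_variant_counts(self, photometry_config):
        sch = sim.generate_conditioning_session(
            photometry_config, sim.make_contingency(0), 1, np.random.default_rng(0)
        )
        ids = [t.cs_id for t in sch.trials]
        assert ids.count("tone") == 4 and ids.count("noise") == 4

    def test_no_long_runs_and_iti_bounds(self):
        cfg = SimConfig()
        for seed in range(10):
            sch = sim.generate_conditioning_session(
                cfg, sim.make_contingency(0), 1, np.random.default_rng(seed)
            )
            ids = [t.cs_id for t in sch.trials]
            for i in range(len(ids) - 2):
                assert not (ids[i] == ids[i + 1] == ids[i + 2])
            prev = 0.0
            for t in sch.trials:
                iti = t.onset_s - prev
                assert 120.0 <= iti <= 240.0
                prev = t.offset_s

    def test_probe_constraint_on_rewards(self, photometry_config):
        sch = sim.generate_conditioning_session(
            photometry_config, sim.make_contingency(0), 1, np.random.default_rng(5)
        )
        for t in sch.trials:
            for r in t.reward_times_s:
                assert r - t.onset_s > 15.0

    def test_outcomes_follow_contingency(self):
        cfg = SimConfig()
        c = sim.make_contingency(1)
        sch = sim.generate_conditioning_session(cfg, c, 1, np.random.default_rng(0))
        for t in sch.trials:
            assert t.outcome_id == c.cs_to_outcome[t.cs_id]

    def test_infeasible_count_rejected(self):
        cfg = SimConfig(cs_per_type=0)
        with pytest.raises(ValueError):
            sim.generate_conditioning_session(
                cfg, sim.make_contingency(0), 1, np.random.default_rng(0)
            )

    def test_unpaired_mode_has_no_rewards(self):
        cfg = SimConfig()
        sch = sim.generate_conditioning_session(
            cfg, sim.make_contingency(0), 1, np.random.default_rng(0), unpaired=True
        )
        assert sch.session_kind == "unpaired"
        assert all(not t.reward_times_s for t in sch.trials)


class TestPITSession:
    def test_structure(self):
        cfg = SimConfig()
        sch = sim.generate_pit_session(cfg, np.random.default_rng(0))
        assert sch.extinction_end_s == 300.0
        assert len(sch.trials) == 8
        assert all(not t.reward_times_s for t in sch.trials)
        assert sch.trials[0].onset_s == 300.0
        for a, b in zip(sch.trials, sch.trials[1:]):
            assert b.onset_s - a.offset_s == pytest.approx(240.0)

    def test_zero_reps_gives_extinction_only(self):
        cfg = SimConfig(pit_cs_reps=0)
        sch = sim.generate_pit_session(cfg, np.random.default_rng(0))
        assert sch.trials == []


class TestInstrumentalSession:
    def test_zero_press_rate(self):
        log = sim.generate_instrumental_session(
            SimConfig(), sim.make_contingency(0), "left", 0.0,
            np.random.default_rng(0),
        )
        assert log.end_s == 2700.0
        assert len(log.times("reward_delivery")) == 0

    def test_fast_presser_earns_thirty(self):
        for seed in range(10):
            log = sim.generate_instrumental_session(
                SimConfig(), sim.make_contingency(0), "right", 60.0,
                np.random.default_rng(seed),
            )
            assert len(log.times("reward_delivery")) == 30
            assert log.end_s <= 2700.0

    def test_unknown_lever_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_instrumental_session(
                SimConfig(), sim.make_contingency(0), "middle", 10.0,
                np.random.default_rng(0),
            )

    def test_determinism(self):
        logs = [
            sim.generate_instrumental_session(
                SimConfig(), sim.make_contingency(0), "left", 20.0,
                np.random.default_rng(99),
            )
            for _ in range(2)
        ]
        assert logs[0].events == logs[1].events


class TestSimulateBehavior:
    def test_zero_rates_give_markers_only(self):
        cfg = SimConfig(
            entry_rate_base_per_min=0.0,
            press_rate_base_per_min=0.0,
            retrieval_latency_mean_s=0.0,
        )
        c = sim.make_contingency(0)
        sch = sim.generate_conditioning_session(cfg, c, 1, np.random.default_rng(0))
        log = sim.simulate_behavior(sch, cfg, c, np.random.default_rng(0))
        kinds = {e.kind for e in log.events}
        # retrieval entries still follow deliveries (latency 0)
        assert kinds <= {"cs_on", "cs_off", "reward_delivery", "foodport_entry",
                         "session_start", "session_end"}
        n_deliv = len(log.times("reward_delivery"))
        assert len(log.times("foodport_entry")) == n_deliv

    def test_baseline_entry_count_is_poisson(self):
        # 60-min cue-free, reward-free session at 2 entries/min -> mean 120
        cfg = SimConfig(entry_rate_base_per_min=2.0)
        c = sim.make_contingency(0)
        trial = CSTrial(cs_id="", onset_s=3480.0, offset_s=3480.0)
        sch = SessionSchedule("magazine", 1, [trial])
        rng = np.random.default_rng(11)
        counts = [
            len(sim.simulate_behavior(sch, cfg, c, rng).times("foodport_entry"))
            for _ in range(1000)
        ]
        assert np.mean(counts) == pytest.approx(120.0, abs=1.5)
        assert np.var(counts) == pytest.approx(120.0, rel=0.15)

    def test_same_lever_presses_dominate(self):
        cfg = SimConfig(tau_same=1.0, tau_diff=0.0)
        c = sim.make_contingency(0)
        rng = np.random.default_rng(5)
        same_counts, diff_counts = [], []
        for _ in range(300):
            sch = sim.generate_pit_session(cfg, rng)
            log = sim.simulate_behavior(sch, cfg, c, rng)
            for trial in sch.trials:
                same = c.outcome_to_lever()[c.cs_to_outcome[trial.cs_id]]
                for lever, bucket in (
                    (same, same_counts),
                    ({"left", "right"}.difference({same}).pop(), diff_counts),
                ):
                    presses = log.times("lever_press", lever)
                    bucket.append(
                        np.count_nonzero(
                            (presses >= trial.onset_s) & (presses < trial.offset_s)
                        )
                    )
        assert np.mean(same_counts) > np.mean(diff_counts) * 1.5

    def test_mismatched_contingency_rejected(self):
        cfg = SimConfig()
        c = sim.make_contingency(0)
        sch = sim.generate_conditioning_session(cfg, c, 1, np.random.default_rng(0))
        sch.trials[0].cs_id = "buzzer"
        with pytest.raises(ValueError):
            sim.simulate_behavior(sch, cfg, c, np.random.default_rng(0))


class TestSimulatePhotometry:
    @staticmethod
    def _quiet_config(**kw):
        base = dict(
            bleach_amp1=0.0, bleach_amp2=0.0, motion_sd=0.0, noise_sd=0.0,
            amp_cs=0.0, amp_retrieval=0.0, f0_470=1.0, f0_415=1.0,
            entry_rate_base_per_min=0.0, retrieval_latency_mean_s=0.0,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_all_zero_gives_constant_channels(self):
        cfg = self._quiet_config()
        c = sim.make_contingency(0)
        sch = sim.generate_conditioning_session(cfg, c, 1, np.random.default_rng(0))
        log = sim.simulate_behavior(sch, cfg, c, np.random.default_rng(0))
        rec = sim.simulate_photometry(sch, log, cfg, np.random.default_rng(0))
        for ch in (415, 470):
            _, f = rec.channel_series(ch)
            assert np.allclose(f, 1.0)

    def test_single_transient_peak_matches_kernel_oracle(self):
        cfg = self._quiet_config(amp_cs=0.5, f0_470=2.0)
        c = sim.make_contingency(0)
        onset = 200.0
        sch = SessionSchedule(
            "conditioning", 1,
            [CSTrial(cs_id="tone", onset_s=onset, offset_s=onset + 120.0,
                     outcome_id="sucrose")],
        )
        log = sim.simulate_behavior(sch, cfg, c, np.random.default_rng(0))
        rec = sim.simulate_photometry(sch, log, cfg, np.random.default_rng(0))
        t, f = rec.channel_series(470)
        # oracle: kernel evaluated directly on the sample grid
        rel = np.clip(t - onset, 0.0, None)
        kernel = (1 - np.exp(-rel / cfg.tau_rise_s)) * np.exp(-rel / cfg.tau_decay_s)
        t_peak = cfg.tau_rise_s * np.log1p(cfg.tau_decay_s / cfg.tau_rise_s)
        kernel /= (1 - np.exp(-t_peak / cfg.tau_rise_s)) * np.exp(
            -t_peak / cfg.tau_decay_s
        )
        expected_max = 2.0 * (1 + 0.5 * kernel.max())
        assert f.max() == pytest.approx(expected_max, rel=1e-12)

    def test_channels_interleaved_half_period(self, default_session,
                                              photometry_config):
        _, _, rec, _ = default_session
        t470, _ = rec.channel_series(470)
        t415, _ = rec.channel_series(415)
        half = 0.5 / photometry_config.sample_rate_hz
        assert np.allclose(t415 - t470, half)

    def test_seed_determinism(self, photometry_config):
        c = sim.make_contingency(0)
        recs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            sch = sim.generate_conditioning_session(photometry_config, c, 1, rng)
            log = sim.simulate_behavior(sch, photometry_config, c, rng)
            recs.append(sim.simulate_photometry(sch, log, photometry_config, rng))
        assert np.array_equal(recs[0].fluorescence, recs[1].fluorescence)

    def test_shared_artifact_is_affine_at_matched_times(self):
        cfg = self._quiet_config(motion_sd=2.0, f0_470=100.0, f0_415=80.0,
                                 gain_415=0.8)
        c = sim.make_contingency(0)
        sch = sim.generate_conditioning_session(cfg, c, 1, np.random.default_rng(2))
        log = sim.simulate_behavior(sch, cfg, c, np.random.default_rng(2))
        rec = sim.simulate_photometry(
            sch, log, cfg, np.random.default_rng(2), channel_offset_s=0.0
        )
        _, f470 = rec.channel_series(470)
        _, f415 = rec.channel_series(415)
        assert np.allclose(f470, (100.0 / 80.0) * f415, atol=1e-9)
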