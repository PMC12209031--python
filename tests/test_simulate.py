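import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgtkit.behavior import OMISSION
from rgtkit.ephys import EventSeries, compute_peth, mean_rate_in_window
from rgtkit.simulate import (
    AgentParams,
    SimConfig,
    TaskContingency,
    UnitSpec,
    simulate_ct_table,
    simulate_recording,
    simulate_session,
    simulate_spikes,
)
from rgtkit.expression import relative_expression


def _config(agent: AgentParams, n_trials: int = 90, seed: int = 0, **cont) -> SimConfig:
    return SimConfig(
        contingency=TaskContingency(n_trials=n_trials, **cont),
        agent=agent,
        seed=seed,
    )


class TestSimulateSession:
    def test_degenerate_probabilities_force_all_low_rewarded(self):
        cfg = _config(AgentParams(p_low_choice=1.0, p_omit=0.0), low_risk_prob=1.0)
        session, events = simulate_session(cfg)
        assert len(session) == 90
        assert all(t.outcome == "LR" for t in session.trials)
        assert len(events) == 90

    def test_all_omissions_gives_empty_events(self):
        session, events = simulate_session(_config(AgentParams(p_low_choice=0.5, p_omit=1.0)))
        assert all(t.outcome == OMISSION for t in session.trials)
        assert len(events) == 0

    def test_low_choice_fraction_matches_binomial(self):
        cfg = _config(AgentParams(p_low_choice=0.8, p_omit=0.0), n_trials=10_000, seed=7)
        session, _ = simulate_session(cfg)
        frac = np.mean([t.arm == "low_risk" for t in session.trials])
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(frac - 0.8) < 3 * se

    def test_seed_determinism_is_bit_identical(self):
        cfg = _config(AgentParams(p_low_choice=0.6, p_omit=0.1), seed=42)
        s1, e1 = simulate_session(cfg)
        s2, e2 = simulate_session(cfg)
        assert s1 == s2
        assert np.array_equal(e1.times, e2.times)
        assert np.array_equal(e1.classes, e2.classes)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25)
    def test_trial_conservation(self, seed):
        """trials = completed + omissions; completed = LR+LNo+HR+HNo."""
        cfg = _config(AgentParams(p_low_choice=0.5, p_omit=0.2), seed=seed)
        session, events = simulate_session(cfg)
        counts = {o: sum(t.outcome == o for t in session.trials)
                  for o in ("LR", "LNo", "HR", "HNo", OMISSION)}
        completed = counts["LR"] + counts["LNo"] + counts["HR"] + counts["HNo"]
        assert completed + counts[OMISSION] == len(session)
        assert completed == len(events)

    def test_event_spacing_at_least_inter_trial(self):
        cfg = _config(AgentParams(p_low_choice=0.5, p_omit=0.1), seed=3)
        _, events = simulate_session(cfg)
        assert np.all(np.diff(events.times) >= cfg.contingency.inter_trial)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            TaskContingency(low_risk_prob=1.2)
        with pytest.raises(ValueError):
            AgentParams(p_low_choice=-0.1)

    def test_latencies_within_trial_limit(self):
        cfg = _config(AgentParams(p_low_choice=0.5, latency_mean=10.0, latency_sd=8.0), seed=5)
        session, _ = simulate_session(cfg)
        lats = [t.latency for t in session.completed]
        assert all(0 < l <= cfg.contingency.trial_limit for l in lats)

    def test_mid_session_switch_changes_choice_mix(self):
        agent = AgentParams(p_low_choice=1.0, p_omit=0.0, switch_trial=46, p_low_after=0.0)
        session, _ = simulate_session(_config(agent, seed=2))
        first = [t.arm for t in session.trials[:45]]
        second = [t.arm for t in session.trials[45:]]
        assert set(first) == {"low_risk"} and set(second) == {"high_risk"}


class TestSimulateSpikes:
    def test_silent_unit_yields_empty_train(self):
        unit = UnitSpec(unit_id="u0", baseline_rate=0.0, gain_by_response={"LR": 0.0})
        ev = EventSeries(times=np.array([20.0]), classes=np.array(["LR"], dtype=object))
        (train,) = simulate_spikes([unit], ev, duration=100.0, seed=0)
        assert len(train) == 0

    def test_poisson_count_law_mean_and_variance(self):
        """No events: counts over 200 seeds follow Poisson(rate * duration)."""
        unit = UnitSpec(unit_id="u0", baseline_rate=10.0)
        ev = EventSeries(times=np.empty(0), classes=np.empty(0, dtype=object))
        counts = np.array(
            [len(simulate_spikes([unit], ev, duration=600.0, seed=s)[0]) for s in range(200)],
            dtype=float,
        )
        mu = 6000.0
        assert abs(counts.mean() - mu) < 3 * np.sqrt(mu / 200)
        assert abs(counts.var(ddof=1) - mu) < 3 * mu * np.sqrt(2 / 199)

    def test_gain_three_triples_post_press_rate(self):
        unit = UnitSpec(unit_id="u0", baseline_rate=10.0, gain_by_response={"HR": 3.0})
        times = 20.0 + 20.0 * np.arange(200)
        ev = EventSeries(times=times, classes=np.array(["HR"] * 200, dtype=object))
        (train,) = simulate_spikes([unit], ev, duration=float(times[-1] + 15), seed=1)
        peth = compute_peth(train, ev, class_filter="HR")
        pre = mean_rate_in_window(peth, -5.0, 0.0)
        post = mean_rate_in_window(peth, 0.0, 5.0)
        assert post / pre == pytest.approx(3.0, rel=0.1)

    def test_duration_must_cover_event_windows(self):
        unit = UnitSpec(unit_id="u0", baseline_rate=1.0)
        ev = EventSeries(times=np.array([98.0]), classes=np.array(["LR"], dtype=object))
        with pytest.raises(ValueError):
            simulate_spikes([unit], ev, duration=100.0, seed=0)

    def test_overlapping_windows_warn(self):
        unit = UnitSpec(unit_id="u0", baseline_rate=1.0)
        ev = EventSeries(
            times=np.array([10.0, 12.0]), classes=np.array(["LR", "HR"], dtype=object)
        )
        with pytest.warns(UserWarning, match="overlapping"):
            simulate_spikes([unit], ev, duration=50.0, seed=0)

    def test_timestamps_sorted_within_duration_and_reproducible(self):
        unit = UnitSpec(unit_id="u0", baseline_rate=20.0, gain_by_response={"LR": 2.0})
        ev = EventSeries(times=np.array([30.0, 60.0]), classes=np.array(["LR", "LR"], dtype=object))
        t1 = simulate_spikes([unit], ev, duration=100.0, seed=9)[0].timestamps
        t2 = simulate_spikes([unit], ev, duration=100.0, seed=9)[0].timestamps
        assert np.array_equal(t1, t2)
        assert np.all(np.diff(t1) >= 0)
        assert t1[0] >= 0 and t1[-1] <= 100.0


class TestSimulateCtTable:
    GROUPS = {
        "control": {"GAPDH": (18.0, 0.0), "D1r": (22.0, 0.0)},
        "CFA": {"GAPDH": (18.0, 0.0), "D1r": (21.0, 0.0)},
    }

    def test_zero_sd_replicates_equal_mean(self):
        table = simulate_ct_table(self.GROUPS, n_samples=3, seed=0)
        d1r = table[(table["group"] == "control") & (table["gene"] == "D1r")]
        assert np.allclose(d1r["ct"], 22.0)
        assert d1r.shape[0] == 9  # 3 samples x 3 replicates

    def test_equal_means_give_unit_expression_downstream(self):
        groups = {"g": {"GAPDH": (20.0, 0.0), "tgt": (20.0, 0.0)}}
        table = simulate_ct_table(groups, n_samples=2, seed=0)
        res = relative_expression(table, target="tgt")
        assert np.allclose(res.per_sample["rel_expr"], 1.0)

    def test_one_cycle_shift_halves_expression_downstream(self):
        groups = {"g": {"GAPDH": (20.0, 0.0), "tgt": (21.0, 0.0)}}
        table = simulate_ct_table(groups, n_samples=2, seed=0)
        res = relative_expression(table, target="tgt")
        assert np.allclose(res.per_sample["rel_expr"], 0.5)

    def test_missing_housekeeping_rejected(self):
        with pytest.raises(ValueError, match="housekeeping"):
            simulate_ct_table({"g": {"tgt": (20.0, 0.1)}}, n_samples=2, seed=0)

    def test_determinism(self):
        t1 = simulate_ct_table(self.GROUPS, n_samples=4, seed=5)
        t2 = simulate_ct_table(self.GROUPS, n_samples=4, seed=5)
        assert t1.equals(t2)


class TestRecording:
    def test_recording_is_bit_identical_under_seed(self):
        cfg = SimConfig(
            contingency=TaskContingency(),
            agent=AgentParams(p_low_choice=0.7, p_omit=0.05),
            units=(UnitSpec(unit_id="u0", baseline_rate=6.0, gain_by_response={"LR": 2.0}),),
            seed=21,
        )
        r1 = simulate_recording(cfg)
        r2 = simulate_recording(cfg)
        assert r1.session == r2.session
        assert np.array_equal(r1.spike_trains[0].timestamps, r2.spike_trains[0].timestamps)
        assert r1.duration == r2.duration
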