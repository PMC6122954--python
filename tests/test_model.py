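"""Integrated model behavior: self-localization, encoding, recall,
attention and perturbations."""

import numpy as np
import pytest

from scenemem.analysis import SimulationTrace
from scenemem.experiments import (
    AttentionSchedule,
    apply_rate_noise,
    attention_gain,
    salience_trigger,
    theta_gate,
)
from scenemem.geometry import AgentState, generate_trajectory, square_arena
from scenemem.model import Model
from scenemem.populations import decode_hd, decode_position


@pytest.fixture(scope="module")
def localized_run(arena):
    model = Model(arena, seed=0)
    traj = generate_trajectory(
        arena, [(20, 20), (80, 30), (70, 80), (25, 70)], speed=0.15
    )
    trace = SimulationTrace(populations=Model.POPULATIONS)
    model.run_trajectory(traj, trace=trace)
    return model, trace


class TestSelfLocalization:
    def test_decoded_position_tracks_truth(self, localized_run):
        model, trace = localized_run
        pose = trace.pose
        pc = trace.rates("PC")
        burn = 150
        hits = 0
        for i in range(burn, len(trace)):
            xy = decode_position(pc[i].astype(float), model.layout)
            hits += np.hypot(*(xy - pose[i, :2])) <= model.layout.spacing
        assert hits / (len(trace) - burn) >= 0.95

    def test_ring_follows_heading(self, localized_run):
        model, trace = localized_run
        hd = trace.rates("HD")
        pose = trace.pose
        errs = [
            abs(float(np.angle(np.exp(1j * (decode_hd(hd[i].astype(float))
                                            - pose[i, 2])))))
            for i in range(100, len(trace), 100)
        ]
        assert np.degrees(np.median(errs)) < 5.0


class TestEncodingAndRecall:
    @pytest.fixture(scope="class")
    def encoded_model(self):
        env = square_arena(100.0, objects=[(60.0, 70.0)])
        model = Model(env, seed=0)
        traj = generate_trajectory(env, [(15, 15), (50, 40), (80, 20)],
                                   speed=0.15)
        model.run_trajectory(traj)
        return model

    def test_object_encoded_once(self, encoded_model):
        assert list(encoded_model.weights.events) == ["1"]

    def test_recall_reinstates_heading(self, encoded_model):
        ev = encoded_model.weights.events["1"]
        res = encoded_model.cue_recall("1")
        assert not res["failed"]
        err = np.angle(np.exp(1j * (res["heading"] - ev.heading)))
        assert abs(np.degrees(err)) < 10.0

    def test_recall_reinstates_place_and_scene(self, encoded_model):
        ev = encoded_model.weights.events["1"]
        res = encoded_model.cue_recall("1")
        s = res["state"]
        assert np.corrcoef(s.pc, ev.state.pc)[0, 1] > 0.85
        assert np.corrcoef(s.ovc, ev.state.ovc)[0, 1] > 0.9
        assert res["pw_b"].max() > 0.3  # a scene is reconstructed

    def test_unknown_object_raises(self, encoded_model):
        with pytest.raises(KeyError):
            encoded_model.cue_recall("ghost")

    def test_recall_before_encoding_flags_failure(self):
        env = square_arena(100.0, objects=[(60.0, 70.0)])
        model = Model(env, seed=0)
        res = model.cue_recall("1")
        assert res["failed"]
        assert res["pw_b"].max() < 0.05 and res["pw_o"].max() < 0.05


class TestAttention:
    def test_gains_one_attended_others_suppressed(self):
        sched = AttentionSchedule(["1", "2"])
        g0 = attention_gain(0, sched)
        g1 = attention_gain(600, sched)
        assert g0 == {"1": 1.0, "2": 0.1}
        assert g1 == {"1": 0.1, "2": 1.0}

    def test_single_object_always_attended(self):
        sched = AttentionSchedule(["1"])
        for t in (0, 599, 600, 5000):
            assert attention_gain(t, sched)["1"] == 1.0

    def test_empty_schedule_raises(self):
        with pytest.raises(ValueError):
            attention_gain(0, AttentionSchedule([]))

    def test_model_attends_exactly_one_visible_object(self):
        env = square_arena(100.0, objects=[(40, 70), (60, 70)])
        model = Model(env, seed=0)
        pose = AgentState(np.array([50.0, 40.0]), np.pi / 2)
        model.set_heading(pose.heading)
        seen = set()
        for _ in range(1300):
            model.step_bottom_up(pose)
            att = model._last_attended
            assert att in ("1", "2")
            seen.add(att)
        assert seen == {"1", "2"}  # attention rotates over the cycle


class TestSalience:
    def test_threshold_boundary(self):
        agent = AgentState(np.array([0.0, 0.0]), 0.0)
        assert salience_trigger(agent, ((54.0, 0.0), "1"), encoded=False)
        assert not salience_trigger(agent, ((56.0, 0.0), "1"), encoded=False)

    def test_already_encoded_never_triggers(self):
        agent = AgentState(np.array([0.0, 0.0]), 0.0)
        assert not salience_trigger(agent, ((10.0, 0.0), "1"), encoded=True)


class TestPerturbations:
    def test_rate_noise_statistics(self):
        rates = np.full(100_000, 0.5)
        out = apply_rate_noise(rates, mean=0.2, sd=0.05, seed=3)
        eps = np.abs(out / 0.5 - 1.0)
        assert abs(eps.mean() - 0.2) < 0.005

    def test_rate_noise_zero_params_identity(self):
        rates = np.random.default_rng(0).random(1000)
        assert np.allclose(apply_rate_noise(rates, mean=0.0, sd=0.0, seed=1),
                           rates)

    def test_rate_noise_keeps_zeros_silent(self):
        out = apply_rate_noise(np.zeros(100), seed=2)
        assert not out.any()

    def test_ablation_counts_and_determinism(self, arena):
        from scenemem.experiments import ablate_cells

        m1 = ablate_cells(Model(arena, seed=0), 0.2, seed=9)
        m2 = ablate_cells(Model(arena, seed=0), 0.2, seed=9)
        for pop, mask in m1.ablation_masks.items():
            n = m1.population_size(pop)
            assert (mask == 0).sum() == int(np.floor(0.2 * n))
            assert np.array_equal(mask, m2.ablation_masks[pop])
        assert "HD" not in m1.ablation_masks

    def test_zero_fraction_changes_nothing(self, arena):
        from scenemem.experiments import ablate_cells

        m = ablate_cells(Model(arena, seed=0), 0.0, seed=9)
        for mask in m.ablation_masks.values():
            assert mask.all()

    def test_excessive_fraction_rejected(self, arena):
        from scenemem.experiments import ablate_cells

        with pytest.raises(ValueError):
            ablate_cells(Model(arena, seed=0), 0.7, seed=9)


class TestThetaGate:
    def test_duty_cycle_partition(self):
        modes = [theta_gate(t, period=125, duty=0.8).mode for t in range(125)]
        assert modes.count("bottom_up") == 100
        assert modes.count("top_down") == 25

    def test_both_modes_occur_each_period(self):
        modes = {theta_gate(t, period=50, duty=0.5).mode for t in range(50)}
        assert modes == {"bottom_up", "top_down"}

    def test_degenerate_duty_rejected(self):
        with pytest.raises(ValueError):
            theta_gate(0, duty=1.0)


class TestMentalNavigation:
    def test_zero_velocity_keeps_scene_static(self, arena):
        from scenemem.grids import gc_drive
        from scenemem.populations import place_rates

        m = Model(arena, seed=0)
        m.state.pc = place_rates(
            m.layout, gc_drive(m.gcpc, m.gc, (40, 50)),
            n_steps=200, competition=m.comp,
        )
        m.imagined_pos = np.array([40.0, 50.0])
        m.set_heading(0.0)
        nav = m.mental_navigate([(0.0, 0.0)] * 80)
        first, last = nav[10]["pw_b"], nav[-1]["pw_b"]
        assert np.abs(first - last).max() < 0.05

    def test_decoded_position_tracks_commands(self, arena):
        from scenemem.grids import gc_drive
        from scenemem.populations import place_rates

        m = Model(arena, seed=0)
        m.state.pc = place_rates(
            m.layout, gc_drive(m.gcpc, m.gc, (30, 50)),
            n_steps=200, competition=m.comp,
        )
        m.imagined_pos = np.array([30.0, 50.0])
        m.set_heading(0.0)
        nav = m.mental_navigate([(0.25, 0.0)] * 200)
        for s in nav:
            err = np.hypot(*(decode_position(s["state"].pc, m.layout)
                             - s["imagined_pos"]))
            assert err <= m.layout.spacing

    def test_closed_loop_returns_to_start(self, arena):
        from scenemem.grids import gc_drive
        from scenemem.populations import place_rates

        m = Model(arena, seed=0)
        m.state.pc = place_rates(
            m.layout, gc_drive(m.gcpc, m.gc, (30, 30)),
            n_steps=200, competition=m.comp,
        )
        m.imagined_pos = np.array([30.0, 30.0])
        loop = ([(0.25, 0.0)] * 160 + [(0.25, np.pi / 2)] * 160
                + [(0.25, np.pi)] * 160 + [(0.25, 3 * np.pi / 2)] * 160)
        nav = m.mental_navigate(loop)
        final = decode_position(nav[-1]["state"].pc, m.layout)
        assert np.hypot(*(final - (30, 30))) <= 1.5 * m.layout.spacing

    def test_exit_commands_clipped_with_warning(self, arena):
        from scenemem.grids import gc_drive
        from scenemem.populations import place_rates

        m = Model(arena, seed=0)
        m.state.pc = place_rates(
            m.layout, gc_drive(m.gcpc, m.gc, (95, 50)),
            n_steps=200, competition=m.comp,
        )
        m.imagined_pos = np.array([95.0, 50.0])
        with pytest.warns(UserWarning):
            m.mental_navigate([(2.0, 0.0)] * 10)
        assert m.imagined_pos[0] <= 98.0


class TestGridContribution:
    def test_bottom_up_grid_input_is_minor(self, arena):
        # removing grid input barely moves the bottom-up position estimate
        pose = AgentState(np.array([60.0, 40.0]), 0.5)
        m1 = Model(arena, seed=0)
        m1.set_heading(pose.heading)
        m2 = Model(arena, seed=0)
        m2.set_heading(pose.heading)
        m2.gcpc.bottom_up_gain = 0.0
        for _ in range(250):
            m1.step_bottom_up(pose)
            m2.step_bottom_up(pose)
        d1 = decode_position(m1.state.pc, m1.layout)
        d2 = decode_position(m2.state.pc, m2.layout)
        assert np.hypot(*(d1 - d2)) < m1.layout.spacing

    def test_top_down_collapses_without_grid_input(self, arena):
        from scenemem.grids import gc_drive
        from scenemem.populations import place_rates

        m = Model(arena, seed=0)
        m.state.pc = place_rates(
            m.layout, gc_drive(m.gcpc, m.gc, (30, 50)),
            n_steps=200, competition=m.comp,
        )
        m.imagined_pos = np.array([30.0, 50.0])
        m.set_heading(0.0)
        m.gcpc.top_down_gain = 0.0
        nav = m.mental_navigate([(0.25, 0.0)] * 150)
        final = nav[-1]["state"].pc
        err = (
            np.inf if final.sum() <= 0
            else np.hypot(*(decode_position(final, m.layout)
                            - nav[-1]["imagined_pos"]))
        )
        assert err > 2 * m.layout.spacing  # no longer tracks commands
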