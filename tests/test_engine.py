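import dataclasses

import numpy as np
import pytest

from osteosip.config import (CompartmentGeometry, MechanicalStimulus,
                             SimulationConfig, apply_scale)
from osteosip.engine import (SPECIES, _nearest_within, _shell_bounds,
                             apply_bindings, apply_load, fire_timers,
                             init_state, move_agents, record_counts,
                             run_simulation, sample_timer, square_wave)


class TestSquareWave:
    def test_high_phase_first(self):
        stim = MechanicalStimulus(magnitude=10_000.0, period=1000.0)
        assert square_wave(0.0, stim) == 10_000.0
        assert square_wave(499.0, stim) == 10_000.0
        assert square_wave(600.0, stim) == 100.0

    def test_periodicity(self, rng):
        stim = MechanicalStimulus(magnitude=5000.0, period=730.0)
        t = rng.uniform(0, 1e5, size=1000)
        assert np.array_equal(square_wave(t, stim),
                              square_wave(t + stim.period, stim))


class TestSampleTimer:
    def test_zero_mean(self, rng):
        assert sample_timer(0.0, None, rng) == 0.0

    def test_monte_carlo_mean_and_support(self, rng):
        draws = np.array([sample_timer(10.0, None, rng) for _ in range(10 ** 5)])
        assert draws.mean() == pytest.approx(10.0, abs=0.1)
        assert draws.min() >= 0.0 and draws.max() <= 20.0

    def test_inverted_support_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_timer(5.0, (10.0, 2.0), rng)


class TestInitState:
    def test_counts_and_determinism(self, tiny_config):
        state = init_state(tiny_config)
        assert state.n_alive == tiny_config.total_agents
        again = init_state(tiny_config)
        assert np.array_equal(state.pos[: state.n], again.pos[: again.n])
        assert np.array_equal(state.timer[: state.n], again.timer[: again.n])

    def test_compartment_containment(self, tiny_config):
        state = init_state(tiny_config)
        bounds = _shell_bounds(tiny_config.geometry)
        r = np.linalg.norm(state.pos[: state.n], axis=1)
        sp = state.species[: state.n]
        assert np.all(r >= bounds[0, sp] - 1e-9)
        assert np.all(r <= bounds[1, sp] + 1e-9)

    def test_membrane_species_on_cell_surface(self, tiny_config):
        state = init_state(tiny_config)
        integrin = SPECIES.index("integrin")
        sel = state.species[: state.n] == integrin
        r = np.linalg.norm(state.pos[: state.n][sel], axis=1)
        assert np.allclose(r, tiny_config.geometry.cell_radius)


class TestMoveAgents:
    def test_zero_diffusion_freezes_positions(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, diffusion_step=0.0,
                                  rules=tiny_config.rules)
        state = init_state(cfg)
        before = state.pos[: state.n].copy()
        move_agents(state)
        assert np.array_equal(before, state.pos[: state.n])

    def test_mean_square_displacement(self):
        # wide shell so reflections are negligible over one step
        cfg = SimulationConfig(
            seed=5, duration=10.0,
            geometry=CompartmentGeometry(2.0, 400.0, 401.0),
            initial_counts={"MEK": 20000}, rules=(), diffusion_step=0.7)
        state = init_state(cfg)
        before = state.pos[: state.n].copy()
        move_agents(state)
        sq = np.sum((state.pos[: state.n] - before) ** 2, axis=1)
        assert sq.mean() == pytest.approx(3 * 0.7 ** 2, rel=0.05)

    def test_reflection_keeps_agents_in_shell(self, tiny_config):
        state = init_state(tiny_config)
        bounds = _shell_bounds(tiny_config.geometry)
        for _ in range(300):
            move_agents(state)
        r = np.linalg.norm(state.pos[: state.n], axis=1)
        sp = state.species[: state.n]
        assert np.all(r >= bounds[0, sp] - 1e-9)
        assert np.all(r <= bounds[1, sp] + 1e-9)


class TestBindings:
    @staticmethod
    def _two_agent_state(distance):
        cfg = SimulationConfig(seed=1, duration=10.0, diffusion_step=0.0,
                               initial_counts={"RAF": 1, "MEK": 1})
        state = init_state(cfg)
        raf = int(np.flatnonzero(state.species[: state.n]
                                 == SPECIES.index("RAF"))[0])
        mek = 1 - raf
        state.active[raf] = True
        state.pos[raf] = np.array([3.0, 0.0, 0.0])
        state.pos[mek] = np.array([3.0 + distance, 0.0, 0.0])
        return state, raf, mek

    def test_within_range_forms_complex(self):
        state, raf, mek = self._two_agent_state(0.5)
        apply_bindings(state)
        assert state.bound[mek] == SPECIES.index("RAF")
        assert state.partner[raf] == mek
        assert np.isfinite(state.timer[mek])  # complex clock armed

    def test_beyond_range_no_reaction(self):
        state, raf, mek = self._two_agent_state(1.5)
        apply_bindings(state)
        assert state.bound[mek] == -1

    def test_kdtree_matches_brute_force(self, rng):
        for _ in range(20):
            seek = rng.uniform(-5, 5, size=(rng.integers(1, 40), 3))
            targ = rng.uniform(-5, 5, size=(rng.integers(1, 40), 3))
            a = _nearest_within(seek, targ, 2.0, method="kdtree")
            b = _nearest_within(seek, targ, 2.0, method="brute")
            assert np.array_equal(a, b)

    def test_engine_binding_equals_brute_force_run(self, tiny_config):
        import copy

        s1 = init_state(tiny_config)
        s2 = copy.deepcopy(s1)
        for _ in range(30):
            for state, method in ((s1, "kdtree"), (s2, "brute")):
                state.time += 1.0
                apply_load(state)
                move_agents(state)
                apply_bindings(state, method=method)
                fire_timers(state)
            assert np.array_equal(record_counts(s1), record_counts(s2))


class TestFireTimers:
    def test_timer_countdown_and_firing(self):
        cfg = SimulationConfig(seed=2, duration=10.0, diffusion_step=0.0,
                               initial_counts={"MEK": 1})
        state = init_state(cfg)
        state.active[0] = True
        state.timer[0] = 5.0
        rule_id = next(r for r, rule in enumerate(cfg.rules)
                       if rule.name == "MEK_deactivation")
        state.timer_rule[0] = rule_id
        for _ in range(3):
            fire_timers(state)
        assert state.timer[0] == pytest.approx(2.0)
        assert state.active[0]
        for _ in range(2):
            fire_timers(state)
        assert not state.active[0]  # fired exactly when the clock hit zero

    def test_uniform_survival_curve(self):
        # population of active molecules with uniform clocks on [0, 20]:
        # the survival curve is linear and hits zero at 20 s
        n = 10_000
        cfg = SimulationConfig(seed=3, duration=30.0, diffusion_step=0.0,
                               initial_counts={"MEK": n})
        state = init_state(cfg)
        state.active[:n] = True
        for i in range(n):
            state.rearm(i, keep_running=False)
        deact_mean = cfg.timer_table()["T_MEKact->MEKd"]
        assert deact_mean == 90.0
        survival = []
        for _ in range(25):
            fire_timers(state)
            survival.append(int(state.active[:n].sum()))
        survival = np.array(survival)
        t = np.arange(1, 26)
        expected = n * (1 - t / (2 * deact_mean))
        sigma = np.sqrt(n * (t / (2 * deact_mean)) * (1 - t / (2 * deact_mean)))
        assert np.all(np.abs(survival - expected) < 5 * sigma + 5)


class TestApplyLoad:
    def test_baseline_load_never_activates(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, stimulus=MechanicalStimulus(magnitude=100.0),
            rules=tiny_config.rules)
        state = init_state(cfg)
        integrin = SPECIES.index("integrin")
        for k in range(100):
            state.time = float(k)
            apply_load(state)
            fire_timers(state)
        sel = state.species[: state.n] == integrin
        assert not np.any(state.active[: state.n][sel])

    def test_reference_load_matches_binomial(self):
        cfg = SimulationConfig(seed=9, duration=10.0,
                               initial_counts={"integrin": 2000})
        state = init_state(cfg)
        apply_load(state)  # t=0, high phase at the reference magnitude
        k = int(state.active[: state.n].sum())
        p = cfg.activation_rate
        mean, sd = 2000 * p, np.sqrt(2000 * p * (1 - p))
        assert abs(k - mean) < 3 * sd

    def test_activation_probability_linear_in_reference(self):
        cfg = SimulationConfig(seed=9, duration=10.0,
                               initial_counts={"integrin": 2000})
        half = dataclasses.replace(
            cfg, stimulus=MechanicalStimulus(magnitude=5050.0),
            rules=cfg.rules)
        # (5050 - 100) / (10000 - 100) = 0.5: half the per-step probability
        state = init_state(half)
        draws = []
        for seed in range(20):
            state = init_state(dataclasses.replace(half, seed=seed,
                                                   rules=half.rules))
            apply_load(state)
            draws.append(int(state.active[: state.n].sum()))
        assert np.mean(draws) == pytest.approx(2000 * cfg.activation_rate / 2,
                                               rel=0.15)


class TestRecording:
    def test_fresh_state_matches_initial_counts(self, tiny_config):
        state = init_state(tiny_config)
        row = record_counts(state)
        assert row.sum() == tiny_config.total_agents

    def test_binding_moves_counts_ledger_style(self):
        state, raf, mek = TestBindings._two_agent_state(0.5)
        before = record_counts(state)
        apply_bindings(state)
        after = record_counts(state)
        assert before.sum() == after.sum() == 2
        assert not np.array_equal(before, after)  # two labels changed

    def test_mass_ledger_exact(self, tiny_config):
        state = init_state(tiny_config)
        for k in range(150):
            prev_total = record_counts(state).sum()
            prev_births, prev_deaths = state.births, state.deaths
            state.time = float(k)
            apply_load(state)
            move_agents(state)
            apply_bindings(state)
            fire_timers(state)
            total = record_counts(state).sum()
            assert total - prev_total == ((state.births - prev_births)
                                          - (state.deaths - prev_deaths))


class TestRunSimulation:
    def test_row_count_and_reproducibility(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, duration=100.0,
                                  rules=tiny_config.rules)
        ts1 = run_simulation(cfg)
        ts2 = run_simulation(cfg)
        assert ts1.counts.shape[0] == 101
        assert np.array_equal(ts1.counts, ts2.counts)
        assert ts1.tokens() == ts2.tokens()

    def test_null_network_is_frozen(self):
        cfg = SimulationConfig(
            seed=4, duration=50.0, rules=(), diffusion_step=0.0,
            stimulus=MechanicalStimulus(magnitude=100.0),
            initial_counts={"MEK": 50, "ERK": 30})
        ts = run_simulation(cfg)
        assert np.all(ts.counts == ts.counts[0])

    def test_pinned_baseline_load_keeps_cascade_silent(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, duration=500.0,
            stimulus=MechanicalStimulus(magnitude=100.0),
            rules=tiny_config.rules)
        ts = run_simulation(cfg)
        for pattern in ("MEK.active.any.any", "ERK.active.any.any",
                        "RUNX2.active.any.any"):
            try:
                assert np.all(ts.column(pattern) == 0)
            except KeyError:
                pass  # label never appeared: trivially silent

    def test_mean_active_integrins_monotone_in_magnitude(self):
        means = []
        for magnitude in (1000.0, 5000.0, 10_000.0):
            ensemble = []
            for seed in range(10):
                cfg = apply_scale(SimulationConfig(
                    seed=seed, duration=600.0,
                    stimulus=MechanicalStimulus(magnitude=magnitude,
                                                period=1000.0)), 1 / 16)
                ts = run_simulation(cfg)
                ensemble.append(ts.column("integrin.active.any.any").mean())
            means.append(np.mean(ensemble))
        assert means[0] < means[1] < means[2]
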