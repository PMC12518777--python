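import dataclasses

import numpy as np
import pytest

from ringflock import (Agent, FieldRingNetwork, Frame, PeriodicSpace,
                       SimulationConfig, SocialCoupling, SpinRingNetwork,
                       TargetSpec, apply_frame_switch, compose_sources,
                       run_simulation)
from ringflock.geometry import circ_dist, ring_angles
from ringflock.simulation import (Simulation, advance_target,
                                  sample_frame_mode, social_amplitudes)
from ringflock.spin import bump_states


def make_agent(agent_id=0, position=(100.0, 100.0), heading=0.0,
               mode="allo", origin=0.0, n_s=100, states=None):
    net = SpinRingNetwork(n_s, beta=400.0, states=states)
    return Agent(id=agent_id, position=np.asarray(position, float),
                 heading=heading, velocity=np.zeros(2),
                 frame=Frame(mode, origin), network=net, v0=10.0)


class TestFrameSampling:
    def test_degenerate_probabilities(self, rng):
        assert all(sample_frame_mode(0.0, rng) == "allo" for _ in range(50))
        assert all(sample_frame_mode(1.0, rng) == "ego" for _ in range(50))

    def test_bernoulli_frequency(self, rng):
        n = 100_000
        draws = sum(sample_frame_mode(0.8, rng) == "ego" for _ in range(n))
        assert abs(draws / n - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)


class TestFrameSwitch:
    def test_ego_to_allo_is_shift_free(self):
        states = bump_states(100, 10, 50)
        agent = make_agent(mode="ego", heading=1.0, origin=1.0,
                           states=states.copy())
        v_before = agent.network.velocity(
            agent.frame.origin + ring_angles(100), agent.v0)
        apply_frame_switch(agent, "allo")
        assert agent.frame.mode == "allo"
        assert agent.frame.origin == 1.0
        assert np.array_equal(agent.network.states, states)
        v_after = agent.network.velocity(
            agent.frame.origin + ring_angles(100), agent.v0)
        assert np.allclose(v_before, v_after)

    def test_allo_to_ego_with_matching_origin(self):
        states = bump_states(100, 10, 50)
        agent = make_agent(mode="allo", heading=0.0, origin=0.0,
                           states=states.copy())
        apply_frame_switch(agent, "ego")
        assert np.array_equal(agent.network.states, states)

    def test_switch_preserves_world_readout_direction(self):
        # bump at a nonzero allocentric angle; after re-anchoring to the
        # heading the world direction of the readout moves < one neuron
        n_s = 100
        states = bump_states(n_s, 20, 50)
        agent = make_agent(mode="allo", heading=2.0, origin=0.5,
                           states=states.copy(), n_s=n_s)
        v_before = agent.network.velocity(
            agent.frame.origin + ring_angles(n_s), agent.v0)
        dir_before = np.arctan2(v_before[1], v_before[0])
        apply_frame_switch(agent, "ego")
        assert agent.frame.origin == 2.0
        v_after = agent.network.velocity(
            agent.frame.origin + ring_angles(n_s), agent.v0)
        dir_after = np.arctan2(v_after[1], v_after[0])
        assert circ_dist(dir_before, dir_after) <= 2 * np.pi / n_s + 1e-9

    def test_same_mode_is_noop(self):
        agent = make_agent(mode="allo", origin=0.7)
        apply_frame_switch(agent, "allo")
        assert agent.frame.origin == 0.7


class TestTargets:
    def test_static_and_zero_speed_unchanged(self, rng, space1000):
        t = TargetSpec(position=(5.0, 5.0), amplitude=0.1)
        assert advance_target(t, rng, space1000).position == (5.0, 5.0)
        t2 = TargetSpec(position=(5.0, 5.0), amplitude=0.1,
                        motion="random_walk", v_t=0.0)
        assert advance_target(t2, rng, space1000).position == (5.0, 5.0)

    def test_mean_square_displacement(self, rng):
        # unwrapped per-axis MSD after T steps is v_t^2 * T
        space = PeriodicSpace(1e9)  # avoid wrapping
        v_t, steps, reps = 2.0, 64, 300
        sq = []
        for _ in range(reps):
            t = TargetSpec(position=(5e8, 5e8), amplitude=0.1,
                           motion="random_walk", v_t=v_t)
            for _ in range(steps):
                t = advance_target(t, rng, space)
            sq.append((t.position[0] - 5e8) ** 2)
        msd = np.mean(sq)
        assert msd == pytest.approx(v_t**2 * steps, rel=0.25)

    def test_wrapping_keeps_target_in_box(self, rng):
        space = PeriodicSpace(10.0)
        t = TargetSpec(position=(9.9, 0.1), amplitude=0.1,
                       motion="random_walk", v_t=0.3)
        for _ in range(50):
            t = advance_target(t, rng, space)
            assert 0 <= t.position[0] < 10 and 0 <= t.position[1] < 10


class TestComposeSources:
    def test_pairwise_amplitude_is_total_over_population(self, space1000):
        a = make_agent(0, (100, 100))
        b = make_agent(1, (200, 100))
        coupling = SocialCoupling(h_t_s=0.16)
        sources = compose_sources(a, [b], [], coupling, space1000)
        assert len(sources) == 1
        assert sources[0] == (0.0, pytest.approx(0.08))

    def test_distance_decay_close_and_far(self, space1000):
        coupling = SocialCoupling(h_t_s=0.16, variant="distance_decay",
                                  zeta=0.1)
        a = make_agent(0, (0, 0))
        near = make_agent(1, (1.0, 0))
        far = make_agent(2, (400.0, 0))
        s_near = compose_sources(a, [near], [], coupling, space1000)
        s_far = compose_sources(a, [far], [], coupling, space1000)
        assert s_near[0][1] == pytest.approx(0.08, rel=0.02)
        assert s_far[0][1] == pytest.approx(0.08 * np.exp(-400 / 100))

    def test_short_range_repulsion(self, space1000):
        coupling = SocialCoupling(h_t_s=0.16,
                                  variant="short_range_repulsion",
                                  r_c=20.0, h_rep=-0.5)
        a = make_agent(0, (0, 0))
        close = make_agent(1, (10.0, 0))
        sources = compose_sources(a, [close], [], coupling, space1000)
        assert sources[0][1] == -0.5

    def test_coincident_conspecific_skipped(self, space1000):
        a = make_agent(0, (5, 5))
        twin = make_agent(1, (5, 5))
        sources = compose_sources(a, [twin], [], SocialCoupling(h_t_s=0.1),
                                  space1000)
        assert sources == []

    def test_targets_appended(self, space1000):
        a = make_agent(0, (0, 0))
        t = TargetSpec(position=(0.0, 50.0), amplitude=0.0025)
        sources = compose_sources(a, [], [t], SocialCoupling(), space1000)
        assert sources == [(pytest.approx(np.pi / 2), 0.0025)]


class TestRunContracts:
    def test_zero_steps_records_initial_state_only(self):
        rec = run_simulation(SimulationConfig(model="spin", N=3, steps=0,
                                              seed=1))
        assert len(rec.times) == 1 and rec.positions.shape == (1, 3, 2)

    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(model="spin", N=4, steps=30, seed=9,
                               coupling=SocialCoupling(h_t_s=0.1))
        r1, r2 = run_simulation(cfg), run_simulation(cfg)
        assert np.array_equal(r1.positions, r2.positions)
        assert np.array_equal(r1.headings, r2.headings)

    @pytest.mark.parametrize("model", ["spin", "field"])
    def test_switch_with_degenerate_omega_matches_pure_frames(self, model):
        common = dict(model=model, N=5, steps=40, seed=3,
                      coupling=SocialCoupling(h_t_s=0.1))
        for omega, pure in ((0.0, "allo"), (1.0, "ego")):
            r_switch = run_simulation(SimulationConfig(
                frame_policy="switch", omega=omega, **common))
            r_pure = run_simulation(SimulationConfig(
                frame_policy=pure, **common))
            assert np.array_equal(r_switch.positions, r_pure.positions)
            assert np.array_equal(r_switch.headings, r_pure.headings)

    @pytest.mark.parametrize("model", ["spin", "field",
                                       "field_heading_only"])
    def test_speed_never_exceeds_v0(self, model):
        cfg = SimulationConfig(model=model, N=6, steps=60, seed=5,
                               coupling=SocialCoupling(h_t_s=0.2))
        rec = run_simulation(cfg)
        speeds = np.linalg.norm(rec.velocities, axis=-1)
        assert np.all(speeds <= cfg.resolved().v0 + 1e-9)

    def test_translation_symmetry(self):
        base = SimulationConfig(model="field", N=4, steps=50, seed=11,
                                coupling=SocialCoupling(h_t_s=0.2))
        rec = run_simulation(base)
        shift = np.array([250.0, 125.0])
        shifted_init = PeriodicSpace(1000.0).wrap(rec.positions[0] + shift)
        rec2 = run_simulation(dataclasses.replace(
            base, initial_positions=shifted_init))
        expected = PeriodicSpace(1000.0).wrap(rec.positions + shift)
        assert np.allclose(rec2.positions, expected, atol=1e-8)
        assert np.allclose(rec2.headings, rec.headings, atol=1e-10)

    def test_permutation_symmetry(self):
        # relabeling agents while permuting their seed substreams permutes
        # the trajectories
        seeds = [101, 202, 303, 404]
        base = SimulationConfig(model="spin", N=4, steps=30, seed=7,
                                agent_seeds=seeds,
                                coupling=SocialCoupling(h_t_s=0.15))
        rec = run_simulation(base)
        perm = [2, 0, 3, 1]
        rec2 = run_simulation(dataclasses.replace(
            base, agent_seeds=[seeds[p] for p in perm]))
        assert np.allclose(rec2.positions, rec.positions[:, perm, :])
        assert np.allclose(rec2.headings, rec.headings[:, perm])

    def test_record_thinning_and_final_step(self):
        cfg = SimulationConfig(model="field", N=2, steps=25, seed=2,
                               record_every=10)
        rec = run_simulation(cfg)
        assert list(rec.times) == [0, 10, 20, 25]

    def test_early_stop_on_target_proximity(self):
        # frozen bump pointed straight at the target: deterministic arrival
        st = bump_states(100, 76, 50)  # readout direction ~ 0.0314 rad
        cfg = SimulationConfig(
            model="spin", frame_policy="allo", N=1, beta=1e4, steps=500,
            seed=4, stop_at_target_distance=5.0,
            initial_positions=np.array([[100.0, 500.0]]),
            initial_headings=np.array([0.0]),
            initial_network_states=st[None, :],
            targets=[TargetSpec(position=(300.0, 506.3), amplitude=0.0)])
        rec = run_simulation(cfg)
        assert rec.reached_step is not None
        assert rec.reached_step < 80

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="omega"):
            SimulationConfig(omega=1.5).resolved()
        with pytest.raises(ValueError, match="Ns"):
            SimulationConfig(Ns=2).resolved()


class TestEngineAgreesWithSingleNetworks:
    def test_field_engine_matches_network_object(self):
        # one agent, no input: engine row equals a standalone network
        cfg = SimulationConfig(model="field", N=1, steps=0, seed=21)
        sim = Simulation(cfg)
        net = FieldRingNetwork(100, beta=1000.0, nu=0.5, dt=0.3,
                               u=sim.u[0].copy())
        for _ in range(50):
            sim.step()
            net.step()
        assert np.allclose(sim.u[0], net.u, atol=1e-12)

    def test_heading_only_moves_at_constant_speed(self):
        cfg = SimulationConfig(model="field_heading_only", N=2, steps=40,
                               seed=13, coupling=SocialCoupling(h_t_s=0.2))
        rec = run_simulation(cfg)
        speeds = np.linalg.norm(rec.velocities[1:], axis=-1)
        assert np.allclose(speeds, cfg.resolved().v0)


class TestSocialAmplitudeFunction:
    def test_baseline_scales_inverse_population(self):
        amp = social_amplitudes(np.array([10.0, 500.0]),
                                SocialCoupling(h_t_s=0.4), 20, 1000.0)
        assert np.allclose(amp, 0.02)
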