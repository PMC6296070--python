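"""Time integration, pulse protocols, and endpoint classification."""

import numpy as np
import pytest

from gutswitch import PulseProtocol, Trajectory, classify_endpoint, simulate


class TestPulseProtocol:
    def test_value_lookup(self):
        prot = PulseProtocol(baseline=130.0, segments=((50.0, 170.0, 200.0),))
        assert prot.value_at(10.0) == 130.0
        assert prot.value_at(50.0) == 200.0
        assert prot.value_at(170.0) == 130.0

    @pytest.mark.parametrize(
        "segments",
        [((50.0, 40.0, 1.0),), ((0.0, 10.0, 1.0), (5.0, 20.0, 1.0)), ((0.0, 10.0, -1.0),)],
    )
    def test_invalid_protocols_rejected(self, segments):
        with pytest.raises(ValueError):
            PulseProtocol(baseline=130.0, segments=segments)

    def test_edges_inside_span_only(self):
        prot = PulseProtocol(130.0, ((50.0, 170.0, 200.0), (200.0, 270.0, 50.0)))
        assert prot.edges((0.0, 350.0)) == [50.0, 170.0, 200.0, 270.0]
        assert prot.edges((0.0, 100.0)) == [50.0]


class TestSimulate:
    def test_zero_length_span_returns_initial_state(self, params, stable_pair):
        inflamed, _ = stable_pair
        traj = simulate(inflamed.state, params, "core", (0.0, 0.0))
        assert traj.t.shape == (1,)
        assert np.array_equal(traj.states[0], inflamed.state)

    def test_stable_equilibrium_is_stationary(self, params, stable_pair):
        # eigenvalue analysis says both stable states attract; a trajectory
        # started on one must not drift over a long horizon
        for fp in stable_pair:
            traj = simulate(fp.state, params, "core", (0.0, 100.0))
            dev = np.abs(traj.states - fp.state) / np.maximum(np.abs(fp.state), 1e-12)
            assert dev.max() < 1e-6

    def test_states_remain_admissible(self, params):
        rng = np.random.default_rng(3)
        x0 = np.array([rng.uniform(0, 1), *rng.uniform(0.1, 30, 4)])
        traj = simulate(x0, params, "core", (0.0, 50.0))
        assert traj.states.min() >= 0.0
        assert traj.states[:, 0].max() <= 1.0 + 1e-9

    def test_csv_round_trip(self, params, stable_pair, tmp_path):
        inflamed, _ = stable_pair
        prot = PulseProtocol(130.0, ((5.0, 10.0, 200.0),))
        traj = simulate(inflamed.state, params, "core", (0.0, 20.0), prot)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path, "core")
        assert np.allclose(back.states, traj.states)
        assert np.allclose(back.k_Bo_applied, traj.k_Bo_applied)


class TestSwitching:
    """Pulse-driven transitions between the inflamed and healthy states.

    The high pulse must exceed the fold of the inflamed branch
    (k_Bo = 200.117) with enough margin to cross within the pulse
    duration; 205 suffices.  The low pulse at 50 sits below the fold of
    the healthy branch (k_Bo = 59.17) and switches back.
    """

    AMPLITUDE_HIGH = 205.0

    def test_two_way_switch(self, params, stable_pair):
        inflamed, healthy = stable_pair
        prot = PulseProtocol(
            130.0, ((50.0, 170.0, self.AMPLITUDE_HIGH), (200.0, 270.0, 50.0))
        )
        traj = simulate(inflamed.state, params, "core", (0.0, 350.0), prot)
        keep = traj.t <= 199.0
        mid = Trajectory(traj.t[keep], traj.states[keep], traj.k_Bo_applied[keep])
        assert classify_endpoint(mid, [inflamed, healthy]) == 1
        assert classify_endpoint(traj, [inflamed, healthy]) == 0

    def test_hysteresis_memory(self, params, stable_pair):
        # identical final drive, different pulse history, different attractor
        inflamed, healthy = stable_pair
        high = PulseProtocol(130.0, ((10.0, 130.0, self.AMPLITUDE_HIGH),))
        low = PulseProtocol(130.0, ((10.0, 130.0, 50.0),))
        end_high = simulate(inflamed.state, params, "core", (0.0, 300.0), high)
        end_low = simulate(healthy.state, params, "core", (0.0, 300.0), low)
        assert classify_endpoint(end_high, [inflamed, healthy]) == 1
        assert classify_endpoint(end_low, [inflamed, healthy]) == 0

    def test_monostable_drives_erase_history(self, params):
        # far outside the bistable window every start converges to the
        # single remaining state
        rng = np.random.default_rng(11)
        finals_high, finals_low = [], []
        for _ in range(20):
            x0 = np.array([rng.uniform(0, 1), *rng.uniform(0.1, 30, 4)])
            finals_high.append(
                simulate(x0, params.with_(k_Bo=300.0), "core", (0.0, 400.0)).final_state
            )
            finals_low.append(
                simulate(x0, params.with_(k_Bo=20.0), "core", (0.0, 400.0)).final_state
            )
        assert min(s[-1] for s in finals_high) > 50.0
        assert max(s[-1] for s in finals_low) < 5.0


class TestClassifyEndpoint:
    def test_exact_match(self, params, stable_pair):
        inflamed, healthy = stable_pair
        traj = Trajectory(
            np.array([0.0]), healthy.state[None, :], np.array([130.0])
        )
        assert classify_endpoint(traj, [inflamed, healthy]) == 1

    def test_unresolved_far_from_all(self, params, stable_pair):
        state = np.array([0.5, 0.5, 0.5, 0.5, 25.0])
        traj = Trajectory(np.array([0.0]), state[None, :], np.array([130.0]))
        assert classify_endpoint(traj, list(stable_pair)) == "unresolved"

    def test_empty_candidates_rejected(self):
        traj = Trajectory(np.array([0.0]), np.zeros((1, 5)), np.array([130.0]))
        with pytest.raises(ValueError):
            classify_endpoint(traj, [])
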