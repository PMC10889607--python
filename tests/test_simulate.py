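"""Asynchronous update semantics, entropy profiles, steady-state detection."""

import numpy as np
import pytest

from boolsynergy.cellline import CellLineProfile
from boolsynergy.simulate import (
    EntropyProfile,
    async_step,
    detect_steady_state,
    entropy_profile,
    run_ensemble,
    simulate_cell_line,
    steady_state_activities,
)


class TestAsyncStep:
    def test_fixed_point_returned_unchanged(self, toggle_rules, rng):
        state = {"A": 1, "B": 0}  # A = not B, B = not A: already stable
        assert async_step(state, toggle_rules, rng) == state

    def test_single_flip_per_step(self, mutual_activation_rules, rng):
        state = {"A": 1, "B": 0}
        for _ in range(50):
            new = async_step(state, mutual_activation_rules, rng)
            changed = [n for n in state if new[n] != state[n]]
            assert len(changed) <= 1
            state = new

    def test_uniform_choice_among_updatable(self, mutual_activation_rules, rng):
        """At (1,0) both nodes can change; each is picked ~half the time."""
        picks = {"A": 0, "B": 0}
        for _ in range(10_000):
            new = async_step({"A": 1, "B": 0}, mutual_activation_rules, rng)
            changed = next(n for n in "AB" if new[n] != {"A": 1, "B": 0}[n])
            picks[changed] += 1
        assert picks["A"] / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_clamped_node_never_selected(self, make_rules, rng):
        # A's rule wants to turn on, but A is clamped off; B holds state.
        rules = make_rules({"A": "B", "B": "B"}, clamps={"A": 0})
        state = {"A": 0, "B": 1}
        for _ in range(20):
            assert async_step(state, rules, rng) == state


class TestEntropy:
    @staticmethod
    def _traj(states_per_repeat):
        """(repeats, T+1, n) array from a list of per-repeat state sequences."""
        return np.array(states_per_repeat, dtype=bool)

    def test_single_absorbing_state_zero_entropy(self):
        traj = self._traj([[[1, 0]] * 5] * 4)
        assert entropy_profile(traj).H.tolist() == [0.0] * 5

    def test_two_equal_states_one_bit(self):
        traj = self._traj([[[0, 0]], [[0, 0]], [[1, 1]], [[1, 1]]])
        assert entropy_profile(traj).H[0] == pytest.approx(1.0)

    def test_half_quarter_quarter_is_1p5_bits(self):
        traj = self._traj([[[0, 0]], [[0, 0]], [[0, 1]], [[1, 0]]])
        assert entropy_profile(traj).H[0] == pytest.approx(1.5)


class TestSteadyStateDetection:
    def test_linear_decrease_ties_to_earliest(self):
        H = np.linspace(8.0, 0.0, 501)
        assert detect_steady_state(EntropyProfile(H), window=100, stride=10) == 0

    def test_sharp_drop_detected_inside_drop(self):
        """Flat/drop/flat profile: brute-force windowed argmin lands in the drop."""
        H = np.concatenate([np.full(200, 5.0), np.linspace(5.0, 0.0, 41), np.full(260, 0.0)])
        window, stride = 100, 10
        t_star = detect_steady_state(EntropyProfile(H), window=window, stride=stride)
        # independent brute force over every window position
        best, best_slope = None, np.inf
        half = window // 2
        for t in range(0, len(H), stride):
            lo, hi = max(0, t - half), min(len(H) - 1, t + half)
            slope = (H[hi] - H[lo]) / (hi - lo)
            if slope < best_slope - 1e-15:
                best, best_slope = t, slope
        assert t_star == best
        # within half a smoothing window of the drop interval [200, 240]
        assert 200 - window // 2 <= t_star <= 240 + window // 2

    def test_non_finite_entropy_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            detect_steady_state(EntropyProfile(np.array([1.0, np.nan, 0.0])))


class TestEnsembles:
    def test_absorbed_all_ones_gives_unit_activities(self, mutual_activation_rules):
        init = np.ones((10, 2), dtype=bool)
        res = run_ensemble(mutual_activation_rules, init, steps=50, seed=0)
        assert res.steady_activity.tolist() == [1.0, 1.0]

    def test_clamped_node_activity_exactly_clamp(self, make_rules):
        rules = make_rules({"A": "B", "B": "A"}, clamps={"A": 0})
        init = np.ones((20, 2), dtype=bool)
        res = run_ensemble(rules, init, steps=100, seed=1)
        assert res.steady_activity["A"] == 0.0

    def test_activities_bounded(self, toggle_rules, rng):
        init = rng.random((50, 2)) < 0.5
        res = run_ensemble(toggle_rules, init, steps=200, seed=2)
        assert np.all(res.activities >= 0) and np.all(res.activities <= 1)

    def test_toggle_symmetry_half_activity(self, toggle_rules):
        """Mutual inhibition from uniform initial states: each node ~0.5."""
        profile = CellLineProfile("X", {"A": 0.5, "B": 0.5})
        res = simulate_cell_line(toggle_rules, profile, steps=500, repeats=100, seed=3)
        assert res.steady_activity["A"] == pytest.approx(0.5, abs=0.05)
        assert res.steady_activity["B"] == pytest.approx(0.5, abs=0.05)

    def test_seed_determinism_bit_identical(self, toggle_rules):
        profile = CellLineProfile("X", {"A": 0.5, "B": 0.5})
        runs = [
            simulate_cell_line(
                toggle_rules, profile, steps=300, repeats=30, seed=9,
                record_trajectories=True,
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].trajectories, runs[1].trajectories)
        assert runs[0].steady_start == runs[1].steady_start

    def test_consecutive_states_differ_by_at_most_one_node(self, toggle_rules):
        profile = CellLineProfile("X", {"A": 0.5, "B": 0.5})
        res = simulate_cell_line(
            toggle_rules, profile, steps=100, repeats=20, seed=4, record_trajectories=True
        )
        diffs = (res.trajectories[:, 1:, :] != res.trajectories[:, :-1, :]).sum(axis=2)
        assert diffs.max() <= 1

    def test_fixed_point_absorbs(self, toggle_rules):
        """Once a trajectory hits a toggle fixed point (A != B) it never moves."""
        profile = CellLineProfile("X", {"A": 0.5, "B": 0.5})
        res = simulate_cell_line(
            toggle_rules, profile, steps=200, repeats=50, seed=5, record_trajectories=True
        )
        for r in range(res.repeats):
            traj = res.trajectories[r]
            fixed = traj[:, 0] != traj[:, 1]
            first = int(np.argmax(fixed)) if fixed.any() else None
            if first is not None:
                np.testing.assert_array_equal(
                    traj[first:], np.broadcast_to(traj[first], traj[first:].shape)
                )

    def test_steady_window_mean_matches_activities(self, toggle_rules):
        profile = CellLineProfile("X", {"A": 0.5, "B": 0.5})
        res = simulate_cell_line(toggle_rules, profile, steps=200, repeats=40, seed=6)
        manual = steady_state_activities(res.activities, res.steady_start, res.nodes)
        np.testing.assert_allclose(res.steady_activity.to_numpy(), manual.to_numpy())
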