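"""Synthetic generators and the exact asynchronous Markov oracle."""

import numpy as np
import pandas as pd
import pytest

from boolsynergy.cellline import CellLineProfile
from boolsynergy.network import SignalingNetwork, compile_default_rules
from boolsynergy.perturb import ANTAGONIST, Drug
from boolsynergy.simulate import simulate_cell_line
from boolsynergy.synthetic import (
    ScenarioConfig,
    exact_mean_occupancy,
    exact_occupancy,
    generate_ground_truth_synergy,
    generate_network,
    make_scenario,
    planted_pss_scenario,
    transition_matrix,
)


class TestGenerateNetwork:
    def test_two_node_full_density_all_activating_is_toggle(self):
        net, rules = generate_network(2, edge_density=1.0, activating_ratio=1.0, seed=1, and_fraction=0)
        assert sorted((s, t) for s, t, _ in net.edges) == [("N00", "N01"), ("N01", "N00")]
        # both fixed points of mutual activation are invariant
        for state in ({"N00": 0, "N01": 0}, {"N00": 1, "N01": 1}):
            assert rules.step_synchronous(state) == state

    def test_deterministic_given_seed(self):
        a = generate_network(8, edge_density=0.3, seed=42)
        b = generate_network(8, edge_density=0.3, seed=42)
        assert a[0].edges == b[0].edges
        assert a[1] == b[1]

    def test_weak_connectivity(self):
        import networkx as nx

        net, _ = generate_network(15, edge_density=0.1, seed=3)
        g = nx.DiGraph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from((s, t) for s, t, _ in net.edges if s != t)
        assert nx.is_weakly_connected(g)

    @pytest.mark.parametrize("density", [0.0, 1.5])
    def test_bad_density_rejected(self, density):
        with pytest.raises(ValueError, match="density"):
            generate_network(5, edge_density=density)

    def test_no_node_left_without_inputs(self):
        net, _ = generate_network(10, edge_density=0.1, seed=7)
        targets = {t for _, t, _ in net.edges}
        assert set(net.nodes) <= targets  # self-loops cover in-degree-0 nodes


class TestExactOracle:
    def test_transition_rows_sum_to_one(self):
        _, rules = generate_network(6, edge_density=0.3, seed=5)
        P = transition_matrix(rules)
        np.testing.assert_allclose(np.asarray(P.sum(axis=1)).ravel(), 1.0)

    def test_point_mass_on_fixed_point_stays(self, mutual_activation_rules):
        occ = exact_occupancy(mutual_activation_rules, {"A": 1.0, "B": 1.0})
        np.testing.assert_allclose(occ.to_numpy(), [1.0, 1.0])

    def test_mutual_inhibition_symmetry(self, toggle_rules):
        occ = exact_occupancy(toggle_rules, {"A": 0.5, "B": 0.5})
        np.testing.assert_allclose(occ.to_numpy(), [0.5, 0.5], atol=1e-9)

    def test_clamped_node_occupancy_equals_clamp(self, make_rules):
        rules = make_rules({"A": "B", "B": "A"}, clamps={"A": 1})
        occ = exact_occupancy(rules, {"A": 0.0, "B": 0.0})
        assert occ["A"] == pytest.approx(1.0)

    def test_chain_attractor_follows_root(self):
        """A -> B -> C chain: the long-run state is A's initial value everywhere."""
        net = SignalingNetwork(
            nodes=["A", "B", "C"], edges=[("A", "B", "+"), ("B", "C", "+")]
        )
        rules = compile_default_rules(net)  # A has no regulators: holds state
        for a0 in (0.0, 1.0):
            occ = exact_occupancy(rules, {"A": a0, "B": 0.5, "C": 0.5})
            np.testing.assert_allclose(occ.to_numpy(), [a0] * 3, atol=1e-9)

    def test_oracle_node_limit(self):
        _, rules = generate_network(13, edge_density=0.1, seed=1)
        with pytest.raises(ValueError, match="oracle limit"):
            transition_matrix(rules)

    def test_window_mean_converges_to_limit(self, toggle_rules):
        limit = exact_occupancy(toggle_rules, {"A": 0.5, "B": 0.5})
        window = exact_mean_occupancy(toggle_rules, {"A": 0.5, "B": 0.5}, 500, 2000)
        np.testing.assert_allclose(window.to_numpy(), limit.to_numpy(), atol=1e-3)

    def test_oracle_matches_long_ensemble(self):
        """Self-consistency: exact window-mean vs Monte-Carlo within 3 SE."""
        for seed in range(3):
            _, rules = generate_network(7, edge_density=0.25, seed=seed + 50)
            probs = {n: 0.5 for n in rules.nodes}
            res = simulate_cell_line(
                rules, CellLineProfile("X", probs), steps=1500, repeats=400,
                seed=seed, record_trajectories=True,
            )
            per_repeat = res.per_repeat_steady_means()
            se = per_repeat.std(axis=0, ddof=1) / np.sqrt(res.repeats)
            oracle = exact_mean_occupancy(rules, probs, res.steady_start, res.steps)
            diff = np.abs(res.steady_activity.to_numpy() - oracle.to_numpy())
            assert np.all(diff <= 3 * se + 1e-12)


class TestGroundTruth:
    def _setup(self):
        net = SignalingNetwork(
            nodes=["L", "E2F1"], edges=[("L", "L", "+"), ("L", "E2F1", "+")]
        )
        rules = compile_default_rules(net)
        drugs = {
            "d1": Drug("d1", targets=(("L", ANTAGONIST),)),
            "d2": Drug("d2", targets=(("L", ANTAGONIST),)),
        }
        probs = {"CL": {"L": 1.0, "E2F1": 0.5}}
        return {"CL": rules}, probs, drugs

    def test_self_pair_scores_zero_without_noise(self):
        rules, probs, drugs = self._setup()
        out = generate_ground_truth_synergy(
            rules, probs, drugs, [("d1", "d1", "CL")], noise_sd=0.0
        )
        assert out["observed_hsa"].iloc[0] == pytest.approx(0.0)

    def test_redundant_target_pair_is_additive_here(self):
        """Two antagonists of the same single input: combo equals monotherapy."""
        rules, probs, drugs = self._setup()
        out = generate_ground_truth_synergy(
            rules, probs, drugs, [("d1", "d2", "CL")], noise_sd=0.0
        )
        assert out["observed_hsa"].iloc[0] == pytest.approx(0.0)

    def test_observed_equals_hsa_of_reported_effects(self):
        scenario = make_scenario(ScenarioConfig(n_nodes=8, n_drugs=4, n_pairs=4,
                                                cell_lines=("CL1", "CL2"), noise_sd=0.0),
                                 seed=5)
        df = scenario.pairs
        expected = df["effect_combo"] - df[["effect_a", "effect_b"]].max(axis=1)
        np.testing.assert_allclose(df["observed_hsa"], expected, atol=1e-12)

    def test_bit_identical_regeneration(self):
        cfg = ScenarioConfig(n_nodes=8, n_drugs=4, n_pairs=4, cell_lines=("CL1", "CL2"))
        s1 = make_scenario(cfg, seed=9)
        s2 = make_scenario(cfg, seed=9)
        pd.testing.assert_frame_equal(s1.pairs, s2.pairs)
        pd.testing.assert_frame_equal(s1.expression, s2.expression)
        assert s1.network.edges == s2.network.edges
        assert s1.mutations.rows == s2.mutations.rows

    def test_scenario_inputs_well_formed(self):
        scenario = make_scenario(ScenarioConfig(n_nodes=10, n_drugs=5, n_pairs=5,
                                                cell_lines=("CL1", "CL2", "CL3")),
                                 seed=2)
        assert (scenario.expression.to_numpy() >= 0).all()
        assert set(scenario.roles) == set(scenario.network.nodes)
        for drug in scenario.drugs:
            assert 1 <= len(drug.targets) <= 4
        assert len(scenario.pairs) == 5 * 3


class TestPlantedScenario:
    def test_shapes_and_determinism(self):
        a = planted_pss_scenario(n_pairs=20, n_noise=5, seed=3)
        b = planted_pss_scenario(n_pairs=20, n_noise=5, seed=3)
        assert a.pss_matrix.shape == (20, 2 + 2 + 5)
        pd.testing.assert_frame_equal(a.pss_matrix, b.pss_matrix)
        pd.testing.assert_series_equal(a.observed, b.observed)

    def test_noiseless_signal_is_exact_sum(self):
        sc = planted_pss_scenario(n_pairs=10, n_noise=3, noise_sd=0.0, seed=4)
        signal = sc.pss_matrix[["E2F1", "CASP3", *sc.informative]].sum(axis=1)
        np.testing.assert_allclose(sc.observed, signal, atol=1e-12)
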