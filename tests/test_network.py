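"""Default rule compilation, mutation clamps and curated overrides."""

import itertools

import pytest

from boolsynergy.logic import parse_expression
from boolsynergy.network import (
    MutationTable,
    NetworkValidationError,
    RuleOverrideTable,
    SignalingNetwork,
    apply_mutations,
    apply_overrides,
    compile_default_rules,
)


def _expr(rules, node):
    return rules.rules[node].expression


class TestNetworkValidation:
    def test_duplicate_nodes_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate node"):
            SignalingNetwork(nodes=["A", "A"], edges=[])

    def test_unknown_endpoint_named(self):
        with pytest.raises(NetworkValidationError, match="GHOST"):
            SignalingNetwork(nodes=["A"], edges=[("A", "GHOST", "+")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate edge"):
            SignalingNetwork(
                nodes=["A", "B"], edges=[("A", "B", "+"), ("A", "B", "activates")]
            )

    def test_self_loops_reported(self):
        net = SignalingNetwork(nodes=["ES", "X"], edges=[("ES", "ES", "+"), ("ES", "X", "+")])
        assert net.self_loops == {"ES"}


class TestDefaultCompilation:
    def test_multiple_activators_become_or(self):
        net = SignalingNetwork(
            nodes=["A", "B", "C"], edges=[("A", "C", "+"), ("B", "C", "+")]
        )
        rules = compile_default_rules(net)
        assert _expr(rules, "C") == parse_expression("A or B")

    def test_inhibitor_wins_shape(self):
        net = SignalingNetwork(
            nodes=["A", "B", "C", "D"],
            edges=[("A", "D", "+"), ("B", "D", "+"), ("C", "D", "-")],
        )
        rules = compile_default_rules(net)
        assert _expr(rules, "D") == parse_expression("(A or B) and not C")

    def test_inhibitor_only_node(self):
        net = SignalingNetwork(nodes=["A", "B", "C"], edges=[("A", "C", "-"), ("B", "C", "-")])
        rules = compile_default_rules(net)
        assert _expr(rules, "C") == parse_expression("not (A or B)")

    def test_regulator_free_node_holds_state(self):
        net = SignalingNetwork(nodes=["LIG", "X"], edges=[("LIG", "X", "+")])
        rules = compile_default_rules(net)
        assert _expr(rules, "LIG") == parse_expression("LIG")
        for v in (0, 1):
            assert rules.rules["LIG"].evaluate({"LIG": v, "X": 0}) == v

    def test_self_loop_included_as_activator(self):
        net = SignalingNetwork(
            nodes=["ES", "Y"], edges=[("ES", "ES", "+"), ("Y", "ES", "+")]
        )
        rules = compile_default_rules(net)
        assert _expr(rules, "ES") == parse_expression("ES or Y")

    def test_dual_sign_regulation_kept(self):
        """Opposite-sign parallel edges both enter the rule; inhibition wins."""
        net = SignalingNetwork(
            nodes=["A", "C"], edges=[("A", "C", "+"), ("A", "C", "-")]
        )
        rules = compile_default_rules(net)
        assert _expr(rules, "C") == parse_expression("A and not A")
        assert rules.rules["C"].evaluate({"A": 1, "C": 0}) == 0

    def test_inhibitor_wins_exhaustively(self):
        """Any active inhibitor forces the target off, whatever the activators."""
        activators = [f"A{i}" for i in range(3)]
        inhibitors = [f"I{i}" for i in range(2)]
        net = SignalingNetwork(
            nodes=activators + inhibitors + ["T"],
            edges=[(a, "T", "+") for a in activators]
            + [(i, "T", "-") for i in inhibitors],
        )
        rule = compile_default_rules(net).rules["T"]
        for bits in itertools.product([0, 1], repeat=5):
            state = dict(zip(activators + inhibitors, bits))
            state["T"] = 0
            if any(state[i] for i in inhibitors):
                assert rule.evaluate(state) == 0
            else:
                assert rule.evaluate(state) == int(any(state[a] for a in activators))


class TestMutations:
    def test_gof_clamps_to_one(self):
        net = SignalingNetwork(nodes=["PIK3CA", "X"], edges=[("PIK3CA", "X", "+")])
        rules = compile_default_rules(net)
        table = MutationTable([("MCF-7", "PIK3CA", "GOF")])
        clamped = apply_mutations(rules, table, "MCF-7")
        assert clamped.clamps == {"PIK3CA": 1}

    def test_lof_clamps_to_zero(self):
        net = SignalingNetwork(nodes=["TP53", "X"], edges=[("TP53", "X", "+")])
        rules = compile_default_rules(net)
        clamped = apply_mutations(rules, MutationTable([("X1", "TP53", "LOF")]), "X1")
        assert clamped.clamps == {"TP53": 0}

    def test_empty_table_no_clamps(self):
        net = SignalingNetwork(nodes=["A"], edges=[])
        rules = compile_default_rules(net)
        assert apply_mutations(rules, MutationTable([]), "any").clamps == {}

    def test_conflicting_annotations_rejected(self):
        with pytest.raises(NetworkValidationError, match="conflicting"):
            MutationTable([("CL", "TP53", "GOF"), ("CL", "TP53", "LOF")])

    def test_other_cell_lines_untouched(self):
        net = SignalingNetwork(nodes=["TP53"], edges=[])
        rules = compile_default_rules(net)
        table = MutationTable([("CL1", "TP53", "LOF")])
        assert apply_mutations(rules, table, "CL2").clamps == {}


class TestOverrides:
    def test_mtorc1_style_override(self):
        """Widening a single-activator rule with OR terms turns the node on
        when any of the added inputs is active."""
        nodes = ["MTORC1_c", "RHEB", "NRG1", "IGF1", "PIM"]
        net = SignalingNetwork(nodes=nodes, edges=[("RHEB", "MTORC1_c", "+")])
        rules = compile_default_rules(net)
        overrides = RuleOverrideTable(
            [("MCF-7", "MTORC1_c", "RHEB or NRG1 or IGF1 or PIM")]
        )
        out = apply_overrides(rules, overrides, "MCF-7")
        state = {n: 0 for n in nodes}
        state["NRG1"] = 1
        assert rules.rules["MTORC1_c"].evaluate(state) == 0
        assert out.rules["MTORC1_c"].evaluate(state) == 1

    def test_and_to_or_override(self):
        """Relaxing AND to OR flips the output on the (0,0) regulator state."""
        nodes = ["KMT2D_c", "PAX7", "AKT_i"]
        net = SignalingNetwork(
            nodes=nodes, edges=[("PAX7", "KMT2D_c", "+"), ("AKT_i", "KMT2D_c", "-")]
        )
        rules = compile_default_rules(net)
        out = apply_overrides(
            rules,
            RuleOverrideTable([("MCF-7", "KMT2D_c", "PAX7 or not AKT_i")]),
            "MCF-7",
        )
        state = {"PAX7": 0, "AKT_i": 0, "KMT2D_c": 0}
        assert rules.rules["KMT2D_c"].evaluate(state) == 0
        assert out.rules["KMT2D_c"].evaluate(state) == 1

    def test_empty_override_is_identity(self):
        net = SignalingNetwork(nodes=["A", "B"], edges=[("A", "B", "+")])
        rules = compile_default_rules(net)
        assert apply_overrides(rules, RuleOverrideTable([]), "CL") == rules

    def test_override_on_clamped_node_warns_clamp_wins(self):
        net = SignalingNetwork(nodes=["A", "B"], edges=[("A", "B", "+")])
        rules = apply_mutations(
            compile_default_rules(net), MutationTable([("CL", "B", "LOF")]), "CL"
        )
        with pytest.warns(UserWarning, match="clamp wins"):
            out = apply_overrides(
                rules, RuleOverrideTable([("CL", "B", "A or B")]), "CL"
            )
        assert out.clamps["B"] == 0


class TestComposition:
    def _base(self):
        net = SignalingNetwork(
            nodes=["A", "B", "C"], edges=[("A", "C", "+"), ("B", "C", "-")]
        )
        return compile_default_rules(net)

    def test_idempotent(self):
        rules = self._base()
        muts = MutationTable([("CL", "A", "GOF")])
        ovr = RuleOverrideTable([("CL", "C", "A or B")])
        once_m = apply_mutations(rules, muts, "CL")
        assert apply_mutations(once_m, muts, "CL") == once_m
        once_o = apply_overrides(rules, ovr, "CL")
        assert apply_overrides(once_o, ovr, "CL") == once_o

    def test_commute_on_disjoint_nodes(self):
        rules = self._base()
        muts = MutationTable([("CL", "A", "GOF")])
        ovr = RuleOverrideTable([("CL", "C", "A or B")])
        mo = apply_overrides(apply_mutations(rules, muts, "CL"), ovr, "CL")
        om = apply_mutations(apply_overrides(rules, ovr, "CL"), muts, "CL")
        assert mo == om
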