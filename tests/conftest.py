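import numpy as np
import pytest

from boolsynergy.logic import parse_expression
from boolsynergy.network import (
    BooleanRule,
    RuleSet,
    SignalingNetwork,
    compile_default_rules,
)


def rules_from_strings(expressions: dict[str, str], clamps: dict[str, int] | None = None) -> RuleSet:
    """Build a RuleSet from {node: infix expression} strings."""
    rules = {
        node: BooleanRule(node, parse_expression(expr))
        for node, expr in expressions.items()
    }
    return RuleSet(rules, clamps=clamps)


@pytest.fixture
def make_rules():
    return rules_from_strings


@pytest.fixture
def toggle_rules():
    """Two-node mutual inhibition: bistable toggle with fixed points (1,0), (0,1)."""
    net = SignalingNetwork(nodes=["A", "B"], edges=[("A", "B", "-"), ("B", "A", "-")])
    return compile_default_rules(net)


@pytest.fixture
def mutual_activation_rules():
    """Two-node mutual activation: fixed points (0,0) and (1,1)."""
    net = SignalingNetwork(nodes=["A", "B"], edges=[("A", "B", "+"), ("B", "A", "+")])
    return compile_default_rules(net)


@pytest.fixture
def cascade_rules():
    """Four-node activation cascade ROOT -> M1 -> M2 -> OUT, ROOT autocrine."""
    net = SignalingNetwork(
        nodes=["ROOT", "M1", "M2", "OUT"],
        edges=[
            ("ROOT", "ROOT", "+"),
            ("ROOT", "M1", "+"),
            ("M1", "M2", "+"),
            ("M2", "OUT", "+"),
        ],
    )
    return compile_default_rules(net)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
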