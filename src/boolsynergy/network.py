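"""Signed signaling networks and their compilation into Boolean update rules.

A :class:`SignalingNetwork` is a signed directed graph whose nodes are merged
protein entities (complexes carry a ``_c`` suffix, merged isoform groups an
``_i`` suffix) and whose edges are activating or inhibitory regulations.
Ligand nodes produced in an autocrine fashion are represented with
auto-activation self-loops.

The default rule compiler turns each node's regulators into a Boolean update
rule under the conventions used for logic models of cancer signaling:
activators combine with OR, inhibitors dominate via AND NOT, and a node with
no regulators holds its state.  Cell-line specificity enters through mutation
clamps (gain-of-function fixes a node at 1, loss-of-function at 0) and through
manually curated per-cell-line rule overrides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .logic import And, Expr, Not, Or, Var, parse_expression

__all__ = [
    "ACTIVATING",
    "INHIBITORY",
    "SignalingNetwork",
    "BooleanRule",
    "RuleSet",
    "MutationTable",
    "RuleOverrideTable",
    "NetworkValidationError",
    "compile_default_rules",
    "apply_overrides",
    "apply_mutations",
]

ACTIVATING = "activating"
INHIBITORY = "inhibitory"

_SIGN_ALIASES = {
    "+": ACTIVATING,
    "-": INHIBITORY,
    "−": INHIBITORY,  # unicode minus in hand-edited tables
    "activates": ACTIVATING,
    "inhibits": INHIBITORY,
    "activating": ACTIVATING,
    "inhibitory": INHIBITORY,
    "activation": ACTIVATING,
    "inhibition": INHIBITORY,
}


class NetworkValidationError(ValueError):
    """Raised when a network, rule set or annotation table is inconsistent."""


def normalize_sign(sign: str) -> str:
    try:
        return _SIGN_ALIASES[str(sign).strip().lower()]
    except KeyError:
        raise NetworkValidationError(f"unrecognised edge sign {sign!r}") from None


@dataclass
class SignalingNetwork:
    """Signed directed graph of merged protein entities.

    Parameters
    ----------
    nodes
        Unique node identifiers.
    edges
        ``(source, target, sign)`` triples, sign in {activating, inhibitory}.
        A self-edge ``(x, x, activating)`` marks autocrine auto-activation.
    """

    nodes: list[str]
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            dupes = sorted({n for n in self.nodes if self.nodes.count(n) > 1})
            raise NetworkValidationError(f"duplicate node identifiers: {dupes}")
        node_set = set(self.nodes)
        normalized = []
        seen = set()
        for src, tgt, sign in self.edges:
            sign = normalize_sign(sign)
            for endpoint in (src, tgt):
                if endpoint not in node_set:
                    raise NetworkValidationError(
                        f"edge ({src}, {tgt}, {sign}) references undeclared node {endpoint!r}"
                    )
            triple = (src, tgt, sign)
            if triple in seen:
                raise NetworkValidationError(f"duplicate edge {triple}")
            seen.add(triple)
            normalized.append(triple)
        self.edges = normalized

    @property
    def self_loops(self) -> set[str]:
        """Nodes with an activating self-edge (autocrine ligands)."""
        return {s for s, t, sign in self.edges if s == t and sign == ACTIVATING}

    def regulators(self, node: str) -> tuple[list[str], list[str]]:
        """Return (activators, inhibitors) of *node*, in edge order."""
        activators = [s for s, t, sign in self.edges if t == node and sign == ACTIVATING]
        inhibitors = [s for s, t, sign in self.edges if t == node and sign == INHIBITORY]
        return activators, inhibitors


@dataclass(frozen=True)
class BooleanRule:
    """Update rule ``target(t+1) = expression(state(t))``."""

    target: str
    expression: Expr

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.expression.evaluate(state)


class RuleSet:
    """Boolean update rules plus mutation clamps for one model.

    Every node has exactly one rule; clamped nodes keep their rule entry but
    the clamp takes precedence during simulation (the node never updates).
    """

    def __init__(
        self,
        rules: Mapping[str, BooleanRule],
        clamps: Mapping[str, int] | None = None,
        nodes: Iterable[str] | None = None,
    ):
        self.rules: dict[str, BooleanRule] = dict(rules)
        self.clamps: dict[str, int] = {k: int(v) for k, v in (clamps or {}).items()}
        self.nodes: list[str] = list(nodes) if nodes is not None else sorted(self.rules)
        self._validate()

    def _validate(self):
        node_set = set(self.nodes)
        missing = node_set - set(self.rules)
        if missing:
            raise NetworkValidationError(f"nodes without a rule: {sorted(missing)}")
        extra = set(self.rules) - node_set
        if extra:
            raise NetworkValidationError(f"rules for undeclared nodes: {sorted(extra)}")
        for node, rule in self.rules.items():
            unknown = rule.expression.variables() - node_set
            if unknown:
                raise NetworkValidationError(
                    f"rule for {node!r} references unknown node(s) {sorted(unknown)}"
                )
        for node, value in self.clamps.items():
            if node not in node_set:
                raise NetworkValidationError(f"clamp on unknown node {node!r}")
            if value not in (0, 1):
                raise NetworkValidationError(f"clamp value for {node!r} must be 0 or 1")

    def copy(self) -> "RuleSet":
        return RuleSet(dict(self.rules), dict(self.clamps), list(self.nodes))

    def with_rule(self, node: str, expression: Expr) -> "RuleSet":
        out = self.copy()
        out.rules[node] = BooleanRule(node, expression)
        out._validate()
        return out

    def step_synchronous(self, state: Mapping[str, int]) -> dict[str, int]:
        """Evaluate every rule on *state* (clamps win); mainly for tests."""
        out = {n: self.rules[n].evaluate(state) for n in self.nodes}
        out.update(self.clamps)
        return out

    def __eq__(self, other):
        # node order is a simulation-indexing detail, not part of identity
        return (
            isinstance(other, RuleSet)
            and sorted(self.nodes) == sorted(other.nodes)
            and self.rules == other.rules
            and self.clamps == other.clamps
        )


@dataclass
class MutationTable:
    """Rows of ``(cell_line, node, effect)`` with effect in {GOF, LOF}."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self):
        seen: dict[tuple[str, str], str] = {}
        normalized = []
        for cell_line, node, effect in self.rows:
            eff = str(effect).strip().upper().replace("-", "_")
            eff = {"GAIN_OF_FUNCTION": "GOF", "LOSS_OF_FUNCTION": "LOF"}.get(eff, eff)
            if eff not in ("GOF", "LOF"):
                raise NetworkValidationError(
                    f"mutation effect must be GOF or LOF, got {effect!r} for {node}"
                )
            key = (cell_line, node)
            if key in seen and seen[key] != eff:
                raise NetworkValidationError(
                    f"conflicting GOF and LOF annotations for {node} in {cell_line}"
                )
            seen[key] = eff
            normalized.append((cell_line, node, eff))
        self.rows = normalized

    def for_cell_line(self, cell_line: str) -> dict[str, str]:
        return {node: eff for cl, node, eff in self.rows if cl == cell_line}


@dataclass
class RuleOverrideTable:
    """Curated per-cell-line rule replacements, ``(cell_line, node, expression)``."""

    rows: list[tuple[str, str, str]]

    def for_cell_line(self, cell_line: str) -> dict[str, Expr]:
        return {
            node: parse_expression(expr) if isinstance(expr, str) else expr
            for cl, node, expr in self.rows
            if cl == cell_line
        }


def compile_default_rules(network: SignalingNetwork) -> RuleSet:
    """Compile a signed network into default Boolean update rules.

    Conventions: multiple activators combine with OR; any inhibitor wins over
    all activators (``(A or B) and not(C or D)``); an inhibitor-only node is
    ``not(C or ...)``; a node with an auto-activation self-loop includes itself
    among its activators; a node with no regulators holds its current value.
    """
    rules: dict[str, BooleanRule] = {}
    for node in network.nodes:
        activators, inhibitors = network.regulators(node)
        act_expr = None
        if activators:
            terms = [Var(a) for a in activators]
            act_expr = terms[0] if len(terms) == 1 else Or(*terms)
        inh_expr = None
        if inhibitors:
            terms = [Var(i) for i in inhibitors]
            inh_expr = Not(terms[0] if len(terms) == 1 else Or(*terms))
        if act_expr is not None and inh_expr is not None:
            expr: Expr = And(act_expr, inh_expr)
        elif act_expr is not None:
            expr = act_expr
        elif inh_expr is not None:
            expr = inh_expr
        else:
            expr = Var(node)  # no regulators: hold current state
        rules[node] = BooleanRule(node, expr)
    return RuleSet(rules, nodes=list(network.nodes))


def apply_overrides(
    rules: RuleSet, overrides: RuleOverrideTable, cell_line: str
) -> RuleSet:
    """Replace rule expressions for the nodes listed for *cell_line*.

    Overrides on clamped nodes are kept in the rule table but have no dynamical
    effect (the clamp wins); a warning is emitted so curation errors surface.
    """
    out = rules.copy()
    for node, expr in overrides.for_cell_line(cell_line).items():
        if node not in set(rules.nodes):
            raise NetworkValidationError(
                f"override for unknown node {node!r} (cell line {cell_line})"
            )
        if node in rules.clamps:
            warnings.warn(
                f"override on clamped node {node!r} in {cell_line}: clamp wins",
                stacklevel=2,
            )
        out.rules[node] = BooleanRule(node, expr)
    out._validate()
    return out


def apply_mutations(
    rules: RuleSet, mutations: MutationTable, cell_line: str
) -> RuleSet:
    """Clamp mutated nodes: gain-of-function to 1, loss-of-function to 0."""
    out = rules.copy()
    node_set = set(rules.nodes)
    for node, effect in mutations.for_cell_line(cell_line).items():
        if node not in node_set:
            raise NetworkValidationError(
                f"mutation on unknown node {node!r} (cell line {cell_line})"
            )
        out.clamps[node] = 1 if effect == "GOF" else 0
    out._validate()
    return out
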