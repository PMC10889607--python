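"""Synthetic scenarios with known ground truth, and an exact dynamics oracle.

Everything the pipeline consumes can be generated here: random signed
signaling networks with mixed AND/OR logic, TPM-like expression matrices,
sparse gain/loss-of-function mutation tables, drug sets hitting 1–4 targets,
and drug-pair lists whose "observed" HSA synergy scores are computed from a
hidden true model rather than hand-assigned.  Two reporter nodes play the
proliferation (E2F1) and apoptosis (CASP3) read-out roles, and a drug's
effect is defined as suppression of the proliferation reporter.

For networks of up to 12 nodes, :func:`exact_occupancy` builds the full
uniform-asynchronous Markov chain over all 2^n states and computes the exact
long-run per-node occupancy from any initial distribution — the independent
oracle against which the Monte-Carlo ensemble simulator is verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .cellline import CellLineProfile
from .logic import And, Not, Or, Var
from .network import (
    ACTIVATING,
    INHIBITORY,
    BooleanRule,
    MutationTable,
    RuleSet,
    SignalingNetwork,
    compile_default_rules,
)
from .perturb import AGONIST, ANTAGONIST, Drug
from .simulate import compile_model
from .synergy import ONCOPROTEIN, TUMOR_SUPPRESSOR, observed_hsa

__all__ = [
    "MAX_ORACLE_NODES",
    "generate_network",
    "exact_occupancy",
    "exact_mean_occupancy",
    "ScenarioConfig",
    "SyntheticScenario",
    "make_scenario",
    "generate_ground_truth_synergy",
    "PlantedScenario",
    "planted_pss_scenario",
]

MAX_ORACLE_NODES = 12
PROLIFERATION_REPORTER = "E2F1"
APOPTOSIS_REPORTER = "CASP3"


# ---------------------------------------------------------------------------
# random signed networks


def generate_network(
    n_nodes: int,
    edge_density: float = 0.2,
    activating_ratio: float = 0.75,
    seed: int = 0,
    and_fraction: float = 0.25,
    autocrine_self_loops: bool = True,
    node_names: Sequence[str] | None = None,
) -> tuple[SignalingNetwork, RuleSet]:
    """Random connected signed digraph plus its compiled Boolean rules.

    A random spanning structure guarantees weak connectivity; extra edges are
    added up to *edge_density* (fraction of the n*(n-1) ordered pairs).  Each
    edge is activating with probability *activating_ratio*.  Nodes left
    without incoming edges receive an activating self-loop (autocrine ligand
    convention).  After default compilation, a random *and_fraction* of nodes
    with two or more activators have their activator OR tightened to AND,
    emulating curated rule refinements.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 < edge_density <= 1.0):
        raise ValueError(f"edge density outside (0, 1]: {edge_density}")
    rng = np.random.default_rng(seed)
    if node_names is None:
        node_names = [f"N{i:02d}" for i in range(n_nodes)]
    nodes = list(node_names)

    def sign():
        return ACTIVATING if rng.random() < activating_ratio else INHIBITORY

    edges: dict[tuple[str, str], str] = {}
    order = rng.permutation(n_nodes)
    for k in range(1, n_nodes):
        parent = nodes[order[int(rng.integers(k))]]
        child = nodes[order[k]]
        edges[(parent, child)] = sign()

    target_edges = max(len(edges), int(round(edge_density * n_nodes * (n_nodes - 1))))
    all_pairs = [
        (a, b) for a in nodes for b in nodes if a != b and (a, b) not in edges
    ]
    rng.shuffle(all_pairs)
    for pair in all_pairs:
        if len(edges) >= target_edges:
            break
        edges[pair] = sign()

    if autocrine_self_loops:
        with_inputs = {t for (_, t) in edges}
        for node in nodes:
            if node not in with_inputs:
                edges[(node, node)] = ACTIVATING

    network = SignalingNetwork(
        nodes=nodes, edges=[(s, t, sg) for (s, t), sg in edges.items()]
    )
    rules = compile_default_rules(network)

    if and_fraction > 0:
        eligible = [
            n for n in nodes if len(network.regulators(n)[0]) >= 2
        ]
        n_rewrite = int(round(and_fraction * len(eligible)))
        for node in rng.permutation(eligible)[:n_rewrite]:
            activators, inhibitors = network.regulators(node)
            act = And(*(Var(a) for a in activators))
            if inhibitors:
                inh_terms = [Var(i) for i in inhibitors]
                inh = inh_terms[0] if len(inh_terms) == 1 else Or(*inh_terms)
                expr: object = And(act, Not(inh))
            else:
                expr = act
            rules.rules[node] = BooleanRule(node, expr)
    return network, rules


# ---------------------------------------------------------------------------
# exact asynchronous Markov-chain oracle


def _state_bits(n: int) -> np.ndarray:
    """(2^n, n) bool matrix: row s holds the bits of state index s."""
    states = np.arange(2**n, dtype=np.int64)
    return ((states[:, None] >> np.arange(n)) & 1).astype(bool)


def transition_matrix(rules: RuleSet) -> sparse.csr_array:
    """Full uniform-asynchronous transition matrix over 2^n states.

    From state s, each node whose (clamp-respecting) rule output differs from
    its current value is chosen with probability 1/|updatable|, flipping that
    node; fixed points self-loop with probability 1.
    """
    n = len(rules.nodes)
    if n > MAX_ORACLE_NODES:
        raise ValueError(
            f"{n} nodes exceeds the {MAX_ORACLE_NODES}-node oracle limit; "
            "use the ensemble simulator instead"
        )
    model = compile_model(rules)
    S = _state_bits(n)
    nxt = model.next_values(S)
    diff = nxt != S
    counts = diff.sum(axis=1)

    rows, cols, vals = [], [], []
    state_idx = np.arange(2**n, dtype=np.int64)
    fixed = counts == 0
    rows.extend(state_idx[fixed])
    cols.extend(state_idx[fixed])
    vals.extend(np.ones(int(fixed.sum())))
    for j in range(n):
        movers = state_idx[diff[:, j]]
        if movers.size:
            rows.extend(movers)
            cols.extend(movers ^ (1 << j))
            vals.extend(1.0 / counts[movers])
    return sparse.csr_array(
        (np.array(vals), (np.array(rows), np.array(cols))), shape=(2**n, 2**n)
    )


def initial_distribution(
    rules: RuleSet, init_prob: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    """Product-Bernoulli distribution over all 2^n states (clamps forced)."""
    nodes = rules.nodes
    n = len(nodes)
    if isinstance(init_prob, Mapping):
        p = np.array([init_prob[node] for node in nodes], dtype=float)
    else:
        p = np.asarray(init_prob, dtype=float)
    for j, node in enumerate(nodes):
        if node in rules.clamps:
            p[j] = float(rules.clamps[node])
    bits = _state_bits(n)
    dist = np.ones(2**n)
    for j in range(n):
        dist *= np.where(bits[:, j], p[j], 1.0 - p[j])
    return dist


def exact_occupancy(
    rules: RuleSet,
    init_prob: Mapping[str, float] | Sequence[float] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> pd.Series:
    """Exact long-run per-node occupancy of the asynchronous chain.

    The limit distribution is found by power iteration on the lazy chain
    (I + P)/2, which shares every limit of P while damping any periodic
    attractor; iteration stops when the distribution moves less than *tol*
    in the max norm.
    """
    n = len(rules.nodes)
    P = transition_matrix(rules)
    if isinstance(init_prob, np.ndarray) and init_prob.size == 2**n:
        dist = init_prob.astype(float)
    else:
        dist = initial_distribution(rules, init_prob)
    dist = dist / dist.sum()
    for _ in range(max_iter):
        new = 0.5 * dist + 0.5 * (dist @ P)
        if np.abs(new - dist).max() < tol:
            dist = new
            break
        dist = new
    else:
        raise RuntimeError("power iteration did not converge; raise max_iter")
    bits = _state_bits(n)
    occupancy = bits.T.astype(float) @ dist
    return pd.Series(occupancy, index=list(rules.nodes), name="occupancy")


def exact_mean_occupancy(
    rules: RuleSet,
    init_prob: Mapping[str, float] | Sequence[float],
    t_start: int,
    t_end: int,
) -> pd.Series:
    """Exact expectation of the simulator's steady-window statistic.

    Evolves the full state distribution step by step from the product-Bernoulli
    initial distribution and averages the per-node occupancy over steps
    [t_start, t_end] — exactly the quantity the ensemble simulator estimates
    by averaging activities over its steady window.  As t_end grows this
    converges to :func:`exact_occupancy`.
    """
    if not (0 <= t_start <= t_end):
        raise ValueError("need 0 <= t_start <= t_end")
    n = len(rules.nodes)
    P = transition_matrix(rules)
    bits = _state_bits(n).astype(float)
    dist = initial_distribution(rules, init_prob)
    dist = dist / dist.sum()
    acc = np.zeros(n)
    count = 0
    for t in range(t_end + 1):
        if t >= t_start:
            acc += bits.T @ dist
            count += 1
        if t < t_end:
            dist = dist @ P
    return pd.Series(acc / count, index=list(rules.nodes), name="mean_occupancy")


# ---------------------------------------------------------------------------
# full scenario generation


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions."""

    n_nodes: int = 12
    edge_density: float = 0.18
    activating_ratio: float = 0.75
    and_fraction: float = 0.25
    n_pathway_hubs: int = 3
    cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3", "CL4", "CL5")
    n_drugs: int = 8
    max_targets: int = 4
    antagonist_prob: float = 0.8
    n_pairs: int = 15
    mutation_rate: float = 0.08
    noise_sd: float = 0.02
    expression_max_low: float = 5.0
    expression_max_high: float = 500.0


@dataclass
class SyntheticScenario:
    """A complete generated study: hidden truth plus every pipeline input."""

    config: ScenarioConfig
    seed: int
    network: SignalingNetwork
    rules: RuleSet  # hidden "true" model (generic, before mutations)
    expression: pd.DataFrame  # genes x cell lines, TPM-like
    mutations: MutationTable
    drugs: list[Drug]
    pairs: pd.DataFrame  # drug_a, drug_b, cell_line, observed_hsa
    roles: dict[str, str]
    reporter: str = PROLIFERATION_REPORTER
    cell_line_rules: dict[str, RuleSet] = field(default_factory=dict)
    cell_line_profiles: dict[str, CellLineProfile] = field(default_factory=dict)


def _drug_effect(
    rules: RuleSet,
    init_prob: Mapping[str, float],
    clamps: Mapping[str, int],
    reporter: str,
) -> float:
    """Effect of a treatment = suppression of the proliferation reporter."""
    clamped = rules.copy()
    for node, v in clamps.items():
        clamped.clamps[node] = v
    occ = exact_occupancy(clamped, init_prob)
    return float(1.0 - occ[reporter])


def generate_ground_truth_synergy(
    rules_by_cell_line: Mapping[str, RuleSet],
    init_probs: Mapping[str, Mapping[str, float]],
    drugs: Mapping[str, Drug],
    pair_list: Sequence[tuple[str, str, str]],
    reporter: str = PROLIFERATION_REPORTER,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed HSA score per (drug_a, drug_b, cell line) from the hidden model.

    Each drug's effect is computed by clamping its targets at full dose in the
    exact oracle and measuring the reporter's suppression; the pair score is
    the HSA statistic on those effects plus optional Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for drug_a, drug_b, cell_line in pair_list:
        rules = rules_by_cell_line[cell_line]
        probs = init_probs[cell_line]
        da, db = drugs[drug_a], drugs[drug_b]
        clamps_a = {node: int(mode == AGONIST) for node, mode in da.targets}
        clamps_b = {node: int(mode == AGONIST) for node, mode in db.targets}
        clamps_ab = {**clamps_a, **clamps_b}
        y_a = _drug_effect(rules, probs, clamps_a, reporter)
        y_b = _drug_effect(rules, probs, clamps_b, reporter)
        y_c = _drug_effect(rules, probs, clamps_ab, reporter)
        score = observed_hsa(y_a, y_b, y_c) + (
            rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        )
        rows.append(
            {
                "drug_a": drug_a,
                "drug_b": drug_b,
                "cell_line": cell_line,
                "observed_hsa": score,
                "effect_a": y_a,
                "effect_b": y_b,
                "effect_combo": y_c,
            }
        )
    return pd.DataFrame(rows)


def make_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> SyntheticScenario:
    """Generate a fully self-consistent synthetic study.

    The hidden model's first two nodes are the proliferation and apoptosis
    reporters (so the downstream panel-selection defaults apply); the next
    ``n_pathway_hubs`` nodes act as parallel pathway hubs that redundantly
    drive proliferation and repress apoptosis — the topology in which HSA
    synergy genuinely arises (inhibiting one redundant pathway achieves
    little; inhibiting two in combination collapses the read-out).  The
    remaining nodes form random upstream signaling.  Observed synergy scores
    are produced by the exact oracle on the per-cell-line (mutation-clamped)
    hidden models.
    """
    config = config or ScenarioConfig()
    if config.n_nodes > MAX_ORACLE_NODES:
        raise ValueError(
            "scenario ground truth needs the exact oracle; use <= "
            f"{MAX_ORACLE_NODES} nodes"
        )
    n_hubs = min(config.n_pathway_hubs, config.n_nodes - 2)
    rng = np.random.default_rng(seed)
    hubs = [f"HUB{i}" for i in range(n_hubs)]
    names = (
        [PROLIFERATION_REPORTER, APOPTOSIS_REPORTER]
        + hubs
        + [f"N{i:02d}" for i in range(2 + n_hubs, config.n_nodes)]
    )
    network, _ = generate_network(
        config.n_nodes,
        edge_density=config.edge_density,
        activating_ratio=config.activating_ratio,
        seed=int(rng.integers(2**31)),
        and_fraction=0.0,
        node_names=names,
    )
    reporters = {PROLIFERATION_REPORTER, APOPTOSIS_REPORTER}

    # rewire the reporters: proliferation = OR of the pathway hubs (parallel
    # redundancy), apoptosis = repressed by the first two hubs
    edges = [
        (s, t, sg)
        for s, t, sg in network.edges
        if t not in reporters and s not in reporters
    ]
    edges += [(h, PROLIFERATION_REPORTER, ACTIVATING) for h in hubs]
    edges += [(h, APOPTOSIS_REPORTER, INHIBITORY) for h in hubs[: max(1, n_hubs - 1)]]
    covered = {t for _, t, _ in edges}
    for node in names:  # keep in-degree-0 nodes self-sustaining (autocrine)
        if node not in covered:
            edges.append((node, node, ACTIVATING))
    network = SignalingNetwork(nodes=names, edges=edges)
    rules = compile_default_rules(network)

    # tighten a fraction of multi-activator rules to AND (curated refinements),
    # sparing the proliferation reporter whose OR redundancy is the point
    eligible = [
        n
        for n in names
        if n != PROLIFERATION_REPORTER and len(network.regulators(n)[0]) >= 2
    ]
    n_rewrite = int(round(config.and_fraction * len(eligible)))
    for node in rng.permutation(eligible)[:n_rewrite]:
        activators, inhibitors = network.regulators(node)
        act: object = And(*(Var(a) for a in activators))
        if inhibitors:
            inh_terms = [Var(i) for i in inhibitors]
            inh = inh_terms[0] if len(inh_terms) == 1 else Or(*inh_terms)
            act = And(act, Not(inh))
        rules.rules[node] = BooleanRule(node, act)

    # TPM-like expression: per gene, a random dynamic range across cell lines
    expr_rows = {}
    for node in names:
        top = rng.uniform(config.expression_max_low, config.expression_max_high)
        values = rng.uniform(0.0, top, size=len(config.cell_lines))
        expr_rows[node] = values
    expression = pd.DataFrame.from_dict(
        expr_rows, orient="index", columns=list(config.cell_lines)
    )

    # sparse GOF/LOF mutations (reporters stay dynamic)
    mut_rows = []
    for cl in config.cell_lines:
        for node in names:
            if node in reporters:
                continue
            if rng.random() < config.mutation_rate:
                effect = "GOF" if rng.random() < 0.5 else "LOF"
                mut_rows.append((cl, node, effect))
    mutations = MutationTable(mut_rows)

    # drugs hitting 1..max_targets non-reporter nodes; pathway hubs are the
    # prime targets (as kinase hubs are in real panels), upstream nodes rarer
    druggable = [n for n in names if n not in reporters]
    weights = np.array([3.0 if n in hubs else 1.0 for n in druggable])
    weights /= weights.sum()
    drugs: list[Drug] = []
    for d in range(config.n_drugs):
        k = int(rng.integers(1, config.max_targets + 1))
        targets = rng.choice(
            len(druggable), size=min(k, len(druggable)), replace=False, p=weights
        )
        drugs.append(
            Drug(
                name=f"DRUG{d:02d}",
                targets=tuple(
                    (
                        druggable[t],
                        ANTAGONIST if rng.random() < config.antagonist_prob else AGONIST,
                    )
                    for t in targets
                ),
            )
        )

    # per-cell-line hidden models and initial probabilities
    from .cellline import build_profile, min_max_scale
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        scaled = min_max_scale(expression)
    cell_line_rules: dict[str, RuleSet] = {}
    cell_line_profiles: dict[str, CellLineProfile] = {}
    for cl in config.cell_lines:
        clamps = {
            node: 1 if eff == "GOF" else 0
            for node, eff in mutations.for_cell_line(cl).items()
        }
        rs = rules.copy()
        rs.clamps.update(clamps)
        cell_line_rules[cl] = rs
        cell_line_profiles[cl] = build_profile(scaled, cl, names, clamps=clamps)

    # drug-pair list with oracle-derived observed synergy
    drug_map = {d.name: d for d in drugs}
    all_pairs = [
        (drugs[i].name, drugs[j].name)
        for i in range(len(drugs))
        for j in range(i + 1, len(drugs))
    ]
    chosen = rng.choice(len(all_pairs), size=min(config.n_pairs, len(all_pairs)), replace=False)
    pair_list = [
        (all_pairs[i][0], all_pairs[i][1], cl)
        for i in sorted(chosen)
        for cl in config.cell_lines
    ]
    init_probs = {
        cl: dict(
            zip(names, cell_line_profiles[cl].probability_vector(names).tolist())
        )
        for cl in config.cell_lines
    }
    pairs = generate_ground_truth_synergy(
        cell_line_rules,
        init_probs,
        drug_map,
        pair_list,
        reporter=PROLIFERATION_REPORTER,
        noise_sd=config.noise_sd,
        seed=int(rng.integers(2**31)),
    )

    # roles: reporters fixed; other nodes' roles drawn once and recorded
    roles = {PROLIFERATION_REPORTER: ONCOPROTEIN, APOPTOSIS_REPORTER: TUMOR_SUPPRESSOR}
    for node in names:
        if node not in roles:
            roles[node] = ONCOPROTEIN if rng.random() < 0.6 else TUMOR_SUPPRESSOR

    return SyntheticScenario(
        config=config,
        seed=seed,
        network=network,
        rules=rules,
        expression=expression,
        mutations=mutations,
        drugs=drugs,
        pairs=pairs,
        roles=roles,
        cell_line_rules=cell_line_rules,
        cell_line_profiles=cell_line_profiles,
    )


# ---------------------------------------------------------------------------
# planted-signal fixtures for the GA


@dataclass
class PlantedScenario:
    """Consensus-PSS matrix whose observed scores follow a known protein pair."""

    pss_matrix: pd.DataFrame  # pairs x candidates (mandatory members included)
    observed: pd.Series
    informative: tuple[str, ...]
    candidates: list[str]


def planted_pss_scenario(
    n_pairs: int = 40,
    n_noise: int = 8,
    n_informative: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
    mandatory: Sequence[str] = (PROLIFERATION_REPORTER, APOPTOSIS_REPORTER),
) -> PlantedScenario:
    """Synthetic GA training set: observed = mandatory + informative sums + noise."""
    rng = np.random.default_rng(seed)
    informative = tuple(f"INF{i}" for i in range(n_informative))
    noise_proteins = [f"NOISE{i}" for i in range(n_noise)]
    columns = list(mandatory) + list(informative) + noise_proteins
    X = rng.uniform(-0.5, 0.5, size=(n_pairs, len(columns)))
    pss = pd.DataFrame(X, columns=columns, index=[f"pair{i:03d}" for i in range(n_pairs)])
    signal = pss[list(mandatory) + list(informative)].sum(axis=1)
    observed = signal + rng.normal(0.0, noise_sd, size=n_pairs)
    return PlantedScenario(
        pss_matrix=pss,
        observed=pd.Series(observed, index=pss.index, name="observed_hsa"),
        informative=informative,
        candidates=columns,
    )
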