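"""Drug perturbations as dose-probability clamps and dose-grid simulation.

A drug is a set of target nodes, each hit as an antagonist (clamp to 0) or an
agonist (clamp to 1).  Dose d in [0, 1] is the probability that a target is
actually clamped in a given simulation repeat: the Bernoulli(d) outcome is
drawn once per target per repeat at the moment the drug is applied, and a
successful draw clamps the node for the remainder of that repeat.  Dose 1
therefore fully inhibits (or activates) the target in every repeat; dose 0
never perturbs.

Drug-pair simulation follows a two-phase protocol: the unperturbed model is
run to its entropy-detected steady state, then — for every cell of the dose
grid (default {0, 0.25, 0.75, 1} x {0, 0.25, 0.75, 1}) — both drugs' clamps
are drawn and applied to the steady-state ensemble, and the run continues to a
new steady state whose activities are recorded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cellline import CellLineProfile
from .network import RuleSet
from .simulate import (
    DEFAULT_ENTROPY_STRIDE,
    DEFAULT_ENTROPY_WINDOW,
    EnsembleResult,
    run_ensemble,
    simulate_cell_line,
)

__all__ = [
    "AGONIST",
    "ANTAGONIST",
    "DEFAULT_DOSES",
    "Drug",
    "DoseGridResult",
    "draw_drug_clamps",
    "simulate_combination_grid",
]

logger = logging.getLogger(__name__)

AGONIST = "agonist"
ANTAGONIST = "antagonist"
DEFAULT_DOSES = (0.0, 0.25, 0.75, 1.0)


@dataclass(frozen=True)
class Drug:
    """A drug and its target nodes with their mode of action."""

    name: str
    targets: tuple[tuple[str, str], ...]  # (node, mode)

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"drug {self.name!r} has no targets")
        for node, mode in self.targets:
            if mode not in (AGONIST, ANTAGONIST):
                raise ValueError(
                    f"drug {self.name!r}: mode for {node!r} must be "
                    f"'{AGONIST}' or '{ANTAGONIST}', got {mode!r}"
                )

    def validate_against(self, nodes: Sequence[str]):
        known = set(nodes)
        for node, _ in self.targets:
            if node not in known:
                raise ValueError(
                    f"drug {self.name!r} targets unknown node {node!r}"
                )


def draw_drug_clamps(
    drugs_and_doses: Sequence[tuple[Drug, float]],
    nodes: Sequence[str],
    repeats: int,
    rng: np.random.Generator,
    model_clamps: dict[str, int] | None = None,
    shared_draw: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-repeat drug clamps for one or more (drug, dose) treatments.

    Each target node receives an independent Bernoulli(dose) draw per repeat
    (``shared_draw=True`` instead draws once per drug per repeat and applies
    the outcome to all of its targets).  Returns ``(mask, values)`` arrays of
    shape (repeats, n_nodes).  A drug clamp that contradicts a constitutive
    mutation clamp is logged and dropped — genetic lesions win.
    """
    index = {n: j for j, n in enumerate(nodes)}
    mask = np.zeros((repeats, len(nodes)), dtype=bool)
    values = np.zeros((repeats, len(nodes)), dtype=bool)
    model_clamps = model_clamps or {}
    for drug, dose in drugs_and_doses:
        if not (0.0 <= dose <= 1.0):
            raise ValueError(f"dose for {drug.name!r} outside [0,1]: {dose}")
        drug.validate_against(nodes)
        drug_hit = rng.random(repeats) < dose if shared_draw else None
        for node, mode in drug.targets:
            clamp_value = mode == AGONIST
            if node in model_clamps and bool(model_clamps[node]) != clamp_value:
                logger.warning(
                    "drug %s clamp on %s (-> %d) conflicts with mutation clamp "
                    "(-> %d); mutation clamp wins",
                    drug.name,
                    node,
                    int(clamp_value),
                    model_clamps[node],
                )
                continue
            hit = drug_hit if shared_draw else rng.random(repeats) < dose
            j = index[node]
            mask[hit, j] = True
            values[hit, j] = clamp_value
    return mask, values


@dataclass
class DoseGridResult:
    """Steady-state activities over a (doseA, doseB) grid for one drug pair."""

    drug_a: str
    drug_b: str
    cell_line: str
    doses: tuple[float, ...]
    nodes: list[str]
    # activity[i, j, k]: steady-state activity of node k at (doseA_i, doseB_j)
    activity: np.ndarray
    repeats: int
    baseline: EnsembleResult | None = field(default=None, repr=False)

    def activity_at(self, dose_a: float, dose_b: float) -> np.ndarray:
        i = self.doses.index(dose_a)
        j = self.doses.index(dose_b)
        return self.activity[i, j]

    def monotherapy_a(self, dose_a: float) -> np.ndarray:
        """Single-agent activities for drug A read off the doseB=0 column."""
        return self.activity_at(dose_a, 0.0)

    def monotherapy_b(self, dose_b: float) -> np.ndarray:
        return self.activity_at(0.0, dose_b)


def simulate_combination_grid(
    rules: RuleSet,
    profile: CellLineProfile,
    drug_a: Drug,
    drug_b: Drug,
    doses: Sequence[float] = DEFAULT_DOSES,
    repeats: int = 30,
    phase1_steps: int = 5000,
    phase2_steps: int = 5000,
    seed: int = 0,
    entropy_window: int = DEFAULT_ENTROPY_WINDOW,
    entropy_stride: int = DEFAULT_ENTROPY_STRIDE,
    baseline: EnsembleResult | None = None,
    shared_draw: bool = False,
) -> DoseGridResult:
    """Simulate a drug pair over the full dose grid for one cell line.

    Phase 1 runs the unperturbed ensemble to steady state (or reuses a
    precomputed *baseline* with matching repeat count, so several pairs on the
    same cell line can share it).  Phase 2 restarts from the phase-1 final
    states with per-repeat drug clamps for each grid cell and reapplies the
    entropy criterion to the post-application segment.
    """
    merged = rules.copy()
    for node, v in profile.clamps.items():
        merged.clamps.setdefault(node, v)
    for d in (drug_a, drug_b):
        d.validate_against(merged.nodes)

    if baseline is None:
        baseline = simulate_cell_line(
            merged,
            profile,
            steps=phase1_steps,
            repeats=repeats,
            seed=seed,
            entropy_window=entropy_window,
            entropy_stride=entropy_stride,
        )
    elif baseline.repeats != repeats:
        raise ValueError("baseline repeat count does not match requested repeats")
    if baseline.entropy.H[-1] > baseline.entropy.H[0] and baseline.entropy.H[-1] > 0:
        logger.warning(
            "phase-1 entropy still rising at T=%d; using last-window activities",
            baseline.steps,
        )

    doses = tuple(float(d) for d in doses)
    nodes = baseline.nodes
    activity = np.empty((len(doses), len(doses), len(nodes)))
    for (i, da), (j, db) in itertools.product(enumerate(doses), repeat=2):
        cell_seed = np.random.SeedSequence([int(seed), i, j, 0xD05E])
        rng = np.random.default_rng(cell_seed)
        mask, values = draw_drug_clamps(
            [(drug_a, da), (drug_b, db)],
            nodes,
            repeats,
            rng,
            model_clamps=merged.clamps,
            shared_draw=shared_draw,
        )
        phase2 = run_ensemble(
            merged,
            baseline.final_states.copy(),
            steps=phase2_steps,
            seed=int(cell_seed.generate_state(1)[0] >> 1),
            entropy_window=entropy_window,
            entropy_stride=entropy_stride,
            extra_clamp_mask=mask,
            extra_clamp_values=values,
        )
        activity[i, j] = phase2.steady_activity.to_numpy()

    return DoseGridResult(
        drug_a=drug_a.name,
        drug_b=drug_b.name,
        cell_line=profile.cell_line,
        doses=doses,
        nodes=list(nodes),
        activity=activity,
        repeats=repeats,
        baseline=baseline,
    )
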