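"""Protein synergy scores (PSS) and HSA-style combination scores.

The PSS transfers the Highest Single Agent (HSA) idea from a viability
read-out to individual protein activities at steady state.  With X/Y the
steady-state activity of a protein after drug 1 alone, drug 2 alone, and the
combination (subscripts 1, 2, 1+2):

    oncoprotein:       PSS = min(X_1, X_2) - X_{1+2}
    tumor suppressor:  PSS = Y_{1+2} - max(Y_1, Y_2)

so a positive PSS means the pair pushes the protein further in the
therapeutically desirable direction than the better single agent (down for
oncoproteins, up for tumor suppressors).  PSS lies in [-1, +1]; 0 is additive.

The consensus PSS of a protein for a drug pair is the 75th percentile of its
PSS over all cells of the dose grid, and the predicted HSA synergy score of
the pair is the sum of consensus PSS over a selected protein panel.  The
observed HSA score from a viability screen is ``y_c - max(y_A, y_B)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .perturb import DoseGridResult

__all__ = [
    "ONCOPROTEIN",
    "TUMOR_SUPPRESSOR",
    "DEFAULT_ROLES",
    "DEFAULT_SELECTION",
    "pss",
    "pss_grid",
    "consensus_pss",
    "observed_hsa",
    "predicted_hsa",
    "PSSProfile",
    "score_pair",
]

ONCOPROTEIN = "oncoprotein"
TUMOR_SUPPRESSOR = "tumor-suppressor"

# Built-in role assignment for the selected panel, inferred from the sign
# semantics of the synergy read-outs (desirable = down for oncoproteins,
# up for tumor suppressors).  User role tables override it.
DEFAULT_ROLES: dict[str, str] = {
    "BCL2": ONCOPROTEIN,
    "CYCLIN_D": ONCOPROTEIN,
    "CYCLIN_D_c": ONCOPROTEIN,
    "MTORC1": ONCOPROTEIN,
    "MTORC1_c": ONCOPROTEIN,
    "ESR1": ONCOPROTEIN,
    "PGR": ONCOPROTEIN,
    "PAK1": ONCOPROTEIN,
    "STAT3": ONCOPROTEIN,
    "WNT1": ONCOPROTEIN,
    "E2F1": ONCOPROTEIN,
    "BID": TUMOR_SUPPRESSOR,
    "GATA3": TUMOR_SUPPRESSOR,
    "FADD": TUMOR_SUPPRESSOR,
    "P21": TUMOR_SUPPRESSOR,
    "CASP3": TUMOR_SUPPRESSOR,
}

# The 13-protein panel used for the predicted HSA score.
DEFAULT_SELECTION: tuple[str, ...] = (
    "BCL2",
    "CYCLIN_D",
    "MTORC1",
    "ESR1",
    "PGR",
    "PAK1",
    "STAT3",
    "WNT1",
    "BID",
    "GATA3",
    "FADD",
    "P21",
    "CASP3",
)

CONSENSUS_PERCENTILE = 75.0


def pss(role: str, act_drug1: float, act_drug2: float, act_combo: float) -> float:
    """Protein synergy score for one protein at one dose-grid cell."""
    for name, a in (("drug1", act_drug1), ("drug2", act_drug2), ("combo", act_combo)):
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"{name} activity outside [0,1]: {a}")
    if role == ONCOPROTEIN:
        return float(min(act_drug1, act_drug2) - act_combo)
    if role == TUMOR_SUPPRESSOR:
        return float(act_combo - max(act_drug1, act_drug2))
    raise ValueError(f"cannot score role {role!r}; assign oncoprotein or tumor-suppressor")


def pss_grid(
    grid: DoseGridResult, roles: Mapping[str, str], nodes: Sequence[str] | None = None
) -> dict[str, np.ndarray]:
    """Per-node PSS over every cell of the dose grid.

    Monotherapy activities for cell (a, b) are taken from the grid edges
    (a, 0) and (0, b), mirroring the per-dose HSA construction.  Only nodes
    with an assigned role are scored.
    """
    nodes = list(nodes) if nodes is not None else [n for n in grid.nodes if n in roles]
    idx = {n: k for k, n in enumerate(grid.nodes)}
    n_d = len(grid.doses)
    out: dict[str, np.ndarray] = {}
    for node in nodes:
        role = roles[node]
        k = idx[node]
        mono_a = grid.activity[:, 0, k]  # X1 at each doseA (doseB = 0)
        mono_b = grid.activity[0, :, k]  # X2 at each doseB (doseA = 0)
        combo = grid.activity[:, :, k]
        scores = np.empty((n_d, n_d))
        for i in range(n_d):
            for j in range(n_d):
                scores[i, j] = pss(role, mono_a[i], mono_b[j], combo[i, j])
        out[node] = scores
    return out


def consensus_pss(values: np.ndarray | Sequence[float]) -> float:
    """75th percentile (linear interpolation) of PSS over all dose cells."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("consensus PSS of an empty value set is undefined")
    return float(np.percentile(values, CONSENSUS_PERCENTILE, method="linear"))


def observed_hsa(y_a: float, y_b: float, y_c: float) -> float:
    """HSA synergy score ``y_c - max(y_A, y_B)`` of combination effect y_c."""
    return float(y_c - max(y_a, y_b))


@dataclass
class PSSProfile:
    """Consensus PSS per scored protein for one (drug pair, cell line)."""

    drug_a: str
    drug_b: str
    cell_line: str
    consensus: pd.Series  # index: node, value: consensus PSS
    per_dose: dict[str, np.ndarray]  # node -> (n_doses, n_doses) PSS


def predicted_hsa(
    profile: PSSProfile | Mapping[str, float],
    selected: Sequence[str] = DEFAULT_SELECTION,
) -> float:
    """Predicted HSA synergy score: sum of consensus PSS over the panel."""
    consensus = profile.consensus if isinstance(profile, PSSProfile) else profile
    missing = [n for n in selected if n not in consensus]
    if missing:
        raise KeyError(f"selected node(s) without a consensus PSS: {missing}")
    return float(sum(consensus[n] for n in selected))


def score_pair(grid: DoseGridResult, roles: Mapping[str, str]) -> PSSProfile:
    """PSS profile (per-dose and consensus) of one simulated drug pair."""
    per_dose = pss_grid(grid, roles)
    consensus = pd.Series(
        {node: consensus_pss(v) for node, v in per_dose.items()}, name="consensus_pss"
    )
    return PSSProfile(
        drug_a=grid.drug_a,
        drug_b=grid.drug_b,
        cell_line=grid.cell_line,
        consensus=consensus,
        per_dose=per_dose,
    )
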