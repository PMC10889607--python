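"""Cell-line initial-state probabilities from expression profiles.

TPM-scale expression values are min–max scaled per gene across the modeled
cell lines, and each scaled value is interpreted as the probability that the
corresponding node starts in the ON state: a scaled value of 0.7 means the
node is initialised to 1 with a 70% chance in every simulation repeat.

Model nodes that are not measured directly (complexes, ligands) default to
probability 0.5; nodes merged from several genes take the mean of their member
genes' scaled values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "min_max_scale",
    "CellLineProfile",
    "build_profile",
    "sample_initial_state",
    "sample_initial_matrix",
]

UNMEASURED_DEFAULT = 0.5


def min_max_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Min–max scale each gene (row) across cell lines (columns) into [0, 1].

    ``x'_jk = (x_jk - min(x_j)) / (max(x_j) - min(x_j))``.  A gene with zero
    range is uninformative and is mapped to 0.5 everywhere (with a warning)
    rather than forcing the node on or off.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    if matrix.shape[1] < 1:
        raise ValueError("expression matrix needs at least one cell line column")
    lo = matrix.min(axis=1)
    hi = matrix.max(axis=1)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with constant expression scaled to 0.5",
            stacklevel=2,
        )
    safe_span = span.replace(0, np.nan)
    scaled = matrix.sub(lo, axis=0).div(safe_span, axis=0)
    scaled.loc[degenerate] = UNMEASURED_DEFAULT
    return scaled


@dataclass
class CellLineProfile:
    """Initial-state probabilities and mutation clamps for one cell line."""

    cell_line: str
    init_prob: dict[str, float]
    clamps: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for node, p in self.init_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"initial probability for {node!r} outside [0,1]: {p}")
        for node, v in self.clamps.items():
            if v not in (0, 1):
                raise ValueError(f"clamp for {node!r} must be 0 or 1")

    def probability_vector(self, nodes: Sequence[str]) -> np.ndarray:
        """Per-node ON probability with clamps applied, in *nodes* order."""
        p = np.array([self.init_prob[n] for n in nodes], dtype=float)
        for i, n in enumerate(nodes):
            if n in self.clamps:
                p[i] = float(self.clamps[n])
        return p


def build_profile(
    scaled: pd.DataFrame,
    cell_line: str,
    nodes: Sequence[str],
    node_genes: Mapping[str, Sequence[str]] | None = None,
    clamps: Mapping[str, int] | None = None,
    default: float = UNMEASURED_DEFAULT,
) -> CellLineProfile:
    """Assemble a :class:`CellLineProfile` from a scaled expression matrix.

    ``node_genes`` maps merged model nodes to their member genes (a complex or
    isoform group averages its members' scaled values).  Nodes absent from both
    the matrix and the mapping receive *default*.
    """
    if cell_line not in scaled.columns:
        raise KeyError(f"cell line {cell_line!r} not in expression matrix")
    column = scaled[cell_line]
    node_genes = dict(node_genes or {})
    probs: dict[str, float] = {}
    for node in nodes:
        genes = node_genes.get(node, [node] if node in column.index else [])
        measured = [g for g in genes if g in column.index]
        if measured:
            probs[node] = float(np.mean([column[g] for g in measured]))
        else:
            probs[node] = default
    return CellLineProfile(cell_line, probs, dict(clamps or {}))


def sample_initial_state(
    profile: CellLineProfile, nodes: Sequence[str], rng_seed: int
) -> dict[str, int]:
    """Draw one full 0/1 state: independent Bernoulli(init_prob) per node,
    clamped nodes fixed at their clamp value.  Reproducible given the seed."""
    rng = np.random.default_rng(rng_seed)
    p = profile.probability_vector(nodes)
    draws = (rng.random(len(nodes)) < p).astype(int)
    return dict(zip(nodes, draws.tolist()))


def sample_initial_matrix(
    profile: CellLineProfile, nodes: Sequence[str], repeats: int, seed: int
) -> np.ndarray:
    """Sample a ``(repeats, n_nodes)`` boolean initial-state matrix.

    Each repeat uses its own deterministic stream (``seed + repeat index``) so
    ensembles are reproducible repeat-by-repeat regardless of batch size.
    """
    p = profile.probability_vector(nodes)
    out = np.empty((repeats, len(nodes)), dtype=bool)
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        out[r] = rng.random(len(nodes)) < p
    return out
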