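"""End-to-end orchestration: simulate, score, select, evaluate, cluster.

This is the programmatic surface behind the command-line interface and the
reproduction script: given per-cell-line models and profiles, a drug set and a
pair list, it simulates every (pair, cell line) dose grid (sharing one
unperturbed baseline ensemble per cell line), computes consensus PSS
profiles, optionally runs the GA panel selection, and evaluates predicted
against observed HSA scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cellline import CellLineProfile
from .evaluate import EvaluationReport, MechanismClustering, classify_and_score, cluster_pss
from .ga import GAConfig, GAResult, evolve
from .network import RuleSet
from .perturb import DEFAULT_DOSES, Drug, simulate_combination_grid
from .simulate import EnsembleResult, simulate_cell_line
from .synergy import PSSProfile, predicted_hsa, score_pair

__all__ = ["SimulationSettings", "PipelineResult", "score_all_pairs", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class SimulationSettings:
    """Simulator knobs shared across the pipeline stages."""

    steps: int = 5000
    repeats: int = 100
    grid_repeats: int = 30
    doses: tuple[float, ...] = DEFAULT_DOSES
    entropy_window: int = 100
    entropy_stride: int = 10
    seed: int = 0


@dataclass
class PipelineResult:
    pss_profiles: list[PSSProfile]
    pss_matrix: pd.DataFrame  # rows: (pair, cell line); columns: scored nodes
    observed: pd.Series
    predicted: pd.Series
    report: EvaluationReport | None = None
    ga: GAResult | None = None
    selection: tuple[str, ...] = ()
    clustering: MechanismClustering | None = None
    baselines: dict[str, EnsembleResult] = field(default_factory=dict)


def score_all_pairs(
    cell_line_rules: Mapping[str, RuleSet],
    profiles: Mapping[str, CellLineProfile],
    drugs: Mapping[str, Drug],
    pairs: pd.DataFrame,
    roles: Mapping[str, str],
    settings: SimulationSettings | None = None,
) -> tuple[list[PSSProfile], dict[str, EnsembleResult]]:
    """Simulate and PSS-score every (drug pair, cell line) row of *pairs*.

    One unperturbed phase-1 ensemble per cell line is simulated once and
    reused as the baseline for all of that cell line's dose grids.
    """
    settings = settings or SimulationSettings()
    baselines: dict[str, EnsembleResult] = {}
    out: list[PSSProfile] = []
    for _, row in pairs.iterrows():
        cl = row["cell_line"]
        if cl not in baselines:
            baselines[cl] = simulate_cell_line(
                cell_line_rules[cl],
                profiles[cl],
                steps=settings.steps,
                repeats=settings.grid_repeats,
                seed=settings.seed,
                entropy_window=settings.entropy_window,
                entropy_stride=settings.entropy_stride,
            )
        grid = simulate_combination_grid(
            cell_line_rules[cl],
            profiles[cl],
            drugs[row["drug_a"]],
            drugs[row["drug_b"]],
            doses=settings.doses,
            repeats=settings.grid_repeats,
            phase1_steps=settings.steps,
            phase2_steps=settings.steps,
            seed=settings.seed,
            entropy_window=settings.entropy_window,
            entropy_stride=settings.entropy_stride,
            baseline=baselines[cl],
        )
        out.append(score_pair(grid, roles))
        logger.info(
            "scored %s + %s on %s", row["drug_a"], row["drug_b"], cl
        )
    return out, baselines


def profiles_to_matrix(profiles: Sequence[PSSProfile]) -> pd.DataFrame:
    """Stack consensus PSS profiles into a (pair, cell line) x node matrix."""
    rows = {
        f"{p.drug_a}+{p.drug_b}@{p.cell_line}": p.consensus for p in profiles
    }
    return pd.DataFrame(rows).T


def run_pipeline(
    cell_line_rules: Mapping[str, RuleSet],
    profiles: Mapping[str, CellLineProfile],
    drugs: Mapping[str, Drug],
    pairs: pd.DataFrame,
    roles: Mapping[str, str],
    settings: SimulationSettings | None = None,
    ga_config: GAConfig | None = None,
    selection: Sequence[str] | None = None,
    cluster_k: int | None = None,
) -> PipelineResult:
    """Full run: dose-grid simulation, PSS, panel selection, evaluation.

    If *selection* is given it is used directly; otherwise the GA selects the
    panel (mandatory members included) against the observed scores.
    """
    settings = settings or SimulationSettings()
    pss_profiles, baselines = score_all_pairs(
        cell_line_rules, profiles, drugs, pairs, roles, settings
    )
    matrix = profiles_to_matrix(pss_profiles)
    observed = pd.Series(
        pairs["observed_hsa"].to_numpy(), index=matrix.index, name="observed_hsa"
    )

    ga_result = None
    if selection is None:
        cfg = ga_config or GAConfig(seed=settings.seed)
        candidates = [c for c in matrix.columns]
        ga_result = evolve(cfg, candidates, matrix, observed)
        selection = tuple(sorted(ga_result.best))
    else:
        selection = tuple(selection)

    predicted = pd.Series(
        [predicted_hsa(dict(matrix.loc[idx]), selection) for idx in matrix.index],
        index=matrix.index,
        name="predicted_hsa",
    )
    report = classify_and_score(
        predicted.to_numpy(), observed.to_numpy(), rescale_predictions=True
    )

    clustering = None
    if cluster_k is not None and len(matrix) >= 2:
        clustering = cluster_pss(matrix[list(selection)], k=cluster_k)

    return PipelineResult(
        pss_profiles=pss_profiles,
        pss_matrix=matrix,
        observed=observed,
        predicted=predicted,
        report=report,
        ga=ga_result,
        selection=selection,
        clustering=clustering,
        baselines=baselines,
    )
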