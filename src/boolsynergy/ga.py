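"""Genetic algorithm selecting the protein panel behind the predicted score.

Chromosomes are variable-length protein subsets (E2F1 and CASP3 are always
members).  A chromosome's fitness is the Pearson correlation between the
predicted HSA scores it induces — the sum of its proteins' consensus PSS per
drug pair — and the observed HSA scores over the training pairs.

Each generation: rank the population by fitness, keep the top half as
parents, breed as many offspring by uniform set-crossover plus add/remove/swap
mutation (each applied with probability 0.9 — the search space is large), and
top the population back up with fresh random chromosomes.  Parents do not
re-enter the next population; a one-slot hall of fame preserves the best
chromosome ever seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MANDATORY_MEMBERS", "GAConfig", "GAResult", "fitness", "evolve"]

MANDATORY_MEMBERS = ("E2F1", "CASP3")


@dataclass
class GAConfig:
    """Population bookkeeping and operator rates for the subset GA."""

    population_size: int = 60
    survivors: int = 30
    offspring: int = 30
    fresh: int = 30
    mutation_prob: float = 0.9
    crossover_prob: float = 0.9
    generations: int = 500
    min_length: int = 3
    max_length: int = 20
    seed: int = 0
    mandatory: tuple[str, ...] = MANDATORY_MEMBERS

    def __post_init__(self):
        for name in ("mutation_prob", "crossover_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {p}")
        if self.survivors > self.population_size:
            raise ValueError("survivors cannot exceed population size")
        if self.offspring + self.fresh != self.population_size:
            raise ValueError("offspring + fresh must rebuild the full population")
        if self.min_length < len(self.mandatory):
            self.min_length = len(self.mandatory)


def fitness(
    chromosome: Sequence[str] | frozenset[str],
    pss_matrix: pd.DataFrame,
    observed: Sequence[float] | pd.Series,
) -> float:
    """Pearson r between chromosome-predicted and observed HSA scores.

    *pss_matrix* holds consensus PSS values, rows = drug pairs (training
    samples), columns = candidate proteins.  Constant predictions carry no
    ranking information and score -1 (worst).
    """
    observed = np.asarray(observed, dtype=float)
    if len(observed) != len(pss_matrix):
        raise ValueError("observed scores and PSS matrix rows do not align")
    if len(observed) < 3:
        raise ValueError("need at least 3 drug pairs to correlate")
    if np.std(observed) == 0:
        raise ValueError("observed scores have zero variance")
    members = sorted(set(chromosome))
    predictions = pss_matrix[members].to_numpy().sum(axis=1)
    if np.std(predictions) == 0:
        return -1.0
    return float(np.corrcoef(predictions, observed)[0, 1])


@dataclass
class GAResult:
    best: frozenset[str]
    best_fitness: float
    trace: pd.DataFrame = field(repr=False)  # generation, best fitness, subset
    evaluations: int = 0


def _random_chromosome(
    optional_pool: Sequence[str], cfg: GAConfig, rng: np.random.Generator
) -> frozenset[str]:
    mandatory = [m for m in cfg.mandatory]
    lo = max(0, cfg.min_length - len(mandatory))
    hi = min(len(optional_pool), cfg.max_length - len(mandatory))
    k = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    picked = rng.choice(len(optional_pool), size=k, replace=False) if k else []
    return frozenset(mandatory) | frozenset(optional_pool[i] for i in picked)


def _mutate(
    chrom: frozenset[str],
    optional_pool: Sequence[str],
    cfg: GAConfig,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Add, remove, or swap one optional protein (mandatory members untouched)."""
    optional_in = sorted(chrom - set(cfg.mandatory))
    optional_out = sorted(set(optional_pool) - chrom)
    moves = []
    if optional_out and len(chrom) < cfg.max_length:
        moves.append("add")
    if optional_in and len(chrom) > cfg.min_length:
        moves.append("remove")
    if optional_in and optional_out:
        moves.append("swap")
    if not moves:
        return chrom
    move = moves[int(rng.integers(len(moves)))]
    if move == "add":
        return chrom | {optional_out[int(rng.integers(len(optional_out)))]}
    if move == "remove":
        return chrom - {optional_in[int(rng.integers(len(optional_in)))]}
    gained = optional_out[int(rng.integers(len(optional_out)))]
    lost = optional_in[int(rng.integers(len(optional_in)))]
    return (chrom - {lost}) | {gained}


def _crossover(
    a: frozenset[str],
    b: frozenset[str],
    cfg: GAConfig,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Uniform set-crossover: each optional protein of either parent is
    inherited from a uniformly chosen parent."""
    child = set(cfg.mandatory)
    for protein in sorted((a | b) - set(cfg.mandatory)):
        parent = a if rng.random() < 0.5 else b
        if protein in parent:
            child.add(protein)
    return frozenset(child)


def _clip_length(
    chrom: frozenset[str],
    optional_pool: Sequence[str],
    cfg: GAConfig,
    rng: np.random.Generator,
) -> frozenset[str]:
    chrom = set(chrom)
    optional = sorted(chrom - set(cfg.mandatory))
    while len(chrom) > cfg.max_length and optional:
        drop = optional.pop(int(rng.integers(len(optional))))
        chrom.discard(drop)
    candidates = sorted(set(optional_pool) - chrom)
    while len(chrom) < cfg.min_length and candidates:
        add = candidates.pop(int(rng.integers(len(candidates))))
        chrom.add(add)
    return frozenset(chrom)


def evolve(
    cfg: GAConfig,
    candidates: Sequence[str],
    pss_matrix: pd.DataFrame,
    observed: Sequence[float] | pd.Series,
) -> GAResult:
    """Run the GA and return the best-ever chromosome with its fitness trace.

    *candidates* is the full protein pool (must contain the mandatory
    members, which every chromosome keeps).  Fitness values are cached by
    protein set, so later generations mostly pay only for novel subsets.
    """
    candidates = list(dict.fromkeys(candidates))
    missing = [m for m in cfg.mandatory if m not in candidates]
    if missing:
        raise ValueError(f"candidate pool is missing mandatory member(s) {missing}")
    missing_cols = [c for c in candidates if c not in pss_matrix.columns]
    if missing_cols:
        raise ValueError(f"PSS matrix lacks candidate column(s) {missing_cols}")
    optional_pool = [c for c in candidates if c not in cfg.mandatory]
    if len(optional_pool) + len(cfg.mandatory) < cfg.min_length:
        raise ValueError("candidate pool smaller than the minimum chromosome length")

    rng = np.random.default_rng(cfg.seed)
    cache: dict[frozenset[str], float] = {}
    evaluations = 0

    def score(chrom: frozenset[str]) -> float:
        nonlocal evaluations
        if chrom not in cache:
            cache[chrom] = fitness(chrom, pss_matrix, observed)
            evaluations += 1
        return cache[chrom]

    population = [_random_chromosome(optional_pool, cfg, rng) for _ in range(cfg.population_size)]
    best: frozenset[str] | None = None
    best_fit = -np.inf
    trace_rows = []

    for generation in range(cfg.generations + 1):
        ranked = sorted(population, key=score, reverse=True)
        if score(ranked[0]) > best_fit:
            best, best_fit = ranked[0], score(ranked[0])
        trace_rows.append(
            {
                "generation": generation,
                "best_fitness": best_fit,
                "best_subset": ",".join(sorted(best)),
            }
        )
        if generation == cfg.generations:
            break
        parents = ranked[: cfg.survivors]
        offspring = []
        for _ in range(cfg.offspring):
            i, j = rng.integers(len(parents)), rng.integers(len(parents))
            child = parents[int(i)]
            if rng.random() < cfg.crossover_prob:
                child = _crossover(parents[int(i)], parents[int(j)], cfg, rng)
            if rng.random() < cfg.mutation_prob:
                child = _mutate(child, optional_pool, cfg, rng)
            offspring.append(_clip_length(child, optional_pool, cfg, rng))
        fresh = [_random_chromosome(optional_pool, cfg, rng) for _ in range(cfg.fresh)]
        population = offspring + fresh

    assert best is not None
    return GAResult(
        best=best,
        best_fitness=float(best_fit),
        trace=pd.DataFrame(trace_rows),
        evaluations=evaluations,
    )
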