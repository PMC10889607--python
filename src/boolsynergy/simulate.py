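"""Uniform-asynchronous ensemble simulation with entropy-based steady state.

At every time step of a trajectory, exactly one node is updated: among all
non-clamped nodes whose rule output differs from their current value, one is
chosen uniformly at random and flipped.  A state in which no node can change
is a fixed point and absorbs the trajectory.

Steady state is detected from the entropy of the empirical state distribution
of the ensemble.  With ``P_t(S)`` the frequency of full network state ``S``
among the repeats at step t,

    H(t) = -sum_S P_t(S) * log2 P_t(S)      [bits]

H starts near log2(repeats) while trajectories are scattered and falls as a
dominant state (or small attractor set) takes over; the steady state is
declared at the step where the windowed slope of H(t) is at its minimum —
the heart of the collapse — and per-node activities are averaged from that
step to the end of the run.

The ensemble is advanced as a (repeats, n_nodes) boolean matrix so that one
NumPy pass per step serves every repeat; trajectories remain independent
(one flip per repeat per step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cellline import CellLineProfile, sample_initial_matrix
from .network import RuleSet

__all__ = [
    "CompiledModel",
    "EntropyProfile",
    "EnsembleResult",
    "async_step",
    "compile_model",
    "run_ensemble",
    "simulate_cell_line",
    "entropy_profile",
    "detect_steady_state",
    "steady_state_activities",
]

DEFAULT_STEPS = 5000
DEFAULT_REPEATS = 100
DEFAULT_ENTROPY_WINDOW = 100
DEFAULT_ENTROPY_STRIDE = 10


# ---------------------------------------------------------------------------
# model compilation


@dataclass
class CompiledModel:
    """A rule set lowered to vectorised update functions over a node order."""

    nodes: list[str]
    index: dict[str, int]
    functions: list[Callable[[np.ndarray], np.ndarray]]
    clamp_mask: np.ndarray  # (n,) bool
    clamp_values: np.ndarray  # (n,) bool

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def next_values(self, S: np.ndarray) -> np.ndarray:
        """Synchronous image of every rule on state matrix S (clamps applied)."""
        nxt = np.empty_like(S)
        for j, f in enumerate(self.functions):
            nxt[:, j] = f(S)
        nxt[:, self.clamp_mask] = self.clamp_values[self.clamp_mask]
        return nxt


def compile_model(rules: RuleSet) -> CompiledModel:
    nodes = list(rules.nodes)
    index = {n: j for j, n in enumerate(nodes)}
    functions = [rules.rules[n].expression.compile(index) for n in nodes]
    clamp_mask = np.zeros(len(nodes), dtype=bool)
    clamp_values = np.zeros(len(nodes), dtype=bool)
    for node, value in rules.clamps.items():
        clamp_mask[index[node]] = True
        clamp_values[index[node]] = bool(value)
    return CompiledModel(nodes, index, functions, clamp_mask, clamp_values)


# ---------------------------------------------------------------------------
# single-state stepping (reference semantics; the ensemble core matches it)


def async_step(
    state: dict[str, int], rules: RuleSet, rng: np.random.Generator
) -> dict[str, int]:
    """One uniform-asynchronous update of a single full state.

    Among non-clamped nodes whose rule output differs from their current
    value, one is chosen uniformly and updated; a fixed point is returned
    unchanged.
    """
    candidates = [
        n
        for n in rules.nodes
        if n not in rules.clamps and rules.rules[n].evaluate(state) != state[n]
    ]
    new = dict(state)
    for node, value in rules.clamps.items():
        new[node] = int(value)
    if not candidates:
        return new
    pick = candidates[int(rng.integers(len(candidates)))]
    new[pick] = 1 - new[pick]
    return new


# ---------------------------------------------------------------------------
# entropy bookkeeping


@dataclass
class EntropyProfile:
    """Entropy H(t) in bits of the ensemble state distribution at each step."""

    H: np.ndarray
    n_repeats: int = 0

    def __len__(self):
        return len(self.H)


def _state_entropy(S: np.ndarray) -> float:
    """Entropy in bits of the distribution of full states across repeats."""
    packed = np.packbits(S, axis=1)
    _, counts = np.unique(packed, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_profile(trajectories: np.ndarray) -> EntropyProfile:
    """Entropy profile of an ensemble given as a (repeats, T+1, n) bool array.

    ``P_t(S)`` is the empirical frequency of full state S among the repeats at
    step t, so H(t) is bounded by log2(repeats) and reaches exactly 0 once
    every trajectory sits in the same state.
    """
    if trajectories.ndim != 3 or trajectories.shape[0] < 1:
        raise ValueError("expected a (repeats, steps+1, nodes) array")
    H = np.empty(trajectories.shape[1])
    for t in range(trajectories.shape[1]):
        H[t] = _state_entropy(trajectories[:, t, :])
    return EntropyProfile(H, trajectories.shape[0])


# ---------------------------------------------------------------------------
# steady-state detection


def detect_steady_state(
    profile: EntropyProfile | np.ndarray,
    window: int = DEFAULT_ENTROPY_WINDOW,
    stride: int = DEFAULT_ENTROPY_STRIDE,
) -> int:
    """Step at which the windowed slope of H(t) is minimal (earliest on ties).

    H is subsampled every *stride* steps and the slope at each sample is a
    centered finite difference over ±window/2 (truncated at the ends).
    """
    H = profile.H if isinstance(profile, EntropyProfile) else np.asarray(profile, float)
    if not np.all(np.isfinite(H)):
        raise ValueError("entropy profile contains non-finite values")
    if len(H) < 2:
        return 0
    stride = max(1, min(stride, len(H) - 1))
    sub = H[::stride]
    k_max = len(sub) - 1
    half = max(1, int(round(window / (2 * stride))))
    slopes = np.empty(k_max + 1)
    for k in range(k_max + 1):
        lo = max(0, k - half)
        hi = min(k_max, k + half)
        slopes[k] = (sub[hi] - sub[lo]) / ((hi - lo) * stride)
    # earliest tie, with a tolerance so float fuzz cannot defeat the tie-break
    min_slope = slopes.min()
    k_star = int(np.argmax(slopes <= min_slope + 1e-12))
    return k_star * stride


def steady_state_activities(
    activities: np.ndarray, steady_start: int, nodes: Sequence[str]
) -> pd.Series:
    """Mean per-node activity over steps [steady_start, T]."""
    if steady_start >= activities.shape[0]:
        raise ValueError("steady_start beyond the simulated horizon")
    return pd.Series(
        activities[steady_start:].mean(axis=0), index=list(nodes), name="activity"
    )


# ---------------------------------------------------------------------------
# ensemble core


@dataclass
class EnsembleResult:
    """Outcome of an asynchronous ensemble run."""

    nodes: list[str]
    activities: np.ndarray  # (steps+1, n): ensemble mean per step
    entropy: EntropyProfile
    steady_start: int
    steady_activity: pd.Series
    final_states: np.ndarray  # (repeats, n) bool
    repeats: int
    steps: int
    trajectories: np.ndarray | None = field(default=None, repr=False)

    def per_repeat_steady_means(self) -> np.ndarray:
        """(repeats, n) per-repeat mean activity over the steady window.

        Requires the run to have recorded trajectories.
        """
        if self.trajectories is None:
            raise ValueError("run with record_trajectories=True to get per-repeat means")
        return self.trajectories[:, self.steady_start :, :].mean(axis=1)


def run_ensemble(
    rules: RuleSet,
    init_states: np.ndarray,
    steps: int = DEFAULT_STEPS,
    seed: int = 0,
    entropy_window: int = DEFAULT_ENTROPY_WINDOW,
    entropy_stride: int = DEFAULT_ENTROPY_STRIDE,
    extra_clamp_mask: np.ndarray | None = None,
    extra_clamp_values: np.ndarray | None = None,
    record_trajectories: bool = False,
) -> EnsembleResult:
    """Advance an ensemble of asynchronous trajectories and summarise it.

    Parameters
    ----------
    init_states
        (repeats, n_nodes) boolean initial states (one row per repeat).
    extra_clamp_mask, extra_clamp_values
        Optional per-repeat clamps (e.g. drug perturbations), shape
        (repeats, n_nodes).  Model-level clamps (mutations) take precedence on
        conflicting nodes.  Extra-clamped nodes are set to their clamp value at
        step 0 of this run and held.
    """
    model = compile_model(rules)
    S = np.array(init_states, dtype=bool)
    if S.ndim != 2 or S.shape[1] != model.n_nodes:
        raise ValueError("init_states must be (repeats, n_nodes)")
    R = S.shape[0]

    # model clamps enforced on the initial states
    S[:, model.clamp_mask] = model.clamp_values[model.clamp_mask]

    mask = np.broadcast_to(model.clamp_mask, S.shape).copy()
    values = np.broadcast_to(model.clamp_values, S.shape).copy()
    if extra_clamp_mask is not None:
        extra_clamp_mask = np.asarray(extra_clamp_mask, dtype=bool)
        extra_clamp_values = np.asarray(extra_clamp_values, dtype=bool)
        free = extra_clamp_mask & ~mask  # model clamps win on conflict
        values[free] = extra_clamp_values[free]
        mask |= extra_clamp_mask
        S[free] = values[free]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51AB]))
    activities = np.empty((steps + 1, model.n_nodes))
    H = np.empty(steps + 1)
    trajectories = (
        np.empty((R, steps + 1, model.n_nodes), dtype=bool)
        if record_trajectories
        else None
    )

    activities[0] = S.mean(axis=0)
    H[0] = _state_entropy(S)
    if trajectories is not None:
        trajectories[:, 0, :] = S

    arange_R = np.arange(R)
    for t in range(1, steps + 1):
        nxt = model.next_values(S)
        nxt[mask] = values[mask]
        diff = nxt != S
        counts = diff.sum(axis=1)
        # one uniform draw per repeat per step keeps the stream layout fixed
        u = rng.random(R)
        active = counts > 0
        if active.any():
            r_idx = np.minimum((u * counts).astype(np.int64), np.maximum(counts - 1, 0))
            cum = np.cumsum(diff, axis=1)
            pick = (cum > r_idx[:, None]).argmax(axis=1)
            rows = arange_R[active]
            S[rows, pick[rows]] = nxt[rows, pick[rows]]
        activities[t] = S.mean(axis=0)
        H[t] = _state_entropy(S)
        if trajectories is not None:
            trajectories[:, t, :] = S

    profile = EntropyProfile(H, R)
    t_star = detect_steady_state(profile, entropy_window, entropy_stride)
    steady = steady_state_activities(activities, t_star, model.nodes)
    return EnsembleResult(
        nodes=model.nodes,
        activities=activities,
        entropy=profile,
        steady_start=t_star,
        steady_activity=steady,
        final_states=S,
        repeats=R,
        steps=steps,
        trajectories=trajectories,
    )


def simulate_cell_line(
    rules: RuleSet,
    profile: CellLineProfile,
    steps: int = DEFAULT_STEPS,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    entropy_window: int = DEFAULT_ENTROPY_WINDOW,
    entropy_stride: int = DEFAULT_ENTROPY_STRIDE,
    record_trajectories: bool = False,
) -> EnsembleResult:
    """Unperturbed ensemble for one cell line.

    Initial states are Bernoulli draws from the profile's expression-derived
    ON probabilities (one deterministic stream per repeat); mutation clamps
    present in either the rule set or the profile are enforced throughout.
    """
    merged = rules.copy()
    for node, v in profile.clamps.items():
        if node in merged.clamps and merged.clamps[node] != v:
            raise ValueError(f"profile clamp for {node!r} conflicts with rule set clamp")
        merged.clamps[node] = v
    init = sample_initial_matrix(profile, merged.nodes, repeats, seed)
    return run_ensemble(
        merged,
        init,
        steps=steps,
        seed=seed,
        entropy_window=entropy_window,
        entropy_stride=entropy_stride,
        record_trajectories=record_trajectories,
    )
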