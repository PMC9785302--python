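"""Simulated-annealing subset search shared by the LDA and MLR wrappers.

State = a non-empty feature subset of bounded size.  Moves add, drop or swap
a single feature, chosen uniformly among the legal moves.  Worse states are
accepted with Metropolis probability exp(-dE/T) under geometric cooling
T <- gamma*T every ``steps_per_temp`` moves.  Several independent restarts
are run and the best-ever state returned.  Energies are memoized per run,
so revisited subsets cost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["SAParams", "anneal_subset"]


@dataclass
class SAParams:
    """Annealing schedule and budget.

    ``n_moves`` is the total number of proposed moves per restart;
    ``gamma = 0`` freezes the temperature immediately, degenerating to
    greedy hill-climbing from the initial subset.
    """

    max_subset_size: int = 6
    t0: float = 0.5
    gamma: float = 0.95
    steps_per_temp: int = 50
    n_moves: int = 5000
    n_restarts: int = 3
    seed: int = 0
    parsimony_eps: float = 1e-6

    def validate(self) -> None:
        if self.max_subset_size < 1:
            raise ValueError("max_subset_size must be >= 1")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("cooling factor gamma must lie in [0, 1)")
        if self.t0 < 0 or self.n_moves < 1 or self.n_restarts < 1:
            raise ValueError("invalid SA budget")


def _propose(
    subset: frozenset, candidates: Sequence[str], cap: int, rng: np.random.Generator
) -> frozenset:
    outside = [c for c in candidates if c not in subset]
    inside = sorted(subset)
    moves: list[tuple[str, str | None, str | None]] = []
    if len(subset) < cap:
        moves += [("add", c, None) for c in outside]
    if len(subset) > 1:
        moves += [("drop", None, c) for c in inside]
    moves += [("swap", c_in, c_out) for c_out in inside for c_in in outside]
    if not moves:
        return subset
    kind, c_in, c_out = moves[rng.integers(len(moves))]
    if kind == "add":
        return subset | {c_in}
    if kind == "drop":
        return subset - {c_out}
    return (subset - {c_out}) | {c_in}


def anneal_subset(
    candidates: Sequence[str],
    energy_fn: Callable[[tuple[str, ...]], float],
    params: SAParams,
) -> tuple[tuple[str, ...], float]:
    """Minimize ``energy_fn`` over feature subsets.

    ``energy_fn`` receives a sorted tuple of feature names and returns a
    scalar (may be +inf for infeasible subsets).  The parsimony term
    ``parsimony_eps * |subset|`` is added here, so ties in the raw energy
    break toward smaller subsets.  Deterministic given ``params.seed``.

    Returns ``(best_subset, best_energy)`` where the energy includes the
    parsimony term.
    """
    params.validate()
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("empty candidate feature set")
    cap = min(params.max_subset_size, len(candidates))
    rng = np.random.default_rng(params.seed)
    cache: dict[frozenset, float] = {}

    def energy(subset: frozenset) -> float:
        if subset not in cache:
            raw = energy_fn(tuple(sorted(subset)))
            cache[subset] = raw + params.parsimony_eps * len(subset)
        return cache[subset]

    best_subset: frozenset | None = None
    best_e = np.inf
    for _ in range(params.n_restarts):
        size = int(rng.integers(1, cap + 1))
        current = frozenset(
            np.array(candidates)[rng.choice(len(candidates), size, replace=False)]
        )
        e_current = energy(current)
        if e_current < best_e:
            best_subset, best_e = current, e_current
        t = params.t0
        for move in range(params.n_moves):
            proposal = _propose(current, candidates, cap, rng)
            e_prop = energy(proposal)
            if np.isinf(e_prop) and np.isinf(e_current):
                de = 0.0  # keep the walk mobile across infeasible states
            else:
                de = e_prop - e_current
            if de <= 0 or (t > 0 and rng.random() < np.exp(-de / t)):
                current, e_current = proposal, e_prop
                if e_current < best_e:
                    best_subset, best_e = current, e_current
            if (move + 1) % params.steps_per_temp == 0:
                t *= params.gamma
    assert best_subset is not None
    return tuple(sorted(best_subset)), float(best_e)
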