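"""Dimension-adaptive refinement of the sparse sampling plan.

The sampler starts from the single midpoint configuration (all quadrature
orders zero) and repeatedly performs a *look-ahead step*: every admissible
forward neighbor of the accepted index set is evaluated (an ensemble of
simulator calls per new configuration), an error measure is attached to each
candidate — the absolute change in surrogate variance the candidate would
cause — and the candidate with the largest error is accepted.  Refinement
therefore concentrates on the input directions that actually move the output
variance, discovering a low effective dimension when one exists.

The simulator is any callable ``model(config, seed) -> energy`` where
``config`` is a point in the physical input box.  Every configuration is
evaluated once per seed in the fixed seed list and the per-configuration
quantity of interest is the ensemble average (or the single-seed value in
``single_seed`` mode).  All (configuration, seed) evaluations are cached, so
the nested point sets never trigger duplicate simulator calls; the budget
counts simulator calls, look-ahead included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .quadrature import (
    MultiIndex,
    Point,
    SparseGridPlan,
    grid_moments,
    tensor_grid,
)

__all__ = [
    "forward_neighbors",
    "backward_neighbors",
    "is_admissible",
    "admissible_candidates",
    "refinement_error",
    "run_campaign",
    "AdaptiveState",
    "CampaignResult",
    "ModelEvaluationError",
]


class ModelEvaluationError(RuntimeError):
    """Raised when the simulator fails; carries the offending configuration."""

    def __init__(self, config: Tuple[float, ...], seed: int, cause: Exception):
        self.config = config
        self.seed = seed
        self.cause = cause
        super().__init__(
            f"model evaluation failed at configuration {config}, seed {seed}: {cause!r}"
        )


def forward_neighbors(l: MultiIndex) -> Set[MultiIndex]:
    """All indices reachable by incrementing one quadrature order of ``l``."""
    l = tuple(l)
    return {l[:i] + (l[i] + 1,) + l[i + 1 :] for i in range(len(l))}


def backward_neighbors(l: MultiIndex) -> Set[MultiIndex]:
    """All indices reachable by decrementing one positive order of ``l``."""
    l = tuple(l)
    return {
        l[:i] + (l[i] - 1,) + l[i + 1 :] for i in range(len(l)) if l[i] > 0
    }


def is_admissible(index_set) -> bool:
    """True iff the set is downward closed (contains all backward neighbors)."""
    s = {tuple(l) for l in index_set}
    return all(b in s for l in s for b in backward_neighbors(l))


def admissible_candidates(accepted) -> Set[MultiIndex]:
    """Forward neighbors of the accepted set whose acceptance keeps it admissible."""
    s = {tuple(l) for l in accepted}
    cands: Set[MultiIndex] = set()
    for l in s:
        for f in forward_neighbors(l):
            if f not in s and backward_neighbors(f) <= s:
                cands.add(f)
    return cands


@dataclass
class AdaptiveState:
    """Mutable sampler state: accepted set, candidate pool, bookkeeping."""

    accepted: Set[MultiIndex]
    candidates: Set[MultiIndex] = field(default_factory=set)
    errors: Dict[MultiIndex, float] = field(default_factory=dict)
    evaluations_used: int = 0
    budget: int = 0

    def check(self) -> None:
        assert is_admissible(self.accepted), "accepted set lost admissibility"
        for c in self.candidates:
            assert is_admissible(self.accepted | {c}), f"candidate {c} inadmissible"
        assert self.evaluations_used <= self.budget


def refinement_error(
    accepted,
    candidate: MultiIndex,
    values: Mapping[Point, float],
) -> float:
    """Error measure of a candidate: |variance with candidate - variance without|.

    ``values`` must cover the union grid of ``accepted | {candidate}``.
    """
    acc = {tuple(l) for l in accepted}
    candidate = tuple(candidate)
    if candidate in acc or not is_admissible(acc | {candidate}):
        raise ValueError(f"candidate {candidate} is not admissible for this set")
    plan_old = SparseGridPlan.from_index_set(acc)
    plan_new = SparseGridPlan.from_index_set(acc | {candidate})
    _, var_old = grid_moments(plan_old, values)
    _, var_new = grid_moments(plan_new, values)
    return abs(var_new - var_old)


@dataclass
class CampaignResult:
    """Everything a finished adaptive campaign produced."""

    state: AdaptiveState
    plan: SparseGridPlan
    evaluation_table: pd.DataFrame
    moments: Tuple[float, float]
    history: pd.DataFrame
    node_values: Dict[Point, float]

    @property
    def mean(self) -> float:
        return self.moments[0]

    @property
    def variance(self) -> float:
        return self.moments[1]


def _new_points(accepted: Set[MultiIndex], candidate: MultiIndex) -> List[Point]:
    existing = set(SparseGridPlan.from_index_set(accepted).unique_points)
    return [p for p in tensor_grid(candidate).points if p not in existing]


def run_campaign(
    model: Callable[[Tuple[float, ...], int], float],
    input_space,
    seeds: Sequence[int],
    budget: int,
    quantity: str = "ensemble_mean",
    tolerance: float = 0.0,
    max_level: Optional[int] = None,
    explore: bool = False,
    explore_rtol: float = 0.1,
) -> CampaignResult:
    """Run the dimension-adaptive campaign until the budget is exhausted.

    Parameters
    ----------
    model : callable
        ``model(config, seed) -> energy`` with ``config`` in the physical box.
    input_space : object with ``dimension`` and ``to_physical(unit_point)``
        Maps unit-cube collocation points to physical configurations.
    seeds : sequence of int
        Fixed seed list; each configuration is evaluated once per seed.
    budget : int
        Maximum simulator calls, look-ahead evaluations included.
    quantity : {"ensemble_mean", "single_seed"}
        Per-configuration quantity of interest the sampler refines on.
        ``single_seed`` uses only the first seed of the list.
    tolerance : float
        Stop early once the largest candidate error falls below this value
        (0 disables the check; the budget is then the only stopping rule).
    max_level : int, optional
        Cap on any single quadrature order; unlimited when None.
    explore : bool
        The default greedy policy accepts only candidates with a strictly
        positive error, so a dimension whose look-ahead values coincide with
        the current surrogate (for instance because the model vanishes
        identically on the center hyperplane) is never refined.  With
        ``explore=True`` the sampler switches to an exploration step — accept
        the cheapest not-yet-accepted candidate — whenever the largest error
        has converged below ``explore_rtol`` times the current variance.
        This opens up interaction directions that the variance metric alone
        is blind to, at the cost of occasionally refining inert dimensions.
    explore_rtol : float
        Relative convergence threshold that triggers exploration: a best
        candidate that would change the variance by less than this fraction
        of the current variance is treated as converged.
    """
    if quantity not in ("ensemble_mean", "single_seed"):
        raise ValueError(f"unknown quantity mode {quantity!r}")
    active_seeds = [int(seeds[0])] if quantity == "single_seed" else [int(s) for s in seeds]
    if budget < len(active_seeds):
        raise ValueError("budget cannot fit the initial midpoint ensemble")
    d = input_space.dimension

    cache: Dict[Tuple[Point, int], float] = {}
    rows: List[dict] = []
    qoi: Dict[Point, float] = {}
    config_ids: Dict[Point, int] = {}
    state = AdaptiveState(accepted=set(), budget=budget)

    def ensure_evaluated(points: List[Point]) -> None:
        """Evaluate the ensemble at every new unit point, filling cache and QoI."""
        for p in points:
            if p in qoi:
                continue
            config_ids[p] = len(config_ids)
            physical = tuple(input_space.to_physical(p))
            energies = []
            for s in active_seeds:
                key = (p, s)
                if key not in cache:
                    try:
                        cache[key] = float(model(physical, s))
                    except Exception as exc:  # pragma: no cover - defensive
                        raise ModelEvaluationError(physical, s, exc) from exc
                    state.evaluations_used += 1
                    rows.append(
                        {
                            "config_id": config_ids[p],
                            **{
                                name: val
                                for name, val in zip(input_space.names, physical)
                            },
                            "seed": s,
                            "energy": cache[key],
                        }
                    )
                energies.append(cache[key])
            qoi[p] = float(np.mean(energies))

    def ensemble_cost(points: List[Point]) -> int:
        return sum(len(active_seeds) for p in points if p not in qoi)

    root = (0,) * d
    ensure_evaluated(tensor_grid(root).points)
    state.accepted = {root}
    state.candidates = admissible_candidates(state.accepted)
    if max_level is not None:
        state.candidates = {c for c in state.candidates if max(c) <= max_level}

    history_rows: List[dict] = []
    plan = SparseGridPlan.from_index_set(state.accepted)
    mean, var = grid_moments(plan, qoi)
    history_rows.append(
        {"iteration": 0, "accepted_index": str(root), "error": np.nan,
         "mean": mean, "variance": var, "evaluations_used": state.evaluations_used}
    )

    iteration = 0
    while state.candidates:
        # look-ahead: evaluate every not-yet-evaluated candidate's new points
        exhausted = False
        for cand in sorted(state.candidates):
            new_pts = _new_points(state.accepted, cand)
            cost = ensemble_cost(new_pts)
            if state.evaluations_used + cost > budget:
                exhausted = True
                break
            ensure_evaluated(new_pts)
        if exhausted:
            break

        state.errors = {
            cand: refinement_error(state.accepted, cand, qoi)
            for cand in state.candidates
        }
        best_err = max(state.errors.values())
        if tolerance > 0.0 and best_err < tolerance:
            break
        current_mean, current_var = grid_moments(
            SparseGridPlan.from_index_set(state.accepted), qoi
        )
        # errors at the level of summation round-off are treated as zero so
        # that inert dimensions are never refined on numerical noise alone;
        # the cancellation residue scales with the second moment, not the
        # variance (the QoI can sit far from zero)
        noise_floor = 1e-12 * (current_mean**2 + current_var)
        if explore and best_err <= explore_rtol * current_var:
            # exploration: cheapest candidate first, lexicographic tie-break
            best = min(
                state.candidates,
                key=lambda c: (tensor_grid(c).size, c),
            )
            best_err = state.errors[best]
        elif best_err <= noise_floor:
            # no candidate changes the variance; greedy refinement is done
            break
        else:
            # deterministic tie-break: lexicographically smallest among maximal
            best = min(c for c, e in state.errors.items() if e == best_err)

        state.accepted.add(best)
        state.candidates.discard(best)
        for f in admissible_candidates(state.accepted):
            if max_level is None or max(f) <= max_level:
                state.candidates.add(f)
        state.check()

        iteration += 1
        plan = SparseGridPlan.from_index_set(state.accepted)
        mean, var = grid_moments(plan, qoi)
        history_rows.append(
            {"iteration": iteration, "accepted_index": str(best),
             "error": best_err, "mean": mean, "variance": var,
             "evaluations_used": state.evaluations_used}
        )

    plan = SparseGridPlan.from_index_set(state.accepted)
    moments = grid_moments(plan, qoi)
    table = pd.DataFrame(
        rows, columns=["config_id", *input_space.names, "seed", "energy"]
    )
    history = pd.DataFrame(history_rows)
    return CampaignResult(
        state=state,
        plan=plan,
        evaluation_table=table,
        moments=moments,
        history=history,
        node_values=qoi,
    )
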