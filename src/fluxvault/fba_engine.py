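"""Flux balance analysis: steady-state LP over a model plus a modification layer.

The problem is the standard one: maximize c·v subject to S·v = 0 and
lb ≤ v ≤ ub, where S is the species × reactions stoichiometric matrix,
v the flux vector (mmol gDW⁻¹ h⁻¹) and c the objective coefficients.
Knockouts pin a reaction's bounds to (0, 0); bound modifications replace
them.  Modifications are applied from an :class:`EffectiveState` — the
override-resolved layer — regardless of whether the targeted reactions
appear in any view.

Reversible reactions stay single signed-flux columns (no splitting), so
reported fluxes carry their sign.  The LP is solved with HiGHS via
``scipy.optimize.linprog``.  Degenerate optima are a fact of FBA: the
objective value is unique, but the reported flux vector (hence v_min/v_max)
is one optimal vertex and may differ between solvers.

The module also computes the three visual scalars a renderer maps onto
edges: a blue→red color interpolation parameter in [0, 1], an edge width
clamped to a user range, and a particle emission rate proportional to |flux|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import ConsistencyError, SolverError, StateError
from .model_store import ModelRecord
from .modification_trace import EffectiveState

__all__ = [
    "LP_TOLERANCE",
    "FBAProblem",
    "FluxSolution",
    "VisualScalars",
    "build_problem",
    "solve_fba",
    "compute_visual_scalars",
]

LP_TOLERANCE = 1e-9  # primal/dual feasibility tolerance handed to HiGHS


@dataclass(frozen=True)
class FBAProblem:
    species_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: np.ndarray  # species x reactions
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.reaction_ids)
        if not (self.S.shape[1] == len(self.lb) == len(self.ub) == len(self.c) == n):
            raise ValueError("inconsistent problem dimensions")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[i] for i in np.nonzero(self.lb > self.ub)[0]]
            raise ValueError(f"lb > ub for reactions {bad}")


@dataclass(frozen=True)
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: dict[str, float]
    v_min: float | None
    v_max: float | None

    @property
    def v(self) -> np.ndarray:
        return np.array(list(self.fluxes.values()))


@dataclass(frozen=True)
class VisualScalars:
    color_t: dict[str, float]  # 0 = blue (low flux), 1 = red (high flux)
    width: dict[str, float]
    particle_rate: dict[str, float]  # particles / s


def build_problem(model: ModelRecord, state: EffectiveState | None = None) -> FBAProblem:
    """Assemble the LP for a model under an effective modification layer."""
    species_ids = tuple(s.species_id for s in model.species)
    reaction_ids = tuple(r.reaction_id for r in model.reactions)
    sp_index = {sid: i for i, sid in enumerate(species_ids)}
    S = np.zeros((len(species_ids), len(reaction_ids)))
    lb = np.empty(len(reaction_ids))
    ub = np.empty(len(reaction_ids))
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for sid, coeff in rxn.stoichiometry.items():
            S[sp_index[sid], j] = coeff
    c = np.zeros(len(reaction_ids))
    rxn_index = {rid: j for j, rid in enumerate(reaction_ids)}
    for rid, coeff in model.objective.items():
        c[rxn_index[rid]] = coeff

    if state is not None:
        for target, prov in state.items():
            if target not in rxn_index:
                raise ConsistencyError(
                    f"modification target {target!r} is not a reaction of "
                    f"model {model.model_id!r}"
                )
            j = rxn_index[target]
            if prov.entry.operation == "knockout":
                lb[j] = ub[j] = 0.0
            else:  # set_bounds
                lb[j], ub[j] = prov.entry.payload

    return FBAProblem(species_ids, reaction_ids, S, lb, ub, c)


def solve_fba(
    problem: FBAProblem, restrict_to: Sequence[str] | None = None
) -> FluxSolution:
    """Solve the LP; v_min/v_max are extrema over the reported reactions.

    ``restrict_to`` optionally limits the extrema to a subset of reactions
    (e.g. those present in a view), since a renderer colors only the mapped
    pathway.
    """
    res = linprog(
        -problem.c,
        A_eq=problem.S,
        b_eq=np.zeros(problem.S.shape[0]),
        bounds=list(zip(problem.lb, problem.ub)),
        method="highs",
        options={
            "primal_feasibility_tolerance": LP_TOLERANCE,
            "dual_feasibility_tolerance": LP_TOLERANCE,
        },
    )
    if res.status == 2:
        return FluxSolution("infeasible", None, {}, None, None)
    if res.status == 3:
        return FluxSolution("unbounded", None, {}, None, None)
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}", status="error")

    # "+ 0.0" folds IEEE negative zero into plain 0.0 for clean reports
    fluxes = {rid: float(res.x[j]) + 0.0 for j, rid in enumerate(problem.reaction_ids)}
    if restrict_to is not None:
        reported = [fluxes[r] for r in restrict_to if r in fluxes]
    else:
        reported = list(fluxes.values())
    v_min = min(reported) if reported else None
    v_max = max(reported) if reported else None
    return FluxSolution(
        status="optimal",
        objective_value=float(-res.fun) + 0.0,
        fluxes=fluxes,
        v_min=v_min,
        v_max=v_max,
    )


def compute_visual_scalars(
    solution: FluxSolution,
    w_min: float = 1.0,
    w_max: float = 10.0,
    rate_per_flux: float = 1.0,
) -> VisualScalars:
    """Per-reaction render scalars for an optimal solution.

    color_t interpolates linearly between blue (v_min → 0) and red
    (v_max → 1); when all reported fluxes are equal it sits at 0.5.  Width is
    a linear map of |v| onto [w_min, w_max] (clamped), so the largest-|flux|
    edge gets w_max.  Particle rate is ``rate_per_flux * |v|``, hence zero on
    zero-flux edges.
    """
    if solution.status != "optimal":
        raise StateError(f"visual scalars need an optimal solution, got {solution.status!r}")
    if w_min > w_max:
        raise ValueError(f"w_min {w_min} exceeds w_max {w_max}")
    v_min, v_max = solution.v_min, solution.v_max
    span = (v_max - v_min) if (v_min is not None and v_max is not None) else 0.0
    abs_max = max((abs(v) for v in solution.fluxes.values()), default=0.0)

    color_t, width, rate = {}, {}, {}
    for rid, v in solution.fluxes.items():
        if span > 0:
            t = (v - v_min) / span
        else:
            t = 0.5
        color_t[rid] = min(1.0, max(0.0, t))
        w = w_min + (w_max - w_min) * (abs(v) / abs_max) if abs_max > 0 else w_min
        width[rid] = min(w_max, max(w_min, w))
        rate[rid] = rate_per_flux * abs(v)
    return VisualScalars(color_t=color_t, width=width, particle_rate=rate)
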