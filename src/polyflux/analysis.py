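"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA maximizes a linear objective c.v over the steady-state set
{v : S v = 0, lb <= v <= ub} and returns one optimal flux distribution.
FVA computes the per-reaction min/max flux over the same set, optionally
restricted to the near-optimal region c.v >= gamma * FBA-optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NotFullDimensionalError, ValidationError
from .lp import solve_lp
from .model import MetabolicModel
from .polytope import AffineMap, HPolytope, chebyshev_center, remove_redundant_facets


@dataclass
class FBAResult:
    objective_value: float | None
    v_opt: np.ndarray
    status: str  # optimal | infeasible | unbounded

    def to_frame(self, model: MetabolicModel) -> pd.DataFrame:
        return pd.DataFrame(
            {"flux": self.v_opt}, index=pd.Index(model.reaction_ids, name="reaction")
        )


@dataclass
class FVAResult:
    min_flux: np.ndarray
    max_flux: np.ndarray
    gamma: float

    def to_frame(self, model: MetabolicModel) -> pd.DataFrame:
        return pd.DataFrame(
            {"min": self.min_flux, "max": self.max_flux},
            index=pd.Index(model.reaction_ids, name="reaction"),
        )


def _steady_state_args(model: MetabolicModel):
    A_eq = model.S if model.n_metabolites else None
    b_eq = np.zeros(model.n_metabolites) if model.n_metabolites else None
    return A_eq, b_eq, list(zip(model.lb, model.ub))


def fba(model: MetabolicModel, c=None) -> FBAResult:
    """Maximize ``c . v`` over the steady-state set (c defaults to model.c)."""
    c = model.c if c is None else np.asarray(c, dtype=float).ravel()
    if c.shape != (model.n_reactions,):
        raise ValidationError("objective vector length mismatch")
    if not np.any(c):
        raise ValidationError("objective vector is all-zero; supply one for FBA")
    A_eq, b_eq, bounds = _steady_state_args(model)
    res = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, maximize=True)
    if not res.optimal:
        return FBAResult(objective_value=None, v_opt=np.empty(0), status=res.status)
    return FBAResult(objective_value=res.objective, v_opt=res.x, status="optimal")


def fva(model: MetabolicModel, gamma: float = 0.0, c=None) -> FVAResult:
    """Per-reaction flux ranges, optionally within a fraction of the optimum.

    With ``gamma > 0`` (and a non-zero objective) the constraint
    ``c . v >= gamma * opt`` is added, where ``opt`` is the FBA optimum
    computed once; 2n LPs follow.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValidationError(f"gamma must lie in [0, 1], got {gamma}")
    c = model.c if c is None else np.asarray(c, dtype=float).ravel()
    A_eq, b_eq, bounds = _steady_state_args(model)
    A_ub = b_ub = None
    if gamma > 0.0 and np.any(c):
        opt = fba(model, c=c)
        if opt.status != "optimal":
            raise ValidationError(f"FBA for the gamma constraint is {opt.status}")
        A_ub = -c[None, :]
        b_ub = np.array([-gamma * opt.objective_value])
    n = model.n_reactions
    lo = np.empty(n)
    hi = np.empty(n)
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        r_min = solve_lp(e, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
        r_max = solve_lp(e, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                         bounds=bounds, maximize=True)
        if not (r_min.optimal and r_max.optimal):
            raise ValidationError(
                f"FVA LP failed for reaction {model.reaction_ids[j]}: "
                f"{r_min.status}/{r_max.status}")
        lo[j], hi[j] = r_min.objective, r_max.objective
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return FVAResult(min_flux=lo, max_flux=hi, gamma=gamma)


def add_optimality_constraint(
    P: HPolytope, T: AffineMap, model: MetabolicModel, gamma: float
) -> HPolytope:
    """Restrict the sampling polytope to fluxes with ``c . v >= gamma * opt``.

    In polytope coordinates ``v = N x + shift`` the constraint becomes
    ``(-c^T N) x <= c . shift - gamma * opt``.  ``gamma = 1`` generally
    selects a lower-dimensional optimal face and is rejected; rebuild the
    polytope on that face instead if optimal-only sampling is needed.
    """
    if not np.any(model.c):
        raise ValidationError("model has an all-zero objective")
    if not 0.0 <= gamma <= 1.0:
        raise ValidationError(f"gamma must lie in [0, 1], got {gamma}")
    if gamma >= 1.0:
        raise NotFullDimensionalError(
            "gamma = 1 restricts sampling to the optimal face, which is not "
            "full-dimensional; use gamma < 1 or rebuild the polytope on the face")
    opt = fba(model)
    if opt.status != "optimal":
        raise ValidationError(f"FBA is {opt.status}; cannot constrain optimality")
    row = -(model.c @ T.N)
    rhs = float(model.c @ T.shift) - gamma * opt.objective_value
    norm = np.linalg.norm(row)
    if norm < 1e-12:
        # objective constant on the polytope: constraint is vacuous or empty
        if rhs < -1e-9:
            raise NotFullDimensionalError(
                "objective is constant below the requested optimality level")
        return P
    A = np.vstack([P.A, row / norm])
    b = np.concatenate([P.b, [rhs / norm]])
    out = remove_redundant_facets(HPolytope(A, b, normalize=False))
    chebyshev_center(out)  # raises NotFullDimensionalError when too flat
    return out
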