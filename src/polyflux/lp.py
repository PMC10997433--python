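"""Solver-agnostic linear programming interface.

Everything in polyflux that needs an LP goes through :func:`solve_lp`, which
currently delegates to HiGHS via ``scipy.optimize.linprog``.  Any solver with
~1e-9 feasibility tolerance could be swapped in behind this function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

#: Name/version string logged for provenance.
SOLVER_NAME = "scipy-highs"


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    x: np.ndarray | None
    objective: float | None
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_lp(
    cost,
    A_ub=None,
    b_ub=None,
    A_eq=None,
    b_eq=None,
    bounds=None,
    maximize: bool = False,
) -> LPResult:
    """Minimize (or maximize) ``cost @ x`` subject to linear constraints.

    ``bounds`` follows the scipy convention: sequence of (lo, hi) pairs or
    None for free variables (default free, unlike scipy's default of x >= 0).
    """
    cost = np.asarray(cost, dtype=float)
    if bounds is None:
        bounds = [(None, None)] * cost.size
    res = linprog(
        -cost if maximize else cost,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(status=status, x=None, objective=None, message=res.message)
    obj = float(res.fun)
    if maximize:
        obj = -obj
    return LPResult(status="optimal", x=np.asarray(res.x), objective=obj,
                    message=res.message)
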