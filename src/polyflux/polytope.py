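"""Full-dimensional polytope construction from a metabolic model.

The steady-state flux space {v : S v = 0, lb <= v <= ub} is generally not
full-dimensional in flux coordinates.  This module restates it as a
full-dimensional H-polytope {x : A x <= b} in null-space coordinates,
together with the affine map v = N x + shift back to flux space.
Preprocessing tightens bounds with per-reaction LPs (flux variability),
folds near-fixed reactions into the equality system, and strips redundant
facets, mirroring the PolyRound-style pipeline used for flux sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BoundednessError,
    InfeasibleModelError,
    NotFullDimensionalError,
    ValidationError,
)
from .lp import solve_lp
from .model import MetabolicModel

FULL_DIM_RADIUS = 1e-7
DEFAULT_WIDTH_TOL = 1e-7


class HPolytope:
    """Bounded, full-dimensional polytope {x in R^d : A x <= b}.

    Rows of ``A`` are normalized to unit Euclidean norm on construction so
    that slacks ``b - A x`` are geometric distances and billiard reflections
    use unit facet normals.
    """

    def __init__(self, A, b, normalize: bool = True):
        A = np.atleast_2d(np.asarray(A, dtype=float))
        b = np.asarray(b, dtype=float).ravel()
        if A.shape[0] != b.shape[0]:
            raise ValidationError(
                f"A has {A.shape[0]} rows but b has {b.shape[0]} entries")
        if normalize:
            norms = np.linalg.norm(A, axis=1)
            if np.any(norms < 1e-14):
                raise ValidationError("zero row in constraint matrix A")
            A = A / norms[:, None]
            b = b / norms
        self.A = A
        self.b = b

    @property
    def dim(self) -> int:
        return self.A.shape[1]

    @property
    def n_facets(self) -> int:
        return self.A.shape[0]

    def contains(self, X, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask over columns of X (d x n) for membership up to tol."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.dim:
            X = X.T
        return np.all(self.A @ X <= self.b[:, None] + tol, axis=0)

    def slacks(self, x) -> np.ndarray:
        return self.b - self.A @ np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "b": self.b.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "HPolytope":
        return cls(np.asarray(d["A"]), np.asarray(d["b"]), normalize=False)

    def __repr__(self):
        return f"HPolytope(k={self.n_facets}, d={self.dim})"


@dataclass
class AffineMap:
    """Affine map v = N x + shift from polytope coordinates to flux space.

    ``N`` has orthonormal columns spanning the null space of the augmented
    stoichiometric system; ``shift`` is a strictly interior particular
    solution (the v-space Chebyshev center).
    """

    N: np.ndarray
    shift: np.ndarray

    def __post_init__(self):
        self.N = np.atleast_2d(np.asarray(self.N, dtype=float))
        self.shift = np.asarray(self.shift, dtype=float).ravel()
        if self.N.shape[0] != self.shift.shape[0]:
            raise ValidationError("N rows and shift length differ")

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def to_dict(self) -> dict:
        return {"N": self.N.tolist(), "shift": self.shift.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineMap":
        return cls(np.asarray(d["N"]), np.asarray(d["shift"]))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def chebyshev_center(P: HPolytope) -> tuple[np.ndarray, float]:
    """Largest inscribed ball: maximize r s.t. A x + r <= b (unit rows).

    Raises :class:`NotFullDimensionalError` when the radius is below 1e-7
    and :class:`BoundednessError` when the LP is unbounded.
    """
    d = P.dim
    # variables (x, r); rows of A are unit-norm so the ball constraint is A x + r <= b
    cost = np.zeros(d + 1)
    cost[-1] = 1.0
    A_ub = np.hstack([P.A, np.ones((P.n_facets, 1))])
    bounds = [(None, None)] * d + [(0.0, None)]
    res = solve_lp(cost, A_ub=A_ub, b_ub=P.b, bounds=bounds, maximize=True)
    if res.status == "unbounded":
        raise BoundednessError("polytope admits arbitrarily large inscribed balls")
    if not res.optimal:
        raise InfeasibleModelError("polytope is empty", certificate=res.message)
    center, radius = res.x[:d], float(res.objective)
    if radius < FULL_DIM_RADIUS:
        raise NotFullDimensionalError(
            f"Chebyshev radius {radius:.2e} below {FULL_DIM_RADIUS:.0e}")
    return center, radius


def bounding_box(P: HPolytope) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box via 2d LPs; raises on unbounded directions."""
    d = P.dim
    lo = np.empty(d)
    hi = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = 1.0
        for sign, target in ((1.0, hi), (-1.0, lo)):
            res = solve_lp(sign * e, A_ub=P.A, b_ub=P.b, maximize=True)
            if res.status == "unbounded":
                raise BoundednessError(f"polytope unbounded along coordinate {i}")
            if not res.optimal:
                raise InfeasibleModelError("polytope is empty",
                                           certificate=res.message)
            target[i] = sign * res.objective
    return lo, hi


def remove_redundant_facets(P: HPolytope, tol: float = DEFAULT_WIDTH_TOL) -> HPolytope:
    """Drop constraints that never bind, keeping the point set intact.

    Facet i is tested by maximizing A_i x over the other retained facets with
    its own bound relaxed by 1; if the optimum cannot exceed b_i + tol the
    facet is redundant (this also removes exact duplicates one at a time).
    The operation is idempotent.
    """
    A, b = P.A.copy(), P.b.copy()
    keep = np.ones(len(b), dtype=bool)
    for i in range(len(b)):
        keep[i] = False
        rows = keep.copy()
        rows[i] = True  # keep own constraint, relaxed, to avoid unbounded LPs
        b_rel = b[rows].copy()
        # relax the tested facet
        pos = np.where(np.where(rows)[0] == i)[0][0]
        b_rel[pos] += 1.0
        res = solve_lp(A[i], A_ub=A[rows], b_ub=b_rel, maximize=True)
        if res.optimal and res.objective <= b[i] + tol:
            continue  # redundant, stays dropped
        keep[i] = True
    return HPolytope(A[keep], b[keep], normalize=False)


def tighten_bounds(
    model: MetabolicModel, tol: float = DEFAULT_WIDTH_TOL
) -> tuple[MetabolicModel, list[int]]:
    """Shrink flux bounds to their feasible range and detect fixed reactions.

    For every reaction the min and max flux over {S v = 0, lb <= v <= ub}
    is computed by LP; bounds are replaced by that range.  Reactions whose
    range is narrower than ``tol`` are pinned to the interval midpoint and
    returned as the fixed set (they become implicit equalities downstream).
    """
    n = model.n_reactions
    vb = list(zip(model.lb, model.ub))
    A_eq = model.S if model.n_metabolites else None
    b_eq = np.zeros(model.n_metabolites) if model.n_metabolites else None
    lo = np.empty(n)
    hi = np.empty(n)
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        r_min = solve_lp(e, A_eq=A_eq, b_eq=b_eq, bounds=vb)
        r_max = solve_lp(e, A_eq=A_eq, b_eq=b_eq, bounds=vb, maximize=True)
        if not (r_min.optimal and r_max.optimal):
            raise InfeasibleModelError(
                f"steady-state set empty while bounding reaction "
                f"{model.reaction_ids[j]}",
                certificate=r_min.message or r_max.message,
            )
        lo[j], hi[j] = r_min.objective, r_max.objective
    # guard against LP round-off inverting tiny intervals
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    fixed = [j for j in range(n) if hi[j] - lo[j] < tol]
    for j in fixed:
        mid = 0.5 * (lo[j] + hi[j])
        lo[j] = hi[j] = mid
    out = model.copy()
    out.lb, out.ub = lo, hi
    return out, fixed


def _numerical_rank(M: np.ndarray) -> tuple[int, np.ndarray]:
    """Rank and orthonormal null-space basis via SVD with the standard cutoff."""
    if M.shape[0] == 0:
        n = M.shape[1]
        return 0, np.eye(n)
    u, s, vt = np.linalg.svd(M, full_matrices=True)
    cutoff = (s[0] if s.size else 0.0) * max(M.shape) * 1e-12
    rank = int(np.sum(s > cutoff))
    return rank, vt[rank:].T


def build_polytope(
    model: MetabolicModel, tol: float = DEFAULT_WIDTH_TOL
) -> tuple[HPolytope, AffineMap]:
    """Preprocess a model into a full-dimensional H-polytope + flux map.

    Steps: feasibility check, per-reaction bound tightening, folding of
    fixed reactions into the equality system S_aug, null-space projection
    (d = n - rank(S_aug)), interior particular solution via a v-space
    Chebyshev LP, and redundant-facet removal.  Every x with A x <= b maps
    to a flux vector v = N x + shift with S v ~ 0 and lb <= v <= ub.
    """
    tightened, fixed = tighten_bounds(model, tol=tol)
    n = model.n_reactions

    rows = [model.S] if model.n_metabolites else []
    rhs = [np.zeros(model.n_metabolites)] if model.n_metabolites else []
    for j in fixed:
        e = np.zeros(n)
        e[j] = 1.0
        rows.append(e[None, :])
        rhs.append(np.array([tightened.lb[j]]))
    if rows:
        S_aug = np.vstack(rows)
        rhs = np.concatenate(rhs)
    else:
        S_aug = np.zeros((0, n))
        rhs = np.zeros(0)

    rank, N = _numerical_rank(S_aug)
    d = n - rank
    if d == 0:
        raise NotFullDimensionalError(
            "all fluxes are fixed; the steady-state set is a single point")

    shift = _interior_particular_solution(tightened, S_aug, rhs, fixed)

    free = [j for j in range(n) if j not in set(fixed)]
    A0 = np.vstack([N[free, :], -N[free, :]])
    b0 = np.concatenate(
        [tightened.ub[free] - shift[free], shift[free] - tightened.lb[free]]
    )
    norms = np.linalg.norm(A0, axis=1)
    nz = norms > 1e-12
    P = HPolytope(A0[nz], b0[nz])
    P = remove_redundant_facets(P, tol=tol)
    chebyshev_center(P)  # raises if flat or empty
    return P, AffineMap(N=N, shift=shift)


def _interior_particular_solution(model, S_aug, rhs, fixed) -> np.ndarray:
    """Chebyshev-style LP in v-space: push v away from its free bounds."""
    n = model.n_reactions
    fixed_set = set(fixed)
    cost = np.zeros(n + 1)
    cost[-1] = 1.0
    rows_ub, b_ub = [], []
    for j in range(n):
        if j in fixed_set:
            continue
        e = np.zeros(n + 1)
        e[j], e[-1] = 1.0, 1.0
        rows_ub.append(e)
        b_ub.append(model.ub[j])
        e2 = np.zeros(n + 1)
        e2[j], e2[-1] = -1.0, 1.0
        rows_ub.append(e2)
        b_ub.append(-model.lb[j])
    has_eq = S_aug.shape[0] > 0
    A_eq = np.hstack([S_aug, np.zeros((S_aug.shape[0], 1))]) if has_eq else None
    res = solve_lp(
        cost,
        A_ub=np.asarray(rows_ub) if rows_ub else None,
        b_ub=np.asarray(b_ub) if b_ub else None,
        A_eq=A_eq,
        b_eq=rhs if has_eq else None,
        bounds=[(lo, hi) for lo, hi in zip(model.lb, model.ub)] + [(0, None)],
        maximize=True,
    )
    if not res.optimal:
        raise InfeasibleModelError("steady-state set is empty",
                                   certificate=res.message)
    shift = res.x[:n]
    if S_aug.shape[0]:
        # project onto the equality set exactly (solver tolerance cleanup)
        correction, *_ = np.linalg.lstsq(S_aug, S_aug @ shift - rhs, rcond=None)
        shift = shift - correction
    return shift


def map_to_fluxes(X: np.ndarray, T: AffineMap) -> np.ndarray:
    """Map d x n sample columns to flux space: each column v = N x + shift."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != T.dim:
        raise ValidationError(
            f"sample rows ({X.shape[0]}) do not match map dimension ({T.dim})")
    return T.N @ X + T.shift[:, None]
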