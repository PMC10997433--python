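"""Geometric random walks for uniform sampling of an H-polytope.

Implemented kernels:

* CDHR / RDHR — hit-and-run along a coordinate axis / a uniform sphere
  direction, with the new point uniform on the resulting chord.
* ball walk — lazy Metropolis move uniform in a ball of radius delta.
* billiard walk — straight trajectory of random exponential length with
  specular reflections off facets; rejected (stay put) when the reflection
  budget is exhausted.
* Dikin walk — Metropolis proposal uniform in the log-barrier Hessian
  ellipsoid, accepted with the determinant ratio that makes the uniform
  distribution stationary.

The "john" and "vaidya" walk names are reserved and raise NotImplementedError.
All randomness flows through one ``numpy.random.Generator`` per chain, so a
chain is a pure function of (polytope, walk, parameters, seed, start).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundednessError, GeometryError, ValidationError
from .polytope import HPolytope, bounding_box, chebyshev_center

FEAS_TOL = 1e-9

WALK_NAMES = ("cdhr", "rdhr", "ball", "billiard", "dikin")
RESERVED_WALKS = ("john", "vaidya")


@dataclass
class WalkState:
    """Current point, RNG and tunables of one chain."""

    x: np.ndarray
    rng: np.random.Generator
    params: dict = field(default_factory=dict)
    # params keys: tau (billiard trajectory scale), R (max reflections),
    # delta (ball-walk radius), dikin_radius


@dataclass
class SampleChain:
    """d x n sample matrix in column (time) order plus provenance."""

    X: np.ndarray
    walk_name: str
    walk_length: int
    seed: int
    phase_id: int = 0

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def dim(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# chord oracle
# ---------------------------------------------------------------------------


def boundary_intersection(P: HPolytope, x, u):
    """Intersection of the line x + t u with the polytope boundary.

    Returns ``(t_minus, t_plus, facet_plus)`` with t_minus < 0 < t_plus and
    facet_plus the index of the facet hit in the +u direction.  Raises
    :class:`BoundednessError` when the chord is unbounded in +u.
    """
    Au = P.A @ u
    slack = np.maximum(P.b - P.A @ x, 0.0)
    pos = Au > 1e-14
    neg = Au < -1e-14
    if not np.any(pos):
        raise BoundednessError("chord is unbounded in the +u direction")
    ratios_plus = slack[pos] / Au[pos]
    i_plus = int(np.argmin(ratios_plus))
    t_plus = float(ratios_plus[i_plus])
    facet_plus = int(np.where(pos)[0][i_plus])
    if np.any(neg):
        t_minus = float(np.max(slack[neg] / Au[neg]))
    else:
        raise BoundednessError("chord is unbounded in the -u direction")
    return t_minus, t_plus, facet_plus


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------


def _unit_sphere(rng: np.random.Generator, d: int) -> np.ndarray:
    u = rng.standard_normal(d)
    return u / np.linalg.norm(u)


def _uniform_ball(rng: np.random.Generator, d: int) -> np.ndarray:
    return _unit_sphere(rng, d) * rng.uniform() ** (1.0 / d)


def cdhr_step(P: HPolytope, state: WalkState) -> WalkState:
    """Coordinate-directions hit-and-run: uniform point on an axis chord."""
    d = P.dim
    i = int(state.rng.integers(d))
    Au = P.A[:, i]
    slack = np.maximum(P.b - P.A @ state.x, 0.0)
    pos = Au > 1e-14
    neg = Au < -1e-14
    if not (np.any(pos) and np.any(neg)):
        raise BoundednessError(f"chord along coordinate {i} is unbounded")
    t_plus = np.min(slack[pos] / Au[pos])
    t_minus = np.max(slack[neg] / Au[neg])
    t = state.rng.uniform(t_minus, t_plus)
    x = state.x.copy()
    x[i] += t
    return WalkState(x=x, rng=state.rng, params=state.params)


def rdhr_step(P: HPolytope, state: WalkState) -> WalkState:
    """Random-directions hit-and-run: uniform point on a sphere-direction chord."""
    u = _unit_sphere(state.rng, P.dim)
    t_minus, t_plus, _ = boundary_intersection(P, state.x, u)
    t = state.rng.uniform(t_minus, t_plus)
    return WalkState(x=state.x + t * u, rng=state.rng, params=state.params)


def ball_walk_step(P: HPolytope, state: WalkState) -> WalkState:
    """Lazy Metropolis ball walk: move iff the proposal stays feasible."""
    delta = state.params["delta"]
    y = state.x + delta * _uniform_ball(state.rng, P.dim)
    if np.all(P.A @ y <= P.b):
        return WalkState(x=y, rng=state.rng, params=state.params)
    return state


def _billiard_trajectory(P: HPolytope, x, u, length, max_reflections):
    """Advance x along u for `length`, reflecting specularly off facets.

    Returns (endpoint, n_reflections) or (None, n) when the reflection budget
    is exhausted.  Rows of A are unit normals, so the reflection is
    u <- u - 2 (u . A_i) A_i at facet i.
    """
    x = x.copy()
    u = u.copy()
    remaining = float(length)
    for refl in range(max_reflections + 1):
        Au = P.A @ u
        slack = np.maximum(P.b - P.A @ x, 0.0)
        # ignore the facet we are sitting on when moving away from it
        pos = Au > 1e-14
        if not np.any(pos):
            raise BoundednessError("billiard trajectory unbounded")
        ratios = np.where(pos, slack / np.where(pos, Au, 1.0), np.inf)
        i_hit = int(np.argmin(ratios))
        t_hit = float(ratios[i_hit])
        if remaining <= t_hit:
            x = x + remaining * u
            if np.max(P.A @ x - P.b) > 1e-8:
                raise GeometryError("billiard trajectory escaped the polytope")
            return x, refl
        x = x + t_hit * u
        remaining -= t_hit
        a = P.A[i_hit]
        u = u - 2.0 * (u @ a) * a
        if np.max(P.A @ x - P.b) > 1e-8:
            raise GeometryError("billiard trajectory escaped the polytope")
    return None, max_reflections


def billiard_step(P: HPolytope, state: WalkState) -> WalkState:
    """Billiard walk step with exponential trajectory length -tau ln(eta)."""
    tau = state.params["tau"]
    R = int(state.params["R"])
    if tau <= 0 or R < 0:
        raise ValidationError("billiard requires tau > 0 and R >= 0")
    u = _unit_sphere(state.rng, P.dim)
    length = -tau * math.log(state.rng.uniform())
    end, _ = _billiard_trajectory(P, state.x, u, length, R)
    if end is None:  # too many reflections: reject, stay at start
        return state
    return WalkState(x=end, rng=state.rng, params=state.params)


def _dikin_hessian(P: HPolytope, x) -> np.ndarray:
    s = P.b - P.A @ x
    if np.any(s <= 0):
        raise GeometryError("Dikin Hessian requested at a non-interior point")
    W = P.A / s[:, None]
    return W.T @ W


def dikin_step(P: HPolytope, state: WalkState) -> WalkState:
    """Dikin walk: uniform proposal in the log-barrier Hessian ellipsoid.

    Proposal y is uniform in {z : (z-x)^T H(x) (z-x) <= r^2}; it is rejected
    outright when x falls outside the same-radius ellipsoid at y, and
    otherwise accepted with probability min(1, sqrt(det H(y) / det H(x))),
    which makes the uniform law stationary.
    """
    r = state.params["dikin_radius"]
    x = state.x
    Hx = _dikin_hessian(P, x)
    Lx = np.linalg.cholesky(Hx)
    w = _uniform_ball(state.rng, P.dim)
    y = x + r * np.linalg.solve(Lx.T, w)
    if np.any(P.b - P.A @ y <= 0):
        return state
    Hy = _dikin_hessian(P, y)
    diff = x - y
    if diff @ Hy @ diff > r * r:
        return state
    Ly = np.linalg.cholesky(Hy)
    # log det H = 2 sum log diag(chol)
    log_ratio = np.sum(np.log(np.diag(Ly))) - np.sum(np.log(np.diag(Lx)))
    if math.log(state.rng.uniform()) <= log_ratio:
        return WalkState(x=y, rng=state.rng, params=state.params)
    return state


_STEP_FUNCTIONS = {
    "cdhr": cdhr_step,
    "rdhr": rdhr_step,
    "ball": ball_walk_step,
    "billiard": billiard_step,
    "dikin": dikin_step,
}


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------


def default_walk_length(walk: str, d: int) -> int:
    """Thinning defaults: 1 for billiard (long trajectories decorrelate),
    ceil(d/2) for the local walks."""
    if walk == "billiard":
        return 1
    return max(1, math.ceil(d / 2))


def default_params(P: HPolytope, walk: str) -> dict:
    """Geometry-derived tunables for each walk on this polytope."""
    d = P.dim
    params: dict = {}
    if walk == "billiard":
        lo, hi = bounding_box(P)
        params["tau"] = float(np.linalg.norm(hi - lo))
        params["R"] = 10 * d
    elif walk == "ball":
        _, r_cheb = chebyshev_center(P)
        params["delta"] = 4.0 * r_cheb / math.sqrt(d)
    elif walk == "dikin":
        params["dikin_radius"] = 0.5
    return params


def sample(
    P: HPolytope,
    walk: str,
    n_target: int,
    walk_length: int | None = None,
    seed: int = 0,
    start: np.ndarray | None = None,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> SampleChain:
    """Run ``walk`` and record every ``walk_length``-th point.

    The chain starts at ``start`` (default: Chebyshev center, strictly
    interior by construction) and is deterministic given
    (polytope, walk, params, seed, start).  An explicit ``rng`` overrides
    ``seed`` so phases of a larger scheme can share one stream.
    """
    if walk in RESERVED_WALKS:
        raise NotImplementedError(
            f"walk {walk!r} is reserved but not implemented")
    if walk not in _STEP_FUNCTIONS:
        raise NotImplementedError(f"unknown walk {walk!r}; "
                                  f"choose from {WALK_NAMES}")
    if n_target < 1:
        raise ValidationError("n_target must be >= 1")
    d = P.dim
    if walk_length is None:
        walk_length = default_walk_length(walk, d)
    full_params = default_params(P, walk)
    if params:
        full_params.update(params)
    if start is None:
        start, _ = chebyshev_center(P)
    start = np.asarray(start, dtype=float).ravel()
    if np.max(P.A @ start - P.b) > FEAS_TOL:
        raise ValidationError("start point is not inside the polytope")
    if rng is None:
        rng = np.random.default_rng(seed)
    step = _STEP_FUNCTIONS[walk]
    state = WalkState(x=start, rng=rng, params=full_params)
    X = np.empty((d, n_target))
    for i in range(n_target):
        for _ in range(walk_length):
            state = step(P, state)
        X[:, i] = state.x
    return SampleChain(X=X, walk_name=walk, walk_length=walk_length, seed=seed)
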