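"""Deterministic toy models and reference polytopes with known properties.

Everything here is generated in code so tests and examples never need a
model download: linear pathway ("chain") models, a branched pathway, and
reference polytopes (cube, simplex, stretched box, random skew) whose exact
uniform-distribution moments are returned alongside the geometry.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .model import MetabolicModel
from .polytope import HPolytope


def make_chain_model(k: int, caps) -> MetabolicModel:
    """Linear pathway M1 -> M2 -> ... with k reactions capped at ``caps``.

    Steady state forces all fluxes equal, so the feasible range of every
    reaction is [0, min(caps)].  The default objective maximizes the last
    (export) flux.
    """
    caps = np.asarray(caps, dtype=float).ravel()
    if k < 1 or caps.shape != (k,):
        raise ValidationError("need k >= 1 and exactly k caps")
    S = np.zeros((k - 1, k))
    for i in range(k - 1):
        S[i, i] = 1.0
        S[i, i + 1] = -1.0
    c = np.zeros(k)
    c[-1] = 1.0
    return MetabolicModel(
        S=S,
        lb=np.zeros(k),
        ub=caps,
        c=c,
        reaction_ids=[f"R{j + 1}" for j in range(k)],
        metabolite_ids=[f"M{i + 1}" for i in range(k - 1)],
    )


def make_branch_model() -> MetabolicModel:
    """Branched pathway A -> B, then B -> C and B -> D (A, C, D external).

    With ub = [10, 4, 3] the flux polytope is two-dimensional:
    {vC in [0, 4], vD in [0, 3], vC + vD <= 10}; the default objective
    maximizes vC + vD (optimum 7).
    """
    S = np.array([[1.0, -1.0, -1.0]])  # metabolite B balance
    return MetabolicModel(
        S=S,
        lb=np.zeros(3),
        ub=np.array([10.0, 4.0, 3.0]),
        c=np.array([0.0, 1.0, 1.0]),
        reaction_ids=["R_AB", "R_BC", "R_BD"],
        metabolite_ids=["B"],
    )


def make_reference_polytope(
    kind: str, d: int, seed: int = 0, stretch: float = 100.0
) -> tuple[HPolytope, dict]:
    """Reference body plus exact moments of its uniform distribution.

    kinds:
      * ``cube`` — [-1, 1]^d; mean 0, covariance (1/3) I.
      * ``simplex`` — {x >= 0, sum x <= 1}; coordinate mean 1/(d+1),
        variance d / ((d+1)^2 (d+2)), pairwise covariance
        -1 / ((d+1)^2 (d+2)).
      * ``stretched_box`` — cube scaled by diag(geomspace(1, stretch, d)).
      * ``random_skew`` — seeded invertible linear image of the cube with
        moments transformed by the affine law.
    """
    if d < 1:
        raise ValidationError("dimension must be >= 1")
    eye = np.eye(d)
    if kind == "cube":
        P = HPolytope(np.vstack([eye, -eye]), np.ones(2 * d))
        return P, {"mean": np.zeros(d), "cov": eye / 3.0}
    if kind == "simplex":
        A = np.vstack([-eye, np.ones((1, d))])
        b = np.concatenate([np.zeros(d), [1.0]])
        P = HPolytope(A, b)
        denom = (d + 1) ** 2 * (d + 2)
        cov = -np.ones((d, d)) / denom
        np.fill_diagonal(cov, d / denom)
        return P, {"mean": np.full(d, 1.0 / (d + 1)), "cov": cov}
    if kind == "stretched_box":
        scales = np.geomspace(1.0, stretch, d)
        # x = diag(scales) z for z in the cube
        A = np.vstack([np.diag(1.0 / scales), -np.diag(1.0 / scales)])
        P = HPolytope(A, np.ones(2 * d))
        return P, {"mean": np.zeros(d), "cov": np.diag(scales**2) / 3.0}
    if kind == "random_skew":
        rng = np.random.default_rng(seed)
        L = rng.standard_normal((d, d)) + 2.0 * np.eye(d)  # well-conditioned
        if abs(np.linalg.det(L)) < 1e-8:
            L = L + np.eye(d)
        Linv = np.linalg.inv(L)
        A = np.vstack([Linv, -Linv])
        P = HPolytope(A, np.ones(2 * d))
        return P, {"mean": np.zeros(d), "cov": L @ L.T / 3.0}
    raise ValidationError(f"unknown reference polytope kind: {kind!r}")
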