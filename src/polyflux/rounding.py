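"""Rounding transforms and the two headline sampling regimes.

Skewed flux polytopes mix poorly; both regimes first bring the body to
near-isotropic position with an affine map estimated from pilot samples
(covariance whitening), then sample until the ESS/PSRF gates pass:

* :func:`mmcs` — multiphase Monte Carlo sampling: rounding and sampling are
  unified in one pass; early phases refine the transform, later phases
  accumulate the returned chain.
* :func:`bwr` — billiard walk with rounding: rounding runs as a separate
  preprocessing step (:func:`round_by_covariance`), then billiard batches.

Samples are always returned in the original polytope coordinates.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass

import numpy as np

from .diagnostics import (
    DEFAULT_ESS_GATE,
    DEFAULT_PSRF_GATE,
    DiagnosticsReport,
    evaluate_gates,
)
from .errors import ConvergenceError, ValidationError
from .polytope import HPolytope, chebyshev_center
from .walks import SampleChain, default_params, sample

ROUNDNESS_THRESHOLD = 3.0
MAX_ROUNDING_PHASES = 20
MAX_MMCS_PHASES = 100
#: Samples per accumulation batch are capped so absurd gate requests cannot
#: exhaust memory before the time budget fires.
MAX_BATCH = 50_000


@dataclass
class RoundingTransform:
    """Invertible affine map x = L y + t from rounded to original coordinates."""

    L: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        self.t = np.asarray(self.t, dtype=float).ravel()

    def apply(self, Y: np.ndarray) -> np.ndarray:
        """Map d x n rounded-coordinate columns back to original coordinates."""
        return self.L @ Y + self.t[:, None]

    def compose(self, L2: np.ndarray, t2: np.ndarray) -> "RoundingTransform":
        """Append an inner map y = L2 z + t2: x = (L L2) z + (L t2 + t)."""
        return RoundingTransform(L=self.L @ L2, t=self.L @ t2 + self.t)

    @classmethod
    def identity(cls, d: int) -> "RoundingTransform":
        return cls(L=np.eye(d), t=np.zeros(d))

    def to_dict(self) -> dict:
        return {"L": self.L.tolist(), "t": self.t.tolist()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class PhaseReport:
    phase_id: int
    n_samples: int
    covariance_condition: float
    terminated: bool

    def to_dict(self) -> dict:
        return {
            "phase_id": self.phase_id,
            "n_samples": self.n_samples,
            "covariance_condition": self.covariance_condition,
            "terminated": self.terminated,
        }


def _covariance_condition(C: np.ndarray) -> float:
    s = np.linalg.svd(C, compute_uv=False)
    if s[-1] <= 0:
        return float("inf")
    return float(s[0] / s[-1])


def _whitening_map(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Symmetric square root of the sample covariance and the sample mean.

    Returns (L_phase, mean, condition) where applying y = L^-1 (x - mean)
    makes the sample covariance approximately the identity.
    """
    mean = X.mean(axis=1)
    C = np.cov(X)
    C = np.atleast_2d(C)
    cond = _covariance_condition(C)
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, 1e-300)
    L = (V * np.sqrt(w)) @ V.T
    return L, mean, cond


def _transform_polytope(P: HPolytope, L: np.ndarray, t: np.ndarray) -> HPolytope:
    """Polytope in new coordinates z with x = L z + t (rows re-normalized)."""
    return HPolytope(P.A @ L, P.b - P.A @ t)


def _pilot_size(d: int) -> int:
    return max(500, 20 * d)


def round_by_covariance(
    P: HPolytope,
    walk: str = "billiard",
    n_pilot: int | None = None,
    seed: int = 0,
    target_condition: float = ROUNDNESS_THRESHOLD,
    max_phases: int = MAX_ROUNDING_PHASES,
) -> tuple[HPolytope, RoundingTransform, list[PhaseReport]]:
    """Iterate pilot-sample / whiten until the sample covariance is round.

    Terminates when the ratio of extreme singular values of the pilot
    covariance drops to ``target_condition`` (default 3) and returns the
    transformed polytope, the composed transform and per-phase reports.
    """
    d = P.dim
    if n_pilot is None:
        n_pilot = _pilot_size(d)
    rng = np.random.default_rng(seed)
    transform = RoundingTransform.identity(d)
    reports: list[PhaseReport] = []
    P_cur = P
    start = None
    last_cond = float("inf")
    for phase in range(max_phases):
        chain = sample(P_cur, walk, n_pilot, seed=seed, start=start, rng=rng)
        L, mean, cond = _whitening_map(chain.X)
        last_cond = cond
        done = cond <= target_condition
        reports.append(PhaseReport(phase, n_pilot, cond, done))
        if done:
            return P_cur, transform, reports
        P_cur = _transform_polytope(P_cur, L, mean)
        transform = transform.compose(L, mean)
        # continue the chain from the last point, expressed in new coordinates
        start = np.linalg.solve(L, chain.X[:, -1] - mean)
    raise ConvergenceError(
        f"rounding did not reach condition {target_condition} in "
        f"{max_phases} phases (last condition {last_cond:.3g})",
        payload={"reports": reports},
    )


def _billiard_tau_from_cov(C: np.ndarray) -> float:
    lam = float(np.linalg.eigvalsh(np.atleast_2d(C))[-1])
    return 6.0 * math.sqrt(max(lam, 1e-300))


def mmcs(
    P: HPolytope,
    ess_target: int = DEFAULT_ESS_GATE,
    psrf_limit: float = DEFAULT_PSRF_GATE,
    walk: str = "billiard",
    seed: int = 0,
    target_condition: float = ROUNDNESS_THRESHOLD,
    max_phases: int = MAX_MMCS_PHASES,
    budget_seconds: float | None = None,
) -> tuple[SampleChain, RoundingTransform, list[PhaseReport], DiagnosticsReport]:
    """Multiphase Monte Carlo sampling: round and sample in one pass.

    Early phases draw pilot samples and refine the whitening transform while
    the sample-covariance condition number exceeds ``target_condition``;
    those samples are discarded (they follow a changing kernel).  Once the
    geometry is round the transform is frozen and batches of ``ess_target``
    samples accumulate until min-coordinate ESS >= ess_target and
    max-coordinate PSRF <= psrf_limit, re-checkable by an independent
    diagnostics pass on the returned chain.
    """
    if ess_target < 1:
        raise ValidationError("ess_target must be >= 1")
    if psrf_limit <= 1.0:
        raise ValidationError("psrf_limit must exceed 1")
    d = P.dim
    t0 = time.monotonic()
    rng = np.random.default_rng(seed)
    transform = RoundingTransform.identity(d)
    reports: list[PhaseReport] = []
    P_cur = P
    start = None
    tau = None
    rounded = False
    batches: list[np.ndarray] = []
    diag = None
    for phase in range(max_phases):
        n_phase = min(ess_target, MAX_BATCH) if rounded else _pilot_size(d)
        params = {"tau": tau} if (tau is not None and walk == "billiard") else None
        chain = sample(P_cur, walk, n_phase, seed=seed, start=start,
                       params=params, rng=rng)
        C = np.atleast_2d(np.cov(chain.X))
        cond = _covariance_condition(C)
        start = chain.X[:, -1]
        if walk == "billiard":
            tau = _billiard_tau_from_cov(C)
        if not rounded:
            if cond > target_condition:
                L, mean, _ = _whitening_map(chain.X)
                P_cur = _transform_polytope(P_cur, L, mean)
                transform = transform.compose(L, mean)
                start = np.linalg.solve(L, start - mean)
                tau = None  # geometry changed; re-derive the trajectory scale
                reports.append(PhaseReport(phase, n_phase, cond, False))
                _check_budget(t0, budget_seconds, reports, diag)
                continue
            rounded = True
        batches.append(transform.apply(chain.X))
        X_all = np.concatenate(batches, axis=1)
        diag = evaluate_gates(X_all, ess_gate=ess_target, psrf_gate=psrf_limit)
        reports.append(PhaseReport(phase, n_phase, cond, diag.passed))
        if diag.passed:
            out = SampleChain(X=X_all, walk_name=f"mmcs:{walk}",
                              walk_length=chain.walk_length, seed=seed)
            return out, transform, reports, diag
        _check_budget(t0, budget_seconds, reports, diag)
    raise ConvergenceError(
        f"MMCS did not meet its gates within {max_phases} phases",
        payload={"reports": reports, "diagnostics": diag},
    )


def bwr(
    P: HPolytope,
    ess_target: int = DEFAULT_ESS_GATE,
    psrf_limit: float = DEFAULT_PSRF_GATE,
    seed: int = 0,
    max_batches: int = MAX_MMCS_PHASES,
    budget_seconds: float | None = None,
) -> tuple[SampleChain, RoundingTransform, DiagnosticsReport]:
    """Billiard walk with rounding: whiten first, then billiard batches.

    Rounding runs as preprocessing (:func:`round_by_covariance`), then
    billiard samples accumulate in batches of ``ess_target`` until both
    diagnostic gates pass; the chain is returned in original coordinates.
    """
    if ess_target < 1:
        raise ValidationError("ess_target must be >= 1")
    if psrf_limit <= 1.0:
        raise ValidationError("psrf_limit must exceed 1")
    t0 = time.monotonic()
    P_round, transform, phase_reports = round_by_covariance(
        P, walk="billiard", seed=seed)
    rng = np.random.default_rng(seed)
    start, _ = chebyshev_center(P_round)
    tau = None
    batches: list[np.ndarray] = []
    diag = None
    for _ in range(max_batches):
        params = {"tau": tau} if tau is not None else None
        chain = sample(P_round, "billiard", min(ess_target, MAX_BATCH),
                       seed=seed, start=start, params=params, rng=rng)
        start = chain.X[:, -1]
        tau = _billiard_tau_from_cov(np.cov(chain.X))
        batches.append(transform.apply(chain.X))
        X_all = np.concatenate(batches, axis=1)
        diag = evaluate_gates(X_all, ess_gate=ess_target, psrf_gate=psrf_limit)
        if diag.passed:
            out = SampleChain(X=X_all, walk_name="bwr", walk_length=1, seed=seed)
            return out, transform, diag
        _check_budget(t0, budget_seconds, None, diag)
    raise ConvergenceError(
        f"BWR did not meet its gates within {max_batches} batches",
        payload={"diagnostics": diag},
    )


def _check_budget(t0, budget_seconds, reports, diag):
    if budget_seconds is not None and time.monotonic() - t0 > budget_seconds:
        raise ConvergenceError(
            f"time budget of {budget_seconds} s exhausted before the "
            "diagnostic gates passed",
            payload={"reports": reports, "diagnostics": diag},
        )
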