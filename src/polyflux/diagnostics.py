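"""MCMC sample-quality diagnostics: effective sample size and split-chain PSRF.

A returned flux sample is only trusted when both gates hold for every
coordinate: minimum ESS at least ``ess_gate`` (default 1000) and maximum
potential scale reduction factor at most ``psrf_gate`` (default 1.1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSeriesError, ValidationError

DEFAULT_ESS_GATE = 1000
DEFAULT_PSRF_GATE = 1.1


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance function via FFT (lag 0 .. n-1)."""
    n = x.size
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    return acov / n


def ess(series) -> float:
    """Single-chain effective sample size, n / (1 + 2 sum rho_t).

    The autocorrelation sum is truncated by Geyer's initial monotone
    positive sequence: consecutive lag pairs Gamma_k = rho_{2k} + rho_{2k+1}
    are kept while positive and forced non-increasing.  The estimate is
    capped at 2n to bound antithetic chains.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValidationError(f"need at least 10 points for ESS, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series has no ESS")
    acov = _autocovariance(x)
    if acov[0] <= 0 or not np.isfinite(acov[0]):
        raise DegenerateSeriesError("constant series has no ESS")
    rho = acov / acov[0]
    # pair sums of consecutive lags, starting at (rho_0 + rho_1)
    n_pairs = n // 2
    gamma = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    tau = 0.0
    prev = np.inf
    for g in gamma:
        if g <= 0:
            break
        g = min(g, prev)  # enforce monotone non-increasing
        tau += g
        prev = g
    iat = max(2.0 * tau - 1.0, 1e-12)  # 1 + 2 sum_{t>=1} rho_t
    return float(min(n / iat, 2.0 * n))


def psrf(series) -> float:
    """Split-chain Gelman-Rubin R-hat of a single series.

    The series is split into two halves of length h (one leading element is
    dropped when the length is odd) and

        R-hat = sqrt( ((h-1)/h * W + B/h) / W ),

    with W the mean within-half variance and B = h * variance of the two
    half-means.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 20:
        raise ValidationError(f"need at least 20 points for PSRF, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("zero within-half variance")
    if x.size % 2 == 1:
        x = x[1:]
    h = x.size // 2
    halves = x.reshape(2, h)
    W = float(np.mean(np.var(halves, axis=1, ddof=1)))
    if W <= 0 or not np.isfinite(W):
        raise DegenerateSeriesError("zero within-half variance")
    B = h * float(np.var(np.mean(halves, axis=1), ddof=1))
    var_hat = (h - 1) / h * W + B / h
    return float(np.sqrt(var_hat / W))


@dataclass
class DiagnosticsReport:
    """Per-coordinate ESS/PSRF with pass/fail against the gates."""

    ess_per_coord: np.ndarray
    psrf_per_coord: np.ndarray
    ess_gate: int
    psrf_gate: float
    excluded_coords: list[int] = field(default_factory=list)

    @property
    def min_ess(self) -> float:
        return float(np.min(self.ess_per_coord))

    @property
    def max_psrf(self) -> float:
        return float(np.max(self.psrf_per_coord))

    @property
    def passed(self) -> bool:
        return self.min_ess >= self.ess_gate and self.max_psrf <= self.psrf_gate

    def to_dict(self) -> dict:
        return {
            "ess_per_coord": self.ess_per_coord.tolist(),
            "psrf_per_coord": self.psrf_per_coord.tolist(),
            "min_ess": self.min_ess,
            "max_psrf": self.max_psrf,
            "ess_gate": self.ess_gate,
            "psrf_gate": self.psrf_gate,
            "excluded_coords": self.excluded_coords,
            "passed": self.passed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate_gates(
    X,
    ess_gate: int = DEFAULT_ESS_GATE,
    psrf_gate: float = DEFAULT_PSRF_GATE,
) -> DiagnosticsReport:
    """Apply ESS and PSRF per coordinate of a d x n sample matrix.

    Accepts a SampleChain or a bare matrix.  Zero-variance coordinates are
    excluded from gating and listed in the report (fixed fluxes should have
    been removed during preprocessing).
    """
    X = getattr(X, "X", X)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d, n = X.shape
    if n < 20:
        raise ValidationError(f"need at least 20 samples to evaluate gates, got {n}")
    ess_vals, psrf_vals, excluded = [], [], []
    for i in range(d):
        row = X[i]
        if np.ptp(row) == 0:
            excluded.append(i)
            continue
        ess_vals.append(ess(row))
        psrf_vals.append(psrf(row))
    if not ess_vals:
        raise DegenerateSeriesError("all coordinates have zero variance")
    return DiagnosticsReport(
        ess_per_coord=np.asarray(ess_vals),
        psrf_per_coord=np.asarray(psrf_vals),
        ess_gate=ess_gate,
        psrf_gate=psrf_gate,
        excluded_coords=excluded,
    )
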