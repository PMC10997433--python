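"""Empirical bivariate copulas between reaction fluxes.

The copula of two flux series is the joint distribution of their
rank-transformed values; it isolates the dependence structure from the
marginals and is the screening tool for flux coupling in sampled models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateSeriesError, ValidationError


@dataclass
class CopulaGrid:
    """m x m grid of probability mass with uniform marginals by construction."""

    M: np.ndarray
    reaction_pair: tuple[str, str]
    m: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def compute_copula(
    flux_i,
    flux_j,
    m: int = 10,
    reaction_pair: tuple[str, str] = ("i", "j"),
) -> CopulaGrid:
    """Empirical copula on an m x m grid from two flux series.

    Each series is converted to normalized ranks (rank - 0.5)/n in (0, 1)
    (average ranks on ties); cell (a, b) holds the fraction of points whose
    rank pair falls in ((a-1)/m, a/m] x ((b-1)/m, b/m].  Row and column sums
    are 1/m up to discretization, i.e. the marginals are uniform.
    """
    if m < 2:
        raise ValidationError(f"grid resolution m must be >= 2, got {m}")
    x = np.asarray(flux_i, dtype=float).ravel()
    y = np.asarray(flux_j, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("flux series have different lengths")
    n = x.size
    if n < m:
        raise ValidationError(f"need at least m={m} points, got {n}")
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise DegenerateSeriesError("constant flux series has no copula")
    u = (rankdata(x, method="average") - 0.5) / n
    v = (rankdata(y, method="average") - 0.5) / n
    a = np.minimum((u * m).astype(int), m - 1)
    b = np.minimum((v * m).astype(int), m - 1)
    M = np.zeros((m, m))
    np.add.at(M, (a, b), 1.0)
    M /= n
    return CopulaGrid(M=M, reaction_pair=tuple(reaction_pair), m=m)


def dependence_indicator(G: CopulaGrid, band: int = 1) -> float:
    """Ratio of copula mass near the diagonal to mass near the anti-diagonal.

    Values > 1 indicate positive flux dependence, < 1 negative dependence,
    and ~1 independence.  Returns ``inf`` (sentinel) when the anti-diagonal
    band carries no mass, as for perfectly comonotone fluxes.
    """
    m = G.m
    if not 0 <= band < m:
        raise ValidationError(f"band must lie in [0, {m - 1}], got {band}")
    a, b = np.indices((m, m))
    diag_mass = float(G.M[np.abs(a - b) <= band].sum())
    anti_mass = float(G.M[np.abs(a + b - (m - 1)) <= band].sum())
    if anti_mass <= 0.0:
        return float("inf")
    return diag_mass / anti_mass
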