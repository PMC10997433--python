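"""Constraint-based metabolic model container.

A metabolic network at steady state is described by a stoichiometric matrix
``S`` (metabolites x reactions), flux bounds ``lb <= v <= ub`` and a linear
objective ``c``.  The steady-state flux space is the polytope

    {v : S v = 0, lb <= v <= ub},

where the production rate of every metabolite balances its consumption.
Fluxes are conventionally in mmol / gDW / h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds and a linear objective.

    Parameters
    ----------
    S : (m, n) ndarray
        Stoichiometric coefficients; rows are metabolites, columns reactions.
    lb, ub : (n,) ndarray
        Lower / upper flux bounds. ``lb[j] == ub[j]`` encodes a fixed flux.
    c : (n,) ndarray
        Objective coefficients (maximization is canonical).
    reaction_ids, metabolite_ids : list of str
        Unique identifiers aligned with columns / rows of ``S``.
    objective_negated : bool
        True when a declared "minimize" objective was negated on read so that
        maximization stays canonical.
    """

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    objective_negated: bool = field(default=False)

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.S.size == 0:
            self.S = self.S.reshape(0, len(self.reaction_ids))
        self.lb = np.asarray(self.lb, dtype=float).ravel()
        self.ub = np.asarray(self.ub, dtype=float).ravel()
        self.c = np.asarray(self.c, dtype=float).ravel()
        self.reaction_ids = list(self.reaction_ids)
        self.metabolite_ids = list(self.metabolite_ids)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        m, n = self.S.shape
        if n == 0:
            raise ValidationError("model has no reactions")
        for name, vec in (("lb", self.lb), ("ub", self.ub), ("c", self.c)):
            if vec.shape != (n,):
                raise ValidationError(
                    f"{name} has length {vec.shape[0]}, expected {n}"
                )
        if len(self.reaction_ids) != n:
            raise ValidationError("reaction_ids do not align with S columns")
        if len(self.metabolite_ids) != m:
            raise ValidationError("metabolite_ids do not align with S rows")
        if len(set(self.reaction_ids)) != n:
            dupes = sorted(
                {r for r in self.reaction_ids if self.reaction_ids.count(r) > 1}
            )
            raise ValidationError(f"duplicate reaction ids: {dupes}")
        if len(set(self.metabolite_ids)) != m:
            raise ValidationError("duplicate metabolite ids")
        if not np.all(np.isfinite(self.S)):
            raise ValidationError("S contains NaN/Inf entries")
        if np.any(np.isnan(self.lb)) or np.any(np.isnan(self.ub)):
            raise ValidationError("bounds contain NaN")
        bad = np.where(self.lb > self.ub)[0]
        if bad.size:
            names = [self.reaction_ids[j] for j in bad]
            raise ValidationError(f"lb > ub for reactions: {names}")

    # -- conveniences ------------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ValidationError(f"unknown reaction id: {rid}") from None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            c=self.c.copy(),
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            objective_negated=self.objective_negated,
        )
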