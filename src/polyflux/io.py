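"""Readers and writers for constraint-based metabolic models.

Three on-disk formats are supported for reading: SBML Level 3 with the FBC
extension (``.xml``), COBRA JSON (``.json``) and the COBRA MATLAB struct
convention (``.mat``).  COBRA JSON is the canonical serialization and the
only write format.

Infinite bounds are clamped to a configurable big-M (default +/-1000, the
COBRA community convention) so the flux polytope is always bounded.
"""

from __future__ import annotations

import json
import os
from typing import Literal

import numpy as np

from .errors import ModelParseError, ValidationError
from .model import MetabolicModel

DEFAULT_BIG_M = 1000.0

_EXT_TO_FORMAT = {".xml": "sbml", ".sbml": "sbml", ".json": "json", ".mat": "mat"}


def _clamp_bounds(lb: np.ndarray, ub: np.ndarray, big_m: float):
    lb = np.asarray(lb, dtype=float).copy()
    ub = np.asarray(ub, dtype=float).copy()
    lb[np.isneginf(lb)] = -big_m
    ub[np.isposinf(ub)] = big_m
    lb = np.clip(lb, -big_m, big_m)
    ub = np.clip(ub, -big_m, big_m)
    return lb, ub


def read_model(
    path: str | os.PathLike,
    format_hint: Literal["sbml", "json", "mat", "auto"] = "auto",
    big_m: float = DEFAULT_BIG_M,
) -> MetabolicModel:
    """Read a metabolic model, auto-detecting the format from the extension.

    Returns a validated :class:`MetabolicModel` with infinite bounds clamped
    to ``+/- big_m`` and the objective taken from the model's declared
    objective (all-zero when none is declared).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt == "auto":
        ext = os.path.splitext(path)[1].lower()
        if ext not in _EXT_TO_FORMAT:
            raise ModelParseError("auto", f"cannot infer format from extension {ext!r}")
        fmt = _EXT_TO_FORMAT[ext]
    if fmt == "json":
        return _read_json(path, big_m)
    if fmt == "sbml":
        return _read_sbml(path, big_m)
    if fmt == "mat":
        return _read_mat(path, big_m)
    raise ModelParseError(str(fmt), "unknown format hint")


def write_model(model: MetabolicModel, path: str | os.PathLike,
                format: Literal["json"] = "json") -> None:
    """Write a model as COBRA JSON (lossless round-trip with read_model)."""
    if format != "json":
        raise ValidationError(f"unsupported write format: {format}")
    model.validate()
    mets = [{"id": mid} for mid in model.metabolite_ids]
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        nz = np.nonzero(col)[0]
        rxns.append(
            {
                "id": rid,
                "metabolites": {model.metabolite_ids[i]: float(col[i]) for i in nz},
                "lower_bound": float(model.lb[j]),
                "upper_bound": float(model.ub[j]),
                "objective_coefficient": float(model.c[j]),
            }
        )
    doc = {"metabolites": mets, "reactions": rxns, "genes": [], "id": "polyflux_model"}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# format-specific readers
# ---------------------------------------------------------------------------


def _read_json(path: str, big_m: float) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelParseError("json", f"not valid JSON: {exc}") from exc
    try:
        met_ids = [m["id"] for m in doc["metabolites"]]
        rxns = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelParseError("json", f"missing COBRA-JSON field: {exc}") from exc
    if len(set(met_ids)) != len(met_ids):
        raise ValidationError("duplicate metabolite ids in JSON model")
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    n = len(rxns)
    rxn_ids = [r["id"] for r in rxns]
    if len(set(rxn_ids)) != n:
        dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        raise ValidationError(f"duplicate reaction ids in JSON model: {dupes}")
    S = np.zeros((len(met_ids), n))
    lb = np.empty(n)
    ub = np.empty(n)
    c = np.zeros(n)
    for j, r in enumerate(rxns):
        for mid, coeff in r.get("metabolites", {}).items():
            if mid not in met_index:
                raise ModelParseError("json", f"reaction {r['id']} references "
                                      f"unknown metabolite {mid}")
            S[met_index[mid], j] = float(coeff)
        lb[j] = float(r.get("lower_bound", -big_m))
        ub[j] = float(r.get("upper_bound", big_m))
        c[j] = float(r.get("objective_coefficient", 0.0))
    lb, ub = _clamp_bounds(lb, ub, big_m)
    return MetabolicModel(S=S, lb=lb, ub=ub, c=c,
                          reaction_ids=rxn_ids, metabolite_ids=met_ids)


def _clip_sbml_id(sid: str, prefix: str) -> str:
    # COBRA convention: SBML ids carry an "R_"/"M_" prefix that tools strip
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: str, big_m: float) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError("sbml", err.getMessage() if err else "unreadable SBML")
    if doc.getLevel() < 3:
        raise ModelParseError(
            "sbml",
            f"SBML Level {doc.getLevel()} not supported; "
            "export the model as Level 3 with the FBC extension",
        )
    sb = doc.getModel()
    if sb is None:
        raise ModelParseError("sbml", "document contains no model")
    fbc = sb.getPlugin("fbc")

    met_ids = []
    boundary = set()
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
        else:
            met_ids.append(sp.getId())
    met_index = {mid: i for i, mid in enumerate(met_ids)}

    # fbc flux bounds live in global Parameter elements referenced by id
    params = {}
    for i in range(sb.getNumParameters()):
        p = sb.getParameter(i)
        params[p.getId()] = p.getValue()

    n = sb.getNumReactions()
    rxn_ids = []
    S = np.zeros((len(met_ids), n))
    lb = np.full(n, -np.inf)
    ub = np.full(n, np.inf)
    for j in range(n):
        rx = sb.getReaction(j)
        rxn_ids.append(rx.getId())
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            sid = ref.getSpecies()
            if sid not in boundary:
                S[met_index[sid], j] -= ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            sid = ref.getSpecies()
            if sid not in boundary:
                S[met_index[sid], j] += ref.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is None:
            raise ModelParseError(
                "sbml", f"reaction {rx.getId()} carries no FBC bounds; "
                "only Level 3 + FBC models are supported")
        lb_id, ub_id = rfbc.getLowerFluxBound(), rfbc.getUpperFluxBound()
        if lb_id:
            lb[j] = params.get(lb_id, -np.inf)
        if ub_id:
            ub[j] = params.get(ub_id, np.inf)
    if len(set(rxn_ids)) != n:
        raise ValidationError("duplicate reaction ids in SBML model")

    c = np.zeros(n)
    negated = False
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        sense = obj.getType()  # "maximize" or "minimize"
        rindex = {rid: j for j, rid in enumerate(rxn_ids)}
        for k in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(k)
            c[rindex[fo.getReaction()]] = fo.getCoefficient()
        if sense == "minimize":
            c = -c
            negated = True
    lb, ub = _clamp_bounds(lb, ub, big_m)
    return MetabolicModel(
        S=S, lb=lb, ub=ub, c=c,
        reaction_ids=[_clip_sbml_id(r, "R_") for r in rxn_ids],
        metabolite_ids=[_clip_sbml_id(m, "M_") for m in met_ids],
        objective_negated=negated)


def _read_mat(path: str, big_m: float) -> MetabolicModel:
    from scipy.io import loadmat
    from scipy.sparse import issparse

    try:
        mat = loadmat(path, simplify_cells=False)
    except Exception as exc:  # scipy raises several types for bad files
        raise ModelParseError("mat", f"not a readable MATLAB file: {exc}") from exc
    candidates = [k for k in mat if not k.startswith("__")]
    struct = None
    for key in candidates:
        entry = mat[key]
        if hasattr(entry, "dtype") and entry.dtype.names and "S" in entry.dtype.names:
            struct = entry[0, 0]
            break
    if struct is None:
        raise ValidationError(
            "no COBRA struct (fields S, lb, ub, c, rxns, mets) found in .mat file")
    names = struct.dtype.names
    required = {"S", "lb", "ub", "rxns", "mets"}
    missing = required - set(names)
    if missing:
        raise ValidationError(f"COBRA struct missing fields: {sorted(missing)}")

    S = struct["S"]
    if issparse(S):
        S = S.toarray()
    S = np.asarray(S, dtype=float)
    lb = np.asarray(struct["lb"], dtype=float).ravel()
    ub = np.asarray(struct["ub"], dtype=float).ravel()
    c = (np.asarray(struct["c"], dtype=float).ravel()
         if "c" in names else np.zeros(S.shape[1]))

    def _cellstr(arr):
        out = []
        for item in np.asarray(arr).ravel():
            while isinstance(item, np.ndarray):
                item = item.item() if item.size == 1 else item[0]
            out.append(str(item))
        return out

    rxn_ids = _cellstr(struct["rxns"])
    met_ids = _cellstr(struct["mets"])
    lb, ub = _clamp_bounds(lb, ub, big_m)
    return MetabolicModel(S=S, lb=lb, ub=ub, c=c,
                          reaction_ids=rxn_ids, metabolite_ids=met_ids)
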