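"""Model readers and writers.

Two on-disk formats are supported:

* a versioned JSON dialect (schema documented in ``docs/json-model-schema.md``),
  whose writer is deterministic so that ``write(read(f))`` is byte-stable on
  canonicalized input;
* SBML Level 3 + FBC v2 (bounds as parameters, objective via the FBC
  objective list, GPRs as gene-product associations), through python-libsbml.

Bounds and GPR strings survive a JSON round-trip bit-exactly; the SBML
reader renders gene-product associations back to the canonical
``and``/``or`` infix spelling.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import libsbml

from lipoflux.model import (
    FormatError,
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationError,
    gpr_to_string,
    parse_gpr,
)

__all__ = ["load_model", "save_model", "JSON_SCHEMA_VERSION"]

JSON_SCHEMA_VERSION = 1

_SBML_INF = 1e6  # finite stand-in never used; we write true infinities


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from *path* in ``"json"`` or ``"sbml-fbc"`` format.

    With ``format=None`` the format is inferred from the suffix
    (``.json`` → JSON, ``.xml``/``.sbml`` → SBML-FBC).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"json": "json", ".json": "json", ".xml": "sbml-fbc", ".sbml": "sbml-fbc"}.get(
            suffix
        )
        if format is None:
            raise FormatError(f"cannot infer model format from suffix {suffix!r}")
    if format == "json":
        return _read_json(path)
    if format == "sbml-fbc":
        return _read_sbml(path)
    raise FormatError(f"unknown model format {format!r} (expected 'json' or 'sbml-fbc')")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write *model* to *path* in ``"json"`` or ``"sbml-fbc"`` format."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".json": "json", ".xml": "sbml-fbc", ".sbml": "sbml-fbc"}.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer model format from suffix {suffix!r}")
    if format == "json":
        _write_json(model, path)
    elif format == "sbml-fbc":
        _write_sbml(model, path)
    else:
        raise FormatError(f"unknown model format {format!r} (expected 'json' or 'sbml-fbc')")


# --- JSON dialect ------------------------------------------------------------


def _num(value: float):
    """JSON-safe number: infinities become the strings '-inf'/'inf'."""
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return value


def _denum(value) -> float:
    if isinstance(value, str):
        if value == "inf":
            return math.inf
        if value == "-inf":
            return -math.inf
        raise FormatError(f"invalid numeric bound {value!r}")
    return float(value)


def _read_json(path: Path) -> MetabolicModel:
    try:
        with open(path) as handle:
            doc = json.load(handle)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "reactions" not in doc or "metabolites" not in doc:
        raise FormatError(f"{path}: missing 'metabolites'/'reactions' sections")
    version = doc.get("schema_version", JSON_SCHEMA_VERSION)
    if version != JSON_SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported schema_version {version!r}")
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
            )
            for m in doc["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=_denum(r["lower_bound"]),
                upper_bound=_denum(r["upper_bound"]),
                gpr=r.get("gpr"),
                is_exchange=bool(r.get("is_exchange", False)),
            )
            for r in doc["reactions"]
        ]
    except KeyError as exc:
        raise FormatError(f"{path}: reaction/metabolite entry missing field {exc}") from exc
    return MetabolicModel(
        id=doc.get("id", path.stem),
        metabolites=metabolites,
        reactions=reactions,
        genes=set(doc.get("genes", [])),
        default_objective=doc.get("default_objective"),
    )


def _write_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "default_objective": model.default_objective,
        "genes": sorted(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": _num(r.lower_bound),
                "upper_bound": _num(r.upper_bound),
                "gpr": r.gpr,
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=2)
        handle.write("\n")


# --- SBML Level 3 + FBC v2 ---------------------------------------------------


def _sbml_check(obj, what: str):
    if obj is None:
        raise FormatError(f"libsbml failed while building {what}")
    return obj


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = _sbml_check(doc.createModel(), "model")
    sbml_model.setId(model.id)
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    for comp_id in dict.fromkeys(m.compartment for m in model.metabolites):
        comp = _sbml_check(sbml_model.createCompartment(), f"compartment {comp_id}")
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = _sbml_check(sbml_model.createSpecies(), f"species {met.id}")
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    for gene in sorted(model.genes):
        gp = _sbml_check(fbc.createGeneProduct(), f"gene {gene}")
        gp.setId(gene)
        gp.setLabel(gene)

    # flux bounds are shared constant parameters, one per distinct value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = _sbml_check(sbml_model.createParameter(), f"parameter {pid}")
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = _sbml_check(sbml_model.createReaction(), f"reaction {rxn.id}")
        sr.setId(rxn.id)
        sr.setName(rxn.name)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = sr.createReactant()
            else:
                ref = sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            _set_association(gpa, parse_gpr(rxn.gpr))

    if model.default_objective is not None:
        objective = _sbml_check(fbc.createObjective(), "objective")
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(model.default_objective)
        flux_obj.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise FormatError(f"could not write SBML to {path}")


def _set_association(gpa, ast) -> None:
    if isinstance(ast, str):
        ref = gpa.createGeneProductRef()
        ref.setGeneProduct(ast)
        return
    op, operands = ast
    node = gpa.createAnd() if op == "and" else gpa.createOr()
    for child in operands:
        _append_association(node, child)


def _append_association(parent, ast) -> None:
    if isinstance(ast, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(ast)
        return
    op, operands = ast
    node = parent.createAnd() if op == "and" else parent.createOr()
    for child in operands:
        _append_association(node, child)


def _association_to_ast(assoc):
    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        return ("and", [_association_to_ast(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())])
    if isinstance(assoc, libsbml.FbcOr):
        return ("or", [_association_to_ast(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())])
    raise FormatError(f"unsupported gene association element {type(assoc).__name__}")


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: SBML document contains no model")
    fbc = sbml_model.getPlugin("fbc")

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        formula = None
        sp_fbc = sp.getPlugin("fbc")
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula = sp_fbc.getChemicalFormula()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )

    def parameter_value(pid: str, rxn_id: str) -> float:
        par = sbml_model.getParameter(pid)
        if par is None:
            raise FormatError(f"{path}: reaction {rxn_id!r} cites missing flux bound {pid!r}")
        return par.getValue()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rfbc = sr.getPlugin("fbc")
        if rfbc is None or not rfbc.isSetLowerFluxBound() or not rfbc.isSetUpperFluxBound():
            raise FormatError(f"{path}: reaction {sr.getId()!r} has no FBC flux bounds")
        gpr = None
        if rfbc.isSetGeneProductAssociation():
            ast = _association_to_ast(rfbc.getGeneProductAssociation().getAssociation())
            if ast is not None:
                gpr = gpr_to_string(ast)
        reactions.append(
            Reaction(
                id=sr.getId(),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=parameter_value(rfbc.getLowerFluxBound(), sr.getId()),
                upper_bound=parameter_value(rfbc.getUpperFluxBound(), sr.getId()),
                gpr=gpr,
                is_exchange=len(stoich) == 1,
            )
        )

    genes: set[str] = set()
    default_objective = None
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            genes.add(fbc.getGeneProduct(i).getId())
        objective = fbc.getActiveObjective()
        if objective is not None and objective.getNumFluxObjectives() > 0:
            default_objective = objective.getFluxObjective(0).getReaction()

    try:
        return MetabolicModel(
            id=sbml_model.getId() or path.stem,
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            default_objective=default_objective,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
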