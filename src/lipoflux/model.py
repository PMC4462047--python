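"""Core data model for constraint-based metabolic networks.

A :class:`MetabolicModel` is a list of metabolites and reactions plus the
gene set referenced by gene–protein–reaction (GPR) rules.  Conventions:

* Stoichiometric coefficients are signed: negative = consumed, positive =
  produced, in mol per mol of reaction flux.
* Flux bounds are in mmol·gDW⁻¹·h⁻¹.
* Exchange reactions are written as export (``metabolite → ∅``), so uptake
  is a negative flux and a :class:`MediumSpec` holds non-negative allowed
  uptake magnitudes.
* GPR rules are boolean expressions over gene ids with ``and`` / ``or``
  (case-insensitive) and parentheses: ``and`` models complex subunits
  (all required), ``or`` models isozymes (any suffices).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import sparse

__all__ = [
    "ModelError",
    "FormatError",
    "ValidationError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "stoichiometric_matrix",
    "apply_medium",
    "gene_deletion_reactions",
    "parse_gpr",
    "gpr_genes",
    "evaluate_gpr",
]


class ModelError(Exception):
    """Base class for model construction and I/O errors."""


class FormatError(ModelError):
    """A file could not be parsed in the requested format."""


class ValidationError(ModelError):
    """A model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``compartment`` is a plain label (e.g. ``"c"`` for cytosol, ``"m"`` for
    mitochondrion, ``"e"`` for extracellular); no compartment-specific
    behaviour is attached beyond cofactor-id selection downstream.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry, flux bounds and an optional GPR."""

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str | None = None
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        # normalize away explicit zeros so the invariant "only nonzero
        # coefficients" holds regardless of how the dict was assembled
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items() if c != 0}
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite, "
                f"touches {len(self.stoichiometry)}"
            )
        if self.gpr is not None:
            parse_gpr(self.gpr)  # raises FormatError on bad syntax

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> frozenset[str]:
        """Gene ids referenced by this reaction's GPR (empty if none)."""
        return gpr_genes(parse_gpr(self.gpr)) if self.gpr else frozenset()


@dataclass
class MetabolicModel:
    """A validated constraint-based metabolic network."""

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    default_objective: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        declared = set(met_ids)
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in declared:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
            missing = rxn.genes() - self.genes
            if missing:
                raise ValidationError(
                    f"reaction {rxn.id!r} GPR references genes not in the model: "
                    f"{sorted(missing)}"
                )
        if self.default_objective is not None and self.default_objective not in set(rxn_ids):
            raise ValidationError(
                f"default objective {self.default_objective!r} is not a reaction id"
            )

    # --- convenience lookups -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def metabolite(self, met_id: str) -> Metabolite:
        for met in self.metabolites:
            if met.id == met_id:
                return met
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


class MediumSpec(dict):
    """Map exchange-reaction id → maximum uptake rate (non-negative).

    The magnitude is the allowed import rate in mmol·gDW⁻¹·h⁻¹; under the
    export convention it becomes ``lower_bound = −uptake`` on the exchange.
    """

    def __init__(self, uptakes: Mapping[str, float] | None = None) -> None:
        super().__init__()
        for rxn_id, rate in (uptakes or {}).items():
            rate = float(rate)
            if rate < 0:
                raise ValidationError(f"medium uptake for {rxn_id!r} must be ≥ 0, got {rate}")
            self[rxn_id] = rate


# --- stoichiometric matrix ---------------------------------------------------


def stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """Sparse stoichiometric matrix S (metabolites × reactions).

    ``S[i, j]`` is the coefficient of metabolite ``i`` in reaction ``j``;
    rows and columns follow declaration order, so the matrix is
    deterministic for a given model.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coef)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


# --- medium application ------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: MediumSpec | Mapping[str, float]) -> MetabolicModel:
    """Return a copy of *model* with exchange lower bounds set from *medium*.

    Every exchange reaction gets ``lower_bound = −uptake`` if it appears in
    the medium and ``lower_bound = 0`` (no uptake) otherwise; export
    (upper) bounds are untouched.  The input model is not modified.
    """
    medium = MediumSpec(medium)
    exchange_ids = {r.id for r in model.exchanges()}
    for rxn_id in medium:
        if rxn_id not in exchange_ids:
            raise ValidationError(f"medium entry {rxn_id!r} is not an exchange reaction")
    out = model.copy()
    for rxn in out.reactions:
        if rxn.is_exchange:
            rxn.lower_bound = -medium.get(rxn.id, 0.0)
    return out


# --- GPR parsing and evaluation ----------------------------------------------
#
# Grammar (case-insensitive keywords):
#   expr   := term ("or" term)*
#   term   := factor ("and" factor)*
#   factor := GENE | "(" expr ")"
#
# The AST is nested tuples: ("and", [..]) / ("or", [..]) / "gene_id".

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        match = _GPR_TOKEN.match(text, pos)
        if match is None:
            break
        tokens.append(match.group(1))
        pos = match.end()
    return tokens


def parse_gpr(text: str):
    """Parse a GPR string into an AST; raise :class:`FormatError` on bad syntax."""
    tokens = _tokenize_gpr(text)
    if not tokens:
        raise FormatError(f"empty GPR expression: {text!r}")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_factor():
        tok = peek()
        if tok is None:
            raise FormatError(f"GPR ended unexpectedly: {text!r}")
        if tok == "(":
            advance()
            node = parse_expr()
            if peek() != ")":
                raise FormatError(f"unbalanced parentheses in GPR: {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise FormatError(f"unexpected token {tok!r} in GPR: {text!r}")
        return advance()

    def parse_term():
        operands = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            advance()
            operands.append(parse_factor())
        return operands[0] if len(operands) == 1 else ("and", operands)

    def parse_expr():
        operands = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            advance()
            operands.append(parse_term())
        return operands[0] if len(operands) == 1 else ("or", operands)

    ast = parse_expr()
    if pos != len(tokens):
        raise FormatError(f"trailing tokens in GPR: {text!r}")
    return ast


def gpr_genes(ast) -> frozenset[str]:
    """All gene ids appearing in a parsed GPR."""
    if isinstance(ast, str):
        return frozenset([ast])
    _, operands = ast
    out: set[str] = set()
    for op in operands:
        out |= gpr_genes(op)
    return frozenset(out)


def evaluate_gpr(ast, present: Mapping[str, bool]) -> bool:
    """Evaluate a parsed GPR with ``present[gene] = False`` for deleted genes.

    Genes missing from *present* are treated as present.
    """
    if isinstance(ast, str):
        return bool(present.get(ast, True))
    op, operands = ast
    values = (evaluate_gpr(child, present) for child in operands)
    return all(values) if op == "and" else any(values)


def gpr_to_string(ast) -> str:
    """Canonical infix rendering of a GPR AST (used by the SBML reader)."""
    if isinstance(ast, str):
        return ast
    op, operands = ast
    parts = []
    for child in operands:
        text = gpr_to_string(child)
        if not isinstance(child, str) and child[0] != op:
            text = f"({text})"
        parts.append(text)
    return f" {op} ".join(parts)


def gene_deletion_reactions(model: MetabolicModel, genes: Iterable[str]) -> set[str]:
    """Reaction ids disabled when *genes* are deleted.

    A reaction is disabled iff its GPR evaluates false with the deleted
    genes set false and all other genes true.  Reactions without a GPR are
    never disabled.  Deleting the empty set disables nothing; deleting a
    superset of genes disables a superset of reactions (monotonicity).
    """
    deleted = set(genes)
    unknown = deleted - model.genes
    if unknown:
        raise ValidationError(f"unknown gene ids in deletion set: {sorted(unknown)}")
    present = {g: g not in deleted for g in model.genes}
    disabled = set()
    for rxn in model.reactions:
        if rxn.gpr is not None and not evaluate_gpr(parse_gpr(rxn.gpr), present):
            disabled.add(rxn.id)
    return disabled
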