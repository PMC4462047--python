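"""NADPH (or any cofactor) producer/consumer accounting.

Two complementary views of cofactor balance:

* a *structural* partition of reactions into anabolic (can produce the
  cofactor), catabolic (can consume it) and ambiguous-reversible (could do
  either depending on direction), based on stoichiometry and bounds alone;
* a *flux* report ranking realized producers and consumers under one
  solved flux distribution, where a reversible reaction is assigned to a
  side by its realized direction.

At steady state the cofactor row of S·v = 0 forces total production to
equal total consumption, which the report checks and exposes.
"""

from __future__ import annotations

from dataclasses import dataclass

from lipoflux.flux import FluxDistribution
from lipoflux.model import MetabolicModel, ValidationError

__all__ = ["CofactorReport", "classify_cofactor_reactions", "cofactor_flux_report"]

RATE_TOL = 1e-9  # rates below this are numerical noise and omitted


@dataclass
class CofactorReport:
    """Ranked cofactor producers and consumers under one flux state.

    ``producers``/``consumers`` are lists of ``(reaction_id, rate, share)``
    with rate = Σ coefficient × flux over the cofactor ids (always positive
    on its own side; consumer rates are magnitudes) and share the fraction
    of that side's total.  Sorted by |rate| descending, ties by reaction id.
    """

    cofactor_ids: frozenset[str]
    producers: list[tuple[str, float, float]]
    consumers: list[tuple[str, float, float]]
    total_production: float
    total_consumption: float

    @property
    def balance_gap(self) -> float:
        return abs(self.total_production - self.total_consumption)


def _cofactor_coefficient(rxn, cofactor_ids: frozenset[str]) -> float:
    return sum(rxn.stoichiometry.get(m, 0.0) for m in cofactor_ids)


def _check_cofactors(model: MetabolicModel, cofactor_ids) -> frozenset[str]:
    cofactor_ids = frozenset(cofactor_ids)
    missing = cofactor_ids - set(model.metabolite_ids)
    if missing:
        raise ValidationError(f"cofactor ids not in model: {sorted(missing)}")
    return cofactor_ids


def classify_cofactor_reactions(
    model: MetabolicModel, cofactor_ids
) -> dict[str, list[str]]:
    """Structural partition {anabolic, catabolic, ambiguous_reversible}.

    A reaction whose net cofactor coefficient is positive in its feasible
    flux direction is anabolic (a potential producer), negative catabolic;
    reversible reactions with nonzero coefficient are ambiguous.  Reverse-
    only reactions (ub ≤ 0) are classified with the sign flipped.
    """
    cofactor_ids = _check_cofactors(model, cofactor_ids)
    out: dict[str, list[str]] = {"anabolic": [], "catabolic": [], "ambiguous_reversible": []}
    for rxn in model.reactions:
        coef = _cofactor_coefficient(rxn, cofactor_ids)
        if coef == 0:
            continue
        if rxn.lower_bound < 0 < rxn.upper_bound:
            out["ambiguous_reversible"].append(rxn.id)
            continue
        if rxn.upper_bound <= 0:  # can only run in reverse
            coef = -coef
        if rxn.lower_bound == rxn.upper_bound == 0:
            continue  # permanently blocked
        out["anabolic" if coef > 0 else "catabolic"].append(rxn.id)
    return out


def cofactor_flux_report(
    model: MetabolicModel,
    flux: FluxDistribution,
    cofactor_ids,
    rate_tol: float = RATE_TOL,
) -> CofactorReport:
    """Rank realized cofactor producers and consumers under *flux*."""
    cofactor_ids = _check_cofactors(model, cofactor_ids)
    if flux.status != "optimal":
        raise ValidationError(f"flux distribution status is {flux.status!r}, need optimal")
    producers = []
    consumers = []
    for rxn in model.reactions:
        coef = _cofactor_coefficient(rxn, cofactor_ids)
        if coef == 0:
            continue
        rate = coef * flux.fluxes[rxn.id]
        if rate > rate_tol:
            producers.append((rxn.id, rate))
        elif rate < -rate_tol:
            consumers.append((rxn.id, -rate))
    total_prod = sum(r for _, r in producers)
    total_cons = sum(r for _, r in consumers)
    key = lambda item: (-item[1], item[0])  # |rate| descending, then id
    producers.sort(key=key)
    consumers.sort(key=key)
    return CofactorReport(
        cofactor_ids=cofactor_ids,
        producers=[(rid, r, r / total_prod if total_prod else 0.0) for rid, r in producers],
        consumers=[(rid, r, r / total_cons if total_cons else 0.0) for rid, r in consumers],
        total_production=total_prod,
        total_consumption=total_cons,
    )
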