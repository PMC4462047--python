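"""Flux balance analysis, parsimonious reference fluxes, MOMA knockouts,
and deletion screening.

FBA solves ``max/min c·v`` subject to steady state ``S v = 0``, flux bounds
``lb ≤ v ≤ ub`` and optional exact pins (e.g. biomass flux pinned at the
minimal proliferation rate μ = 0.03 h⁻¹).  Because FBA optima are usually
degenerate, the wild-type reference fed to MOMA is the parsimonious
solution: among optima it minimizes Σ|v|, which also forces internal
cycles to zero and makes the reference unique in practice.

MOMA predicts a knockout phenotype as the feasible mutant flux vector with
the least squared Euclidean distance to the wild-type reference — the
assumption being that a freshly perturbed metabolism stays as close as
possible to its previous operating point rather than re-optimizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from lipoflux._qp import project_to_polytope
from lipoflux.model import (
    MetabolicModel,
    ValidationError,
    gene_deletion_reactions,
    stoichiometric_matrix,
)

__all__ = [
    "FBAProblem",
    "FluxDistribution",
    "DeletionResult",
    "fba",
    "parsimonious_reference",
    "moma",
    "deletion_screen",
]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6


@dataclass
class FBAProblem:
    """An FBA instance: model, objective reaction, sense, and exact pins.

    ``pinned_fluxes`` maps reaction ids to exact flux values; the common
    use is pinning the biomass reaction at a minimal proliferation rate
    (μ, h⁻¹) while maximizing a product exchange.  Pins must lie within
    the declared bounds of their reactions; a pin that the network cannot
    actually carry surfaces as an infeasible solve, not an exception.
    """

    model: MetabolicModel
    objective_id: str
    sense: str = "maximize"
    pinned_fluxes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise ValidationError(f"sense must be 'maximize' or 'minimize', got {self.sense!r}")
        rxn_ids = set(self.model.reaction_ids)
        if self.objective_id not in rxn_ids:
            raise ValidationError(f"objective {self.objective_id!r} is not a reaction id")
        for rxn_id, value in self.pinned_fluxes.items():
            if rxn_id not in rxn_ids:
                raise ValidationError(f"pinned reaction {rxn_id!r} is not in the model")
            rxn = self.model.reaction(rxn_id)
            if not (rxn.lower_bound <= value <= rxn.upper_bound):
                raise ValidationError(
                    f"pin {rxn_id}={value} outside declared bounds "
                    f"[{rxn.lower_bound}, {rxn.upper_bound}]"
                )


@dataclass
class FluxDistribution:
    """A solved flux state: reaction→flux map, objective value, LP status.

    ``role`` distinguishes the wild-type reference (w) fed to MOMA from a
    mutant solution (v).  For MOMA solutions ``objective_value`` is the
    squared Euclidean distance to the reference.
    """

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # "optimal" | "infeasible" | "unbounded"
    role: str = "wild-type-reference"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def as_vector(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])

    def is_feasible(self, model: MetabolicModel, tol: float = FEASIBILITY_TOL) -> bool:
        """Check ‖S·v‖∞ ≤ tol·max(1, ‖v‖∞) and bounds within tol."""
        if self.status != "optimal":
            return False
        v = self.as_vector(model.reaction_ids)
        S = stoichiometric_matrix(model).toarray()
        scale = max(1.0, float(np.abs(v).max(initial=0.0)))
        if np.abs(S @ v).max(initial=0.0) > tol * scale:
            return False
        for rxn, flux in zip(model.reactions, v):
            if flux < rxn.lower_bound - tol * scale or flux > rxn.upper_bound + tol * scale:
                return False
        return True


@dataclass
class DeletionResult:
    """One row of a deletion screen."""

    deletion: frozenset[str]
    kind: str  # "genes" | "reactions"
    report_reaction: str
    wild_type_flux: float
    mutant_flux: float | None
    status: str
    disabled_reactions: frozenset[str]

    @property
    def percent_change(self) -> float | None:
        """100 × (mutant − wild)/wild; None when undefined (wt flux 0 or
        infeasible mutant).  Reductions are negative."""
        if self.mutant_flux is None or self.wild_type_flux == 0:
            return None
        return 100.0 * (self.mutant_flux - self.wild_type_flux) / self.wild_type_flux


_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _problem_arrays(problem: FBAProblem):
    model = problem.model
    n = len(model.reactions)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for rxn_id, value in problem.pinned_fluxes.items():
        j = index[rxn_id]
        lb[j] = ub[j] = value
    S = stoichiometric_matrix(model).toarray()
    return S, lb, ub, index, n


def fba(problem: FBAProblem) -> FluxDistribution:
    """Solve the FBA linear program.

    Returns status ``"infeasible"`` or ``"unbounded"`` (with empty fluxes)
    rather than raising when the LP has no optimum.
    """
    S, lb, ub, index, n = _problem_arrays(problem)
    c = np.zeros(n)
    c[index[problem.objective_id]] = -1.0 if problem.sense == "maximize" else 1.0
    res = optimize.linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _LP_STATUS.get(res.status)
    if status is None:
        raise RuntimeError(f"LP solver failed: {res.message}")
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    fluxes = {rid: float(res.x[j]) for rid, j in index.items()}
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=fluxes[problem.objective_id],
        status="optimal",
    )


def parsimonious_reference(problem: FBAProblem) -> FluxDistribution:
    """Parsimonious FBA: fix the objective at its optimum, minimize Σ|v|.

    The second-stage LP splits each flux into non-negative forward and
    reverse parts; internal cycles add |v| without improving the (fixed)
    objective, so they carry zero flux.  This is the wild-type reference
    used by :func:`moma` and :func:`deletion_screen`.
    """
    first = fba(problem)
    if first.status != "optimal":
        return first
    z_star = first.objective_value

    S, lb, ub, index, n = _problem_arrays(problem)
    m = S.shape[0]
    j_obj = index[problem.objective_id]

    # variables: [v+, v-], v = v+ − v−
    c = np.ones(2 * n)
    A_eq = np.hstack([S, -S])
    obj_row = np.zeros(2 * n)
    obj_row[j_obj] = 1.0
    obj_row[n + j_obj] = -1.0
    A_eq = np.vstack([A_eq, obj_row])
    b_eq = np.concatenate([np.zeros(m), [z_star]])
    # box bounds on the split variables, plus bound rows for v itself when
    # a bound does not pass through zero
    plus_ub = np.maximum(ub, 0.0)
    minus_ub = np.maximum(-lb, 0.0)
    bounds = np.column_stack([np.zeros(2 * n), np.concatenate([plus_ub, minus_ub])])
    A_ub_rows = []
    b_ub = []
    for j in range(n):
        if lb[j] > 0:  # v_j ≥ lb_j not implied by the split bounds
            row = np.zeros(2 * n)
            row[j], row[n + j] = -1.0, 1.0
            A_ub_rows.append(row)
            b_ub.append(-lb[j])
        if ub[j] < 0:  # v_j ≤ ub_j < 0
            row = np.zeros(2 * n)
            row[j], row[n + j] = 1.0, -1.0
            A_ub_rows.append(row)
            b_ub.append(ub[j])
    res = optimize.linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=np.array(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"parsimonious stage failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v[j]) for rid, j in index.items()}
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=float(v[j_obj]),
        status="optimal",
        role="wild-type-reference",
    )


def moma(
    model: MetabolicModel,
    reference: FluxDistribution,
    disabled: Iterable[str],
    pinned_fluxes: Mapping[str, float] | None = None,
    variant: str = "quadratic",
) -> FluxDistribution:
    """MOMA knockout prediction.

    Finds ``argmin Σ_j (v_j − w_j)²`` over the mutant polytope
    ``{S v = 0, lb ≤ v ≤ ub, v_k = 0 ∀ k disabled, pins}`` where *w* is
    the wild-type *reference*.  Only the quadratic (Euclidean) variant is
    implemented; ``variant`` is a config switch reserved for a linear
    distance.
    """
    if variant != "quadratic":
        raise NotImplementedError(f"MOMA variant {variant!r} not implemented")
    if reference.status != "optimal":
        raise ValidationError("MOMA requires an optimal wild-type reference")
    disabled = set(disabled)
    rxn_ids = set(model.reaction_ids)
    unknown = disabled - rxn_ids
    if unknown:
        raise ValidationError(f"unknown reaction ids in disabled set: {sorted(unknown)}")

    n = len(model.reactions)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for rxn_id, value in (pinned_fluxes or {}).items():
        if rxn_id not in index:
            raise ValidationError(f"pinned reaction {rxn_id!r} is not in the model")
        lb[index[rxn_id]] = ub[index[rxn_id]] = value
    for rxn_id in disabled:
        lb[index[rxn_id]] = ub[index[rxn_id]] = 0.0
    if np.any(lb > ub):
        return FluxDistribution({}, None, "infeasible", role="mutant")

    w = reference.as_vector(model.reaction_ids)
    S = stoichiometric_matrix(model).toarray()
    result = project_to_polytope(S, np.zeros(S.shape[0]), w, lb, ub)
    if result.status != "optimal":
        return FluxDistribution({}, None, "infeasible", role="mutant")
    fluxes = {rid: float(result.x[j]) for rid, j in index.items()}
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=2.0 * result.objective,  # Σ (v−w)²
        status="optimal",
        role="mutant",
    )


def deletion_screen(
    model: MetabolicModel,
    problem: FBAProblem,
    deletions: Sequence[Iterable[str]],
    report_reaction: str,
) -> list[DeletionResult]:
    """MOMA screen over gene sets (or raw reaction sets).

    The parsimonious wild-type reference is computed once; each deletion
    set is mapped to disabled reactions through the GPR rules (a set whose
    ids are all reaction ids is applied directly), MOMA is run with the
    problem's pins kept in force, and the flux through *report_reaction*
    is compared with the wild type.  Per-deletion infeasibility is
    recorded in the row, not raised.
    """
    if report_reaction not in set(model.reaction_ids):
        raise ValidationError(f"report reaction {report_reaction!r} is not in the model")
    reference = parsimonious_reference(problem)
    if reference.status != "optimal":
        raise ValidationError(f"wild type is not solvable (status {reference.status})")
    wt_flux = reference.fluxes[report_reaction]

    rxn_ids = set(model.reaction_ids)
    results = []
    for deletion in deletions:
        deletion = frozenset(deletion)
        if deletion <= model.genes:
            kind = "genes"
            disabled = frozenset(gene_deletion_reactions(model, deletion))
        elif deletion <= rxn_ids:
            kind = "reactions"
            disabled = deletion
        else:
            raise ValidationError(
                f"deletion set {sorted(deletion)} is neither all genes nor all reaction ids"
            )
        if not disabled:
            # nothing disabled → the mutant is the wild type, 0% change
            results.append(
                DeletionResult(
                    deletion=deletion,
                    kind=kind,
                    report_reaction=report_reaction,
                    wild_type_flux=wt_flux,
                    mutant_flux=wt_flux,
                    status="optimal",
                    disabled_reactions=disabled,
                )
            )
            continue
        mutant = moma(model, reference, disabled, pinned_fluxes=problem.pinned_fluxes)
        results.append(
            DeletionResult(
                deletion=deletion,
                kind=kind,
                report_reaction=report_reaction,
                wild_type_flux=wt_flux,
                mutant_flux=mutant.fluxes.get(report_reaction) if mutant.status == "optimal" else None,
                status=mutant.status,
                disabled_reactions=disabled,
            )
        )
    return results
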