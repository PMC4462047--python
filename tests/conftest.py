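import numpy as np
import pytest

from lipoflux.flux import FBAProblem
from lipoflux.model import MetabolicModel, Metabolite, Reaction
from lipoflux.synthetic import ToyNetworkConfig, toy_core_network


def build_model(reactions, metabolites=None, genes=(), objective=None, model_id="m"):
    """Assemble a model from (id, stoich, lb, ub[, gpr, is_exchange]) tuples."""
    mets = set()
    rxns = []
    for spec in reactions:
        rid, stoich, lb, ub = spec[:4]
        gpr = spec[4] if len(spec) > 4 else None
        is_exchange = spec[5] if len(spec) > 5 else len(stoich) == 1
        mets |= set(stoich)
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=dict(stoich),
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                is_exchange=is_exchange,
            )
        )
    if metabolites is None:
        metabolites = [Metabolite(id=m) for m in sorted(mets)]
    return MetabolicModel(
        id=model_id,
        metabolites=metabolites,
        reactions=rxns,
        genes=set(genes),
        default_objective=objective,
    )


@pytest.fixture
def chain_model():
    """→ A → B → : a three-step irreversible chain, all upper bounds 10."""
    return build_model(
        [
            ("r1", {"A": 1}, 0, 10, None, True),
            ("r2", {"A": -1, "B": 1}, 0, 10),
            ("r3", {"B": -1}, 0, 10, None, True),
        ]
    )


@pytest.fixture(scope="session")
def toy_model():
    return toy_core_network()


@pytest.fixture(scope="session")
def toy_model_no_me():
    return toy_core_network(ToyNetworkConfig(me_cap=0.0))


@pytest.fixture
def toy_problem(toy_model):
    return FBAProblem(
        model=toy_model, objective_id="EX_aa", pinned_fluxes={"BIOMASS": 0.03}
    )


def model_arrays(model, pins=None):
    """(S, lb, ub, index) dense arrays with optional pins applied."""
    from lipoflux.model import stoichiometric_matrix

    S = stoichiometric_matrix(model).toarray()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for rid, value in (pins or {}).items():
        lb[index[rid]] = ub[index[rid]] = value
    return S, lb, ub, index
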