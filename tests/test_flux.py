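"""FBA, parsimonious reference, MOMA and deletion screening."""

import numpy as np
import pytest

from conftest import build_model, model_arrays
from lipoflux.flux import (
    FBAProblem,
    FluxDistribution,
    deletion_screen,
    fba,
    moma,
    parsimonious_reference,
)
from lipoflux.model import ValidationError
from oracles import lp_vertex_oracle, random_bounded_network, slsqp_moma_oracle


class TestFBA:
    def test_irreversible_chain(self, chain_model):
        sol = fba(FBAProblem(model=chain_model, objective_id="r3"))
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_minimize_sense(self, chain_model):
        sol = fba(FBAProblem(model=chain_model, objective_id="r3", sense="minimize"))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_pin_above_reachable_maximum_is_infeasible(self, chain_model):
        # r2 caps the chain at 10; pinning the export above that has no solution
        model = build_model(
            [
                ("r1", {"A": 1}, 0, 100, None, True),
                ("r2", {"A": -1, "B": 1}, 0, 10),
                ("r3", {"B": -1}, 0, 100, None, True),
            ]
        )
        sol = fba(FBAProblem(model=model, objective_id="r1", pinned_fluxes={"r3": 50}))
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_pin_outside_declared_bounds_rejected(self, chain_model):
        with pytest.raises(ValidationError, match="pin"):
            FBAProblem(model=chain_model, objective_id="r3", pinned_fluxes={"r2": 99})

    def test_unbounded(self):
        model = build_model(
            [
                ("in", {"A": 1}, -np.inf, np.inf, None, True),
                ("out", {"A": -1}, -np.inf, np.inf, None, True),
            ]
        )
        sol = fba(FBAProblem(model=model, objective_id="out"))
        assert sol.status == "unbounded"

    def test_toy_optimum_matches_vertex_oracle(self, toy_model, toy_problem):
        sol = fba(toy_problem)
        S, lb, ub, index = model_arrays(toy_model, pins={"BIOMASS": 0.03})
        c = np.zeros(len(toy_model.reactions))
        c[index["EX_aa"]] = 1.0
        # cap the huge bounds so the vertex oracle's polytope stays bounded
        lb, ub = np.maximum(lb, -1e4), np.minimum(ub, 1e4)
        assert sol.objective_value == pytest.approx(10.4865, abs=1e-9)
        assert sol.objective_value == pytest.approx(
            lp_vertex_oracle(S, c, lb, ub), abs=1e-6
        )

    def test_solution_feasible(self, toy_model, toy_problem):
        sol = fba(toy_problem)
        assert sol.is_feasible(toy_model)

    @pytest.mark.parametrize("seed", range(40))
    def test_random_network_oracle_equivalence(self, seed):
        """FBA matches vertex enumeration on random bounded networks."""
        S, c, lb, ub = random_bounded_network(seed)
        mets = [f"M{i}" for i in range(S.shape[0])]
        reactions = []
        for j in range(S.shape[1]):
            stoich = {mets[i]: S[i, j] for i in range(S.shape[0]) if S[i, j] != 0}
            reactions.append((f"R{j}", stoich, lb[j], ub[j], None, len(stoich) <= 1))
        model = build_model(
            [r for r in reactions if r[1]] + [
                (rid, {mets[0]: 1.0}, l, u, None, True)
                for rid, stoich, l, u, *_ in reactions
                if not stoich
            ]
        )
        # rebuild arrays in the model's final reaction order
        S2, lb2, ub2, index = model_arrays(model)
        c2 = np.zeros(len(model.reactions))
        j_obj = int(np.argmax(c))
        obj_id = f"R{j_obj}"
        c2[index[obj_id]] = 1.0
        sol = fba(FBAProblem(model=model, objective_id=obj_id))
        expected = lp_vertex_oracle(S2, c2, lb2, ub2)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)


class TestParsimoniousReference:
    def test_chain_identical_to_fba(self, chain_model):
        problem = FBAProblem(model=chain_model, objective_id="r3")
        plain, sparse_ref = fba(problem), parsimonious_reference(problem)
        assert sparse_ref.objective_value == pytest.approx(plain.objective_value, abs=1e-9)
        for rid in chain_model.reaction_ids:
            assert sparse_ref.fluxes[rid] == pytest.approx(plain.fluxes[rid], abs=1e-9)

    def test_internal_loop_carries_zero_flux(self):
        # fwd: A→B and back: B→A form a directed cycle that could circulate
        # at any rate; it adds Σ|v| with no objective gain
        model = build_model(
            [
                ("in", {"A": 1}, 0, 10, None, True),
                ("fwd", {"A": -1, "B": 1}, 0, 100),
                ("back", {"B": -1, "A": 1}, 0, 100),
                ("out", {"B": -1}, 0, 10, None, True),
            ]
        )
        ref = parsimonious_reference(FBAProblem(model=model, objective_id="out"))
        assert ref.objective_value == pytest.approx(10.0, abs=1e-9)
        assert ref.fluxes["fwd"] == pytest.approx(10.0, abs=1e-9)
        assert ref.fluxes["back"] == pytest.approx(0.0, abs=1e-9)

    def test_shorter_route_preferred(self):
        # one-step route vs a two-step detour with equal capacity
        model = build_model(
            [
                ("in", {"A": 1}, 0, 10, None, True),
                ("direct", {"A": -1, "B": 1}, 0, 100),
                ("step1", {"A": -1, "X": 1}, 0, 100),
                ("step2", {"X": -1, "B": 1}, 0, 100),
                ("out", {"B": -1}, 0, 10, None, True),
            ]
        )
        ref = parsimonious_reference(FBAProblem(model=model, objective_id="out"))
        assert ref.fluxes["direct"] == pytest.approx(10.0, abs=1e-9)
        assert ref.fluxes["step1"] == pytest.approx(0.0, abs=1e-9)

    def test_declaration_order_invariance(self):
        """Looped fixture: the parsimonious optimum ignores reaction order."""
        specs = [
            ("in", {"A": 1}, 0, 10, None, True),
            ("fwd", {"A": -1, "B": 1}, 0, 100),
            ("back", {"B": -1, "A": 1}, 0, 100),
            ("out", {"B": -1}, 0, 10, None, True),
        ]
        ref1 = parsimonious_reference(
            FBAProblem(model=build_model(specs), objective_id="out")
        )
        ref2 = parsimonious_reference(
            FBAProblem(model=build_model(specs[::-1]), objective_id="out")
        )
        for rid in ("in", "fwd", "back", "out"):
            assert ref1.fluxes[rid] == pytest.approx(ref2.fluxes[rid], abs=1e-9)

    def test_propagates_infeasible_status(self, chain_model):
        model = build_model(
            [
                ("r1", {"A": 1}, 0, 1, None, True),
                ("r2", {"A": -1}, 5, 10, None, True),
            ]
        )
        ref = parsimonious_reference(FBAProblem(model=model, objective_id="r1"))
        assert ref.status == "infeasible"


class TestMOMA:
    def test_deleting_zero_flux_reaction_keeps_reference(self, toy_model, toy_problem):
        ref = parsimonious_reference(toy_problem)
        assert abs(ref.fluxes["NADPH_SINK"]) < 1e-9
        mutant = moma(toy_model, ref, {"NADPH_SINK"}, pinned_fluxes={"BIOMASS": 0.03})
        assert mutant.objective_value == pytest.approx(0.0, abs=1e-9)
        for rid in toy_model.reaction_ids:
            assert mutant.fluxes[rid] == pytest.approx(ref.fluxes[rid], abs=1e-6)

    def test_parallel_path_rerouting(self):
        """WT runs 10 on path 1; knocking it out reroutes onto path 2 up to
        its capacity 4 (the constrained least-squares solution)."""
        model = build_model(
            [
                ("in", {"A": 1}, 0, 10, None, True),
                ("path1", {"A": -1, "B": 1}, 0, 100),
                ("path2", {"A": -1, "B": 1}, 0, 4),
                ("out", {"B": -1}, 0, 100, None, True),
            ]
        )
        ref = parsimonious_reference(FBAProblem(model=model, objective_id="out"))
        assert ref.fluxes["path1"] == pytest.approx(10.0, abs=1e-9)
        mutant = moma(model, ref, {"path1"})
        assert mutant.status == "optimal"
        # closed form: min (p2−0)² + (in−10)² + (out−10)² with p2=in=out ≤ 4
        assert mutant.fluxes["path2"] == pytest.approx(4.0, abs=1e-6)

    def test_infeasible_when_pin_unreachable(self, toy_model, toy_problem):
        ref = parsimonious_reference(toy_problem)
        mutant = moma(toy_model, ref, {"NH4t"}, pinned_fluxes={"BIOMASS": 0.03})
        assert mutant.status == "infeasible"

    def test_requires_optimal_reference(self, toy_model):
        bad = FluxDistribution(fluxes={}, objective_value=None, status="infeasible")
        with pytest.raises(ValidationError):
            moma(toy_model, bad, set())

    @pytest.mark.parametrize("seed", range(12))
    def test_toy_knockouts_match_slsqp_oracle(self, toy_model, toy_problem, seed):
        rng = np.random.default_rng(seed)
        genes = sorted(toy_model.genes)
        deletion = set(rng.choice(genes, size=rng.integers(1, 4), replace=False))
        from lipoflux.model import gene_deletion_reactions

        disabled = gene_deletion_reactions(toy_model, deletion)
        ref = parsimonious_reference(toy_problem)
        mutant = moma(toy_model, ref, disabled, pinned_fluxes={"BIOMASS": 0.03})
        S, lb, ub, index = model_arrays(toy_model, pins={"BIOMASS": 0.03})
        for rid in disabled:
            lb[index[rid]] = ub[index[rid]] = 0.0
        expected = slsqp_moma_oracle(S, ref.as_vector(toy_model.reaction_ids), lb, ub)
        if mutant.status == "infeasible":
            assert expected is None
        else:
            v = mutant.as_vector(toy_model.reaction_ids)
            assert np.linalg.norm(v - expected) < 1e-5

    def test_first_order_optimality(self, toy_model, toy_problem):
        """No feasible step of norm 1e-3 from the MOMA optimum materially
        decreases the squared distance."""
        from scipy.optimize import linprog

        ref = parsimonious_reference(toy_problem)
        mutant = moma(toy_model, ref, {"PGD"}, pinned_fluxes={"BIOMASS": 0.03})
        w = ref.as_vector(toy_model.reaction_ids)
        x = mutant.as_vector(toy_model.reaction_ids)
        S, lb, ub, index = model_arrays(toy_model, pins={"BIOMASS": 0.03})
        lb[index["PGD"]] = ub[index["PGD"]] = 0.0
        f0 = np.dot(x - w, x - w)
        rng = np.random.default_rng(0)
        for _ in range(25):
            res = linprog(
                rng.standard_normal(len(x)),
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=np.column_stack([lb, ub]),
                method="highs",
            )
            gap = res.x - x
            norm = np.linalg.norm(gap)
            if norm < 1e-3:
                continue
            step = x + gap * (1e-3 / norm)  # feasible by convexity
            assert np.dot(step - w, step - w) >= f0 - 1e-6


class TestDeletionScreen:
    def test_empty_deletion_zero_change(self, toy_model, toy_problem):
        (row,) = deletion_screen(toy_model, toy_problem, [set()], "EX_aa")
        assert row.percent_change == pytest.approx(0.0, abs=1e-12)

    def test_deleting_report_reaction_is_minus_100(self, toy_model, toy_problem):
        (row,) = deletion_screen(toy_model, toy_problem, [{"EX_aa"}], "EX_aa")
        assert row.kind == "reactions"
        assert row.mutant_flux == pytest.approx(0.0, abs=1e-12)
        assert row.percent_change == pytest.approx(-100.0, abs=1e-9)

    def test_mixed_id_set_rejected(self, toy_model, toy_problem):
        with pytest.raises(ValidationError, match="neither"):
            deletion_screen(toy_model, toy_problem, [{"gG6PD", "EX_aa"}], "EX_aa")

    def test_infeasible_row_not_fatal(self, toy_model, toy_problem):
        rows = deletion_screen(
            toy_model, toy_problem, [{"NH4t"}, set()], "EX_aa"
        )
        assert rows[0].status == "infeasible"
        assert rows[0].percent_change is None
        assert rows[1].status == "optimal"

    def test_screen_matches_qp_oracle(self, toy_model, toy_problem):
        """Percent changes for the PPP/ME deletions match the independent
        constrained least-squares oracle."""
        from lipoflux.model import gene_deletion_reactions

        deletions = [{"gG6PD"}, {"gPGD"}, {"gG6PD", "gPGD"}, {"gME"}]
        rows = deletion_screen(toy_model, toy_problem, deletions, "EX_aa")
        ref = parsimonious_reference(toy_problem)
        w = ref.as_vector(toy_model.reaction_ids)
        j_aa = toy_model.reaction_ids.index("EX_aa")
        for row, deletion in zip(rows, deletions):
            S, lb, ub, index = model_arrays(toy_model, pins={"BIOMASS": 0.03})
            for rid in gene_deletion_reactions(toy_model, deletion):
                lb[index[rid]] = ub[index[rid]] = 0.0
            expected = slsqp_moma_oracle(S, w, lb, ub)
            assert row.mutant_flux == pytest.approx(expected[j_aa], abs=1e-5)
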