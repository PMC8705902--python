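"""Stoichiometric matrix, FBA, FVA and flux-coupling behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutflux.bruteforce import fva_bruteforce
from gutflux.core import (
    CouplingConstraint,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    ValidationError,
    add_flux_coupling,
    build_stoichiometric_matrix,
    run_fva,
    solve_fba,
)
from gutflux.synth import random_lp_model


class TestStoichiometricMatrix:
    def test_column_reproduces_reaction(self, chain_model):
        S, mets, rxns = build_stoichiometric_matrix(chain_model)
        assert mets == [("A", "c"), ("B", "c")]
        assert rxns == ["C1", "EX_A", "EX_B"]
        dense = S.toarray()
        np.testing.assert_array_equal(dense[:, rxns.index("C1")], [-1, 1])
        np.testing.assert_array_equal(dense[:, rxns.index("EX_A")], [-1, 0])
        np.testing.assert_array_equal(dense[:, rxns.index("EX_B")], [0, -1])

    def test_empty_model(self):
        m = MetabolicModel(id="empty")
        S, mets, rxns = build_stoichiometric_matrix(m)
        assert S.shape == (0, 0) and mets == [] and rxns == []

    def test_undeclared_metabolite_rejected(self):
        m = MetabolicModel(id="bad")
        m.add_compartment("c")
        m.add_metabolite(Metabolite("A", "c"))
        rxn = Reaction("R1", {("A", "c"): -1.0, ("ghost", "c"): 1.0})
        with pytest.raises(ModelStructureError, match="R1"):
            m.add_reaction(rxn)

    def test_exchange_convention_enforced(self):
        rxn = Reaction("EX_A", {("A", "c"): -2.0}, kind="exchange")
        with pytest.raises(ModelStructureError, match="coefficient -1"):
            rxn.validate()


class TestFBA:
    def test_chain_optimum_limited_by_supply(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_all_bounds_zero(self, chain_model):
        for rxn in chain_model.reactions.values():
            rxn.lb = rxn.ub = 0.0
        sol = solve_fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_inverted_bounds_rejected_before_solving(self, chain_model):
        chain_model.reactions["EX_A"].lb = 5
        chain_model.reactions["EX_A"].ub = -5
        with pytest.raises(ValidationError):
            solve_fba(chain_model)

    def test_optimal_solution_is_mass_balanced(self, chain_model):
        sol = solve_fba(chain_model)
        S, _, rxns = build_stoichiometric_matrix(chain_model)
        v = np.array([sol.fluxes[r] for r in rxns])
        assert np.max(np.abs(S @ v)) <= 1e-6
        for rid in rxns:
            rxn = chain_model.reactions[rid]
            assert rxn.lb - 1e-6 <= sol.fluxes[rid] <= rxn.ub + 1e-6


class TestFVA:
    def test_chain_unconstrained(self, chain_model):
        assert run_fva(chain_model, ["EX_B"], 0.0)["EX_B"] == \
            pytest.approx((0.0, 10.0), abs=1e-6)

    def test_blocked_reaction(self, chain_model):
        chain_model.add_metabolite(Metabolite("C", "c"))
        chain_model.add_reaction(
            Reaction("C2", {("C", "c"): -1.0, ("B", "c"): 1.0}, lb=0, ub=1000)
        )
        vmin, vmax = run_fva(chain_model, ["C2"], 0.0)["C2"]
        assert (vmin, vmax) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_objective_pinned_at_gamma_one(self, chain_model):
        assert run_fva(chain_model, ["EX_B"], 1.0)["EX_B"] == \
            pytest.approx((10.0, 10.0), abs=1e-6)

    def test_unknown_reaction_rejected(self, chain_model):
        with pytest.raises(KeyError):
            run_fva(chain_model, ["nope"])

    def test_fva_sandwich(self, chain_model):
        sol = solve_fba(chain_model)
        fva = run_fva(chain_model)
        for rid, (vmin, vmax) in fva.items():
            assert vmin <= vmax + 1e-6
            assert vmin - 1e-6 <= sol.fluxes[rid] <= vmax + 1e-6

    def test_oracle_equivalence_on_random_models(self, rng):
        for _ in range(25):
            model = random_lp_model(rng)
            ours = run_fva(model)
            brute = fva_bruteforce(model)
            for rid in ours:
                assert ours[rid][0] == pytest.approx(brute[rid][0], abs=1e-6)
                assert ours[rid][1] == pytest.approx(brute[rid][1], abs=1e-6)

    def test_cross_check_against_cobrapy(self, rng):
        """Independent whole-stack check: the same random models solved by
        cobrapy (GLPK) give the same FVA bounds."""
        import cobra
        from cobra.flux_analysis import flux_variability_analysis

        for _ in range(5):
            model = random_lp_model(rng)
            cm = cobra.Model(model.id)
            mets = {
                key: cobra.Metabolite(f"{key[0]}_{key[1]}",
                                      compartment=key[1])
                for key in model.metabolites
            }
            rxns = []
            for rid in model.reaction_ids():
                rxn = model.reactions[rid]
                cr = cobra.Reaction(rid, lower_bound=rxn.lb,
                                    upper_bound=rxn.ub)
                rxns.append(cr)
            cm.add_reactions(rxns)
            for rid in model.reaction_ids():
                cm.reactions.get_by_id(rid).add_metabolites({
                    mets[key]: coef
                    for key, coef in model.reactions[rid].stoichiometry.items()
                })
            frame = flux_variability_analysis(cm, fraction_of_optimum=0.0)
            ours = run_fva(model)
            for rid in ours:
                assert ours[rid][0] == pytest.approx(
                    frame.loc[rid, "minimum"], abs=1e-6)
                assert ours[rid][1] == pytest.approx(
                    frame.loc[rid, "maximum"], abs=1e-6)


def _coupled_toy(v_bio: float, c: float, u: float) -> MetabolicModel:
    """Producer with a biomass pinned at ``v_bio`` and a coupled secretion."""
    m = MetabolicModel(id="coupled")
    m.add_compartment("c")
    for mid in ("A", "B", "X"):
        m.add_metabolite(Metabolite(mid, "c"))
    m.add_reaction(Reaction("EX_A", {("A", "c"): -1.0}, lb=-1000, ub=1000,
                            kind="exchange"))
    m.add_reaction(Reaction("CONV", {("A", "c"): -1.0, ("B", "c"): 1.0},
                            lb=-1000, ub=1000))
    m.add_reaction(Reaction("EX_B", {("B", "c"): -1.0}, lb=-1000, ub=1000,
                            kind="exchange"))
    m.add_reaction(Reaction("BIO", {("X", "c"): 1.0}, lb=v_bio, ub=v_bio,
                            kind="biomass"))
    m.add_reaction(Reaction("EX_X", {("X", "c"): -1.0}, lb=0, ub=1000,
                            kind="exchange"))
    m.objective = {"BIO": 1.0}
    return add_flux_coupling(m, {"s": (["CONV", "EX_B", "EX_A"], "BIO")},
                             c=c, u=u)


class TestCoupling:
    def test_cap_equals_c_times_biomass(self):
        model = _coupled_toy(v_bio=0.01, c=400.0, u=0.0)
        vmin, vmax = run_fva(model, ["EX_B"], 0.0)["EX_B"]
        assert (vmin, vmax) == pytest.approx((-4.0, 4.0), abs=1e-6)

    def test_zero_biomass_shuts_down_flux(self):
        model = _coupled_toy(v_bio=0.0, c=400.0, u=0.0)
        fva = run_fva(model, ["EX_B", "CONV"], 0.0)
        for rid in ("EX_B", "CONV"):
            assert fva[rid] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_negative_factor_rejected(self, chain_model):
        with pytest.raises(ValidationError):
            add_flux_coupling(chain_model, {"s": (["C1"], "EX_B")}, c=-1.0)
        with pytest.raises(ValidationError):
            CouplingConstraint("C1", "EX_B", factor=400.0, slack=-0.1)

    def test_missing_anchor_rejected(self, chain_model):
        with pytest.raises(ModelStructureError):
            add_flux_coupling(chain_model, {"s": (["C1"], "ghost")})

    @given(bio_ub=st.floats(min_value=0.0, max_value=2.0))
    def test_secretion_cap_monotone_in_biomass_allowance(self, bio_ub):
        model = _coupled_toy(v_bio=0.0, c=400.0, u=0.0)
        model.reactions["BIO"].lb = 0.0
        model.reactions["BIO"].ub = bio_ub
        _, vmax = run_fva(model, ["EX_B"], 0.0)["EX_B"]
        assert vmax <= 400.0 * bio_ub + 1e-6
        model.reactions["BIO"].ub = bio_ub + 0.5
        _, vmax_more = run_fva(model, ["EX_B"], 0.0)["EX_B"]
        assert vmax_more >= vmax - 1e-6
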