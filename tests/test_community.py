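"""Abundance filtering, strain tagging and community assembly."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutflux.community import (
    AbundanceProfile,
    CommunityConfig,
    apply_diet,
    assemble_community,
    filter_and_renormalize,
    tag_strain_model,
)
from gutflux.core import ModelStructureError, ValidationError, run_fva, solve_fba
from gutflux.diet import DietFluxVector
from gutflux.synth import StrainTemplateSpec, generate_strain_template


def _profile(values: dict[str, float], sample="s") -> AbundanceProfile:
    return AbundanceProfile(sample_id=sample, abundances=values)


class TestFilterAndRenormalize:
    def test_drops_subthreshold_and_rescales(self):
        prof = _profile({"a": 0.5, "b": 0.4, "c": 0.0995, "d": 0.0005})
        out = filter_and_renormalize(prof, 0.001)
        assert set(out.abundances) == {"a", "b", "c"}
        assert out.abundances["a"] == pytest.approx(0.5 / 0.9995, rel=1e-12)
        assert out.abundances["b"] == pytest.approx(0.4 / 0.9995, rel=1e-12)
        assert out.abundances["c"] == pytest.approx(0.0995 / 0.9995, rel=1e-12)
        assert math.isclose(sum(out.abundances.values()), 1.0, abs_tol=1e-12)
        assert out.filtered

    def test_identity_when_all_pass(self):
        prof = _profile({"a": 0.6, "b": 0.4})
        out = filter_and_renormalize(prof, 0.001)
        assert out.abundances == pytest.approx({"a": 0.6, "b": 0.4})

    def test_empty_community_error(self):
        with pytest.raises(ValidationError, match="empty community"):
            filter_and_renormalize(_profile({"a": 0.0005, "b": 0.0004}), 0.001)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            _profile({"a": -0.1})

    @given(
        st.dictionaries(
            st.text(st.characters(categories=("Ll",)), min_size=1, max_size=4),
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=8,
        )
    )
    def test_idempotent(self, values):
        total = sum(values.values())
        if total <= 0:
            return
        values = {k: v / total for k, v in values.items()}  # unit-sum input
        if all(v < 0.001 for v in values.values()):
            return
        once = filter_and_renormalize(_profile(values), 0.001)
        twice = filter_and_renormalize(once, 0.001)
        assert set(once.abundances) == set(twice.abundances)
        for strain in once.abundances:
            assert twice.abundances[strain] == pytest.approx(
                once.abundances[strain], abs=1e-12)


@pytest.fixture
def producer_model():
    return generate_strain_template(StrainTemplateSpec(
        "S1", substrates=["glc", "pre"], products=["fol"],
        yields={"fol": 1.0},
    ))


class TestTagStrainModel:
    def test_iex_naming_and_exchange_removal(self, producer_model):
        tagged = tag_strain_model(producer_model, "S1")
        assert "S1_IEX_fol[u]tr" in tagged.reactions
        assert not any(r.kind == "exchange" for r in tagged.reactions.values())
        # secretion direction positive: lumen species is the product
        iex = tagged.reactions["S1_IEX_fol[u]tr"]
        assert iex.stoichiometry[("fol", "u")] == 1.0
        assert iex.stoichiometry[("fol", "c_S1")] == -1.0

    def test_two_strains_have_disjoint_reaction_ids(self, producer_model):
        t1 = tag_strain_model(producer_model, "S1")
        t2 = tag_strain_model(producer_model, "S2")
        assert not (set(t1.reactions) & set(t2.reactions))

    def test_double_tagging_rejected(self, producer_model):
        tagged = tag_strain_model(producer_model, "S1")
        with pytest.raises(ModelStructureError, match="already tagged"):
            tag_strain_model(tagged, "S2")

    def test_biomass_species_stays_private(self, producer_model):
        tagged = tag_strain_model(producer_model, "S1")
        assert ("biomass", "u") not in tagged.metabolites


class TestAssembleCommunity:
    def test_biomass_coefficients_equal_abundances(self, producer_model):
        models = {"S1": producer_model, "S2": producer_model}
        prof = filter_and_renormalize(_profile({"S1": 0.6, "S2": 0.4}))
        com = assemble_community(models, prof, CommunityConfig())
        bio = com.reactions["communityBiomass"]
        assert bio.stoichiometry[("biomass", "c_S1")] == pytest.approx(-0.6)
        assert bio.stoichiometry[("biomass", "c_S2")] == pytest.approx(-0.4)

    def test_reaction_count_bookkeeping(self, producer_model):
        models = {"S1": producer_model, "S2": producer_model}
        prof = filter_and_renormalize(_profile({"S1": 0.6, "S2": 0.4}))
        com = assemble_community(models, prof, CommunityConfig())
        # per strain: T_glc, T_pre, T_fol, CONV_fol, BIO = 5 internal/tagged
        # plus 3 IEX each; lumen mets {glc, pre, fol} -> 4 reactions each;
        # plus communityBiomass + its transport + its fecal exchange
        assert len(com.reactions) == 2 * 5 + 2 * 3 + 4 * 3 + 3

    def test_unfiltered_profile_rejected(self, producer_model):
        with pytest.raises(ValidationError, match="filtered"):
            assemble_community({"S1": producer_model},
                               _profile({"S1": 1.0}))

    def test_missing_model_rejected(self, producer_model):
        prof = filter_and_renormalize(_profile({"S1": 0.5, "ghost": 0.5}))
        with pytest.raises(ModelStructureError, match="ghost"):
            assemble_community({"S1": producer_model}, prof)

    def test_single_strain_equivalence(self, producer_model):
        """A one-strain community reproduces the strain's own FBA optimum
        under the same nutrient supply."""
        supply = {"glc": 10.0, "pre": 5.0}
        strain = producer_model.copy()
        for met, flux in supply.items():
            strain.reactions[f"EX_{met}"].lb = -flux
            strain.reactions[f"EX_{met}"].ub = 0.0
        strain_opt = solve_fba(strain).objective_value

        prof = filter_and_renormalize(_profile({"S1": 1.0}))
        config = CommunityConfig(biomass_bounds=(0.0, 1000.0))
        com = assemble_community({"S1": producer_model}, prof, config)
        com = apply_diet(com, DietFluxVector(dict(supply)))
        community_opt = solve_fba(com).objective_value
        assert community_opt == pytest.approx(strain_opt, abs=1e-6)
        assert community_opt == pytest.approx(100.0, abs=1e-6)  # 10 / 0.1

    def test_halving_producer_abundance_does_not_raise_secretion(
            self, producer_model):
        inert = generate_strain_template(
            StrainTemplateSpec("I", substrates=["glc"]))
        diet = DietFluxVector({"glc": 10.0, "pre": 500.0})
        caps = []
        for a in (0.4, 0.2):
            prof = filter_and_renormalize(
                _profile({"S1": a, "I": 1.0 - a}))
            com = assemble_community({"S1": producer_model, "I": inert},
                                     prof, CommunityConfig())
            com = apply_diet(com, diet)
            _, vmax = run_fva(com, ["EX_fol[fe]"], 0.9999)["EX_fol[fe]"]
            caps.append(vmax)
        assert caps[1] <= caps[0] + 1e-6


class TestApplyDiet:
    def test_sign_convention(self, producer_model):
        prof = filter_and_renormalize(_profile({"S1": 1.0}))
        com = assemble_community({"S1": producer_model}, prof)
        fed = apply_diet(com, DietFluxVector({"glc": 10.0}))
        assert fed.reactions["EX_glc[d]"].lb == -10.0
        assert fed.reactions["EX_glc[d]"].ub == 0.0
        assert fed.reactions["EX_pre[d]"].lb == 0.0  # absent from diet
        assert fed.reactions["EX_glc[fe]"].ub > 0  # fecal outflow open

    def test_unknown_diet_metabolite_skipped(self, producer_model):
        prof = filter_and_renormalize(_profile({"S1": 1.0}))
        com = assemble_community({"S1": producer_model}, prof)
        fed = apply_diet(com, DietFluxVector({"glc": 10.0, "unicorn": 3.0}))
        assert fed.metadata["diet_skipped"] == ["unicorn"]

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DietFluxVector({"glc": -1.0})
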