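"""Assemble per-strain models into one diet-constrained community model.

Strains above an abundance cutoff (0.1% by default) are kept and their
fractions renormalised; each strain model is tagged into its own compartment
and wired to a shared lumen pool ``[u]`` through per-strain IEX transport
reactions. The lumen connects to a diet inflow layer ``[d]`` and a fecal
outflow layer ``[fe]``; an abundance-weighted community biomass reaction
drains each strain's biomass species, and every strain reaction is
flux-coupled to its own biomass so organisms cannot carry flux without
growing in proportion to their abundance.

Layout and naming (``EX_m[d]``, ``DUt_m``, ``UFEt_m``, ``EX_m[fe]``,
``IEX``) follow the common community-modelling convention so outputs stay
comparable with established toolboxes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .core import (
    DEFAULT_BOUND,
    CouplingConstraint,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    ValidationError,
    add_flux_coupling,
)
from .diet import DietFluxVector, supplement_micronutrients

__all__ = [
    "AbundanceProfile",
    "CommunityConfig",
    "CommunityModel",
    "SupplementPolicy",
    "StrainRecord",
    "filter_and_renormalize",
    "tag_strain_model",
    "assemble_community",
    "apply_diet",
    "LUMEN",
    "DIET",
    "FECAL",
]

logger = logging.getLogger(__name__)

LUMEN = "u"
DIET = "d"
FECAL = "fe"

COMMUNITY_BIOMASS_MET = "microbeBiomass"
COMMUNITY_BIOMASS_RXN = "communityBiomass"


@dataclass
class AbundanceProfile:
    """Per-sample strain relative abundances (fractions, not percent)."""

    sample_id: str
    abundances: dict[str, float] = field(default_factory=dict)
    filtered: bool = False
    cutoff: float = 0.001

    def __post_init__(self) -> None:
        for strain, frac in self.abundances.items():
            if frac < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative abundance for "
                    f"{strain!r}: {frac}"
                )

    def strains(self) -> list[str]:
        return sorted(self.abundances)

    def total(self) -> float:
        return sum(self.abundances.values())


@dataclass
class SupplementPolicy:
    """Trace diet allowance for essential micronutrients absent from the
    composed diet (mmol/day)."""

    essential: list[str] = field(default_factory=list)
    epsilon: float = 0.1


@dataclass
class CommunityConfig:
    """Tunable knobs of community construction and simulation."""

    cutoff: float = 0.001
    coupling_factor: float = 400.0
    coupling_slack: float = 0.01
    biomass_bounds: tuple[float, float] = (0.4, 1.0)
    objective_fraction: float = 0.9999
    supplement: SupplementPolicy | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff < 1.0:
            raise ValidationError(f"cutoff must lie in [0, 1), got {self.cutoff}")
        if self.coupling_factor < 0 or self.coupling_slack < 0:
            raise ValidationError("coupling factor and slack must be >= 0")
        if self.biomass_bounds[0] > self.biomass_bounds[1]:
            raise ValidationError(
                f"biomass bounds inverted: {self.biomass_bounds}"
            )
        if not 0.0 <= self.objective_fraction <= 1.0:
            raise ValidationError("objective_fraction must lie in [0, 1]")


@dataclass
class StrainRecord:
    """Bookkeeping for one strain inside a community model."""

    compartment: str
    reaction_ids: list[str]
    biomass_reaction: str
    iex_reactions: dict[str, str]  # lumen metabolite id -> IEX reaction id
    abundance: float


@dataclass
class CommunityModel(MetabolicModel):
    strain_registry: dict[str, StrainRecord] = field(default_factory=dict)

    def lumen_metabolites(self) -> list[str]:
        return sorted(
            mid for (mid, comp) in self.metabolites
            if comp == LUMEN and mid != COMMUNITY_BIOMASS_MET
        )

    def exchanged_metabolites(self) -> list[str]:
        """Lumen metabolites possessing both a diet and a fecal exchange."""
        return [
            m for m in self.lumen_metabolites()
            if f"EX_{m}[{DIET}]" in self.reactions
            and f"EX_{m}[{FECAL}]" in self.reactions
        ]

    def copy(self, new_id: str | None = None) -> "CommunityModel":
        base = MetabolicModel.copy(self, new_id)
        return CommunityModel(
            id=base.id,
            compartments=base.compartments,
            metabolites=base.metabolites,
            reactions=base.reactions,
            objective=base.objective,
            couplings=base.couplings,
            metadata=base.metadata,
            strain_registry={
                s: StrainRecord(
                    r.compartment, list(r.reaction_ids), r.biomass_reaction,
                    dict(r.iex_reactions), r.abundance,
                )
                for s, r in self.strain_registry.items()
            },
        )


# ---------------------------------------------------------------------------
# Abundance filtering
# ---------------------------------------------------------------------------

def filter_and_renormalize(
    profile: AbundanceProfile, cutoff: float | None = None
) -> AbundanceProfile:
    """Drop strains below the abundance cutoff and rescale to unit sum.

    The cutoff is applied to the raw relative abundances before
    renormalisation; strains at exactly the cutoff are retained.
    """
    tau = profile.cutoff if cutoff is None else cutoff
    if not 0.0 <= tau < 1.0:
        raise ValidationError(f"cutoff must lie in [0, 1), got {tau}")
    kept = {s: a for s, a in profile.abundances.items() if a >= tau}
    removed = sorted(set(profile.abundances) - set(kept))
    if removed:
        logger.info(
            "sample %s: removed %d strains below cutoff %g: %s",
            profile.sample_id, len(removed), tau, ", ".join(removed),
        )
    total = sum(kept.values())
    if not kept or total <= 0.0:
        raise ValidationError(
            f"sample {profile.sample_id!r}: empty community after applying "
            f"abundance cutoff {tau}"
        )
    rescaled = {s: a / total for s, a in sorted(kept.items())}
    return AbundanceProfile(
        sample_id=profile.sample_id,
        abundances=rescaled,
        filtered=True,
        cutoff=tau,
    )


# ---------------------------------------------------------------------------
# Strain tagging
# ---------------------------------------------------------------------------

def _extracellular_compartment(model: MetabolicModel) -> str:
    comps = {
        next(iter(rxn.stoichiometry))[1]
        for rxn in model.reactions.values()
        if rxn.kind == "exchange"
    }
    if len(comps) != 1:
        raise ModelStructureError(
            f"model {model.id!r}: cannot identify a unique extracellular "
            f"compartment from its exchange reactions (found {sorted(comps)})"
        )
    return comps.pop()


def _biomass_reaction(model: MetabolicModel) -> Reaction:
    bios = [r for r in model.reactions.values() if r.kind == "biomass"]
    if len(bios) != 1:
        raise ModelStructureError(
            f"model {model.id!r}: expected exactly one biomass reaction, "
            f"found {len(bios)}"
        )
    return bios[0]


def tag_strain_model(model: MetabolicModel, strain: str) -> MetabolicModel:
    """Rewrite a single-strain model for community membership.

    Reaction ids gain a ``strain_`` prefix; the extracellular compartment is
    renamed to ``c_<strain>`` (other compartments to ``<strain>_<tag>``);
    every formerly exchanged metabolite gains a reversible IEX transport
    ``<strain>_IEX_<m>[u]tr`` into the shared lumen, positive in the
    secretion direction, and the strain-level exchange reactions are removed.
    Products of the biomass reaction stay private to the strain (they are
    drained by the community biomass reaction, not the lumen).
    """
    if model.metadata.get("strain_tag"):
        raise ModelStructureError(
            f"model {model.id!r} is already tagged for strain "
            f"{model.metadata['strain_tag']!r}"
        )
    exchanges = [r for r in model.reactions.values() if r.kind == "exchange"]
    if not exchanges:
        raise ModelStructureError(
            f"model {model.id!r} has no exchange reactions to rewire"
        )
    ext = _extracellular_compartment(model)
    biomass = _biomass_reaction(model)
    biomass_products = {k for k, c in biomass.stoichiometry.items() if c > 0}

    comp_map = {}
    for tag in model.compartments:
        new = f"c_{strain}" if tag == ext else f"{strain}_{tag}"
        if new in comp_map.values():
            raise ModelStructureError(
                f"model {model.id!r}: compartment rename collision on {new!r}"
            )
        comp_map[tag] = new

    out = MetabolicModel(id=f"{strain}", metadata=dict(model.metadata))
    out.metadata["strain_tag"] = strain
    for tag, name in sorted(model.compartments.items()):
        out.add_compartment(comp_map[tag], name)
    out.add_compartment(LUMEN, "lumen")
    for key in sorted(model.metabolites):
        met = model.metabolites[key]
        out.add_metabolite(
            Metabolite(met.id, comp_map[met.compartment], met.name, met.subsystem)
        )

    iex: dict[str, str] = {}
    for rid in model.reaction_ids():
        rxn = model.reactions[rid]
        if rxn.kind == "exchange":
            (mid, comp), _ = next(iter(rxn.stoichiometry.items()))
            if (mid, comp) in biomass_products:
                continue  # biomass species: no lumen route
            if (mid, LUMEN) not in out.metabolites:
                src = model.metabolites[(mid, comp)]
                out.add_metabolite(
                    Metabolite(mid, LUMEN, src.name, src.subsystem)
                )
            iex_id = f"{strain}_IEX_{mid}[{LUMEN}]tr"
            if iex_id in out.reactions:
                raise ModelStructureError(f"IEX id collision: {iex_id!r}")
            out.add_reaction(Reaction(
                iex_id,
                {(mid, comp_map[comp]): -1.0, (mid, LUMEN): 1.0},
                lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND, kind="transport",
            ))
            iex[mid] = iex_id
            continue
        new_id = f"{strain}_{rid}"
        if new_id in out.reactions:
            raise ModelStructureError(f"reaction id collision: {new_id!r}")
        out.add_reaction(Reaction(
            new_id,
            {(mid, comp_map[comp]): coef
             for (mid, comp), coef in rxn.stoichiometry.items()},
            lb=rxn.lb, ub=rxn.ub, kind=rxn.kind,
        ))
    out.metadata["iex_reactions"] = iex
    out.metadata["biomass_reaction"] = f"{strain}_{biomass.id}"
    out.metadata["extracellular"] = f"c_{strain}"
    return out


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def _lumen_plumbing(community: CommunityModel, mid: str) -> None:
    """Add diet/fecal species and the EX/DUt/UFEt/EX quartet for one lumen
    metabolite. Diet exchanges start closed; :func:`apply_diet` opens them."""
    src = community.metabolites[(mid, LUMEN)]
    for comp in (DIET, FECAL):
        community.add_metabolite(Metabolite(mid, comp, src.name, src.subsystem))
    community.add_reaction(Reaction(
        f"EX_{mid}[{DIET}]", {(mid, DIET): -1.0}, lb=0.0, ub=0.0,
        kind="exchange",
    ))
    community.add_reaction(Reaction(
        f"DUt_{mid}", {(mid, DIET): -1.0, (mid, LUMEN): 1.0},
        lb=0.0, ub=DEFAULT_BOUND, kind="transport",
    ))
    community.add_reaction(Reaction(
        f"UFEt_{mid}", {(mid, LUMEN): -1.0, (mid, FECAL): 1.0},
        lb=0.0, ub=DEFAULT_BOUND, kind="transport",
    ))
    community.add_reaction(Reaction(
        f"EX_{mid}[{FECAL}]", {(mid, FECAL): -1.0}, lb=0.0, ub=DEFAULT_BOUND,
        kind="exchange",
    ))


def assemble_community(
    models: dict[str, MetabolicModel] | list[MetabolicModel],
    profile: AbundanceProfile,
    config: CommunityConfig | None = None,
) -> CommunityModel:
    """Build the multi-compartment community model for one sample.

    ``models`` maps strain id to its (untagged) model; a list is accepted and
    keyed by model id. The profile must already be filtered/renormalised.
    """
    config = config or CommunityConfig()
    if isinstance(models, list):
        models = {m.id: m for m in models}
    if not profile.filtered:
        raise ValidationError(
            f"sample {profile.sample_id!r}: profile must be filtered and "
            "renormalised before assembly (see filter_and_renormalize)"
        )
    missing = [s for s in profile.strains() if s not in models]
    if missing:
        raise ModelStructureError(
            f"sample {profile.sample_id!r}: no model supplied for retained "
            f"strains: {missing}"
        )

    community = CommunityModel(id=f"community_{profile.sample_id}")
    community.metadata["sample_id"] = profile.sample_id
    community.metadata["units"] = "mmol/day (community exchange layer)"
    community.metadata["config"] = {
        "cutoff": config.cutoff,
        "coupling_factor": config.coupling_factor,
        "coupling_slack": config.coupling_slack,
        "biomass_bounds": list(config.biomass_bounds),
        "objective_fraction": config.objective_fraction,
    }
    for comp, name in ((LUMEN, "lumen"), (DIET, "diet"), (FECAL, "fecal")):
        community.add_compartment(comp, name)

    biomass_terms: dict[tuple[str, str], float] = {}
    for strain in profile.strains():
        tagged = tag_strain_model(models[strain], strain)
        for tag, name in sorted(tagged.compartments.items()):
            community.add_compartment(tag, name)
        for key in sorted(tagged.metabolites):
            if key not in community.metabolites:
                community.add_metabolite(tagged.metabolites[key])
        for rid in tagged.reaction_ids():
            community.add_reaction(tagged.reactions[rid].copy())
        bio_id = tagged.metadata["biomass_reaction"]
        bio = community.reactions[bio_id]
        products = {k for k, c in bio.stoichiometry.items() if c > 0}
        if not products:
            # pure-drain biomass: give it an explicit species to weight
            key = ("biomass", f"c_{strain}")
            if key not in community.metabolites:
                community.add_metabolite(
                    Metabolite("biomass", f"c_{strain}", "biomass")
                )
            bio.stoichiometry[key] = 1.0
            products = {key}
        if len(products) != 1:
            raise ModelStructureError(
                f"strain {strain!r}: biomass reaction {bio_id!r} must "
                "produce exactly one biomass species"
            )
        abundance = profile.abundances[strain]
        biomass_terms[products.pop()] = -abundance
        community.strain_registry[strain] = StrainRecord(
            compartment=tagged.metadata["extracellular"],
            reaction_ids=tagged.reaction_ids(),
            biomass_reaction=bio_id,
            iex_reactions=dict(tagged.metadata["iex_reactions"]),
            abundance=abundance,
        )

    for mid in community.lumen_metabolites():
        _lumen_plumbing(community, mid)

    # community biomass layer
    community.add_metabolite(Metabolite(COMMUNITY_BIOMASS_MET, LUMEN,
                                        "community biomass"))
    community.add_metabolite(Metabolite(COMMUNITY_BIOMASS_MET, FECAL,
                                        "community biomass"))
    stoich = dict(biomass_terms)
    stoich[(COMMUNITY_BIOMASS_MET, LUMEN)] = 1.0
    community.add_reaction(Reaction(
        COMMUNITY_BIOMASS_RXN, stoich,
        lb=config.biomass_bounds[0], ub=config.biomass_bounds[1],
        kind="biomass",
    ))
    community.add_reaction(Reaction(
        f"UFEt_{COMMUNITY_BIOMASS_MET}",
        {(COMMUNITY_BIOMASS_MET, LUMEN): -1.0,
         (COMMUNITY_BIOMASS_MET, FECAL): 1.0},
        lb=0.0, ub=DEFAULT_BOUND, kind="transport",
    ))
    community.add_reaction(Reaction(
        f"EX_{COMMUNITY_BIOMASS_MET}[{FECAL}]",
        {(COMMUNITY_BIOMASS_MET, FECAL): -1.0},
        lb=0.0, ub=DEFAULT_BOUND, kind="exchange",
    ))
    community.objective = {f"EX_{COMMUNITY_BIOMASS_MET}[{FECAL}]": 1.0}

    groups = {
        strain: (
            rec.reaction_ids + sorted(rec.iex_reactions.values()),
            rec.biomass_reaction,
        )
        for strain, rec in community.strain_registry.items()
    }
    coupled = add_flux_coupling(
        community, groups, c=config.coupling_factor, u=config.coupling_slack
    )
    community.couplings = coupled.couplings
    community.validate()
    return community


def apply_diet(
    community: CommunityModel,
    diet: DietFluxVector,
    supplement_policy: SupplementPolicy | None = None,
) -> CommunityModel:
    """Constrain the diet exchange layer to a diet flux vector.

    For each diet metabolite with a lumen counterpart the diet exchange gets
    ``lb = -flux, ub = 0`` (negative flux = inflow); lumen metabolites absent
    from the diet stay closed unless the supplement policy opens them at a
    trace flux. Diet entries with no lumen counterpart are skipped with a
    warning. Fecal exchanges remain open above zero.
    """
    out = community.copy()
    effective = diet.copy()
    if supplement_policy is not None:
        effective = supplement_micronutrients(
            effective, community,
            epsilon=supplement_policy.epsilon,
            essential=supplement_policy.essential,
        )
    skipped = []
    lumen = set(out.lumen_metabolites())
    for met, flux in effective.items():
        if flux < 0:
            raise ValidationError(f"negative diet flux for {met!r}")
        if met not in lumen:
            skipped.append(met)
            continue
        ex = out.reactions[f"EX_{met}[{DIET}]"]
        ex.lb, ex.ub = -float(flux), 0.0
    for met in sorted(lumen - set(effective.fluxes)):
        ex = out.reactions[f"EX_{met}[{DIET}]"]
        ex.lb, ex.ub = 0.0, 0.0
    if skipped:
        logger.warning(
            "diet: skipped %d metabolites with no lumen counterpart: %s",
            len(skipped), ", ".join(skipped),
        )
    out.metadata["diet"] = {m: f for m, f in effective.items()}
    out.metadata["diet_skipped"] = skipped
    return out
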