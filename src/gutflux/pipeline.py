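"""Per-sample FVA profiling of a community model.

For every metabolite exchanged with the environment the pipeline reports the
four FVA primitives — maximal/minimal fecal secretion and maximal/minimal
diet uptake — plus the derived net secretion and net uptake, classifies each
metabolite's overall role across samples, sums positive net secretion by
metabolism subsystem, attributes production to individual strains via their
IEX transport fluxes, and computes the Shannon alpha-diversity of the
abundance profile.

Sign conventions (all primitives are emitted so either reading of the
verbal net-flux definition can be reconstructed):

* ``max_secretion`` / ``min_secretion``: max/min flux of ``EX_m[fe]`` (>= 0).
* ``max_uptake``: the *signed* minimum flux of ``EX_m[d]`` (<= 0, most
  negative = strongest draw); ``min_uptake``: the maximum flux of
  ``EX_m[d]`` (the least-required draw).
* ``net_secretion = max_secretion + max_uptake`` (signed sum).
* ``net_uptake = |max_uptake| + min_secretion``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .community import (
    DIET,
    FECAL,
    AbundanceProfile,
    CommunityConfig,
    CommunityModel,
    SupplementPolicy,
    apply_diet,
)
from .core import InfeasibleModelError, run_fva
from .diet import DietFluxVector

__all__ = [
    "NetFluxRecord",
    "ContributionRecord",
    "SubsystemSummary",
    "simulate_sample",
    "classify_exchange_roles",
    "subsystem_totals",
    "strain_contributions",
    "shannon",
    "ROLE_TOL",
]

logger = logging.getLogger(__name__)

#: net fluxes below this magnitude count as zero for role classification
ROLE_TOL = 1e-6


@dataclass
class NetFluxRecord:
    """FVA summary for one metabolite in one sample (mmol/day)."""

    sample_id: str
    metabolite: str
    max_secretion: float
    min_secretion: float
    max_uptake: float  # signed (<= 0): min flux of the diet exchange
    min_uptake: float  # max flux of the diet exchange
    net_secretion: float
    net_uptake: float


@dataclass
class ContributionRecord:
    """One strain's attainable IEX secretion of one metabolite."""

    sample_id: str
    metabolite: str
    strain: str
    min_flux: float
    max_flux: float
    share: float


#: sample_id -> {subsystem -> summed positive net secretion}
SubsystemSummary = dict[str, dict[str, float]]


def simulate_sample(
    community: CommunityModel,
    diet: DietFluxVector | None = None,
    config: CommunityConfig | None = None,
) -> list[NetFluxRecord]:
    """Joint FVA over all diet and fecal exchanges of one community.

    ``diet`` is applied first when given (otherwise the community must
    already carry its diet bounds). One record per lumen metabolite with
    both exchanges, ordered lexicographically.
    """
    config = config or CommunityConfig()
    if diet is not None:
        community = apply_diet(community, diet, config.supplement)
    sample_id = community.metadata.get("sample_id", community.id)
    mets = community.exchanged_metabolites()
    if not mets:
        logger.warning("community %s has no exchanged metabolites", community.id)
        return []
    targets = [f"EX_{m}[{FECAL}]" for m in mets] + [f"EX_{m}[{DIET}]" for m in mets]
    try:
        fva = run_fva(
            community, targets, objective_fraction=config.objective_fraction
        )
    except InfeasibleModelError as err:
        raise InfeasibleModelError(
            f"sample {sample_id!r}: community model infeasible under the "
            f"applied diet; community biomass bounds "
            f"{config.biomass_bounds} may demand more substrate than the "
            f"diet supplies ({err})"
        ) from err
    records = []
    for m in mets:
        fe_min, fe_max = fva[f"EX_{m}[{FECAL}]"]
        d_min, d_max = fva[f"EX_{m}[{DIET}]"]
        records.append(NetFluxRecord(
            sample_id=sample_id,
            metabolite=m,
            max_secretion=fe_max,
            min_secretion=fe_min,
            max_uptake=d_min,
            min_uptake=d_max,
            net_secretion=fe_max + d_min,
            net_uptake=abs(d_min) + fe_min,
        ))
    return records


def classify_exchange_roles(
    records: list[NetFluxRecord], tol: float = ROLE_TOL
) -> dict[str, str]:
    """Assign each metabolite one of four exchange roles across all samples.

    ``secreted_only`` / ``uptake_only`` / ``both`` / ``inert`` according to
    whether net secretion and/or net uptake exceed ``tol`` in at least one
    sample; the four classes partition the metabolite universe.
    """
    secreted: dict[str, bool] = {}
    taken_up: dict[str, bool] = {}
    for rec in records:
        secreted[rec.metabolite] = (
            secreted.get(rec.metabolite, False) or rec.net_secretion > tol
        )
        taken_up[rec.metabolite] = (
            taken_up.get(rec.metabolite, False) or rec.net_uptake > tol
        )
    roles = {}
    for met in sorted(secreted):
        if secreted[met] and taken_up[met]:
            roles[met] = "both"
        elif secreted[met]:
            roles[met] = "secreted_only"
        elif taken_up[met]:
            roles[met] = "uptake_only"
        else:
            roles[met] = "inert"
    return roles


def subsystem_totals(
    records: list[NetFluxRecord],
    subsystem_map: dict[str, str] | None = None,
) -> SubsystemSummary:
    """Sum positive net secretion per metabolism subsystem, per sample.

    Metabolites missing from ``subsystem_map`` fall into ``"other"`` (the
    count is logged once per call).
    """
    subsystem_map = subsystem_map or {}
    totals: SubsystemSummary = {}
    unmapped = set()
    for rec in records:
        sub = subsystem_map.get(rec.metabolite)
        if sub is None:
            unmapped.add(rec.metabolite)
            sub = "other"
        sample = totals.setdefault(rec.sample_id, {})
        sample.setdefault(sub, 0.0)
        if rec.net_secretion > 0:
            sample[sub] += rec.net_secretion
    if unmapped:
        logger.warning(
            "%d metabolites without subsystem assignment counted as 'other': %s",
            len(unmapped), ", ".join(sorted(unmapped)),
        )
    return totals


def strain_contributions(
    community: CommunityModel,
    diet: DietFluxVector | None = None,
    metabolite: str | None = None,
    config: CommunityConfig | None = None,
) -> list[ContributionRecord]:
    """FVA of every strain's IEX flux for one metabolite, secretion positive.

    The share is each strain's positive maximal secretion over the sum of
    positive maxima; strains that cannot secrete (max <= 0) get share 0.
    """
    config = config or CommunityConfig()
    if metabolite is None:
        raise ValueError("metabolite is required")
    if diet is not None:
        community = apply_diet(community, diet, config.supplement)
    sample_id = community.metadata.get("sample_id", community.id)
    if (metabolite, "u") not in community.metabolites and not any(
        metabolite in rec.iex_reactions
        for rec in community.strain_registry.values()
    ):
        raise KeyError(f"unknown community metabolite {metabolite!r}")
    carriers = sorted(
        (strain, rec.iex_reactions[metabolite])
        for strain, rec in community.strain_registry.items()
        if metabolite in rec.iex_reactions
    )
    if not carriers:
        return []
    fva = run_fva(
        community,
        [iex for _, iex in carriers],
        objective_fraction=config.objective_fraction,
    )
    positive_total = sum(
        max(0.0, fva[iex][1]) for _, iex in carriers
    )
    records = []
    for strain, iex in carriers:
        vmin, vmax = fva[iex]
        share = (
            max(0.0, vmax) / positive_total if positive_total > 0 else 0.0
        )
        records.append(ContributionRecord(
            sample_id=sample_id,
            metabolite=metabolite,
            strain=strain,
            min_flux=vmin,
            max_flux=vmax,
            share=share,
        ))
    return records


def shannon(profile: AbundanceProfile) -> float:
    """Shannon alpha diversity ``H = -sum a ln a`` (natural log).

    Zero abundances are ignored (the ``0 ln 0 := 0`` limit convention); the
    fractions must sum to 1.
    """
    total = profile.total()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"sample {profile.sample_id!r}: abundances sum to {total}, not 1 "
            "(filter_and_renormalize first)"
        )
    h = 0.0
    for frac in profile.abundances.values():
        if frac < 0:
            raise ValueError("negative abundance")
        if frac > 0:
            h -= frac * math.log(frac)
    return h
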