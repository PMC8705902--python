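"""Synthetic strains, abundance series, diets and clinical series.

Every pipeline stage is testable without any external model collection or
sequencing data: small chain-topology strain models (uptake -> conversion ->
secretion, plus a biomass demand) have analytically known community FVA
answers, the abundance series mirror the 7-timepoint longitudinal study
design with one monotonically increasing producer (a *B. longum*-like folate
secretor) and one decreasing producer (a *B. timonensis*-like secretor of a
branched-chain ketoacid), and clinical series are built by constructing rank
permutations at an exact squared rank distance so the planted Spearman
correlation is attained exactly.

The default scenario: 10 strains (two producers, one strain planted below
the 0.1% abundance cutoff, the rest inert glucose consumers), a diet fixed
across timepoints supplying glucose for growth plus the two precursors in
excess, so the flux-coupling cap ``c * a_k * mu + u`` is the binding
constraint and the planted net-secretion series inherit the producers'
abundance trends.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .community import AbundanceProfile, CommunityConfig, filter_and_renormalize
from .core import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .diet import DietFluxVector
from .stats import ClinicalSeries

__all__ = [
    "StrainTemplateSpec",
    "ScenarioBundle",
    "generate_strain_template",
    "generate_scenario",
    "generate_clinical",
    "analytic_net_secretion",
    "random_lp_model",
    "attainable_rho",
    "PRODUCT_INC",
    "PRODUCT_DEC",
]

#: planted metabolite whose secretion rises over the intervention
PRODUCT_INC = "fol"
#: planted metabolite whose secretion falls over the intervention
PRODUCT_DEC = "3mop"

GROWTH_SUBSTRATE = "glc"
BIOMASS_DEMAND = 0.1  # mol substrate per unit biomass
GROWTH_SUPPLY = 10.0  # mmol/day
PRECURSOR_SUPPLY = 200.0  # mmol/day, in excess so coupling caps bind

_SUBSYSTEM_OF = {
    PRODUCT_INC: "vitamin and cofactor metabolism",
    PRODUCT_DEC: "amino acid metabolism",
    GROWTH_SUBSTRATE: "carbohydrate metabolism",
}


@dataclass
class StrainTemplateSpec:
    """Blueprint for a chain-topology toy strain.

    Each product is made from ``conversion_substrate`` (default: the last
    substrate) at its stated molar yield; biomass consumes the first
    substrate at ``biomass_substrate_demand`` per unit of biomass flux.
    """

    name: str
    substrates: list[str]
    products: list[str] = field(default_factory=list)
    yields: dict[str, float] = field(default_factory=dict)
    biomass_substrate_demand: float = BIOMASS_DEMAND
    reversible_conversions: bool = False
    conversion_substrate: str | None = None

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValueError(f"strain {self.name!r}: at least one substrate")
        for product, y in self.yields.items():
            if y < 0:
                raise ValueError(
                    f"strain {self.name!r}: negative yield for {product!r}"
                )
        if self.biomass_substrate_demand < 0:
            raise ValueError(f"strain {self.name!r}: negative biomass demand")


def generate_strain_template(spec: StrainTemplateSpec) -> MetabolicModel:
    """Build the FBA-solvable strain model for a template spec.

    Compartments ``c`` (cytosol) and ``e`` (extracellular); exchange and
    transport for every substrate and product; one conversion per product;
    a biomass reaction producing a private biomass species (objective).
    """
    model = MetabolicModel(id=spec.name)
    model.add_compartment("c", "cytosol")
    model.add_compartment("e", "extracellular")
    csub = spec.conversion_substrate or spec.substrates[-1]
    if csub not in spec.substrates:
        raise ValueError(
            f"strain {spec.name!r}: conversion substrate {csub!r} is not a "
            "declared substrate"
        )
    species = list(dict.fromkeys(spec.substrates + spec.products))
    for mid in species:
        sub = _SUBSYSTEM_OF.get(mid, "other")
        for comp in ("c", "e"):
            model.add_metabolite(Metabolite(mid, comp, mid, sub))
        model.add_reaction(Reaction(
            f"EX_{mid}", {(mid, "e"): -1.0},
            lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND, kind="exchange",
        ))
        model.add_reaction(Reaction(
            f"T_{mid}", {(mid, "e"): -1.0, (mid, "c"): 1.0},
            lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND, kind="transport",
        ))
    for product in spec.products:
        y = spec.yields.get(product, 1.0)
        stoich = {(csub, "c"): -1.0}
        if y > 0:
            stoich[(product, "c")] = y
        model.add_reaction(Reaction(
            f"CONV_{product}", stoich,
            lb=-DEFAULT_BOUND if spec.reversible_conversions else 0.0,
            ub=DEFAULT_BOUND, kind="internal",
        ))
    model.add_metabolite(Metabolite("biomass", "e", "biomass"))
    bio_stoich: dict[tuple[str, str], float] = {("biomass", "e"): 1.0}
    if spec.biomass_substrate_demand > 0:
        bio_stoich[(spec.substrates[0], "c")] = -spec.biomass_substrate_demand
    model.add_reaction(Reaction(
        "BIO", bio_stoich, lb=0.0, ub=DEFAULT_BOUND, kind="biomass",
    ))
    model.add_reaction(Reaction(
        "EX_biomass", {("biomass", "e"): -1.0},
        lb=0.0, ub=DEFAULT_BOUND, kind="exchange",
    ))
    model.objective = {"BIO": 1.0}
    model.metadata["template"] = {
        "kind": "chain",
        "substrates": list(spec.substrates),
        "products": list(spec.products),
        "yields": {p: spec.yields.get(p, 1.0) for p in spec.products},
        "conversion_substrate": csub,
        "biomass_substrate_demand": spec.biomass_substrate_demand,
    }
    return model


# ---------------------------------------------------------------------------
# Rank permutations at an exact Spearman rho
# ---------------------------------------------------------------------------

def attainable_rho(n: int, rho: float) -> tuple[float, int]:
    """Snap ``rho`` to the discrete lattice attainable at ``n`` (tie-free).

    Returns ``(rho_attained, sum_d2)`` where ``sum_d2`` is the even squared
    rank distance realising it; warns when snapping moves the value.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    denom = n * (n * n - 1)
    s_exact = denom * (1.0 - rho) / 6.0
    s = int(round(s_exact / 2.0)) * 2
    s = min(max(s, 0), denom // 3)
    attained = 1.0 - 6.0 * s / denom
    if abs(attained - rho) > 1e-9:
        warnings.warn(
            f"target rho {rho} not attainable at n={n}; using nearest "
            f"attainable {attained:.6f}",
            stacklevel=2,
        )
    return attained, s


def _permutation_at_d2(ref_ranks: np.ndarray, s: int,
                       rng: np.random.Generator) -> np.ndarray:
    """A permutation of 1..n with squared rank distance ``s`` from
    ``ref_ranks`` (exact; enumeration for small n, local search otherwise)."""
    n = ref_ranks.size
    ref = np.asarray(ref_ranks, dtype=int)
    if n <= 8:
        for perm in permutations(range(1, n + 1)):
            if int(np.sum((np.array(perm) - ref) ** 2)) == s:
                return np.array(perm)
        raise ValueError(f"no permutation of 1..{n} at squared distance {s}")
    # stochastic pair-swap search; every even s in range is reachable
    current = ref.copy()
    d2 = 0
    for _ in range(200000):
        if d2 == s:
            return current
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        new_d2 = d2 - (current[i] - ref[i]) ** 2 - (current[j] - ref[j]) ** 2 \
            + (current[j] - ref[i]) ** 2 + (current[i] - ref[j]) ** 2
        if abs(new_d2 - s) <= abs(d2 - s) and rng.random() < 0.9:
            current[i], current[j] = current[j], current[i]
            d2 = new_d2
    raise RuntimeError(f"could not reach squared distance {s} at n={n}")


def generate_clinical(
    n_timepoints: int,
    targets: list[tuple[str, str, float]],
    seed: int,
    references: dict[str, np.ndarray] | None = None,
    extra_noise_parameters: list[str] = ("TNFa",),
) -> tuple[ClinicalSeries, dict[str, np.ndarray]]:
    """Clinical series with planted rank correlations against references.

    ``targets`` lists ``(parameter, reference name, rho)``; each parameter's
    values follow a rank permutation at the exact squared rank distance
    realising the (nearest attainable) rho against the reference series.
    When ``references`` is None a strictly increasing synthetic series is
    drawn for each referenced name. Parameters in
    ``extra_noise_parameters`` (and any of BMI/leptin/adiponectin not
    targeted) get independent random permutations.

    Returns the ClinicalSeries and the reference (metabolite) series used.
    """
    if n_timepoints < 4:
        raise ValueError("need at least 4 timepoints")
    rng = np.random.default_rng(seed)
    timepoints = [f"day{i}" for i in range(n_timepoints)]
    if references is None:
        references = {}
        for _, ref_name, _ in targets:
            if ref_name not in references:
                base = np.sort(rng.uniform(1.0, 10.0, size=n_timepoints))
                references[ref_name] = base
    params: dict[str, list[float]] = {}
    from scipy.stats import rankdata

    for name, ref_name, rho in targets:
        ref_series = np.asarray(references[ref_name], dtype=float)
        ref_ranks = rankdata(ref_series).astype(int)
        _, s = attainable_rho(n_timepoints, rho)
        perm = _permutation_at_d2(ref_ranks, s, rng)
        base = 10.0 + 2.0 * perm + rng.uniform(-0.4, 0.4, size=n_timepoints)
        params[name] = [float(v) for v in base]
    defaults = ["BMI", "leptin", "adiponectin", *extra_noise_parameters]
    for name in defaults:
        if name in params:
            continue
        perm = rng.permutation(n_timepoints) + 1
        base = 10.0 + 2.0 * perm + rng.uniform(-0.4, 0.4, size=n_timepoints)
        params[name] = [float(v) for v in base]
    clinical = ClinicalSeries(timepoints=timepoints, parameters=params)
    return clinical, references


# ---------------------------------------------------------------------------
# Scenario bundles
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """A complete synthetic study with analytically known answers."""

    models: dict[str, MetabolicModel]
    profiles: list[AbundanceProfile]
    diet: DietFluxVector
    clinical: ClinicalSeries
    truth: dict
    seed: int
    config: CommunityConfig

    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]


def _default_strains(n_strains: int) -> tuple[list[str], str, str, str | None]:
    """Strain name roster: (all, increasing producer, decreasing producer,
    below-cutoff strain or None)."""
    inc = "B_longum_synth"
    if n_strains == 1:
        return [inc], inc, "", None
    dec = "B_timonensis_synth"
    names = [inc, dec]
    rare = None
    if n_strains >= 4:
        rare = "rare_strain_synth"
    n_inert = n_strains - len(names) - (1 if rare else 0)
    names += [f"inert_{i:02d}" for i in range(n_inert)]
    if rare:
        names.append(rare)
    return names, inc, dec, rare


def generate_scenario(
    n_strains: int = 10,
    n_timepoints: int = 7,
    seed: int = 0,
    config: CommunityConfig | None = None,
    clinical_targets: list[tuple[str, str, float]] | None = None,
) -> ScenarioBundle:
    """Generate the default longitudinal community scenario.

    Deterministic for a given ``(seed, arguments)``; the planted truth
    (producer per metabolite, expected net secretion per sample, clinical
    targets) is stored in ``bundle.truth``.
    """
    if n_strains < 1:
        raise ValueError("need at least one strain")
    if n_timepoints < 4:
        raise ValueError("need at least 4 timepoints")
    config = config or CommunityConfig()
    rng = np.random.default_rng(seed)
    names, inc, dec, rare = _default_strains(n_strains)

    models: dict[str, MetabolicModel] = {}
    for name in names:
        if name == inc:
            spec = StrainTemplateSpec(
                name, substrates=[GROWTH_SUBSTRATE, "fol_pre"],
                products=[PRODUCT_INC], yields={PRODUCT_INC: 1.0},
            )
        elif name == dec:
            spec = StrainTemplateSpec(
                name, substrates=[GROWTH_SUBSTRATE, "mop_pre"],
                products=[PRODUCT_DEC], yields={PRODUCT_DEC: 1.0},
            )
        else:
            spec = StrainTemplateSpec(name, substrates=[GROWTH_SUBSTRATE])
        models[name] = generate_strain_template(spec)

    # abundance series: increasing / decreasing producers, constant inerts
    inc_series = np.linspace(0.05, 0.25, n_timepoints)
    dec_series = np.linspace(0.25, 0.05, n_timepoints)
    rare_abundance = 5e-4
    profiles = []
    inert_names = [n for n in names if n not in (inc, dec, rare)]
    weights = rng.uniform(0.5, 1.5, size=len(inert_names))
    weights = weights / weights.sum() if len(inert_names) else weights
    for t in range(n_timepoints):
        ab: dict[str, float] = {}
        if n_strains == 1:
            ab[inc] = 1.0
        else:
            ab[inc] = float(inc_series[t])
            ab[dec] = float(dec_series[t])
            remaining = 1.0 - ab[inc] - ab[dec]
            if rare:
                ab[rare] = rare_abundance
                remaining -= rare_abundance
            for name, w in zip(inert_names, weights):
                ab[name] = float(remaining * w)
        profiles.append(AbundanceProfile(sample_id=f"day{t}", abundances=ab))

    diet = DietFluxVector({
        GROWTH_SUBSTRATE: GROWTH_SUPPLY,
        "fol_pre": PRECURSOR_SUPPLY,
        "mop_pre": PRECURSOR_SUPPLY,
    })

    truth: dict = {
        "template_kind": "chain",
        "producers": {PRODUCT_INC: inc},
        "precursors": {PRODUCT_INC: "fol_pre"},
        "yields": {PRODUCT_INC: 1.0},
        "below_cutoff_strains": [rare] if rare else [],
    }
    if n_strains >= 2:
        truth["producers"][PRODUCT_DEC] = dec
        truth["precursors"][PRODUCT_DEC] = "mop_pre"
        truth["yields"][PRODUCT_DEC] = 1.0

    bundle = ScenarioBundle(
        models=models, profiles=profiles, diet=diet,
        clinical=ClinicalSeries(timepoints=[p.sample_id for p in profiles]),
        truth=truth, seed=seed, config=config,
    )
    expected = analytic_net_secretion(bundle)
    truth["expected_net_secretion"] = {
        met: {s: float(expected.loc[s, met]) for s in expected.index}
        for met in expected.columns
    }

    if clinical_targets is None:
        # nearest attainable |rho| to 0.89 at this n (sum d^2 = 6 at n = 7)
        denom = n_timepoints * (n_timepoints ** 2 - 1)
        s = int(round(denom * (1 - 0.89) / 12.0)) * 2
        target_rho = 1.0 - 6.0 * s / denom
        clinical_targets = [("BMI", PRODUCT_INC, -target_rho)]
        if PRODUCT_DEC in truth["producers"]:
            clinical_targets += [
                ("leptin", PRODUCT_DEC, target_rho),
                ("adiponectin", PRODUCT_INC, target_rho),
            ]
    references = {
        met: np.array([series[s] for s in bundle.sample_ids()])
        for met, series in truth["expected_net_secretion"].items()
    }
    clinical, _ = generate_clinical(
        n_timepoints, clinical_targets, seed=seed, references=references,
    )
    bundle.clinical = clinical
    truth["clinical_targets"] = [
        [name, ref, float(rho)] for name, ref, rho in clinical_targets
    ]
    return bundle


def analytic_net_secretion(bundle: ScenarioBundle) -> pd.DataFrame:
    """Closed-form expected net secretion for the planted products.

    For a chain template the community-level maximal secretion of product
    ``p`` with precursor supply ``S``, molar yield ``y`` and coupling cap
    ``C = c * a_k * mu_max + u`` is ``min(y * min(S, C), C)`` — precursor
    uptake, conversion and IEX secretion are each confined to ``C`` while
    the community biomass runs at ``mu_max``. The product is absent from
    the diet, so this equals its net secretion.

    Only defined for bundles built from chain templates.
    """
    if bundle.truth.get("template_kind") != "chain":
        raise NotImplementedError(
            "no closed form for non-chain templates; use the brute-force "
            "LP oracle instead"
        )
    cfg = bundle.config
    c, u = cfg.coupling_factor, cfg.coupling_slack
    lo, hi = cfg.biomass_bounds
    glc_supply = bundle.diet[GROWTH_SUBSTRATE]
    mu_max = min(hi, glc_supply / BIOMASS_DEMAND)
    if mu_max < lo - 1e-12:
        raise ValueError("scenario diet cannot sustain the biomass lower bound")
    rows = {}
    for profile in bundle.profiles:
        filtered = filter_and_renormalize(profile, cfg.cutoff)
        row = {}
        for met, producer in sorted(bundle.truth["producers"].items()):
            y = bundle.truth["yields"][met]
            supply = bundle.diet[bundle.truth["precursors"][met]]
            a = filtered.abundances.get(producer, 0.0)
            if a == 0.0:
                row[met] = 0.0
                continue
            cap = c * a * mu_max + u
            row[met] = min(y * min(supply, cap), cap)
        rows[profile.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Random models for oracle cross-checks
# ---------------------------------------------------------------------------

def random_lp_model(
    rng: np.random.Generator,
    max_metabolites: int = 6,
    max_reactions: int = 8,
) -> MetabolicModel:
    """A random small stoichiometric model with finite, zero-straddling
    bounds and mixed reversibility (always feasible at v = 0)."""
    n_m = int(rng.integers(1, max_metabolites + 1))
    n_r = int(rng.integers(2, max_reactions + 1))
    model = MetabolicModel(id=f"random_{rng.integers(1 << 30)}")
    model.add_compartment("c", "cytosol")
    mets = [f"M{i}" for i in range(n_m)]
    for mid in mets:
        model.add_metabolite(Metabolite(mid, "c"))
    coefs = np.array([-2.0, -1.0, 1.0, 2.0])
    for j in range(n_r):
        if rng.random() < 0.4:  # boundary reaction
            mid = mets[int(rng.integers(n_m))]
            stoich = {(mid, "c"): -1.0}
            kind = "exchange"
        else:
            k = int(rng.integers(1, min(3, n_m) + 1))
            chosen = rng.choice(n_m, size=k, replace=False)
            stoich = {
                (mets[int(i)], "c"): float(rng.choice(coefs)) for i in chosen
            }
            kind = "internal"
        reversible = rng.random() < 0.5
        lb = float(rng.choice([-10.0, -5.0])) if reversible else 0.0
        ub = float(rng.choice([5.0, 10.0]))
        model.add_reaction(Reaction(f"R{j}", stoich, lb=lb, ub=ub, kind=kind))
    model.objective = {"R0": 1.0}
    return model
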