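"""Stoichiometric model representation and the FBA/FVA engine.

A :class:`MetabolicModel` holds metabolites (keyed by ``(id, compartment)``),
bounded reactions, an objective and optional flux-coupling constraints.
Flux balance analysis (FBA) maximises or minimises the objective flux subject
to steady-state mass balance ``S v = 0`` and the flux bounds; flux variability
analysis (FVA) reports the attainable min/max flux of each requested reaction,
optionally while holding the objective at a fraction of its optimum.

Coupling constraints tie the magnitude of a reaction's flux to an anchor
(biomass) flux, ``|v| <= c * v_anchor + u``, which is what prevents organisms
with zero growth from carrying flux in community models.

All linear programs are solved with the HiGHS solver through
:func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "CouplingConstraint",
    "MetabolicModel",
    "LPSolution",
    "FVARange",
    "ModelStructureError",
    "ValidationError",
    "InfeasibleModelError",
    "build_stoichiometric_matrix",
    "solve_fba",
    "run_fva",
    "add_flux_coupling",
    "DEFAULT_BOUND",
    "FLUX_TOL",
]

#: default magnitude used for "unbounded" reaction bounds
DEFAULT_BOUND = 1000.0

#: absolute feasibility / optimality tolerance on fluxes
FLUX_TOL = 1e-6

REACTION_KINDS = ("internal", "exchange", "transport", "biomass")

SUBSYSTEMS = (
    "amino acid metabolism",
    "vitamin and cofactor metabolism",
    "carbohydrate metabolism",
    "lipid metabolism",
    "nucleotide metabolism",
    "inorganic",
    "central metabolism",
    "other",
)


class ModelStructureError(ValueError):
    """A reaction references undeclared metabolites/compartments, ids collide, etc."""


class ValidationError(ValueError):
    """A numeric field violates its contract (e.g. inverted flux bounds)."""


class InfeasibleModelError(RuntimeError):
    """The base LP of a model is infeasible (or unbounded) where a solution is required."""


@dataclass(frozen=True)
class Metabolite:
    """One chemical species in one compartment.

    ``id`` follows the short VMH-style token convention (``fol``, ``thf``,
    ``3mop`` ...); ``subsystem`` is a coarse metabolism category used for
    secretion summaries.
    """

    id: str
    compartment: str
    name: str = ""
    subsystem: str = "other"

    @property
    def key(self) -> tuple[str, str]:
        return (self.id, self.compartment)

    def __str__(self) -> str:  # "fol[u]"
        return f"{self.id}[{self.compartment}]"


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps ``(metabolite id, compartment)`` to a nonzero
    coefficient; negative coefficients are consumed. ``kind`` distinguishes
    boundary exchanges (single species, coefficient -1; negative flux =
    uptake, positive = secretion), transports, biomass and plain internal
    conversions.
    """

    id: str
    stoichiometry: dict[tuple[str, str], float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    kind: str = "internal"

    def validate(self) -> None:
        if not self.id:
            raise ModelStructureError("reaction id must be non-empty")
        if self.kind not in REACTION_KINDS:
            raise ModelStructureError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )
        if self.lb > self.ub:
            raise ValidationError(
                f"reaction {self.id!r}: lb={self.lb} exceeds ub={self.ub}"
            )
        for key, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelStructureError(
                    f"reaction {self.id!r}: zero coefficient for {key}"
                )
        if self.kind == "exchange":
            if len(self.stoichiometry) != 1 or next(
                iter(self.stoichiometry.values())
            ) != -1:
                raise ModelStructureError(
                    f"exchange reaction {self.id!r} must have exactly one "
                    "entry with coefficient -1"
                )

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lb, self.ub, self.kind)


@dataclass(frozen=True)
class CouplingConstraint:
    """``v_coupled - c*v_anchor <= u`` and ``-v_coupled - c*v_anchor <= u``.

    With the anchor a biomass reaction this confines ``|v_coupled|`` to
    ``c * v_biomass + u``; defaults ``c=400``, ``u=0.01`` follow the common
    community-modelling convention.
    """

    coupled_reaction: str
    anchor_reaction: str
    factor: float = 400.0
    slack: float = 0.01

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise ValidationError(f"coupling factor must be >= 0, got {self.factor}")
        if self.slack < 0:
            raise ValidationError(f"coupling slack must be >= 0, got {self.slack}")


@dataclass
class LPSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]


#: reaction id -> (vmin, vmax)
FVARange = dict[str, tuple[float, float]]


@dataclass
class MetabolicModel:
    """A stoichiometric model for one strain or a whole community."""

    id: str
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: dict[tuple[str, str], Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    couplings: list[CouplingConstraint] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_compartment(self, tag: str, name: str = "") -> None:
        self.compartments.setdefault(tag, name or tag)

    def add_metabolite(self, met: Metabolite) -> None:
        if not met.id:
            raise ModelStructureError("metabolite id must be non-empty")
        if met.compartment not in self.compartments:
            raise ModelStructureError(
                f"metabolite {met}: compartment {met.compartment!r} is not "
                f"declared in model {self.id!r}"
            )
        if met.key in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite {met}")
        self.metabolites[met.key] = met

    def add_reaction(self, rxn: Reaction) -> None:
        rxn.validate()
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        for key in rxn.stoichiometry:
            if key not in self.metabolites:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references undeclared metabolite "
                    f"{key[0]}[{key[1]}]"
                )
        self.reactions[rxn.id] = rxn

    # -- queries -----------------------------------------------------------
    def metabolite_keys(self) -> list[tuple[str, str]]:
        return sorted(self.metabolites)

    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def exchanges(self) -> list[Reaction]:
        return [self.reactions[r] for r in self.reaction_ids()
                if self.reactions[r].kind == "exchange"]

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate()
            for key in rxn.stoichiometry:
                if key not in self.metabolites:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r} references undeclared metabolite "
                        f"{key[0]}[{key[1]}]"
                    )
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelStructureError(
                    f"objective references unknown reaction {rid!r}"
                )
        for cpl in self.couplings:
            for rid in (cpl.coupled_reaction, cpl.anchor_reaction):
                if rid not in self.reactions:
                    raise ModelStructureError(
                        f"coupling references unknown reaction {rid!r}"
                    )

    def copy(self, new_id: str | None = None) -> "MetabolicModel":
        return MetabolicModel(
            id=new_id or self.id,
            compartments=dict(self.compartments),
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective=dict(self.objective),
            couplings=list(self.couplings),
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel):
    """Return ``(S, metabolite_keys, reaction_ids)``.

    ``S`` is a CSC sparse matrix with one row per (metabolite, compartment)
    and one column per reaction, both in lexicographic order, so downstream
    outputs are byte-stable.
    """
    model.validate()
    met_keys = model.metabolite_keys()
    rxn_ids = model.reaction_ids()
    row_of = {k: i for i, k in enumerate(met_keys)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for key, coef in sorted(model.reactions[rid].stoichiometry.items()):
            rows.append(row_of[key])
            cols.append(j)
            vals.append(float(coef))
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_keys), len(rxn_ids))
    )
    return S, met_keys, rxn_ids


class _LPSystem:
    """The LP arrays of a model, built once and reused across FVA solves."""

    def __init__(self, model: MetabolicModel):
        self.S, self.met_keys, self.rxn_ids = build_stoichiometric_matrix(model)
        self.col_of = {r: j for j, r in enumerate(self.rxn_ids)}
        n = len(self.rxn_ids)
        self.bounds = [
            (model.reactions[r].lb, model.reactions[r].ub) for r in self.rxn_ids
        ]
        for (lb, ub), rid in zip(self.bounds, self.rxn_ids):
            if lb > ub:
                raise ValidationError(f"reaction {rid!r}: lb={lb} exceeds ub={ub}")
        # coupling rows: v_c - f*v_a <= u  and  -v_c - f*v_a <= u
        rows = []
        rhs = []
        for cpl in model.couplings:
            jc = self.col_of[cpl.coupled_reaction]
            ja = self.col_of[cpl.anchor_reaction]
            for sign in (1.0, -1.0):
                row = np.zeros(n)
                row[jc] = sign
                row[ja] += -cpl.factor
                rows.append(row)
                rhs.append(cpl.slack)
        self.A_ub = np.array(rows) if rows else None
        self.b_ub = np.array(rhs) if rhs else None
        self.objective_vector = np.zeros(n)
        for rid, coef in model.objective.items():
            self.objective_vector[self.col_of[rid]] += coef

    def solve(self, c: np.ndarray, sense: str) -> tuple[str, float, np.ndarray | None]:
        """Optimise ``c @ v``; returns (status, value, flux vector)."""
        sign = -1.0 if sense == "max" else 1.0
        if self.A_ub is not None:
            A_ub, b_ub = self.A_ub, self.b_ub
        else:
            A_ub, b_ub = None, None
        res = linprog(
            sign * c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=self.bounds,
            method="highs",
        )
        if res.status == 0:
            return "optimal", sign * res.fun, res.x
        if res.status == 2:
            return "infeasible", math.nan, None
        if res.status == 3:
            return "unbounded", math.inf if sense == "max" else -math.inf, None
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")

    def with_objective_floor(self, fraction: float, optimum: float) -> "_LPSystem":
        """Clone with the extra row ``objective >= fraction * optimum``."""
        clone = object.__new__(_LPSystem)
        clone.S, clone.met_keys, clone.rxn_ids = self.S, self.met_keys, self.rxn_ids
        clone.col_of = self.col_of
        clone.bounds = self.bounds
        clone.objective_vector = self.objective_vector
        row = -self.objective_vector[None, :]
        rhs = np.array([-fraction * optimum])
        if self.A_ub is not None:
            clone.A_ub = np.vstack([self.A_ub, row])
            clone.b_ub = np.concatenate([self.b_ub, rhs])
        else:
            clone.A_ub = row
            clone.b_ub = rhs
        return clone


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def solve_fba(model: MetabolicModel, sense: str = "max") -> LPSolution:
    """Flux balance analysis: optimise the model's objective flux.

    Raises :class:`ValidationError` before solving if any bound pair is
    inverted; solver infeasibility/unboundedness is reported in the returned
    status, never as a silent zero.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    if not model.reactions:
        raise ModelStructureError("model has no reactions")
    if not model.objective:
        raise ModelStructureError("model has no objective")
    lp = _LPSystem(model)
    status, value, x = lp.solve(lp.objective_vector, sense)
    fluxes = {}
    if x is not None:
        fluxes = {rid: float(x[j]) for j, rid in enumerate(lp.rxn_ids)}
    return LPSolution(status=status, objective_value=float(value), fluxes=fluxes)


def run_fva(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    objective_fraction: float = 0.0,
    _lp: "_LPSystem | None" = None,
) -> FVARange:
    """Flux variability analysis over ``reaction_ids`` (default: all).

    With ``objective_fraction`` (gamma) > 0 the objective flux is held at or
    above gamma times its FBA optimum while each reaction is minimised and
    maximised in turn.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    lp = _lp if _lp is not None else _LPSystem(model)
    if reaction_ids is None:
        reaction_ids = lp.rxn_ids
    for rid in reaction_ids:
        if rid not in lp.col_of:
            raise KeyError(f"unknown reaction {rid!r}")
    if objective_fraction > 0.0:
        if not model.objective:
            raise ModelStructureError(
                "objective_fraction > 0 requires a model objective"
            )
        status, opt, _ = lp.solve(lp.objective_vector, "max")
        if status != "optimal":
            raise InfeasibleModelError(
                f"base model {model.id!r} is {status}: cannot hold the "
                "objective near its optimum (check diet supply vs biomass "
                "bounds and flux couplings)"
            )
        lp = lp.with_objective_floor(objective_fraction, opt)
    n = len(lp.rxn_ids)
    out: FVARange = {}
    for rid in reaction_ids:
        c = np.zeros(n)
        c[lp.col_of[rid]] = 1.0
        smin, vmin, _ = lp.solve(c, "min")
        smax, vmax, _ = lp.solve(c, "max")
        if smin == "infeasible" or smax == "infeasible":
            raise InfeasibleModelError(
                f"model {model.id!r} infeasible during FVA of {rid!r} "
                "(bounds plus mass balance plus couplings admit no flux)"
            )
        out[rid] = (float(vmin), float(vmax))
    return out


def add_flux_coupling(
    model: MetabolicModel,
    strain_groups: dict[str, tuple[list[str], str]],
    c: float = 400.0,
    u: float = 0.01,
) -> MetabolicModel:
    """Couple each listed reaction to its strain's biomass anchor.

    ``strain_groups`` maps a strain label to ``(reaction ids, anchor id)``.
    Returns a new model; the input is untouched.
    """
    if c < 0:
        raise ValidationError(f"coupling factor c must be >= 0, got {c}")
    if u < 0:
        raise ValidationError(f"coupling slack u must be >= 0, got {u}")
    out = model.copy()
    for strain in sorted(strain_groups):
        rids, anchor = strain_groups[strain]
        if anchor not in out.reactions:
            raise ModelStructureError(
                f"strain {strain!r}: anchor reaction {anchor!r} does not exist"
            )
        for rid in rids:
            if rid not in out.reactions:
                raise ModelStructureError(
                    f"strain {strain!r}: coupled reaction {rid!r} does not exist"
                )
            if rid == anchor:
                continue
            out.couplings.append(
                CouplingConstraint(rid, anchor, factor=c, slack=u)
            )
    return out
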