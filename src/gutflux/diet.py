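"""From food-intake records to a quantitative diet flux vector.

The study diet is recorded as grams/day of ready-to-eat foods over three
intervention periods. Combining those intakes with a user-supplied
nutrient-composition table (mass fraction of each metabolite per gram of
food) and molar masses yields the mmol/day uptake allowance per metabolite
that constrains the community model's diet exchanges. The nutrient database
lookup itself is outside this package: the composition table is an input,
and foods missing from public databases are handled by simply adding rows
to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .community import CommunityModel

__all__ = [
    "FoodIntakeTable",
    "NutrientCompositionTable",
    "DietFluxVector",
    "total_intake",
    "compose_flux",
    "supplement_micronutrients",
]

logger = logging.getLogger(__name__)


@dataclass
class FoodIntakeTable:
    """Rows of (food, period, grams/day); multiple rows per (food, period)
    are allowed when several formulas contain the same ingredient."""

    rows: list[tuple[str, str, float]] = field(default_factory=list)

    def add(self, food: str, period: str, grams_per_day: float) -> None:
        if grams_per_day < 0:
            raise ValueError(
                f"intake of {food!r} in period {period!r} is negative"
            )
        self.rows.append((food, period, float(grams_per_day)))

    def foods(self) -> list[str]:
        return sorted({f for f, _, _ in self.rows})

    def periods(self) -> list[str]:
        return sorted({p for _, p, _ in self.rows})


@dataclass
class NutrientCompositionTable:
    """``food -> {metabolite id -> g nutrient per g food}``."""

    fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def set(self, food: str, metabolite: str, fraction: float) -> None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(
                f"composition fraction for {metabolite!r} in {food!r} must "
                f"lie in [0, 1], got {fraction}"
            )
        self.fractions.setdefault(food, {})[metabolite] = float(fraction)

    def validate(self) -> None:
        for food, nutrients in self.fractions.items():
            for met, frac in nutrients.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"fraction of {met!r} in {food!r} outside [0, 1]"
                    )
            if sum(nutrients.values()) > 1.0 + 1e-9:
                raise ValueError(
                    f"composition fractions of {food!r} sum above 1"
                )


@dataclass
class DietFluxVector:
    """Metabolite -> daily uptake allowance, mmol/day, all nonnegative."""

    fluxes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, flux in self.fluxes.items():
            if flux < 0:
                raise ValueError(f"diet flux for {met!r} is negative: {flux}")

    def copy(self) -> "DietFluxVector":
        return DietFluxVector(dict(self.fluxes))

    def items(self):
        return sorted(self.fluxes.items())

    def __contains__(self, met: str) -> bool:
        return met in self.fluxes

    def __getitem__(self, met: str) -> float:
        return self.fluxes[met]


def total_intake(table: FoodIntakeTable, period: str, food: str) -> float:
    """Total grams/day of ``food`` in ``period``, summed across formulas."""
    if period not in table.periods():
        raise KeyError(
            f"unknown period {period!r}; known periods: {table.periods()}"
        )
    if food not in table.foods():
        raise KeyError(f"unknown food {food!r}; known foods: {table.foods()}")
    return sum(g for f, p, g in table.rows if f == food and p == period)


def compose_flux(
    intakes: dict[str, float],
    composition: NutrientCompositionTable,
    molar_masses: dict[str, float],
) -> DietFluxVector:
    """Convert grams/day of foods into mmol/day of metabolites.

    ``flux_m = sum_food g/day * fraction(food, m) / MW_m * 1000``.
    Metabolites with zero total are omitted.
    """
    composition.validate()
    totals: dict[str, float] = {}
    for food in sorted(intakes):
        grams = intakes[food]
        if grams < 0:
            raise ValueError(f"negative intake for {food!r}")
        for met, frac in sorted(composition.fractions.get(food, {}).items()):
            totals[met] = totals.get(met, 0.0) + grams * frac
    fluxes = {}
    for met in sorted(totals):
        if totals[met] == 0.0:
            continue
        if met not in molar_masses:
            raise KeyError(f"no molar mass supplied for metabolite {met!r}")
        fluxes[met] = totals[met] / molar_masses[met] * 1000.0
    return DietFluxVector(fluxes)


def supplement_micronutrients(
    diet: DietFluxVector,
    community: "CommunityModel | None" = None,
    epsilon: float = 0.1,
    essential: list[str] | None = None,
) -> DietFluxVector:
    """Open a trace allowance for essential micronutrients the diet lacks.

    Every metabolite on ``essential`` absent from the diet is added at
    ``epsilon`` mmol/day; present entries are untouched. When a community
    model is given, essential metabolites without a lumen counterpart are
    skipped (they could never be consumed anyway).
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    out = diet.copy()
    if epsilon == 0 or not essential:
        return out
    lumen = None
    if community is not None:
        lumen = community.lumen_metabolites()
    added = []
    for met in sorted(set(essential)):
        if met in out:
            continue
        if lumen is not None and met not in lumen:
            continue
        out.fluxes[met] = float(epsilon)
        added.append(met)
    if added:
        logger.info("supplemented %d micronutrients at %g mmol/day: %s",
                    len(added), epsilon, ", ".join(added))
    return out
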