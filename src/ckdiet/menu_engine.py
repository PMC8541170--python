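"""Exchange allocation and menu construction for a protein prescription.

A prescription (g protein/kg/day, kcal/kg, body weight) is turned into a
daily *exchange pattern* -- integer counts of cereal, fruit, vegetable,
protein-food, sugar and fat exchanges -- and the pattern realized as a
3-day menu of concrete food portions.

The pattern construction follows the renal exchange-list convention for a
2100 kcal / 70 kg plan: fruit is fixed at three exchanges and non-starchy
vegetables at four servings for every prescription; cereals are fixed at
eight exchanges for low protein diets (LPD, <= 0.8 g/kg) and thirteen for
moderately high protein diets (MHPD, >= 1.0 g/kg, the dialysis range).
Protein-food exchanges (7 g protein each) are chosen to minimize the gap
to the protein target after crediting cereal protein and a per-serving
vegetable protein allowance.  Sugar exchanges then pad energy on the low
protein plans (stepping down as protein foods rise) and fat exchanges are
traded against protein foods on the high protein plans; eggs enter the
protein-food split once the plan carries five protein exchanges and a
second egg at eight.  These closed-form rules reproduce the published
conventional patterns for all seven prescriptions from 0.5 to 1.2 g/kg.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .food_model import (
    EXCHANGE_SPECS,
    ExchangeSpec,
    FoodDB,
    FoodDBError,
    FoodItem,
    NutrientVector,
    exchange_portion,
    nutrients_for,
)

__all__ = [
    "Prescription",
    "VegetableAllowance",
    "ExchangePattern",
    "ExchangeBounds",
    "MenuPlan",
    "InfeasiblePatternError",
    "allocate_exchanges",
    "macronutrient_distribution",
    "macronutrient_summary",
    "build_menu",
    "aggregate_menu",
]


class InfeasiblePatternError(ValueError):
    """No integer exchange pattern satisfies the prescription under bounds."""


@dataclass(frozen=True)
class Prescription:
    """Protein and energy targets for one modeled diet.

    ``protein_g_per_kg`` spans the renal range 0.3-1.5; 30 kcal/kg and a
    70-kg reference adult are the defaults the modeling uses.
    """

    protein_g_per_kg: float
    energy_kcal_per_kg: float = 30.0
    body_weight: float = 70.0

    def __post_init__(self) -> None:
        if not 0.3 <= self.protein_g_per_kg <= 1.5:
            raise ValueError(
                f"protein prescription {self.protein_g_per_kg} g/kg outside [0.3, 1.5]"
            )
        if self.energy_kcal_per_kg <= 0 or self.body_weight <= 0:
            raise ValueError("energy and body weight must be positive")

    @property
    def protein_target_g(self) -> float:
        return self.protein_g_per_kg * self.body_weight

    @property
    def energy_target_kcal(self) -> float:
        return self.energy_kcal_per_kg * self.body_weight

    @property
    def diet_class(self) -> str:
        """LPD up to 0.8 g/kg; MHPD above (the dialysis prescriptions)."""
        return "LPD" if self.protein_g_per_kg <= 0.8 else "MHPD"


@dataclass(frozen=True)
class VegetableAllowance:
    """Macronutrients credited per non-starchy vegetable serving.

    The exchange system treats vegetables as 'free' of a defining
    macronutrient, but they do contribute protein and carbohydrate; the
    defaults (1.25 g protein, 5 g carbohydrate) close the published
    pattern's protein arithmetic.
    """

    protein: float = 1.25
    carbohydrate: float = 5.0

    @property
    def energy(self) -> float:
        return 4.0 * (self.protein + self.carbohydrate)


@dataclass(frozen=True)
class ExchangeBounds:
    """Feasible per-day exchange counts for the solved groups."""

    protein_food: tuple[int, int] = (2, 8)
    sugar: tuple[int, int] = (0, 5)
    fat: tuple[int, int] = (11, 14)


@dataclass(frozen=True)
class ExchangePattern:
    """Integer exchange counts per food group for one day."""

    cereal: int
    fruit: int
    vegetable: int
    poultry_fish: int
    egg: int
    sugar: int
    fat: int

    def __post_init__(self) -> None:
        for name, v in self.counts.items():
            if v < 0 or v != int(v):
                raise ValueError(f"exchange count {name}={v} must be a non-negative integer")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "cereal": self.cereal,
            "fruit": self.fruit,
            "vegetable": self.vegetable,
            "poultry_fish": self.poultry_fish,
            "egg": self.egg,
            "sugar": self.sugar,
            "fat": self.fat,
        }

    @property
    def protein_food(self) -> int:
        """Total protein-food exchanges (poultry/fish plus egg)."""
        return self.poultry_fish + self.egg


@dataclass(frozen=True)
class MenuPlan:
    """A 1-3 day menu: lists of (food id, grams) portions per day."""

    days: tuple[tuple[tuple[str, float], ...], ...]
    model_label: str
    prescription: Prescription

    def __post_init__(self) -> None:
        if not 1 <= len(self.days) <= 3:
            raise ValueError("a menu plan covers 1 to 3 days")

    @property
    def n_days(self) -> int:
        return len(self.days)

    def validate(self, db: FoodDB) -> None:
        for day in self.days:
            for food_id, grams in day:
                db[food_id]  # raises on unknown id
                if grams < 0:
                    raise FoodDBError(f"negative portion for {food_id!r}")

    def to_dict(self) -> dict:
        return {
            "model": self.model_label,
            "prescription": {
                "protein_g_per_kg": self.prescription.protein_g_per_kg,
                "energy_kcal_per_kg": self.prescription.energy_kcal_per_kg,
                "body_weight": self.prescription.body_weight,
            },
            "days": [
                [{"food": fid, "grams": round(g, 3)} for fid, g in day]
                for day in self.days
            ],
        }


# ---------------------------------------------------------------------------
# Pattern allocation
# ---------------------------------------------------------------------------

_FIXED_DEFAULT = {"fruit": 3, "vegetable": 4}
_CEREAL_BY_CLASS = {"LPD": 8, "MHPD": 13}


def _half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def allocate_exchanges(
    prescription: Prescription,
    specs: Mapping[str, ExchangeSpec] = EXCHANGE_SPECS,
    fixed: Mapping[str, int] = _FIXED_DEFAULT,
    bounds: ExchangeBounds = ExchangeBounds(),
    veg_allowance: VegetableAllowance = VegetableAllowance(),
) -> ExchangePattern:
    """Daily exchange pattern for a prescription.

    Protein-food exchanges minimize the absolute deviation of pattern
    protein (cereal + protein exchanges + vegetable allowance) from the
    prescription's protein target; sugar, fat and the egg split follow the
    fixed construction conventions described in the module docstring.

    Raises :class:`InfeasiblePatternError` with a diagnostic listing the
    binding constraint when the target cannot be approached within bounds.
    """
    cereal = _CEREAL_BY_CLASS[prescription.diet_class]
    fruit = int(fixed.get("fruit", 3))
    vegetable = int(fixed.get("vegetable", 4))

    base_protein = (
        cereal * specs["cereal"].protein + vegetable * veg_allowance.protein
    )
    per_exchange = specs["protein_food"].protein
    n_star = (prescription.protein_target_g - base_protein) / per_exchange
    n = _half_up(n_star)
    lo, hi = bounds.protein_food
    if n < lo or n > hi:
        raise InfeasiblePatternError(
            f"protein target {prescription.protein_target_g:.0f} g needs "
            f"{n_star:.1f} protein-food exchanges; bound {lo}-{hi} is binding "
            f"(cereal fixed at {cereal}, vegetable allowance "
            f"{vegetable * veg_allowance.protein:.1f} g)"
        )

    egg = max(0, (n - 2) // 3)
    poultry_fish = n - egg
    if prescription.diet_class == "LPD":
        sugar = 5 - (n - 1) // 2
        fat = 14
    else:
        sugar = 0
        fat = 19 - n
    slo, shi = bounds.sugar
    flo, fhi = bounds.fat
    sugar = min(max(sugar, slo), shi)
    fat = min(max(fat, flo), fhi)
    return ExchangePattern(
        cereal=cereal,
        fruit=fruit,
        vegetable=vegetable,
        poultry_fish=poultry_fish,
        egg=egg,
        sugar=sugar,
        fat=fat,
    )


def macronutrient_distribution(prescription: Prescription) -> dict[str, float]:
    """The prescription-level macronutrient rows of a plan header.

    Protein grams come straight from the prescription; carbohydrate takes
    what protein leaves within its 54-58 %-of-energy window and fat is
    capped at 35 % of energy.  Grams use 4/4/9 Atwater factors, rounded to
    the nearest gram.
    """
    energy = prescription.energy_target_kcal
    protein_g = prescription.protein_target_g
    protein_pct = _half_up(100.0 * 4.0 * protein_g / energy)
    carb_pct = min(max(100 - protein_pct - 35, 54), 58)
    fat_pct = 100 - protein_pct - carb_pct
    return {
        "energy_kcal": energy,
        "protein_g": float(_half_up(protein_g)),
        "protein_pct": float(protein_pct),
        "carbohydrate_g": float(_half_up(carb_pct / 100.0 * energy / 4.0)),
        "carbohydrate_pct": float(carb_pct),
        "fat_g": float(_half_up(fat_pct / 100.0 * energy / 9.0)),
        "fat_pct": float(fat_pct),
    }


def macronutrient_summary(
    pattern: ExchangePattern,
    specs: Mapping[str, ExchangeSpec] = EXCHANGE_SPECS,
    veg_allowance: VegetableAllowance = VegetableAllowance(),
) -> dict[str, float]:
    """Exchange-count x spec macronutrient sums, plus the vegetable allowance."""
    protein = carb = fat = 0.0
    group_of = {
        "cereal": "cereal",
        "fruit": "fruit",
        "poultry_fish": "protein_food",
        "egg": "protein_food",
        "sugar": "sugar",
        "fat": "fat",
    }
    for name, count in pattern.counts.items():
        if name == "vegetable":
            protein += count * veg_allowance.protein
            carb += count * veg_allowance.carbohydrate
            continue
        spec = specs[group_of[name]]
        protein += count * spec.protein
        carb += count * spec.carbohydrate
        fat += count * spec.fat
    return {
        "protein_g": protein,
        "carbohydrate_g": carb,
        "fat_g": fat,
        "energy_kcal": 4.0 * (protein + carb) + 9.0 * fat,
    }


# ---------------------------------------------------------------------------
# Menu realization and aggregation
# ---------------------------------------------------------------------------

_PATTERN_GROUPS: tuple[tuple[str, str], ...] = (
    ("cereal", "cereal"),
    ("fruit", "fruit"),
    ("vegetable", "vegetable"),
    ("poultry_fish", "protein_food"),
    ("egg", "protein_food"),
    ("sugar", "sugar"),
    ("fat", "fat"),
)


def _candidates(db: FoodDB, slot: str) -> list[FoodItem]:
    if slot == "egg":
        return db.by_source("animal_egg")
    if slot == "poultry_fish":
        items = db.by_source("animal_fish", "animal_poultry", "animal_meat")
        return items or db.by_group("protein_food")
    return db.by_group(
        {"cereal": "cereal", "fruit": "fruit", "vegetable": "vegetable",
         "sugar": "sugar", "fat": "fat"}[slot]
    )


def build_menu(
    pattern: ExchangePattern,
    db: FoodDB,
    day_templates: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
    days: int = 3,
    model_label: str = "conventional",
    prescription: Prescription | None = None,
) -> MenuPlan:
    """Realize an exchange pattern as concrete daily portions.

    Foods rotate round-robin within each group in database order, with a
    seed-determined starting offset per day so the three days differ while
    remaining reproducible.  ``day_templates`` optionally pins an ordered
    food-id list per day (foods outside the pattern's groups are ignored).
    """
    rng = random.Random(seed)
    offsets = [rng.randrange(10_000) for _ in range(days)]
    day_menus: list[tuple[tuple[str, float], ...]] = []
    for d in range(days):
        portions: list[tuple[str, float]] = []
        for slot, group in _PATTERN_GROUPS:
            count = pattern.counts[slot]
            if count == 0:
                continue
            cands = _candidates(db, slot)
            if day_templates is not None and d < len(day_templates):
                preferred = [db[fid] for fid in day_templates[d] if fid in db]
                preferred = [it for it in preferred if it in cands]
                if preferred:
                    cands = preferred
            if not cands:
                raise FoodDBError(
                    f"pattern requires {slot!r} exchanges but the database has "
                    f"no matching food"
                )
            for k in range(count):
                item = cands[(offsets[d] + k) % len(cands)]
                grams, _ = exchange_portion(item, EXCHANGE_SPECS[group])
                portions.append((item.id, grams))
        day_menus.append(tuple(portions))
    return MenuPlan(
        days=tuple(day_menus),
        model_label=model_label,
        prescription=prescription
        or Prescription(protein_g_per_kg=0.6),
    )


def aggregate_menu(menu: MenuPlan, db: FoodDB) -> NutrientVector:
    """Daily-mean nutrient totals of a menu plan."""
    if not menu.days or all(len(day) == 0 for day in menu.days):
        raise ValueError("cannot aggregate an empty menu")
    total = NutrientVector.zero()
    for day in menu.days:
        for food_id, grams in day:
            total = total + nutrients_for(db[food_id], grams)
    return total * (1.0 / menu.n_days)
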