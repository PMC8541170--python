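"""Plant-based and vegetarian substitution models.

Six diet patterns are modeled.  The *conventional* diet keeps at least
half its protein as high-biological-value animal protein.  The five
substitution models replace animal protein-food exchanges of a
conventional menu, exchange for exchange (equal protein grams), leaving
every other food group untouched:

* ``plado`` -- plant-dominant: about 70 % of total protein from plants,
  30 % from animal foods.
* ``vegan`` -- all animal foods removed; soy and legume exchanges replace
  them.
* ``ovo`` -- eggs are the only animal food; 1-3 egg exchanges per day.
* ``lacto`` -- dairy is the only animal food; 1-2 dairy exchanges per day.
* ``lacto_ovo`` -- eggs (1-3) and dairy (1-2) allowed.

Substitution preserves each day's total protein (fractional exchanges are
permitted), so the substituted menus stay within 2 % of the conventional
menu's protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .food_model import FoodDB, FoodDBError, FoodItem, NutrientVector, nutrients_for
from .menu_engine import MenuPlan

__all__ = [
    "DietModel",
    "DIET_MODELS",
    "MODEL_LABELS",
    "DietModelError",
    "apply_diet_model",
    "protein_split",
    "validate_model_constraints",
]

_ANIMAL_SOURCES = frozenset(
    {"animal_fish", "animal_poultry", "animal_meat", "animal_egg", "animal_dairy"}
)
_PLANT_PRIORITY = ("plant_soy", "plant_legume", "plant_other")
_EXCHANGE_PROTEIN = 7.0


class DietModelError(ValueError):
    """Raised when a model's substitution cannot be carried out."""


@dataclass(frozen=True)
class DietModel:
    """Constraint set defining one diet pattern."""

    label: str
    animal_fraction_target: float | None = None
    animal_fraction_tol: float = 0.05
    allowed_animal_sources: frozenset[str] = frozenset()
    egg_min: int = 0
    egg_max: int = 0
    dairy_min: int = 0
    dairy_max: int = 0

    def __post_init__(self) -> None:
        if self.egg_min > self.egg_max or self.dairy_min > self.dairy_max:
            raise ValueError(f"{self.label}: min exchanges exceed max")
        if self.label == "vegan" and self.allowed_animal_sources:
            raise ValueError("a vegan model allows no animal source")


#: The conventional target is "at least half animal protein", but realized
#: menus under-run it at low prescriptions (published 0.5 g/kg menus reach
#: only ~42 %, and the fixed exchange construction bottoms out near 38 %
#: once cereal and vegetable protein are credited), hence the wide downward
#: tolerance.  PLADO realizations scatter ~0.29-0.31.
DIET_MODELS: dict[str, DietModel] = {
    "conventional": DietModel(
        label="conventional",
        animal_fraction_target=0.50,
        animal_fraction_tol=0.15,
        allowed_animal_sources=frozenset(_ANIMAL_SOURCES),
    ),
    "plado": DietModel(
        label="plado",
        animal_fraction_target=0.30,
        animal_fraction_tol=0.05,
        allowed_animal_sources=frozenset(_ANIMAL_SOURCES),
    ),
    "vegan": DietModel(label="vegan", animal_fraction_target=0.0),
    "ovo": DietModel(
        label="ovo",
        allowed_animal_sources=frozenset({"animal_egg"}),
        egg_min=1,
        egg_max=3,
    ),
    "lacto": DietModel(
        label="lacto",
        allowed_animal_sources=frozenset({"animal_dairy"}),
        dairy_min=1,
        dairy_max=2,
    ),
    "lacto_ovo": DietModel(
        label="lacto_ovo",
        allowed_animal_sources=frozenset({"animal_egg", "animal_dairy"}),
        egg_min=1,
        egg_max=3,
        dairy_min=1,
        dairy_max=2,
    ),
}

MODEL_LABELS: tuple[str, ...] = tuple(DIET_MODELS)


# ---------------------------------------------------------------------------
# Protein accounting
# ---------------------------------------------------------------------------


def _day_protein(day, db: FoodDB) -> tuple[float, float, float]:
    """(protein-food protein, background protein, animal protein) for a day."""
    pf = bg = animal = 0.0
    for food_id, grams in day:
        item = db[food_id]
        p = nutrients_for(item, grams).protein
        if item.group == "protein_food":
            pf += p
        else:
            bg += p
        if item.is_animal:
            animal += p
    return pf, bg, animal


def protein_split(menu: MenuPlan, db: FoodDB) -> tuple[float, float]:
    """(animal g, plant g) of daily-mean protein.

    Protein from cereals, vegetables and fruit counts as plant protein.
    An empty menu splits as (0, 0).
    """
    animal = total = 0.0
    n_days = max(menu.n_days, 1)
    for day in menu.days:
        for food_id, grams in day:
            item = db[food_id]
            p = nutrients_for(item, grams).protein
            total += p
            if item.is_animal:
                animal += p
    return animal / n_days, (total - animal) / n_days


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------


def _source_candidates(db: FoodDB, sources: Sequence[str], need: str) -> list[FoodItem]:
    items: list[FoodItem] = []
    for src in sources:
        items.extend(db.by_source(src))
    if not items:
        raise DietModelError(f"database lacks any {need} protein food")
    return [it for it in items if it.group == "protein_food"] or items


def _allocate(
    target_protein: float, candidates: Sequence[FoodItem]
) -> list[tuple[str, float]]:
    """Portions worth ``target_protein`` grams of protein, round-robin in
    whole 7 g exchanges with one trailing fractional exchange."""
    portions: list[tuple[str, float]] = []
    remaining = target_protein
    i = 0
    while remaining > 1e-9:
        item = candidates[i % len(candidates)]
        # snap a nearly-full trailing exchange to exactly 7 g so repeated
        # substitution reproduces identical portions
        protein = (
            _EXCHANGE_PROTEIN
            if remaining > _EXCHANGE_PROTEIN - 1e-9
            else remaining
        )
        density = item.nutrient_density.protein
        grams = 100.0 * protein / density
        portions.append((item.id, grams))
        remaining -= protein
        i += 1
    return portions


def _whole_exchanges(protein: float) -> int:
    """Whole 7 g exchanges available, tolerant of float accumulation."""
    return int((protein + 1e-9) // _EXCHANGE_PROTEIN)


def _egg_count(model: DietModel, day, db: FoodDB, pf_protein: float) -> int:
    """Egg exchanges to keep: the input menu's egg exchanges clamped to the
    model's window (and to the protein available)."""
    egg_protein = sum(
        nutrients_for(db[fid], g).protein
        for fid, g in day
        if db[fid].protein_source == "animal_egg"
    )
    n = max(model.egg_min, min(model.egg_max, round(egg_protein / _EXCHANGE_PROTEIN)))
    return min(n, _whole_exchanges(pf_protein)) if pf_protein > 1e-9 else 0


def _dairy_count(model: DietModel, pf_protein: float) -> int:
    """Dairy exchanges scale with the day's protein-food protein (about one
    exchange per three), clamped to the model's window."""
    n = max(
        model.dairy_min,
        min(model.dairy_max, round(pf_protein / (3 * _EXCHANGE_PROTEIN))),
    )
    return min(n, _whole_exchanges(pf_protein)) if pf_protein > 1e-9 else 0


def apply_diet_model(menu: MenuPlan, model: DietModel | str, db: FoodDB) -> MenuPlan:
    """Substitute a menu's protein-food portions to satisfy a diet model.

    Non-protein food groups are left unchanged; each day's protein-food
    protein is re-allotted across the model's allowed sources at equal
    protein grams, so total protein is preserved.  The operation is
    idempotent and deterministic.
    """
    if isinstance(model, str):
        try:
            model = DIET_MODELS[model]
        except KeyError:
            raise DietModelError(f"unknown diet model {model!r}") from None
    menu.validate(db)

    plants = _source_candidates(db, _PLANT_PRIORITY, "plant")
    new_days = []
    for day in menu.days:
        pf_protein, bg_protein, _ = _day_protein(day, db)
        kept = tuple(
            (fid, g) for fid, g in day if db[fid].group != "protein_food"
        )
        if model.label == "conventional":
            new_days.append(day)
            continue

        allocations: list[tuple[str, float]] = []
        remaining = pf_protein
        if model.label == "plado":
            total = pf_protein + bg_protein
            animal_protein = min(pf_protein, model.animal_fraction_target * total)
            animals = _source_candidates(
                db, ("animal_fish", "animal_poultry", "animal_meat"), "animal"
            )
            allocations += _allocate(animal_protein, animals)
            remaining -= animal_protein
        elif model.label == "vegan":
            pass
        else:
            if model.egg_max > 0:
                eggs = _source_candidates(db, ("animal_egg",), "egg")
                egg_protein = _EXCHANGE_PROTEIN * _egg_count(model, day, db, remaining)
                egg_protein = min(egg_protein, remaining)
                allocations += _allocate(egg_protein, eggs)
                remaining -= egg_protein
            if model.dairy_max > 0:
                dairy = _source_candidates(db, ("animal_dairy",), "dairy")
                dairy_protein = _EXCHANGE_PROTEIN * _dairy_count(model, remaining)
                dairy_protein = min(dairy_protein, remaining)
                allocations += _allocate(dairy_protein, dairy)
                remaining -= dairy_protein
        allocations += _allocate(remaining, plants)
        new_days.append(kept + tuple(allocations))

    return replace(menu, days=tuple(new_days), model_label=model.label)


def validate_model_constraints(
    menu: MenuPlan, model: DietModel | str, db: FoodDB
) -> list[str]:
    """Per-day constraint violations; an empty list means the menu conforms."""
    if isinstance(model, str):
        model = DIET_MODELS[model]
    violations: list[str] = []
    for d, day in enumerate(menu.days, start=1):
        pf, bg, animal = _day_protein(day, db)
        total = pf + bg
        egg_x = sum(
            nutrients_for(db[fid], g).protein
            for fid, g in day
            if db[fid].protein_source == "animal_egg"
        ) / _EXCHANGE_PROTEIN
        dairy_x = sum(
            nutrients_for(db[fid], g).protein
            for fid, g in day
            if db[fid].protein_source == "animal_dairy"
        ) / _EXCHANGE_PROTEIN
        for fid, _ in day:
            item = db[fid]
            if item.is_animal and item.protein_source not in model.allowed_animal_sources:
                violations.append(
                    f"day {d}: {item.protein_source} food {fid!r} not allowed by "
                    f"{model.label}"
                )
        tol = 1e-6
        if model.egg_max and egg_x > model.egg_max + tol:
            violations.append(f"day {d}: egg > {model.egg_max}")
        if model.egg_min and egg_x < model.egg_min - tol:
            violations.append(f"day {d}: egg < {model.egg_min}")
        if model.dairy_max and dairy_x > model.dairy_max + tol:
            violations.append(f"day {d}: dairy > {model.dairy_max}")
        if model.dairy_min and dairy_x < model.dairy_min - tol:
            violations.append(f"day {d}: dairy < {model.dairy_min}")
        if model.animal_fraction_target is not None and total > 0:
            frac = animal / total
            target, ftol = model.animal_fraction_target, model.animal_fraction_tol
            if model.label == "conventional":
                if frac < target - ftol:
                    violations.append(
                        f"day {d}: animal protein fraction {frac:.2f} below "
                        f"{target:.2f} (tolerance {ftol:.2f})"
                    )
            elif abs(frac - target) > ftol:
                violations.append(
                    f"day {d}: animal protein fraction {frac:.2f} outside "
                    f"{target:.2f} +- {ftol:.2f}"
                )
    return violations
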