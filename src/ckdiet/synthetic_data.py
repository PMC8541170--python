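"""Synthetic food-composition databases with the class structure the
adequacy analysis rests on.

The generator does not try to mimic a real food-composition database in
detail; it reproduces the *class-level* contrasts that drive the
modeling's conclusions:

* animal protein foods are denser than plant protein foods in lysine
  (75-95 vs 55-70 mg per g protein) and the sulfur amino acids
  (35-52 vs 20-28 mg/g), per-gram anchors taken from published
  per-exchange amino-acid values;
* cobalamin occurs only in animal foods, EPA+DHA only in fish, and
  fiber only in plant foods;
* cereals are lysine-poor relative to vegetables and legumes, which is
  what makes the background (non-protein-food) groups matter at low
  protein prescriptions.

Densities are drawn uniformly inside their class range, jittered with
multiplicative lognormal noise (sigma 0.1) and clipped back to the
range; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diet_models import DIET_MODELS, DietModel, apply_diet_model
from .food_model import FoodDB, FoodItem, NutrientVector
from .menu_engine import MenuPlan, Prescription, allocate_exchanges, build_menu

__all__ = [
    "GeneratorParams",
    "generate_food_db",
    "generate_menu_suite",
]

#: Amino-acid density ranges in mg per gram of protein, by food class.
#: Animal vs plant protein-food anchors derive from per-exchange values of
#: representative foods (e.g. fish lysine 652/7 ~ 93, tofu 463/7 ~ 66 mg/g);
#: background classes follow typical grain / vegetable / fruit profiles.
CLASS_AA_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "animal": {
        "tryptophan": (10, 15),
        "threonine": (38, 47),
        "isoleucine": (44, 55),
        "leucine": (74, 88),
        "lysine": (75, 95),
        "methionine_cysteine": (35, 52),
        "phenylalanine_tyrosine": (70, 93),
        "valine": (48, 65),
        "histidine": (24, 48),
    },
    "plant": {
        "tryptophan": (9, 16),
        "threonine": (34, 42),
        "isoleucine": (40, 50),
        "leucine": (70, 78),
        "lysine": (55, 70),
        "methionine_cysteine": (20, 28),
        "phenylalanine_tyrosine": (72, 88),
        "valine": (44, 56),
        "histidine": (22, 31),
    },
    "cereal": {
        "tryptophan": (9, 13),
        "threonine": (30, 38),
        "isoleucine": (38, 46),
        "leucine": (74, 88),
        "lysine": (36, 46),
        "methionine_cysteine": (38, 48),
        "phenylalanine_tyrosine": (80, 94),
        "valine": (52, 62),
        "histidine": (22, 27),
    },
    "vegetable": {
        "tryptophan": (10, 14),
        "threonine": (36, 44),
        "isoleucine": (38, 46),
        "leucine": (64, 76),
        "lysine": (50, 62),
        "methionine_cysteine": (24, 32),
        "phenylalanine_tyrosine": (64, 80),
        "valine": (44, 54),
        "histidine": (20, 25),
    },
    "fruit": {
        "tryptophan": (8, 12),
        "threonine": (32, 40),
        "isoleucine": (34, 42),
        "leucine": (58, 70),
        "lysine": (45, 55),
        "methionine_cysteine": (22, 30),
        "phenylalanine_tyrosine": (54, 68),
        "valine": (40, 50),
        "histidine": (18, 24),
    },
}

#: Fraction of the sulfur pair carried as methionine (animal foods are
#: methionine-dominant, plant foods cysteine-leaning).
_MET_SHARE = {"animal": 0.65, "plant": 0.45, "cereal": 0.5, "vegetable": 0.5, "fruit": 0.5}


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic database generator.

    ``n_foods_per_group`` gives the number of foods per protein-source
    class (for protein foods) and per background group; ``noise_sigma``
    is the lognormal jitter applied to every drawn density.
    """

    seed: int
    n_foods_per_group: Mapping[str, int] = field(
        default_factory=lambda: {
            "animal_fish": 2,
            "animal_poultry": 2,
            "animal_egg": 1,
            "animal_dairy": 2,
            "plant_soy": 2,
            "plant_legume": 3,
            "cereal": 4,
            "fruit": 5,
            "vegetable": 5,
            "fat": 2,
            "sugar": 1,
            "beverage": 1,
        }
    )
    aa_ranges: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: CLASS_AA_RANGES
    )
    noise_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for cls, ranges in self.aa_ranges.items():
            for aa, (lo, hi) in ranges.items():
                if not 0 < lo < hi:
                    raise ValueError(f"degenerate range for {cls}/{aa}: ({lo}, {hi})")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


_SOURCE_CLASS = {
    "animal_fish": "animal",
    "animal_poultry": "animal",
    "animal_meat": "animal",
    "animal_egg": "animal",
    "animal_dairy": "animal",
    "plant_soy": "plant",
    "plant_legume": "plant",
    "plant_other": "plant",
}

# (exchange grams low/high, fat g/exchange low/high, carb g/exchange low/high)
_PROTEIN_FOOD_SHAPE = {
    "animal_fish": ((30, 40), (3, 6), (0, 0)),
    "animal_poultry": ((28, 35), (3, 7), (0, 0)),
    "animal_egg": ((50, 60), (5, 6), (0.3, 0.6)),
    "animal_dairy": ((200, 240), (7, 9), (10, 12)),
    "plant_soy": ((80, 95), (3.5, 5), (1.5, 4)),
    "plant_legume": ((70, 85), (0.3, 2.2), (12, 22)),
}


def _draw(rng: np.random.Generator, lo: float, hi: float, sigma: float) -> float:
    v = rng.uniform(lo, hi)
    if sigma > 0:
        v *= float(np.exp(rng.normal(0.0, sigma)))
    return float(np.clip(v, lo, hi))


def _aa_amounts(
    rng: np.random.Generator,
    cls: str,
    grams_protein: float,
    ranges: Mapping[str, Mapping[str, tuple[float, float]]],
    sigma: float,
) -> dict[str, float]:
    out: dict[str, float] = {}
    met_share = _MET_SHARE[cls]
    for aa, (lo, hi) in ranges[cls].items():
        density = _draw(rng, lo, hi, sigma)
        amount = density * grams_protein
        if aa == "methionine_cysteine":
            out["methionine"] = amount * met_share
            out["cysteine"] = amount * (1 - met_share)
        else:
            out[aa] = amount
    return out


def _micro(rng, lo, hi):
    return float(rng.uniform(lo, hi))


def generate_food_db(params: GeneratorParams) -> FoodDB:
    """Deterministically generate a synthetic food database."""
    rng = np.random.default_rng(params.seed)
    sigma = params.noise_sigma
    items: list[FoodItem] = []

    def vec(per_exchange: dict[str, float], grams: float) -> NutrientVector:
        d = dict(per_exchange)
        d["energy"] = 4.0 * (d.get("carbohydrate", 0.0) + d.get("protein", 0.0)) + 9.0 * d.get("fat", 0.0)
        return NutrientVector(**{k: v / grams * 100.0 for k, v in d.items()})

    # protein foods: one exchange = 7 g protein
    for source, n in params.n_foods_per_group.items():
        if source not in _PROTEIN_FOOD_SHAPE:
            continue
        (glo, ghi), (flo, fhi), (clo, chi) = _PROTEIN_FOOD_SHAPE[source]
        cls = _SOURCE_CLASS[source]
        for i in range(n):
            grams = _micro(rng, glo, ghi)
            per = {"protein": 7.0, "fat": _micro(rng, flo, fhi)}
            if chi > 0:
                per["carbohydrate"] = _micro(rng, clo, chi)
            per.update(_aa_amounts(rng, cls, 7.0, params.aa_ranges, sigma))
            if cls == "plant":
                per["fiber"] = _micro(rng, 0.5, 6.5)
            per["sodium"] = _micro(rng, 2, 100)
            per["potassium"] = _micro(rng, 70, 300)
            per["phosphorus"] = _micro(rng, 50, 190)
            per["calcium"] = _micro(rng, 4, 60) if cls == "animal" else _micro(rng, 10, 300)
            per["magnesium"] = _micro(rng, 6, 40)
            per["copper"] = _micro(rng, 15, 60) if cls == "animal" else _micro(rng, 150, 300)
            per["manganese"] = _micro(rng, 0.005, 0.02) if cls == "animal" else _micro(rng, 0.3, 0.9)
            per["iron"] = _micro(rng, 0.1, 1.2) if cls == "animal" else _micro(rng, 1.2, 2.8)
            per["zinc"] = _micro(rng, 0.3, 1.0)
            per["thiamine"] = _micro(rng, 0.02, 0.13)
            per["riboflavin"] = _micro(rng, 0.04, 0.4)
            per["niacin"] = _micro(rng, 0.05, 3.0)
            per["pyridoxine"] = _micro(rng, 0.04, 0.16)
            per["folate"] = _micro(rng, 2, 30) if cls == "animal" else _micro(rng, 15, 150)
            # presence rules
            if cls == "animal":
                per["cobalamin"] = (
                    _micro(rng, 2.0, 6.0) if source == "animal_fish" else _micro(rng, 0.1, 1.2)
                )
            if source == "animal_fish":
                per["epa_dha"] = _micro(rng, 150, 500)
            items.append(
                FoodItem(
                    id=f"{source}_{i}",
                    name=f"synthetic {source.replace('_', ' ')} {i}",
                    group="protein_food",
                    protein_source=source,
                    nutrient_density=vec(per, grams),
                    exchange_grams=grams,
                )
            )

    background = {
        "cereal": dict(protein=2.0, carbohydrate=15.0, fat=0.5, grams=(45, 62), cls="cereal"),
        "fruit": dict(protein=0.5, carbohydrate=15.0, fat=0.0, grams=(60, 150), cls="fruit"),
        "vegetable": dict(protein=1.25, carbohydrate=5.0, fat=0.0, grams=(70, 90), cls="vegetable"),
    }
    for group, shape in background.items():
        for i in range(params.n_foods_per_group.get(group, 0)):
            grams = _micro(rng, *shape["grams"])
            per = {
                "protein": shape["protein"],
                "carbohydrate": shape["carbohydrate"],
                "fat": shape["fat"],
                "fiber": _micro(rng, 0.5, 3.2),
            }
            per.update(
                _aa_amounts(rng, shape["cls"], shape["protein"], params.aa_ranges, sigma)
            )
            per["sodium"] = _micro(rng, 1, 60)
            per["potassium"] = _micro(rng, 30, 420)
            per["phosphorus"] = _micro(rng, 10, 50)
            per["calcium"] = _micro(rng, 4, 120)
            per["magnesium"] = _micro(rng, 5, 60)
            per["copper"] = _micro(rng, 15, 150)
            per["manganese"] = _micro(rng, 0.03, 0.8)
            per["iron"] = _micro(rng, 0.1, 2.5)
            per["zinc"] = _micro(rng, 0.05, 0.7)
            per["thiamine"] = _micro(rng, 0.01, 0.12)
            per["riboflavin"] = _micro(rng, 0.01, 0.2)
            per["niacin"] = _micro(rng, 0.1, 1.6)
            per["pyridoxine"] = _micro(rng, 0.02, 0.24)
            per["folate"] = _micro(rng, 3, 130)
            items.append(
                FoodItem(
                    id=f"{group}_{i}",
                    name=f"synthetic {group} {i}",
                    group=group,
                    protein_source="none",
                    nutrient_density=vec(per, grams),
                    exchange_grams=grams,
                )
            )

    for i in range(params.n_foods_per_group.get("fat", 0)):
        items.append(
            FoodItem(
                id=f"fat_{i}",
                name=f"synthetic oil {i}",
                group="fat",
                protein_source="none",
                nutrient_density=NutrientVector(fat=100.0, energy=900.0),
                exchange_grams=5.0,
            )
        )
    for i in range(params.n_foods_per_group.get("sugar", 0)):
        items.append(
            FoodItem(
                id=f"sugar_{i}",
                name=f"synthetic sugar {i}",
                group="sugar",
                protein_source="none",
                nutrient_density=NutrientVector(carbohydrate=100.0, energy=400.0),
                exchange_grams=15.0,
            )
        )
    for i in range(params.n_foods_per_group.get("beverage", 0)):
        items.append(
            FoodItem(
                id=f"beverage_{i}",
                name=f"synthetic beverage {i}",
                group="beverage",
                protein_source="none",
                nutrient_density=NutrientVector(potassium=8.0),
                exchange_grams=240.0,
            )
        )
    return FoodDB(items)


def generate_menu_suite(
    db: FoodDB,
    prescriptions: Sequence[float],
    models: Sequence[str | DietModel],
    seed: int = 0,
    body_weight: float = 70.0,
) -> dict[tuple[str, float], MenuPlan]:
    """One 3-day menu per (model, prescription) cell.

    Conventional menus are built from the exchange pattern; every other
    model is a substitution of that cell's conventional menu, so the suite
    exercises allocation, realization and substitution end to end.
    """
    suite: dict[tuple[str, float], MenuPlan] = {}
    for p in prescriptions:
        rx = Prescription(protein_g_per_kg=p, body_weight=body_weight)
        pattern = allocate_exchanges(rx)
        conventional = build_menu(
            pattern, db, seed=seed, model_label="conventional", prescription=rx
        )
        for model in models:
            label = model if isinstance(model, str) else model.label
            suite[(label, p)] = (
                conventional
                if label == "conventional"
                else apply_diet_model(conventional, model, db)
            )
    return suite
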