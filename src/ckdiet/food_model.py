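"""Food-composition data model and exchange-portion arithmetic.

A food is described by its nutrient *density* (amounts per 100 g edible
portion).  Portions scale linearly with weight, and an *exchange* is the
portion that supplies a food group's defining macronutrient amount
(7 g protein for protein foods, 15 g carbohydrate for cereal/fruit/sugar,
5 g fat for fats) -- the standard renal/diabetic exchange-list convention.

Two fixture databases ship with the package:

``protein_exchange_foods.csv``
    Seven protein-food sources (fish, chicken, egg, whole milk, tofu,
    lentils, chickpeas) whose per-exchange weights and leucine, lysine,
    methionine and cysteine contents follow the published food-composition
    values used by the modeling study; every other nutrient column is a
    synthetic-but-plausible estimate and is labeled as such.

``menu_foods_synthetic.csv``
    Representative cereals, fruits, vegetables, fats, sugar and beverages
    of an Asian renal menu.  All nutrient values are synthetic estimates,
    not measured data.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger("ckdiet")

__all__ = [
    "NutrientVector",
    "FoodItem",
    "FoodDB",
    "ExchangeSpec",
    "EXCHANGE_SPECS",
    "FOOD_GROUPS",
    "PROTEIN_SOURCES",
    "FoodDBError",
    "load_food_db",
    "write_food_db",
    "load_protein_foods_db",
    "load_menu_foods_db",
    "load_default_db",
    "exchange_portion",
    "nutrients_for",
]

FOOD_GROUPS = frozenset(
    {"cereal", "fruit", "vegetable", "protein_food", "fat", "sugar", "beverage"}
)

PROTEIN_SOURCES = frozenset(
    {
        "animal_fish",
        "animal_poultry",
        "animal_meat",
        "animal_egg",
        "animal_dairy",
        "plant_soy",
        "plant_legume",
        "plant_other",
        "none",
    }
)


class FoodDBError(ValueError):
    """Raised for malformed food-composition tables or invalid portions."""


@dataclass(frozen=True)
class NutrientVector:
    """One portion's (or one day's) nutrient amounts.

    Units: energy kcal; protein/carbohydrate/fat/fiber g; amino acids,
    EPA+DHA, macrominerals, iron, zinc, manganese (mg); copper and the
    folate/cobalamin vitamins ug; B vitamins mg.  All components are
    non-negative; vectors add component-wise and scale by non-negative
    scalars, with the zero vector as additive identity.
    """

    energy: float = 0.0
    protein: float = 0.0
    carbohydrate: float = 0.0
    fat: float = 0.0
    fiber: float = 0.0
    tryptophan: float = 0.0
    threonine: float = 0.0
    isoleucine: float = 0.0
    leucine: float = 0.0
    lysine: float = 0.0
    methionine: float = 0.0
    cysteine: float = 0.0
    phenylalanine_tyrosine: float = 0.0
    valine: float = 0.0
    histidine: float = 0.0
    epa_dha: float = 0.0
    sodium: float = 0.0
    potassium: float = 0.0
    phosphorus: float = 0.0
    calcium: float = 0.0
    magnesium: float = 0.0
    copper: float = 0.0
    manganese: float = 0.0
    iron: float = 0.0
    zinc: float = 0.0
    thiamine: float = 0.0
    riboflavin: float = 0.0
    niacin: float = 0.0
    pyridoxine: float = 0.0
    folate: float = 0.0
    cobalamin: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"nutrient {f.name!r} is negative: {v}")

    # -- vector algebra ---------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return NutrientVector(
            **{
                f.name: getattr(self, f.name) + getattr(other, f.name)
                for f in fields(self)
            }
        )

    def __mul__(self, scalar: float) -> "NutrientVector":
        if not isinstance(scalar, (int, float)):
            return NotImplemented
        return NutrientVector(
            **{f.name: getattr(self, f.name) * scalar for f in fields(self)}
        )

    __rmul__ = __mul__

    @classmethod
    def zero(cls) -> "NutrientVector":
        return cls()

    # -- derived / reporting ----------------------------------------------
    @property
    def methionine_cysteine(self) -> float:
        """Combined sulfur amino acids, the form reference values use."""
        return self.methionine + self.cysteine

    def get(self, nutrient: str) -> float:
        """Amount of a nutrient, including derived combined names."""
        if nutrient == "methionine_cysteine":
            return self.methionine_cysteine
        return getattr(self, nutrient)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


NUTRIENT_FIELDS: tuple[str, ...] = NutrientVector.field_names()

#: Names of the nine essential-amino-acid entries as compared against
#: reference values (sulfur and aromatic pairs combined).
EAA_REFERENCE_NAMES: tuple[str, ...] = (
    "tryptophan",
    "threonine",
    "isoleucine",
    "leucine",
    "lysine",
    "methionine_cysteine",
    "phenylalanine_tyrosine",
    "valine",
    "histidine",
)


@dataclass(frozen=True)
class FoodItem:
    """A food with group classification and per-100 g nutrient densities."""

    id: str
    name: str
    group: str
    protein_source: str
    nutrient_density: NutrientVector
    exchange_grams: float | None = None

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise FoodDBError(f"unknown group {self.group!r} for food {self.id!r}")
        if self.protein_source not in PROTEIN_SOURCES:
            raise FoodDBError(
                f"unknown protein_source {self.protein_source!r} for food {self.id!r}"
            )
        if self.group == "protein_food" and self.protein_source == "none":
            raise FoodDBError(
                f"protein food {self.id!r} must declare a protein_source"
            )
        if self.protein_source != "none" and self.nutrient_density.protein <= 0:
            raise FoodDBError(
                f"food {self.id!r} has protein_source {self.protein_source!r} "
                "but zero protein density"
            )
        if self.exchange_grams is not None and self.exchange_grams <= 0:
            raise FoodDBError(f"food {self.id!r}: exchange_grams must be positive")

    @property
    def is_animal(self) -> bool:
        return self.protein_source.startswith("animal")


class FoodDB:
    """Collection of :class:`FoodItem` keyed by unique id.

    Preserves insertion order (menu construction cycles foods in db order).
    ``load_report`` maps food id -> list of nutrient columns that were
    missing in the source table and zero-filled.
    """

    def __init__(
        self,
        items: Iterable[FoodItem],
        load_report: Mapping[str, list[str]] | None = None,
    ):
        self._items: dict[str, FoodItem] = {}
        for item in items:
            if item.id in self._items:
                raise FoodDBError(f"duplicate id {item.id!r}")
            self._items[item.id] = item
        if not self._items:
            raise FoodDBError("empty database")
        self.load_report: dict[str, list[str]] = dict(load_report or {})

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._items.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._items

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._items[food_id]
        except KeyError:
            raise FoodDBError(f"unknown food id {food_id!r}") from None

    def by_group(self, group: str) -> list[FoodItem]:
        return [it for it in self if it.group == group]

    def by_source(self, *sources: str) -> list[FoodItem]:
        return [it for it in self if it.protein_source in sources]

    def merged(self, other: "FoodDB") -> "FoodDB":
        return FoodDB(
            list(self) + list(other),
            {**self.load_report, **other.load_report},
        )


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ("id", "name", "group", "protein_source", "exchange_grams")


def load_food_db(
    source: str | Path | io.TextIOBase, *, strict: bool = False
) -> FoodDB:
    """Read a food-composition table (comma or tab delimited, auto-detected).

    Missing nutrient cells are zero-filled with a logged warning and counted
    in ``FoodDB.load_report``.  With ``strict=True``, protein foods whose
    amino-acid columns are all absent are rejected instead.
    """
    # delimiter auto-detection from the header line; round_trip parsing so
    # written databases reload bit-identically
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = Path(source).read_text()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(
        io.StringIO(text), sep=sep, dtype={"id": str}, float_precision="round_trip"
    )
    if df.empty:
        raise FoodDBError("empty database")
    for col in ("id", "name", "group", "protein_source"):
        if col not in df.columns:
            raise FoodDBError(f"missing required column {col!r}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise FoodDBError(f"duplicate id {dup!r}")

    aa_fields = [f for f in EAA_REFERENCE_NAMES if f in NUTRIENT_FIELDS] + [
        "methionine",
        "cysteine",
    ]
    items: list[FoodItem] = []
    report: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        missing: list[str] = []
        values: dict[str, float] = {}
        for name in NUTRIENT_FIELDS:
            raw = row.get(name)
            if raw is None or pd.isna(raw):
                missing.append(name)
                values[name] = 0.0
            else:
                v = float(raw)
                if v < 0:
                    raise FoodDBError(
                        f"negative value for {name!r} in food {row['id']!r}"
                    )
                values[name] = v
        if missing:
            report[str(row["id"])] = missing
            logger.warning(
                "food %r: %d missing nutrient cells zero-filled (%s)",
                row["id"],
                len(missing),
                ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
            )
        if strict and row["group"] == "protein_food":
            if all(m in missing for m in aa_fields if m in NUTRIENT_FIELDS):
                raise FoodDBError(
                    f"strict mode: protein food {row['id']!r} lacks amino-acid data"
                )
        eg = row.get("exchange_grams")
        exchange_grams = None if eg is None or pd.isna(eg) else float(eg)
        items.append(
            FoodItem(
                id=str(row["id"]),
                name=str(row["name"]),
                group=str(row["group"]),
                protein_source=str(row["protein_source"]),
                nutrient_density=NutrientVector(**values),
                exchange_grams=exchange_grams,
            )
        )
    return FoodDB(items, report)


def write_food_db(db: FoodDB, target: str | Path | io.TextIOBase, sep: str = ",") -> None:
    """Emit the same dialect ``load_food_db`` reads; values round-trip
    bit-identically (pandas writes full ``repr`` precision)."""
    rows = []
    for item in db:
        row: dict[str, object] = {
            "id": item.id,
            "name": item.name,
            "group": item.group,
            "protein_source": item.protein_source,
            "exchange_grams": item.exchange_grams,
        }
        row.update(item.nutrient_density.to_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(NUTRIENT_FIELDS))
    # shortest-repr float strings so values round-trip bit-identically
    for col in NUTRIENT_FIELDS + ("exchange_grams",):
        df[col] = df[col].map(lambda v: "" if v is None else repr(float(v)))
    df.to_csv(target, sep=sep, index=False)


def _data_path(name: str):
    return resources.files("ckdiet.data").joinpath(name)


def load_protein_foods_db() -> FoodDB:
    """The seven packaged protein-food exchange records."""
    with resources.as_file(_data_path("protein_exchange_foods.csv")) as p:
        return load_food_db(p)


def load_menu_foods_db() -> FoodDB:
    """Synthetic representative menu foods (cereals, fruits, vegetables...)."""
    with resources.as_file(_data_path("menu_foods_synthetic.csv")) as p:
        return load_food_db(p)


def load_default_db() -> FoodDB:
    """Protein foods plus menu foods: the database menus are built from."""
    return load_protein_foods_db().merged(load_menu_foods_db())


# ---------------------------------------------------------------------------
# Exchange portions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExchangeSpec:
    """Macronutrient definition of one exchange of a food group."""

    group: str
    carbohydrate: float = 0.0
    protein: float = 0.0
    fat: float = 0.0

    def __post_init__(self) -> None:
        if min(self.carbohydrate, self.protein, self.fat) < 0:
            raise ValueError("exchange macronutrients must be non-negative")

    @property
    def defining_nutrient(self) -> tuple[str, float] | None:
        """(nutrient, grams) that defines the portion size, if any."""
        if self.group in ("cereal", "fruit", "sugar"):
            return ("carbohydrate", self.carbohydrate)
        if self.group == "protein_food":
            return ("protein", self.protein)
        if self.group == "fat":
            return ("fat", self.fat)
        return None  # vegetable/beverage: stored serving size

    @property
    def energy(self) -> float:
        """kcal per exchange via 4/4/9 Atwater factors."""
        return 4.0 * self.carbohydrate + 4.0 * self.protein + 9.0 * self.fat


#: One exchange of cereal = 15 g carbohydrate, 2 g protein, 0.5 g fat;
#: fruit or sugar = 15 g carbohydrate; protein food = 7 g protein;
#: fat = 5 g fat.  A vegetable serving is half a cup cooked, carried by
#: each food record's stored serving weight.
EXCHANGE_SPECS: dict[str, ExchangeSpec] = {
    "cereal": ExchangeSpec("cereal", carbohydrate=15.0, protein=2.0, fat=0.5),
    "fruit": ExchangeSpec("fruit", carbohydrate=15.0),
    "sugar": ExchangeSpec("sugar", carbohydrate=15.0),
    "protein_food": ExchangeSpec("protein_food", protein=7.0),
    "fat": ExchangeSpec("fat", fat=5.0),
    "vegetable": ExchangeSpec("vegetable"),
    "beverage": ExchangeSpec("beverage"),
}


def nutrients_for(item: FoodItem, grams: float) -> NutrientVector:
    """Nutrients in ``grams`` of a food: density x grams / 100."""
    if grams < 0:
        raise FoodDBError(f"negative portion for {item.id!r}: {grams} g")
    return item.nutrient_density * (grams / 100.0)


def exchange_portion(
    item: FoodItem, spec: ExchangeSpec | None = None
) -> tuple[float, NutrientVector]:
    """One exchange of a food: its weight in grams and nutrient content.

    A stored per-exchange weight takes precedence; otherwise the weight is
    computed from the defining macronutrient density so that the portion
    supplies the spec's defining amount.
    """
    if spec is None:
        spec = EXCHANGE_SPECS[item.group]
    if item.exchange_grams is not None:
        grams = item.exchange_grams
    else:
        defining = spec.defining_nutrient
        if defining is None:
            raise FoodDBError(
                f"food {item.id!r} ({item.group}) needs a stored exchange_grams"
            )
        nutrient, amount = defining
        density = getattr(item.nutrient_density, nutrient)
        if density <= 0:
            raise FoodDBError(
                f"food {item.id!r} has zero {nutrient} density; cannot size a "
                f"{spec.group} exchange"
            )
        grams = 100.0 * amount / density
    return grams, nutrients_for(item, grams)
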