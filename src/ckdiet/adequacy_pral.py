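"""Adequacy scoring, potential renal acid load, and the report grid.

Percent adequacy is intake / reference x 100, rounded half-up to the
nearest integer percent.  Potential renal acid load (PRAL) follows the
classic estimate of Remer and Manz:

    PRAL (mEq/day) = 0.49 x protein (g)
                   + 0.037 x phosphorus (mg)
                   - 0.021 x potassium (mg)
                   - 0.026 x magnesium (mg)
                   - 0.013 x calcium (mg)

A positive PRAL means the diet produces net acid, a negative PRAL net
base.  The phosphorus-to-protein ratio (mg P per g protein) is the
standard phosphorus-burden metric for renal diets; no bioavailability
weighting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .food_model import EAA_REFERENCE_NAMES, NutrientVector
from .reference_model import ResolvedReference, ResolvedReferences

__all__ = [
    "PRALModel",
    "DEFAULT_PRAL_MODEL",
    "NutrientAssessment",
    "AdequacyReport",
    "GridReport",
    "percent_adequacy",
    "compute_pral",
    "p_prot_ratio",
    "evaluate_profile",
    "adequacy_grid",
    "load_diet_profiles",
]


@dataclass(frozen=True)
class PRALModel:
    """Coefficients of the acid-load estimate (mEq per g or mg).

    Signs are applied as + protein, + phosphorus, - potassium,
    - magnesium, - calcium.
    """

    coef_protein: float = 0.49
    coef_phosphorus: float = 0.037
    coef_potassium: float = 0.021
    coef_magnesium: float = 0.026
    coef_calcium: float = 0.013

    def __post_init__(self) -> None:
        if min(
            self.coef_protein,
            self.coef_phosphorus,
            self.coef_potassium,
            self.coef_magnesium,
            self.coef_calcium,
        ) <= 0:
            raise ValueError("PRAL coefficients must be positive")


DEFAULT_PRAL_MODEL = PRALModel()


def percent_adequacy(intake: float, target: float) -> int:
    """Integer percent of a reference value, rounded half-up."""
    if target <= 0:
        raise ValueError(f"reference target must be positive, got {target}")
    if intake < 0:
        raise ValueError(f"intake must be non-negative, got {intake}")
    return int(math.floor(100.0 * intake / target + 0.5))


def compute_pral(
    profile: NutrientVector, model: PRALModel = DEFAULT_PRAL_MODEL
) -> float:
    """Signed acid-load of a daily profile in mEq/day (unrounded; reports
    print one decimal)."""
    return (
        model.coef_protein * profile.protein
        + model.coef_phosphorus * profile.phosphorus
        - model.coef_potassium * profile.potassium
        - model.coef_magnesium * profile.magnesium
        - model.coef_calcium * profile.calcium
    )


def p_prot_ratio(profile: NutrientVector) -> float:
    """Phosphorus (mg) per gram of protein, rounded to one decimal."""
    if profile.protein <= 0:
        raise ValueError("phosphorus-to-protein ratio undefined for zero protein")
    return round(profile.phosphorus / profile.protein, 1)


# ---------------------------------------------------------------------------
# Profile evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NutrientAssessment:
    """One nutrient's intake against its resolved reference."""

    nutrient: str
    intake: float
    target: float | None
    comparison: str
    percent: int | None
    status: str  # below | meets | above_range | no_reference


@dataclass(frozen=True)
class AdequacyReport:
    """Per-nutrient adequacy of one daily profile, plus PRAL and P/Prot."""

    rows: tuple[NutrientAssessment, ...]
    pral: float
    p_prot: float | None
    diet_label: str = ""
    prescription_g_per_kg: float | None = None

    def __getitem__(self, nutrient: str) -> NutrientAssessment:
        for row in self.rows:
            if row.nutrient == nutrient:
                return row
        raise KeyError(nutrient)

    def status(self, nutrient: str) -> str:
        return self[nutrient].status

    def meets_all_eaa(self) -> bool:
        return all(self[n].status == "meets" for n in EAA_REFERENCE_NAMES)

    def eaa_below(self) -> list[str]:
        return [n for n in EAA_REFERENCE_NAMES if self[n].status == "below"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nutrient": r.nutrient,
                    "intake": r.intake,
                    "reference": r.target,
                    "percent": r.percent,
                    "status": r.status,
                }
                for r in self.rows
            ]
        )


def _assess(
    nutrient: str, intake: float, ref: ResolvedReference, target: float | None
) -> NutrientAssessment:
    if ref.comparison == "none" or (target is None and ref.comparison != "within_range"):
        return NutrientAssessment(nutrient, intake, None, "none", None, "no_reference")
    if ref.comparison == "within_range":
        low, high = ref.range_low, ref.range_high
        status = "below" if intake < low else ("above_range" if intake > high else "meets")
        pct = percent_adequacy(intake, low)
        return NutrientAssessment(nutrient, intake, low, "within_range", pct, status)
    pct = percent_adequacy(intake, target)
    if ref.comparison == "at_most":
        status = "above_range" if intake > target else "meets"
    else:
        status = "meets" if pct >= 100 else "below"
    return NutrientAssessment(nutrient, intake, target, ref.comparison, pct, status)


def evaluate_profile(
    profile: NutrientVector,
    refs: ResolvedReferences,
    diet_label: str = "",
    prescription_g_per_kg: float | None = None,
) -> AdequacyReport:
    """Score a daily nutrient profile against resolved references.

    Methionine and cysteine are combined before comparison; sodium is an
    upper bound; calcium a tolerable window; iron is reported against both
    the male (8 mg) and the 19-50-year female (18 mg) targets as separate
    rows.  An ``at_least`` nutrient is 'below' exactly when its rounded
    percent is under 100.
    """
    rows: list[NutrientAssessment] = []
    for ref in refs:
        intake = profile.get(ref.nutrient)
        if ref.nutrient == "iron":
            rows.append(
                _assess("iron_male", intake, ref, ref.target_male)
            )
            rows.append(
                _assess("iron_female_19_50", intake, ref, ref.target_female)
            )
            continue
        rows.append(_assess(ref.nutrient, intake, ref, ref.target))
    return AdequacyReport(
        rows=tuple(rows),
        pral=compute_pral(profile),
        p_prot=p_prot_ratio(profile) if profile.protein > 0 else None,
        diet_label=diet_label,
        prescription_g_per_kg=prescription_g_per_kg,
    )


# ---------------------------------------------------------------------------
# Grid over (diet model, prescription)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridReport:
    """Adequacy reports per (model, prescription) cell plus PRAL series."""

    cells: Mapping[tuple[str, float], AdequacyReport]
    pral_series: Mapping[str, tuple[tuple[float, float], ...]]

    def pral_sign(self, model: str, prescription: float) -> int:
        """Sign of the cell's unrounded PRAL (the series prints one decimal,
        which can round a marginally positive acid load to 0.0)."""
        v = self.cells[(model, prescription)].pral
        return 0 if v == 0 else int(math.copysign(1, v))

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (model, p), report in self.cells.items():
            for row in report.rows:
                records.append(
                    {
                        "model": model,
                        "prescription": p,
                        "nutrient": row.nutrient,
                        "intake": row.intake,
                        "reference": row.target,
                        "percent": row.percent,
                        "status": row.status,
                    }
                )
            records.append(
                {
                    "model": model,
                    "prescription": p,
                    "nutrient": "pral",
                    "intake": round(report.pral, 1),
                    "reference": None,
                    "percent": None,
                    "status": "no_reference",
                }
            )
        return pd.DataFrame(records)


def adequacy_grid(
    profiles: Mapping[tuple[str, float], NutrientVector],
    refs: ResolvedReferences,
) -> GridReport:
    """Evaluate a (model, prescription) -> profile map into a report grid."""
    if not profiles:
        raise ValueError("at least one profile is required")
    cells = {
        (model, p): evaluate_profile(vec, refs, model, p)
        for (model, p), vec in profiles.items()
    }
    series: dict[str, list[tuple[float, float]]] = {}
    for (model, p), report in cells.items():
        series.setdefault(model, []).append((p, round(report.pral, 1)))
    pral_series = {
        m: tuple(sorted(pairs)) for m, pairs in series.items()
    }
    return GridReport(cells=cells, pral_series=pral_series)


# ---------------------------------------------------------------------------
# Packaged modeled-diet profiles
# ---------------------------------------------------------------------------


def load_diet_profiles() -> dict[tuple[str, float], NutrientVector]:
    """The packaged modeled-diet nutrient profiles (six diet models at the
    seven protein prescriptions, as analyzed with a USDA-based database).

    Combined amino-acid pairs are carried in the ``methionine`` and
    ``phenylalanine_tyrosine`` slots (cysteine zero), matching how the
    reported tables print them; reference comparison is unaffected since
    it uses the combined amounts.
    """
    path = resources.files("ckdiet.data").joinpath("modeled_diet_profiles.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    profiles: dict[tuple[str, float], NutrientVector] = {}
    for _, row in df.iterrows():
        vec = NutrientVector(
            energy=row["energy"],
            carbohydrate=row["carbohydrate"],
            fiber=row["fiber"],
            protein=row["protein"],
            tryptophan=row["tryptophan"],
            threonine=row["threonine"],
            isoleucine=row["isoleucine"],
            leucine=row["leucine"],
            lysine=row["lysine"],
            methionine=row["methionine_cysteine"],
            phenylalanine_tyrosine=row["phenylalanine_tyrosine"],
            valine=row["valine"],
            histidine=row["histidine"],
            fat=row["fat"],
            epa_dha=row["epa_dha"],
            sodium=row["sodium"],
            potassium=row["potassium"],
            phosphorus=row["phosphorus"],
            calcium=row["calcium"],
            magnesium=row["magnesium"],
            copper=row["copper"],
            manganese=row["manganese"],
            iron=row["iron"],
            zinc=row["zinc"],
            thiamine=row["thiamine"],
            riboflavin=row["riboflavin"],
            niacin=row["niacin"],
            pyridoxine=row["pyridoxine"],
            folate=row["folate"],
            cobalamin=row["cobalamin"],
        )
        profiles[(str(row["model"]), float(row["prescription"]))] = vec
    return profiles


def load_diet_profile_extras() -> pd.DataFrame:
    """Side columns of the packaged profiles: printed animal/plant protein
    split and printed phosphorus-to-protein ratio."""
    path = resources.files("ckdiet.data").joinpath("modeled_diet_profiles.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    return df[["model", "prescription", "animal_protein", "plant_protein", "p_prot_printed"]]
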