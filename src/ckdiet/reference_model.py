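"""Dietary reference values (RDA/AI/WHO/CKD-specific) and their resolution.

Reference entries are stored on the *basis* their source defines them:
per-kg of body weight for the adult essential-amino-acid RDAs, per
1000 kcal for the fiber AI, absolute daily amounts for micronutrients,
or a tolerable window (calcium for CKD patients).  ``resolve_references``
turns a reference set into daily targets for a given body weight, energy
prescription and sex.

The adult per-kg EAA constants shipped in the default set (DRI 2005) are
tryptophan 5, threonine 20, isoleucine 19, leucine 42, lysine 38,
methionine+cysteine 19, phenylalanine+tyrosine 33, valine 24 and
histidine 14 mg/kg/day; at the 70-kg reference body weight these resolve
to the familiar adult values (e.g. lysine 2660 mg/day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

from .food_model import NUTRIENT_FIELDS

__all__ = [
    "ReferenceEntry",
    "ResolvedReference",
    "ResolvedReferences",
    "ReferenceError",
    "load_reference_set",
    "load_default_references",
    "resolve_references",
]

_DERIVED_NAMES = {"methionine_cysteine"}
_VALID_KINDS = {"RDA", "AI", "CKD", "WHO"}
_VALID_BASES = {"absolute", "per_kg", "per_1000kcal", "range"}
_VALID_COMPARISONS = {"at_least", "at_most", "within_range", "none"}


class ReferenceError(ValueError):
    """Raised for malformed reference entries or resolution inputs."""


@dataclass(frozen=True)
class ReferenceEntry:
    """One nutrient's reference value on its native basis."""

    nutrient: str
    kind: str
    basis: str
    comparison: str
    value_male: float | None = None
    value_female: float | None = None
    range_low: float | None = None
    range_high: float | None = None
    age_note: str = ""

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENT_FIELDS and self.nutrient not in _DERIVED_NAMES:
            raise ReferenceError(f"unknown nutrient name {self.nutrient!r}")
        if self.kind not in _VALID_KINDS:
            raise ReferenceError(f"unknown reference kind {self.kind!r}")
        if self.basis not in _VALID_BASES:
            raise ReferenceError(f"unknown basis {self.basis!r}")
        if self.comparison not in _VALID_COMPARISONS:
            raise ReferenceError(f"unknown comparison {self.comparison!r}")
        if self.basis == "range":
            if self.range_low is None or self.range_high is None:
                raise ReferenceError(f"{self.nutrient}: range basis needs low and high")
            if not 0 < self.range_low < self.range_high:
                raise ReferenceError(f"{self.nutrient}: require 0 < low < high")
        elif self.comparison != "none":
            if self.value_male is None or self.value_male <= 0:
                raise ReferenceError(f"{self.nutrient}: reference value must be > 0")
            if self.value_female is not None and self.value_female <= 0:
                raise ReferenceError(f"{self.nutrient}: reference value must be > 0")

    def value_for(self, sex: str) -> float | None:
        if sex == "female" and self.value_female is not None:
            return self.value_female
        return self.value_male


@dataclass(frozen=True)
class ResolvedReference:
    """A daily target for one nutrient at a given body weight and energy."""

    nutrient: str
    kind: str
    comparison: str
    target: float | None  # requested sex
    target_male: float | None
    target_female: float | None
    range_low: float | None = None
    range_high: float | None = None
    age_note: str = ""


class ResolvedReferences:
    """Mapping nutrient name -> :class:`ResolvedReference`."""

    def __init__(
        self,
        entries: Iterable[ResolvedReference],
        *,
        body_weight: float,
        energy: float,
        sex: str,
    ):
        self._entries = {e.nutrient: e for e in entries}
        self.body_weight = body_weight
        self.energy = energy
        self.sex = sex

    def __getitem__(self, nutrient: str) -> ResolvedReference:
        try:
            return self._entries[nutrient]
        except KeyError:
            raise ReferenceError(f"no reference for nutrient {nutrient!r}") from None

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self._entries

    def __iter__(self) -> Iterator[ResolvedReference]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def target(self, nutrient: str) -> float:
        t = self[nutrient].target
        if t is None:
            raise ReferenceError(f"nutrient {nutrient!r} carries no target")
        return t


def load_reference_set(source: str | Path | None = None) -> list[ReferenceEntry]:
    """Load a reference set from YAML (the packaged default when omitted)."""
    if source is None:
        data = yaml.safe_load(
            resources.files("ckdiet.data").joinpath("reference_values.yaml").read_text()
        )
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "references" not in data:
        raise ReferenceError("reference file must contain a 'references' list")
    return [ReferenceEntry(**block) for block in data["references"]]


def load_default_references() -> list[ReferenceEntry]:
    return load_reference_set(None)


def resolve_references(
    refset: Iterable[ReferenceEntry],
    body_weight: float,
    energy: float,
    sex: str = "male",
) -> ResolvedReferences:
    """Resolve a reference set to daily targets.

    per_kg entries scale with body weight; per_1000kcal entries scale with
    energy/1000 and are rounded to the nearest gram (the convention the
    fiber AI is quoted with: 14 g/1000 kcal at 2100 kcal -> 29 g/day);
    absolute and range entries pass through unchanged.
    """
    if body_weight <= 0:
        raise ReferenceError(f"body weight must be positive, got {body_weight}")
    if energy <= 0:
        raise ReferenceError(f"energy must be positive, got {energy}")
    if sex not in ("male", "female"):
        raise ReferenceError(f"sex must be 'male' or 'female', got {sex!r}")

    def scale(value: float | None, basis: str) -> float | None:
        if value is None:
            return None
        if basis == "per_kg":
            return value * body_weight
        if basis == "per_1000kcal":
            return float(round(value * energy / 1000.0))
        return value

    resolved = []
    for entry in refset:
        if entry.basis == "range":
            resolved.append(
                ResolvedReference(
                    nutrient=entry.nutrient,
                    kind=entry.kind,
                    comparison=entry.comparison,
                    target=None,
                    target_male=None,
                    target_female=None,
                    range_low=entry.range_low,
                    range_high=entry.range_high,
                    age_note=entry.age_note,
                )
            )
            continue
        male = scale(entry.value_male, entry.basis)
        female = scale(
            entry.value_female if entry.value_female is not None else entry.value_male,
            entry.basis,
        )
        resolved.append(
            ResolvedReference(
                nutrient=entry.nutrient,
                kind=entry.kind,
                comparison=entry.comparison,
                target=female if sex == "female" else male,
                target_male=male,
                target_female=female,
                age_note=entry.age_note,
            )
        )
    return ResolvedReferences(
        resolved, body_weight=body_weight, energy=energy, sex=sex
    )
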