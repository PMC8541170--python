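# Default dietary reference set for adult CKD diet assessment.
#
# Sources (by kind):
#   RDA/AI  - Dietary Reference Intakes: macronutrients & amino acids (2005,
#             per-kg adult EAA values), micronutrient reports (1997, 1998,
#             2000).
#   WHO     - FAO/WHO expert consultation on dietary fats (2008): EPA+DHA.
#   CKD     - kidney-disease-specific recommendations (KDOQI 2020 for sodium
#             and calcium; the classic renal-failure pyridoxine target).
#
# basis: absolute (per day), per_kg (x body weight), per_1000kcal (x energy
# /1000, rounded to nearest gram), range (low..high window).
# comparison: at_least | at_most | within_range | none.
# Units follow the nutrient vector (mg unless noted; copper/folate/cobalamin ug).
references:
  - {nutrient: tryptophan,             kind: RDA, basis: per_kg, value_male: 5,   comparison: at_least}
  - {nutrient: threonine,              kind: RDA, basis: per_kg, value_male: 20,  comparison: at_least}
  - {nutrient: isoleucine,             kind: RDA, basis: per_kg, value_male: 19,  comparison: at_least}
  - {nutrient: leucine,                kind: RDA, basis: per_kg, value_male: 42,  comparison: at_least}
  - {nutrient: lysine,                 kind: RDA, basis: per_kg, value_male: 38,  comparison: at_least}
  - {nutrient: methionine_cysteine,    kind: RDA, basis: per_kg, value_male: 19,  comparison: at_least}
  - {nutrient: phenylalanine_tyrosine, kind: RDA, basis: per_kg, value_male: 33,  comparison: at_least}
  - {nutrient: valine,                 kind: RDA, basis: per_kg, value_male: 24,  comparison: at_least}
  - {nutrient: histidine,              kind: RDA, basis: per_kg, value_male: 14,  comparison: at_least}
  - {nutrient: fiber,                  kind: AI,  basis: per_1000kcal, value_male: 14, comparison: at_least}
  - {nutrient: epa_dha,                kind: WHO, basis: absolute, value_male: 250, comparison: at_least}
  - {nutrient: sodium,                 kind: CKD, basis: absolute, value_male: 2300, comparison: at_most}
  - {nutrient: calcium,                kind: CKD, basis: range, range_low: 800, range_high: 1000, comparison: within_range}
  - {nutrient: magnesium,              kind: RDA, basis: absolute, value_male: 420, value_female: 320, comparison: at_least}
  - {nutrient: copper,                 kind: RDA, basis: absolute, value_male: 900, comparison: at_least}
  - {nutrient: manganese,              kind: AI,  basis: absolute, value_male: 2.3, value_female: 1.8, comparison: at_least}
  - {nutrient: iron,                   kind: RDA, basis: absolute, value_male: 8, value_female: 18, comparison: at_least,
     age_note: "female value applies to women 19-50 years; women over 50 use 8 mg/day"}
  - {nutrient: zinc,                   kind: RDA, basis: absolute, value_male: 11, value_female: 8, comparison: at_least}
  - {nutrient: thiamine,               kind: RDA, basis: absolute, value_male: 1.2, value_female: 1.1, comparison: at_least}
  - {nutrient: riboflavin,             kind: RDA, basis: absolute, value_male: 1.3, value_female: 1.1, comparison: at_least}
  - {nutrient: niacin,                 kind: RDA, basis: absolute, value_male: 16, value_female: 14, comparison: at_least}
  - {nutrient: pyridoxine,             kind: CKD, basis: absolute, value_male: 5.0, comparison: at_least}
  - {nutrient: folate,                 kind: RDA, basis: absolute, value_male: 400, comparison: at_least}
  - {nutrient: cobalamin,              kind: RDA, basis: absolute, value_male: 2.4, comparison: at_least}
  # No reference target exists for dietary phosphorus and potassium; they are
  # reported as amounts (and via the phosphorus-to-protein ratio) only.
  - {nutrient: phosphorus,             kind: CKD, basis: absolute, comparison: none}
  - {nutrient: potassium,              kind: CKD, basis: absolute, comparison: none}
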