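# ckdiet

Exchange-based diet-pattern modeling for chronic kidney disease (CKD)
nutrition: build menus for renal protein prescriptions, apply plant-based
and vegetarian substitution models, score nutrient adequacy against
dietary reference values, and compute the potential renal acid load.

## The problem

Low protein diets (LPD, 0.5–0.8 g protein/kg/day) are prescribed to slow
CKD progression; dialysis patients instead need moderately high protein
(MHPD, 1.0–1.2 g/kg/day). Plant-based and vegetarian versions of these
diets are increasingly recommended, but plant proteins are poorer in
lysine and the sulfur amino acids than animal proteins, so a restricted,
plant-based prescription can silently under-supply essential amino acids
(EAAs). `ckdiet` makes that arithmetic explicit and reproducible for
dietitians and nutrition researchers.

## The model

Menus are built from the renal **exchange system**: one protein-food
exchange carries 7 g protein, one cereal exchange 15 g carbohydrate /
2 g protein / 0.5 g fat, one fruit or sugar exchange 15 g carbohydrate,
one fat exchange 5 g fat, and a vegetable serving is half a cup cooked
(credited 1.25 g protein, 5 g carbohydrate). Every plan fixes 3 fruit
exchanges and 4 vegetable servings; cereals are fixed at 8 exchanges
(LPD) or 13 (MHPD), protein-food exchanges are chosen to meet the
prescription, and sugar/fat exchanges pad the 30 kcal/kg energy target.

Six diet patterns are modeled by substituting a conventional (≥50 %
animal protein) menu exchange-for-exchange at equal protein:
plant-dominant (**PLADO**, ~30 % animal), **vegan**, **ovo-** (1–3 eggs/day),
**lacto-** (1–2 dairy/day) and **lacto-ovo-vegetarian**.

Daily profiles are scored against adult references — per-kg EAA RDAs
(e.g. lysine 38 mg/kg → 2660 mg at 70 kg), the fiber AI (14 g/1000 kcal),
EPA+DHA ≥ 250 mg, and CKD-specific sodium (≤ 2300 mg), calcium
(800–1000 mg) and pyridoxine (5 mg) targets — and two renal metrics:

```
PRAL (mEq/d) = 0.49·protein(g) + 0.037·P(mg) − 0.021·K(mg) − 0.026·Mg(mg) − 0.013·Ca(mg)
P/Prot      = phosphorus (mg) / protein (g)
```

Positive PRAL means the diet produces net acid; negative, net base.

## Worked example

```
$ ckdiet plan -p 0.6
diet class: LPD
prescription: protein 42 g (8%EN), carbohydrate 299 g (57%EN), fat 82 g (35%EN)
cereal: 8
fruit: 3
vegetable: 4
poultry_fish: 3
egg: 0
sugar: 4
fat: 14
```

A 0.6 g/kg prescription for a 70-kg adult resolves to 42 g protein and a
pattern of 8 cereal, 3 protein-food, 4 sugar and 14 fat exchanges. The
same pipeline from Python, comparing conventional and vegan versions of
that menu:

```python
from ckdiet import *

db = load_default_db()
refs = resolve_references(load_default_references(), body_weight=70, energy=2100)
rx = Prescription(protein_g_per_kg=0.6)
menu = build_menu(allocate_exchanges(rx), db, seed=0, prescription=rx)
for label in ("conventional", "vegan"):
    m = menu if label == "conventional" else apply_diet_model(menu, label, db)
    rep = evaluate_profile(aggregate_menu(m, db), refs)
    row = rep["lysine"]
    print(label, round(row.intake), f"{row.percent}% RDA", row.status,
          "PRAL", round(rep.pral, 1))
```

prints

```
conventional 2878 108% RDA meets PRAL -5.6
vegan 2455 92% RDA below PRAL -12.9
```

— the conventional low protein diet just clears the 2660 mg lysine RDA
(108 %), while the vegan substitution of the very same menu falls to
92 % and is flagged below reference; both diets are net base-producing
(negative PRAL) at this prescription.

## Layout

| module | role |
| --- | --- |
| `ckdiet.food_model` | nutrient vectors, food database I/O, exchange portions |
| `ckdiet.reference_model` | reference values and their per-kg / per-1000-kcal resolution |
| `ckdiet.menu_engine` | prescriptions → exchange patterns → 3-day menus → daily totals |
| `ckdiet.diet_models` | the six diet patterns and protein-source accounting |
| `ckdiet.adequacy_pral` | adequacy scoring, PRAL, P/Prot, report grids |
| `ckdiet.synthetic_data` | seeded synthetic food databases and menu suites |
| `ckdiet.cli` | `ckdiet plan / substitute / adequacy / pral / synth / run` |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
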