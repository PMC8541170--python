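# Methods

This note records the modeling choices behind `ckdiet`: what is computed,
which parameters matter, where the design was genuinely open, and what
the packaged fixtures and synthetic data can and cannot show.

## Nutrient accounting

A food is a per-100 g nutrient density vector (energy; protein,
carbohydrate, fat, fiber; the nine EAA entries with methionine/cysteine
stored separately; EPA+DHA; macrominerals; trace elements; B vitamins and
folate/cobalamin). Portions scale linearly and add component-wise; no
cooking-retention or bioavailability adjustment is applied anywhere
(phosphorus in particular is taken at face value, as renal dietetics
tables usually print it). Sodium reflects only what foods naturally
contain — salt and seasonings are deliberately absent from the fixtures,
since condiment use does not discriminate between the diet patterns
being compared.

Methionine + cysteine and phenylalanine + tyrosine are combined at
*reporting* time because reference values address the pairs; storage
keeps them separate so per-food data can be entered as published.

## Exchange construction

One exchange supplies its group's defining macronutrient: 7 g protein
(protein foods), 15 g carbohydrate (cereal, fruit, sugar; cereal also
carries 2 g protein and 0.5 g fat), 5 g fat (fats). Vegetables are a
half-cup cooked serving credited 1.25 g protein and 5 g carbohydrate
per serving. That credit is a fitted allowance, not a measured value: it
is the unique per-serving amount that closes the protein arithmetic of
the published conventional patterns (e.g. 8×2 + 2×7 + 4×1.25 = 35 g at
0.5 g/kg), and it is configurable (`VegetableAllowance`).

Pattern allocation is closed-form rather than a general integer
program. Fruit (3) and vegetables (4) are fixed for every prescription;
cereals are fixed at 8 (LPD, ≤ 0.8 g/kg) or 13 (MHPD, ≥ 1.0 g/kg).
Protein-food exchanges `n` minimize |pattern protein − target|, which is
exact for LPDs and within 3 g for MHPDs (inside the one-exchange, 7 g,
contract). The remaining counts follow the construction conventions of
the published plans: LPD fat is 14 and sugar steps down as protein
foods rise (`sugar = 5 − (n−1)//2`); MHPD sugar is 0 and fat trades
against protein foods (`fat = 19 − n`); one egg exchange enters at five
protein exchanges and a second at eight (`egg = (n−2)//3`). We chose
explicit rules over an energy-minimizing optimizer because no consistent
per-exchange energy assignment makes the published sugar/fat counts the
optimum of a linear objective — the published menus embed dish-level
energy (deep-fried fish, sweetened tea) that exchange arithmetic cannot
see. The 54–58 % carbohydrate and 30–35 % fat energy bands are enforced
at the prescription level (`macronutrient_distribution`) and reported,
not solved for.

Menus realize a pattern as three days of concrete portions, cycling
foods round-robin within each group in database order with a
seed-derived offset per day; identical seed and inputs give identical
menus. The cultural content of a menu (rice vs dosa, which fish) is
data, not logic.

## Substitution models

All substitution operates on protein-food portions only and preserves
each day's protein exactly (fractional exchanges allowed), so total
protein is invariant to the diet model — the property that makes
adequacy differences attributable to protein *sources*. Egg and dairy
exchange windows (ovo 1–3 eggs, lacto 1–2 dairy, lacto-ovo both) are
enforced per day; the "about 70 % plant" PLADO target is likewise
interpreted per day (tolerance ± 0.05), matching how such menus are
planned in practice. Plant substitutes are drawn soy-first, then
legumes, round-robin; the order is configurable data.

The conventional pattern's "at least half animal protein" rule is
validated with a −0.15 tolerance: once cereal and vegetable protein are
credited, the 0.5 g/kg conventional pattern can only realize about 38 %
animal protein (published realizations reach ~42 %), so a strict 0.50
floor would reject the reference diet itself at the lowest
prescriptions.

## References and scoring

Reference entries carry their native basis: per-kg EAA RDAs (tryptophan
5, threonine 20, isoleucine 19, leucine 42, lysine 38, methionine +
cysteine 19, phenylalanine + tyrosine 33, valine 24, histidine 14
mg/kg/day), the fiber AI per 1000 kcal (14 g, rounded to the nearest
gram after scaling — 29 g at 2100 kcal), absolute micronutrient RDAs/AIs
with sex-specific values, and CKD-specific targets (sodium ≤ 2300 mg,
calcium 800–1000 mg as a window with a distinct `above_range` status,
pyridoxine 5 mg). Iron is scored against both the 8 mg (men, older
women) and 18 mg (women 19–50) targets rather than choosing one.
Potassium and phosphorus carry no reference — their clinical targets are
serum-driven — and are reported as amounts plus the P/Prot ratio.

Percent adequacy rounds half-up to the nearest integer percent; an
`at_least` nutrient is "below" exactly when the rounded percent is under
100. Half-up is the only rounding consistent with the full set of
published per-exchange percentages (one case requires 21.50 → 22). PRAL
is the signed linear form 0.49·protein + 0.037·P − 0.021·K − 0.026·Mg −
0.013·Ca, computed unrounded and printed to one decimal; the
phosphorus-to-protein ratio is printed to one decimal.

When the packaged modeled-diet profiles are rescored, recomputed P/Prot
cells can differ from the printed ratios by up to ~0.3 mg/g because the
profiles print integer-rounded protein while the original ratios were
computed from unrounded values; the 0.5 g/kg conventional cell is the
canonical example (525/36 → 14.6 vs printed 14.5). Tests assert
exactness only where the printed inputs reproduce the printed ratio.

## Packaged fixtures

`protein_exchange_foods.csv` holds the seven protein-food records (king
mackerel, chicken, egg, whole milk, tofu, lentils, chickpeas) at their
per-exchange weights; protein, leucine, lysine, methionine and cysteine
are the published food-composition values, and every other nutrient
column is a plausible synthetic estimate. `menu_foods_synthetic.csv`
(cereals, fruits, vegetables, fats, sugar, tea) is entirely synthetic.
`modeled_diet_profiles.csv` transcribes the modeled-diet nutrient tables
(six diet models × seven prescriptions) used as inputs for adequacy and
acid-load scoring. `reference_values.yaml` is the default reference set.

## Synthetic data

The generator emulates the class structure the analysis depends on, not
any real database: amino-acid densities are drawn per gram of protein
inside class ranges (animal lysine 75–95 vs plant 55–70 mg/g; animal
sulfur pair 35–52 vs plant 20–28 — anchors derived from per-exchange
values such as fish lysine 652/7 ≈ 93 and tofu 463/7 ≈ 66), with
multiplicative lognormal jitter (σ = 0.1, clipped back to the range).
Cereals are lysine-poor (36–46 mg/g) relative to vegetables (50–62),
which is what makes the background groups matter at low prescriptions.
Presence rules are absolute: cobalamin only in animal foods, EPA+DHA
only in fish, fiber only in plant foods. Everything is deterministic
given the seed.

What passing synthetic tests shows: the pipeline recovers the
qualitative adequacy trend (vegan 0.6 g/kg fails lysine, conventional
0.6 passes, every diet passes from 0.7 g/kg) whenever the class-level
density contrasts hold. What it does not show: agreement with any real
food's micronutrient profile, food-matrix effects, regional variability
in composition, or fortified/processed products (deliberately excluded,
as are protein-free specialty products and meat analogues).

## Numerical conventions

Exchange-count arithmetic uses half-up integer rounding. Substitution
snaps a nearly-full trailing exchange to exactly 7 g so reapplying a
model reproduces portions bit-for-bit up to 10⁻⁹ g (PLADO re-derives its
30 % animal target from portion sums, which moves the last ulp). Food
tables are parsed with round-trip float precision so write → load is
bit-identical. Problem sizes are small throughout — a full 6 × 7 grid
with 3-day menus is a few thousand portion scalings — so the whole test
and acceptance workload runs in seconds.

## Known limitations

* Menus are idealized patterns, not dietary intake data; adequacy
  conclusions are about prescriptions, not patients.
* The exchange energy model (4/4/9 on defining macronutrients) under-
  counts dish-level energy; realized menu energies legitimately scatter
  around the 2100 kcal target rather than matching it.
* References are adult values; no age stratification beyond the dual
  iron/micronutrient sex values, and no Estimated Average Requirement
  layer.
* No NEAP or alternative acid-load estimators; no phosphorus
  bioavailability weighting.
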