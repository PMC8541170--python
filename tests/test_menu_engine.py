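import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdiet.food_model import FoodDBError, NutrientVector, load_protein_foods_db
from ckdiet.menu_engine import (
    ExchangePattern,
    InfeasiblePatternError,
    MenuPlan,
    Prescription,
    aggregate_menu,
    allocate_exchanges,
    build_menu,
    macronutrient_distribution,
    macronutrient_summary,
)

# the published conventional exchange patterns for a 70-kg adult:
# prescription -> (cereal, fruit, vegetable, poultry_fish, egg, sugar, fat)
PUBLISHED_PATTERNS = {
    0.5: (8, 3, 4, 2, 0, 5, 14),
    0.6: (8, 3, 4, 3, 0, 4, 14),
    0.7: (8, 3, 4, 4, 0, 4, 14),
    0.8: (8, 3, 4, 4, 1, 3, 14),
    1.0: (13, 3, 4, 5, 1, 0, 13),
    1.1: (13, 3, 4, 6, 1, 0, 12),
    1.2: (13, 3, 4, 6, 2, 0, 11),
}

# prescription -> (protein g, protein %EN, carb g, carb %EN, fat g, fat %EN)
PUBLISHED_MACROS = {
    0.5: (35, 7, 305, 58, 82, 35),
    0.6: (42, 8, 299, 57, 82, 35),
    0.7: (49, 9, 294, 56, 82, 35),
    0.8: (56, 11, 284, 54, 82, 35),
    1.0: (70, 13, 284, 54, 77, 33),
    1.1: (77, 15, 284, 54, 72, 31),
    1.2: (84, 16, 284, 54, 70, 30),
}


class TestPrescription:
    def test_targets_scale_with_body_weight(self):
        rx = Prescription(protein_g_per_kg=0.6, body_weight=70)
        assert rx.protein_target_g == 42
        assert rx.energy_target_kcal == 2100

    @pytest.mark.parametrize("p,cls", [(0.5, "LPD"), (0.8, "LPD"), (1.0, "MHPD"), (1.2, "MHPD")])
    def test_diet_class(self, p, cls):
        assert Prescription(protein_g_per_kg=p).diet_class == cls

    def test_out_of_range_prescription_rejected(self):
        with pytest.raises(ValueError):
            Prescription(protein_g_per_kg=2.0)


class TestAllocateExchanges:
    @pytest.mark.parametrize("p", sorted(PUBLISHED_PATTERNS))
    def test_reproduces_published_patterns(self, p):
        pattern = allocate_exchanges(Prescription(protein_g_per_kg=p))
        assert (
            pattern.cereal,
            pattern.fruit,
            pattern.vegetable,
            pattern.poultry_fish,
            pattern.egg,
            pattern.sugar,
            pattern.fat,
        ) == PUBLISHED_PATTERNS[p]

    @pytest.mark.parametrize("p", sorted(PUBLISHED_PATTERNS))
    def test_pattern_protein_within_one_exchange_of_target(self, p):
        rx = Prescription(protein_g_per_kg=p)
        summary = macronutrient_summary(allocate_exchanges(rx))
        assert abs(summary["protein_g"] - rx.protein_target_g) <= 7

    def test_unreachable_protein_target_is_diagnosed(self):
        with pytest.raises(InfeasiblePatternError, match="binding"):
            allocate_exchanges(Prescription(protein_g_per_kg=1.5, body_weight=140))


class TestMacronutrientDistribution:
    @pytest.mark.parametrize("p", sorted(PUBLISHED_MACROS))
    def test_reproduces_published_macro_rows(self, p):
        d = macronutrient_distribution(Prescription(protein_g_per_kg=p))
        pg, ppct, cg, cpct, fg, fpct = PUBLISHED_MACROS[p]
        assert d["protein_g"] == pg
        assert d["protein_pct"] == ppct
        assert d["carbohydrate_g"] == cg
        assert d["carbohydrate_pct"] == cpct
        assert d["fat_g"] == fg
        assert d["fat_pct"] == fpct
        assert d["protein_pct"] + d["carbohydrate_pct"] + d["fat_pct"] == 100


class TestMacronutrientSummary:
    def test_cereal_only_pattern(self):
        pattern = ExchangePattern(cereal=8, fruit=0, vegetable=0, poultry_fish=0,
                                  egg=0, sugar=0, fat=0)
        s = macronutrient_summary(pattern)
        assert (s["protein_g"], s["carbohydrate_g"], s["fat_g"]) == (16, 120, 4)

    def test_protein_and_sugar_pattern(self):
        pattern = ExchangePattern(cereal=0, fruit=0, vegetable=0, poultry_fish=2,
                                  egg=0, sugar=5, fat=0)
        s = macronutrient_summary(pattern)
        assert (s["protein_g"], s["carbohydrate_g"]) == (14, 75)


class TestBuildMenu:
    def test_each_day_realizes_protein_exchanges(self, fixture_db):
        pattern = allocate_exchanges(Prescription(protein_g_per_kg=0.5))
        menu = build_menu(pattern, fixture_db, seed=3)
        for day in menu.days:
            protein_portions = [
                (fid, g) for fid, g in day
                if fixture_db[fid].group == "protein_food"
            ]
            assert len(protein_portions) == 2
            from ckdiet.food_model import nutrients_for

            for fid, g in protein_portions:
                assert nutrients_for(fixture_db[fid], g).protein == pytest.approx(7, rel=1e-9)

    def test_same_seed_reproduces_menu(self, fixture_db):
        pattern = allocate_exchanges(Prescription(protein_g_per_kg=0.7))
        m1 = build_menu(pattern, fixture_db, seed=11)
        m2 = build_menu(pattern, fixture_db, seed=11)
        assert m1.days == m2.days

    def test_missing_group_is_an_error(self):
        db = load_protein_foods_db()  # protein foods only: no cereal/fruit
        pattern = allocate_exchanges(Prescription(protein_g_per_kg=0.5))
        with pytest.raises(FoodDBError, match="no matching food"):
            build_menu(pattern, db, seed=0)


class TestAggregateMenu:
    def test_single_portion_menu_is_that_portion(self, fixture_db):
        from ckdiet.food_model import nutrients_for

        menu = MenuPlan(
            days=((("tofu", 87.0),),),
            model_label="test",
            prescription=Prescription(protein_g_per_kg=0.6),
        )
        assert aggregate_menu(menu, fixture_db) == nutrients_for(fixture_db["tofu"], 87.0)

    def test_identical_days_average_to_one_day(self, fixture_db):
        day = (("king_mackerel", 35.0), ("whole_milk", 220.0))
        one = MenuPlan(days=(day,), model_label="t",
                       prescription=Prescription(protein_g_per_kg=0.6))
        three = MenuPlan(days=(day, day, day), model_label="t",
                         prescription=Prescription(protein_g_per_kg=0.6))
        v1, v3 = aggregate_menu(one, fixture_db), aggregate_menu(three, fixture_db)
        for name in NutrientVector.field_names():
            assert v3.get(name) == pytest.approx(v1.get(name), abs=1e-9)

    def test_fish_plus_milk_day(self, fixture_db):
        """35 g fish + 220 g milk: 14 g protein, lysine 652 + 308 = 960 mg."""
        menu = MenuPlan(
            days=((("king_mackerel", 35.0), ("whole_milk", 220.0)),),
            model_label="t",
            prescription=Prescription(protein_g_per_kg=0.6),
        )
        vec = aggregate_menu(menu, fixture_db)
        assert vec.protein == pytest.approx(14, abs=1e-9)
        assert vec.lysine == pytest.approx(960, abs=1e-9)

    def test_unresolvable_food_id_is_an_error(self, fixture_db):
        menu = MenuPlan(
            days=((("no_such_food", 10.0),),),
            model_label="t",
            prescription=Prescription(protein_g_per_kg=0.6),
        )
        with pytest.raises(FoodDBError, match="unknown food id"):
            aggregate_menu(menu, fixture_db)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(perm=st.permutations([("king_mackerel", 35.0), ("tofu", 87.0),
                                 ("lentils", 78.0), ("whole_milk", 110.0)]))
    def test_permutation_invariance(self, perm):
        db = load_protein_foods_db()
        base = MenuPlan(
            days=((("king_mackerel", 35.0), ("tofu", 87.0),
                   ("lentils", 78.0), ("whole_milk", 110.0)),),
            model_label="t", prescription=Prescription(protein_g_per_kg=0.6),
        )
        shuffled = MenuPlan(days=(tuple(perm),), model_label="t",
                            prescription=Prescription(protein_g_per_kg=0.6))
        v1, v2 = aggregate_menu(base, db), aggregate_menu(shuffled, db)
        for name in NutrientVector.field_names():
            assert v1.get(name) == pytest.approx(v2.get(name), abs=1e-9)
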