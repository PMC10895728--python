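"""Dietary-record parsing, intake aggregation and energy shares."""

import numpy as np
import pandas as pd
import pytest

from diinpx.dietary import (
    DietaryInputError,
    compute_energy_shares,
    compute_intake,
    load_dietary_records,
    load_food_composition,
    load_substitutions,
)

COMP_HEADER = "food_id\tname\tgroup\tsubgroup\titem\tenergy_kcal_per_100g\tfat_g[g]\tfiber_g[g]\n"


def write_comp(tmp_path, rows, header=COMP_HEADER):
    p = tmp_path / "comp.tsv"
    p.write_text(header + "".join(rows))
    return p


def write_records(tmp_path, rows):
    p = tmp_path / "records.tsv"
    p.write_text("subject_id\tday\tfood_id\tgrams\n" + "".join(rows))
    return p


@pytest.fixture
def simple_comp(tmp_path):
    return load_food_composition(
        write_comp(
            tmp_path,
            [
                "A\tbutter\toils\tbutter\tbutter\t717\t10\t0\n",
                "B\tbread\tcereals\tbread\twhite bread\t265\t3.2\t5\n",
                "C\tapple\tfruits\tfresh\tapple\t52\t0.2\t2.4\n",
            ],
        )
    )


class TestLoadComposition:
    def test_well_formed_file_parses(self, simple_comp):
        assert len(simple_comp.table) == 3
        assert simple_comp.units == {"fat_g": "g", "fiber_g": "g"}
        assert simple_comp.table.loc["A", "energy_kcal_per_100g"] == 717

    def test_duplicate_food_id_named_in_error(self, tmp_path):
        rows = [
            "A\tx\tg\ts\ti\t100\t1\t1\n",
            "A\ty\tg\ts\ti\t200\t2\t2\n",
        ]
        with pytest.raises(DietaryInputError, match="A"):
            load_food_composition(write_comp(tmp_path, rows))

    def test_unknown_unit_named_in_error(self, tmp_path):
        header = COMP_HEADER.replace("fat_g[g]", "fat_g[oz]")
        with pytest.raises(DietaryInputError, match="oz"):
            load_food_composition(
                write_comp(tmp_path, ["A\tx\tg\ts\ti\t100\t1\t1\n"], header)
            )

    def test_microgram_alias_normalised(self, tmp_path):
        header = COMP_HEADER.replace("fiber_g[g]", "b12_ug[µg]")
        comp = load_food_composition(
            write_comp(tmp_path, ["A\tx\tg\ts\ti\t100\t1\t1\n"], header)
        )
        assert comp.units["b12_ug"] == "ug"


class TestComputeIntake:
    def test_single_entry_hand_arithmetic(self, simple_comp, tmp_path):
        # 200 g of food A (10 g fat/100 g) on day 1 only
        records = load_dietary_records(write_records(tmp_path, ["S1\t1\tA\t200\n"]))
        (profile,) = compute_intake(records, simple_comp)
        assert profile.mean_daily_nutrients["fat_g"] == pytest.approx(
            200 / 100 * 10 / 7, rel=1e-12
        )
        assert profile.mean_daily_energy == pytest.approx(2 * 717 / 7, rel=1e-12)

    def test_repeated_food_different_days(self, simple_comp, tmp_path):
        # two 100 g servings of B (5 g fiber/100 g) -> 10/7 g/day
        records = load_dietary_records(
            write_records(tmp_path, ["S1\t1\tB\t100\n", "S1\t3\tB\t100\n"])
        )
        (profile,) = compute_intake(records, simple_comp)
        assert profile.mean_daily_nutrients["fiber_g"] == pytest.approx(10 / 7, rel=1e-12)

    def test_nothing_eaten_all_week_gives_zeros(self, simple_comp, tmp_path):
        records = load_dietary_records(write_records(tmp_path, ["S1\t1\tA\t0\n"]))
        (profile,) = compute_intake(records, simple_comp)
        assert profile.mean_daily_energy == 0
        assert all(v == 0 for v in profile.mean_daily_nutrients.values())

    def test_unresolvable_food_names_subject_day_food(self, simple_comp, tmp_path):
        records = load_dietary_records(write_records(tmp_path, ["S9\t4\tZZ\t50\n"]))
        with pytest.raises(DietaryInputError, match=r"S9.*4.*ZZ"):
            compute_intake(records, simple_comp)

    def test_substitution_resolves_missing_food(self, simple_comp, tmp_path):
        records = load_dietary_records(write_records(tmp_path, ["S1\t1\tZZ\t100\n"]))
        (profile,) = compute_intake(records, simple_comp, {"ZZ": "A"})
        assert profile.mean_daily_nutrients["fat_g"] == pytest.approx(10 / 7)

    def test_substitution_cycle_detected(self, simple_comp, tmp_path):
        records = load_dietary_records(write_records(tmp_path, ["S1\t1\tX\t100\n"]))
        with pytest.raises(DietaryInputError, match="cycle"):
            compute_intake(records, simple_comp, {"X": "Y", "Y": "X"})

    def test_scaling_linearity(self, simple_comp, tmp_path):
        rows = ["S1\t1\tA\t120\n", "S1\t2\tB\t80\n", "S1\t5\tC\t150\n"]
        records = load_dietary_records(write_records(tmp_path, rows))
        doubled = records.assign(grams=records["grams"] * 2)
        (p1,) = compute_intake(records, simple_comp)
        (p2,) = compute_intake(doubled, simple_comp)
        for n in p1.mean_daily_nutrients:
            assert p2.mean_daily_nutrients[n] == pytest.approx(
                2 * p1.mean_daily_nutrients[n], rel=1e-12
            )
        s1, s2 = compute_energy_shares(p1), compute_energy_shares(p2)
        for k in s1:
            assert s2[k] == pytest.approx(s1[k], rel=1e-12)

    def test_hierarchy_conservation(self, tiny_cohort):
        composition, records, *_ = tiny_cohort
        profiles = compute_intake(records, composition)
        comp = composition.table
        for p in profiles:
            for group in comp["group"].unique():
                subgroups = comp.loc[comp["group"] == group, "subgroup"].unique()
                g_total = p.food_group_intake.get(("group", group), 0.0)
                s_total = sum(
                    p.food_group_intake.get(("subgroup", s), 0.0) for s in subgroups
                )
                assert s_total == pytest.approx(g_total, rel=1e-9, abs=1e-9)

    def test_agrees_with_entrywise_oracle(self, tiny_cohort):
        composition, records, *_ = tiny_cohort
        profiles = compute_intake(records, composition)
        comp = composition.table
        for p in profiles[:5]:
            sub = records[records["subject_id"] == p.subject_id]
            for nutrient in composition.nutrients:
                total = 0.0
                for _, row in sub.iterrows():
                    total += row["grams"] / 100 * comp.loc[row["food_id"], nutrient]
                assert p.mean_daily_nutrients[nutrient] == pytest.approx(
                    total / 7, rel=1e-9
                )


class TestEnergyShares:
    def _profile(self, energy, **nutrients):
        from diinpx.dietary import NutrientIntakeProfile

        return NutrientIntakeProfile("S", energy, nutrients, {}, {})

    def test_lipid_share_hand_arithmetic(self):
        p = self._profile(1800.0, fat_g=40.0)
        assert compute_energy_shares(p)["lipids"] == pytest.approx(
            40 * 9 / 1800 * 100
        )

    def test_alcohol_share_hand_arithmetic(self):
        p = self._profile(1400.0, alcohol_g=10.0)
        assert compute_energy_shares(p)["alcohol"] == pytest.approx(5.0)

    def test_zero_intake_zero_share(self):
        p = self._profile(2000.0, sfa_g=0.0)
        assert compute_energy_shares(p)["saturated_fat"] == 0.0

    def test_zero_energy_is_error(self):
        p = self._profile(0.0, fat_g=10.0)
        with pytest.raises(DietaryInputError, match="energy"):
            compute_energy_shares(p)

    def test_subcomponents_do_not_exceed_parent(self, tiny_cohort):
        composition, records, *_ = tiny_cohort
        for p in compute_intake(records, composition):
            s = compute_energy_shares(p)
            assert s["saturated_fat"] + s["mufa"] + s["pufa"] <= s["lipids"] + 1e-9
            assert 0 <= s["lipids"] <= 100


def test_load_substitutions_roundtrip(tmp_path):
    p = tmp_path / "subs.tsv"
    p.write_text("missing_food_id\treplacement_food_id\nX\tA\nY\tB\n")
    assert load_substitutions(p) == {"X": "A", "Y": "B"}
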