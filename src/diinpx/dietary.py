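"""Seven-day dietary record processing.

Parses dietary records (one row per subject/day/food/grams), resolves each
food against a per-100 g food-composition table — optionally through an
explicit substitution map for foods missing from the table — and aggregates
per-subject mean daily nutrient intakes, food-group intakes at three
hierarchy levels (group > subgroup > item), and percent-of-energy shares
for the macronutrient classes.

Conventions
-----------
* A record covers exactly seven days; days with no entries contribute zero
  intake, so every mean is a sum over entries divided by 7.
* Nutrient amounts are per 100 g of food; an entry of ``g`` grams therefore
  contributes ``g / 100 * amount_per_100g``.
* Each nutrient carries exactly one declared unit (g, mg or µg) table-wide;
  units are validated at load time and never converted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

DAYS_PER_RECORD = 7

ALLOWED_UNITS = ("g", "mg", "ug")

#: Aliases accepted in composition headers, normalised to ALLOWED_UNITS.
_UNIT_ALIASES = {"g": "g", "mg": "mg", "ug": "ug", "µg": "ug", "mcg": "ug"}

_NUTRIENT_HEADER_RE = re.compile(r"^(?P<name>[^\[\]]+)\[(?P<unit>[^\[\]]+)\]$")

#: kcal released per gram, used only for percent-energy shares.  Total
#: energy always comes from the composition table's own kcal column.
DEFAULT_ENERGY_FACTORS: dict[str, float] = {
    "carbohydrate": 4.0,
    "protein": 4.0,
    "lipid": 9.0,
    "alcohol": 7.0,
}

#: Macronutrient classes reported as %En/day -> (nutrient column, factor class).
DEFAULT_SHARE_COMPONENTS: dict[str, tuple[str, str]] = {
    "lipids": ("fat_g", "lipid"),
    "saturated_fat": ("sfa_g", "lipid"),
    "mufa": ("mufa_g", "lipid"),
    "pufa": ("pufa_g", "lipid"),
    "omega3_pufa": ("n3_pufa_g", "lipid"),
    "omega6_pufa": ("n6_pufa_g", "lipid"),
    "proteins": ("protein_g", "protein"),
    "carbohydrates": ("carbohydrate_g", "carbohydrate"),
    "soluble_carbohydrates": ("sugars_g", "carbohydrate"),
    "alcohol": ("alcohol_g", "alcohol"),
}


class DietaryInputError(ValueError):
    """Malformed or unresolvable dietary input."""


@dataclass(frozen=True)
class FoodCompositionTable:
    """Per-100 g energy and nutrient contents with a three-level hierarchy.

    ``table`` is indexed by ``food_id`` with columns ``name``, ``group``,
    ``subgroup``, ``item``, ``energy_kcal_per_100g`` and one column per
    nutrient.  ``units`` maps nutrient column -> declared unit.
    """

    table: pd.DataFrame
    units: dict[str, str]

    @property
    def nutrients(self) -> list[str]:
        return list(self.units)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.table.index


@dataclass(frozen=True)
class NutrientIntakeProfile:
    """Per-subject mean daily intakes over the seven-day record."""

    subject_id: str
    mean_daily_energy: float
    mean_daily_nutrients: dict[str, float]
    food_group_intake: dict[tuple[str, str], float]  # (level, name) -> g/day
    units: dict[str, str] = field(default_factory=dict)


def load_food_composition(path) -> FoodCompositionTable:
    """Read a composition TSV with header
    ``food_id name group subgroup item energy_kcal_per_100g <nutrient>[unit] ...``.

    Raises
    ------
    DietaryInputError
        On duplicated ``food_id``, unknown nutrient unit, missing required
        columns, or negative amounts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"food_id": str})
    required = ["food_id", "name", "group", "subgroup", "item", "energy_kcal_per_100g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DietaryInputError(f"composition table missing columns: {missing}")

    dupes = df["food_id"][df["food_id"].duplicated()].unique()
    if len(dupes):
        raise DietaryInputError(f"duplicated food_id in composition table: {sorted(dupes)}")

    units: dict[str, str] = {}
    renames: dict[str, str] = {}
    for col in df.columns:
        if col in required:
            continue
        m = _NUTRIENT_HEADER_RE.match(col.strip())
        if not m:
            raise DietaryInputError(
                f"nutrient column {col!r} must be of the form name[unit]"
            )
        raw_unit = m.group("unit").strip()
        if raw_unit not in _UNIT_ALIASES:
            raise DietaryInputError(
                f"unknown unit {raw_unit!r} in column {col!r}; allowed: g, mg, µg"
            )
        name = m.group("name").strip()
        if name in units:
            raise DietaryInputError(f"nutrient {name!r} declared twice")
        units[name] = _UNIT_ALIASES[raw_unit]
        renames[col] = name

    df = df.rename(columns=renames).set_index("food_id")
    numeric = ["energy_kcal_per_100g", *units]
    df[numeric] = df[numeric].astype(float)
    if (df[numeric] < 0).any().any():
        bad = [c for c in numeric if (df[c] < 0).any()]
        raise DietaryInputError(f"negative amounts in columns: {bad}")
    return FoodCompositionTable(table=df, units=units)


def load_dietary_records(path) -> pd.DataFrame:
    """Read records TSV with header ``subject_id day food_id grams``."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "food_id": str})
    required = ["subject_id", "day", "food_id", "grams"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DietaryInputError(f"records table missing columns: {missing}")
    df["day"] = df["day"].astype(int)
    df["grams"] = df["grams"].astype(float)
    if not df["day"].between(1, DAYS_PER_RECORD).all():
        raise DietaryInputError("record day outside 1..7")
    if (df["grams"] < 0).any():
        raise DietaryInputError("negative grams in records")
    return df[required]


def load_substitutions(path) -> dict[str, str]:
    """Read a two-column TSV ``missing_food_id replacement_food_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise DietaryInputError("substitution map must have exactly two columns")
    df.columns = ["missing_food_id", "replacement_food_id"]
    if df["missing_food_id"].duplicated().any():
        raise DietaryInputError("duplicated missing_food_id in substitution map")
    return dict(zip(df["missing_food_id"], df["replacement_food_id"]))


def _resolve_food(food_id: str, composition: FoodCompositionTable,
                  subs: Mapping[str, str]) -> str:
    """Follow the substitution chain until a food present in the table."""
    seen = set()
    fid = food_id
    while fid not in composition:
        if fid in seen:
            raise DietaryInputError(f"substitution cycle involving {food_id!r}")
        seen.add(fid)
        if fid not in subs:
            raise DietaryInputError(f"unresolvable food_id {fid!r}")
        fid = subs[fid]
    return fid


def compute_intake(
    records: pd.DataFrame,
    composition: FoodCompositionTable,
    subs: Mapping[str, str] | None = None,
) -> list[NutrientIntakeProfile]:
    """Aggregate per-subject mean daily intakes from seven-day records.

    For each subject and nutrient the mean daily intake is
    ``sum over entries of grams/100 * per-100g amount, divided by 7``;
    energy is analogous from the kcal column, and food-group intakes (g/day)
    are accumulated at the group, subgroup and item levels.

    Subjects are returned sorted by ``subject_id``.  An entry whose
    ``food_id`` is absent from the table and not resolvable through ``subs``
    raises, naming subject, day and food.
    """
    subs = dict(subs or {})
    profiles: list[NutrientIntakeProfile] = []
    nutrient_cols = composition.nutrients
    comp = composition.table

    for subject_id, sub_df in records.groupby("subject_id", sort=True):
        try:
            resolved = [
                _resolve_food(fid, composition, subs) for fid in sub_df["food_id"]
            ]
        except DietaryInputError:
            # rerun entry-wise to produce a precise message
            for _, row in sub_df.iterrows():
                try:
                    _resolve_food(row["food_id"], composition, subs)
                except DietaryInputError as exc:
                    raise DietaryInputError(
                        f"subject {subject_id!r} day {row['day']}: {exc}"
                    ) from None
            raise  # pragma: no cover

        rows = comp.loc[resolved]
        scale = sub_df["grams"].to_numpy() / 100.0
        energy = float(rows["energy_kcal_per_100g"].to_numpy() @ scale) / DAYS_PER_RECORD
        nutrients = {
            n: float(rows[n].to_numpy() @ scale) / DAYS_PER_RECORD
            for n in nutrient_cols
        }
        grams_per_day = sub_df["grams"].to_numpy() / DAYS_PER_RECORD
        group_intake: dict[tuple[str, str], float] = {}
        for level in ("group", "subgroup", "item"):
            names = rows[level].to_numpy()
            for name, g in zip(names, grams_per_day):
                key = (level, str(name))
                group_intake[key] = group_intake.get(key, 0.0) + float(g)
        profiles.append(
            NutrientIntakeProfile(
                subject_id=str(subject_id),
                mean_daily_energy=energy,
                mean_daily_nutrients=nutrients,
                food_group_intake=group_intake,
                units=dict(composition.units),
            )
        )
    return profiles


def compute_energy_shares(
    profile: NutrientIntakeProfile,
    factors: Mapping[str, float] | None = None,
    components: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Percent of daily energy from each macronutrient class.

    ``%En(x) = g/day(x) * kcal_per_gram(class of x) / mean_daily_energy * 100``.
    Components whose nutrient column is absent from the profile are omitted.
    """
    if profile.mean_daily_energy <= 0:
        raise DietaryInputError(
            f"subject {profile.subject_id!r}: zero daily energy, shares undefined"
        )
    factors = dict(DEFAULT_ENERGY_FACTORS, **(factors or {}))
    components = dict(components or DEFAULT_SHARE_COMPONENTS)
    shares: dict[str, float] = {}
    for share_name, (nutrient, factor_class) in components.items():
        if nutrient not in profile.mean_daily_nutrients:
            continue
        kcal = profile.mean_daily_nutrients[nutrient] * factors[factor_class]
        shares[share_name] = kcal / profile.mean_daily_energy * 100.0
    return shares


def profiles_frame(profiles: list[NutrientIntakeProfile]) -> pd.DataFrame:
    """Wide per-subject table: energy plus one column per nutrient."""
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "mean_daily_energy": p.mean_daily_energy}
        row.update(p.mean_daily_nutrients)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id").sort_index()


def food_group_frame(profiles: list[NutrientIntakeProfile]) -> pd.DataFrame:
    """Long table ``subject_id level name grams_per_day``."""
    rows = [
        {"subject_id": p.subject_id, "level": lvl, "name": name, "grams_per_day": g}
        for p in profiles
        for (lvl, name), g in sorted(p.food_group_intake.items())
    ]
    return pd.DataFrame(rows, columns=["subject_id", "level", "name", "grams_per_day"])
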