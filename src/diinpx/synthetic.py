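"""Seeded synthetic cohorts for end-to-end pipeline testing.

Real seven-day dietary records and Olink-style NPX panels are rarely
redistributable, so this module generates a full input bundle with the
statistical structure the analysis assumes:

* a food-composition table (~30 foods, invented but nutritionally
  plausible per-100 g values, with the group > subgroup > item hierarchy);
* seven-day dietary records drawn from two dietary archetypes — a
  "western" pattern (more butter, cheese, red/processed meat, sweets and
  refined bread; less vegetables, fruit, legumes, fish, nuts and olive
  oil) and a "prudent" pattern (the reverse) — so that western subjects
  ingest more saturated fat and less fibre, PUFA and micronutrients;
* an illustrative DII reference table whose effect scores are positive
  for saturated fat and negative for fibre, PUFA and micronutrients, so
  the archetypes separate in expected DII;
* an NPX matrix ``baseline_p + subject_offset_s + planted shift + noise``
  on the log2 scale, with a mean shift planted in a subset of proteins
  for the high-DII archetype (mostly upward, a few downward) and pure
  noise elsewhere;
* a GMT annotation built over the synthetic panel, including one term
  that collects the planted proteins.

Every draw flows from the single ``rng_seed``; the same config produces
byte-identical files.  The ground truth (archetype labels, planted
proteins with shift signs) is returned and emitted so recovery metrics
can be computed against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dietary import FoodCompositionTable, load_food_composition
from .dii import DIIReferenceTable

WESTERN, PRUDENT = "western", "prudent"

NUTRIENT_UNITS = {
    "protein_g": "g",
    "carbohydrate_g": "g",
    "sugars_g": "g",
    "fat_g": "g",
    "sfa_g": "g",
    "mufa_g": "g",
    "pufa_g": "g",
    "n3_pufa_g": "g",
    "n6_pufa_g": "g",
    "fiber_g": "g",
    "vitamin_c_mg": "mg",
    "alcohol_g": "g",
}

# food_id, name, group, subgroup, item, kcal/100g, then NUTRIENT_UNITS order:
# protein, carb, sugars, fat, sfa, mufa, pufa, n3, n6, fiber, vitC(mg), alcohol
_FOOD_ROWS = [
    ("F01", "tomato", "vegetables", "fruiting vegetables", "tomato", 18, 0.9, 3.9, 2.6, 0.2, 0.03, 0.03, 0.08, 0.003, 0.08, 1.2, 14, 0),
    ("F02", "spinach", "vegetables", "leafy vegetables", "spinach", 23, 2.9, 3.6, 0.4, 0.4, 0.06, 0.01, 0.17, 0.14, 0.03, 2.2, 28, 0),
    ("F03", "broccoli", "vegetables", "cruciferous vegetables", "broccoli", 34, 2.8, 6.6, 1.7, 0.4, 0.04, 0.01, 0.04, 0.02, 0.02, 2.6, 89, 0),
    ("F04", "apple", "fruits", "fresh fruits", "apple", 52, 0.3, 13.8, 10.4, 0.2, 0.03, 0.01, 0.05, 0.01, 0.04, 2.4, 4.6, 0),
    ("F05", "orange", "fruits", "fresh fruits", "orange", 47, 0.9, 11.8, 9.4, 0.1, 0.02, 0.02, 0.03, 0.01, 0.02, 2.4, 53, 0),
    ("F06", "banana", "fruits", "fresh fruits", "banana", 89, 1.1, 22.8, 12.2, 0.3, 0.11, 0.03, 0.07, 0.03, 0.05, 2.6, 8.7, 0),
    ("F07", "lentils", "legumes", "pulses", "lentils", 116, 9.0, 20.1, 1.8, 0.4, 0.05, 0.06, 0.18, 0.04, 0.14, 7.9, 1.5, 0),
    ("F08", "chickpeas", "legumes", "pulses", "chickpeas", 164, 8.9, 27.4, 4.8, 2.6, 0.27, 0.58, 1.16, 0.04, 1.11, 7.6, 1.3, 0),
    ("F09", "white bread", "cereals", "bread", "white bread", 265, 9.0, 49.0, 5.0, 3.2, 0.72, 0.64, 1.36, 0.06, 1.30, 2.7, 0, 0),
    ("F10", "wholemeal bread", "cereals", "bread", "wholemeal bread", 247, 13.0, 41.0, 6.0, 3.4, 0.74, 0.69, 1.66, 0.10, 1.56, 7.0, 0, 0),
    ("F11", "pasta", "cereals", "pasta", "pasta", 158, 5.8, 30.9, 0.6, 0.9, 0.18, 0.13, 0.32, 0.02, 0.30, 1.8, 0, 0),
    ("F12", "rice", "cereals", "rice", "white rice", 130, 2.7, 28.2, 0.1, 0.3, 0.08, 0.09, 0.08, 0.01, 0.07, 0.4, 0, 0),
    ("F13", "potato", "tubers", "potatoes", "potato", 77, 2.0, 17.5, 0.8, 0.1, 0.03, 0.00, 0.04, 0.01, 0.03, 2.2, 19.7, 0),
    ("F14", "salmon", "fish", "oily fish", "salmon", 208, 20.4, 0, 0, 13.4, 3.05, 3.77, 3.89, 2.30, 0.90, 0, 0, 0),
    ("F15", "cod", "fish", "white fish", "cod", 82, 17.8, 0, 0, 0.7, 0.13, 0.09, 0.23, 0.20, 0.01, 0, 1, 0),
    ("F16", "olive oil", "oils and vegetable fats", "oils", "olive oil", 884, 0, 0, 0, 100, 13.8, 73.0, 10.5, 0.76, 9.76, 0, 0, 0),
    ("F17", "sunflower oil", "oils and vegetable fats", "oils", "sunflower oil", 884, 0, 0, 0, 100, 10.3, 19.5, 65.7, 0.10, 65.6, 0, 0, 0),
    ("F18", "walnuts", "nuts", "tree nuts", "walnuts", 654, 15.2, 13.7, 2.6, 65.2, 6.13, 8.93, 47.2, 9.08, 38.1, 6.7, 1.3, 0),
    ("F19", "milk", "dairy", "milk and yogurt", "whole milk", 61, 3.2, 4.8, 5.1, 3.3, 1.87, 0.81, 0.20, 0.08, 0.12, 0, 0, 0),
    ("F20", "yogurt", "dairy", "milk and yogurt", "plain yogurt", 59, 10.0, 3.6, 3.2, 0.4, 0.12, 0.05, 0.01, 0.00, 0.01, 0, 0, 0),
    ("F21", "hard cheese", "dairy", "cheese", "hard cheese", 402, 25.0, 1.3, 0.5, 33.0, 21.0, 9.25, 0.94, 0.14, 0.80, 0, 0, 0),
    ("F22", "butter", "oils and vegetable fats", "butter and margarine", "butter", 717, 0.9, 0.1, 0.1, 81.1, 51.4, 21.0, 3.0, 0.32, 2.68, 0, 0, 0),
    ("F23", "beef", "meat", "red meat", "beef", 250, 26.0, 0, 0, 15.4, 6.00, 6.90, 0.50, 0.05, 0.45, 0, 0, 0),
    ("F24", "chicken", "meat", "white meat", "chicken breast", 165, 31.0, 0, 0, 3.6, 1.01, 1.24, 0.77, 0.06, 0.71, 0, 0, 0),
    ("F25", "salami", "meat", "preserved meat", "salami", 336, 21.7, 1.2, 0.6, 26.4, 9.89, 12.3, 2.62, 0.27, 2.35, 0, 0, 0),
    ("F26", "egg", "eggs", "eggs", "hen egg", 155, 12.6, 1.1, 1.1, 10.6, 3.27, 4.08, 1.41, 0.07, 1.34, 0, 0, 0),
    ("F27", "cookies", "sweets", "baked sweets", "cookies", 480, 5.0, 64.0, 25.0, 24.0, 12.0, 8.00, 2.00, 0.10, 1.90, 1.5, 0, 0),
    ("F28", "chocolate", "sweets", "chocolate", "milk chocolate", 546, 4.9, 60.5, 48.0, 31.3, 18.5, 9.54, 1.08, 0.09, 0.99, 3.4, 0, 0),
    ("F29", "soft drink", "beverages", "sugar-sweetened beverages", "cola", 41, 0, 10.6, 10.6, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    ("F30", "red wine", "beverages", "alcoholic beverages", "red wine", 83, 0.1, 2.6, 0.6, 0, 0, 0, 0, 0, 0, 0, 0, 10.6),
    ("F31", "beer", "beverages", "alcoholic beverages", "lager beer", 43, 0.5, 3.6, 0, 0, 0, 0, 0, 0, 0, 0, 0, 3.9),
]

# food_id -> (typical portion g, daily consumption prob: prudent, western)
_PREFERENCES = {
    "F01": (100, 0.80, 0.35),
    "F02": (80, 0.50, 0.15),
    "F03": (100, 0.50, 0.15),
    "F04": (150, 0.70, 0.30),
    "F05": (150, 0.60, 0.25),
    "F06": (120, 0.50, 0.30),
    "F07": (120, 0.40, 0.10),
    "F08": (120, 0.35, 0.10),
    "F09": (80, 0.30, 0.80),
    "F10": (80, 0.70, 0.20),
    "F11": (180, 0.60, 0.55),
    "F12": (150, 0.40, 0.30),
    "F13": (150, 0.40, 0.35),
    "F14": (120, 0.35, 0.08),
    "F15": (150, 0.35, 0.10),
    "F16": (20, 0.90, 0.40),
    "F17": (15, 0.10, 0.45),
    "F18": (30, 0.40, 0.10),
    "F19": (200, 0.50, 0.60),
    "F20": (125, 0.50, 0.40),
    "F21": (50, 0.30, 0.60),
    "F22": (15, 0.10, 0.60),
    "F23": (120, 0.20, 0.50),
    "F24": (120, 0.30, 0.50),
    "F25": (50, 0.10, 0.50),
    "F26": (60, 0.30, 0.40),
    "F27": (40, 0.20, 0.60),
    "F28": (30, 0.20, 0.50),
    "F29": (330, 0.10, 0.50),
    "F30": (150, 0.40, 0.25),
    "F31": (330, 0.15, 0.30),
}

# Illustrative DII reference: parameter, unit, global mean & SD of daily
# intake (set near the mixed-population marginals of this generator, rounded),
# inflammatory effect score.  NOT the published global-database values.
_DII_REFERENCE_ROWS = [
    ("protein_g", "g", 85.0, 15.0, 0.05),
    ("carbohydrate_g", "g", 180.0, 40.0, 0.10),
    ("sugars_g", "g", 57.0, 18.0, 0.15),
    ("fat_g", "g", 68.0, 15.0, 0.30),
    ("sfa_g", "g", 23.0, 8.0, 0.40),
    ("mufa_g", "g", 25.0, 6.0, -0.05),
    ("pufa_g", "g", 13.0, 4.0, -0.25),
    ("n3_pufa_g", "g", 1.8, 1.0, -0.45),
    ("n6_pufa_g", "g", 11.0, 3.5, -0.15),
    ("fiber_g", "g", 19.0, 7.0, -0.65),
    ("vitamin_c_mg", "mg", 100.0, 50.0, -0.40),
    ("alcohol_g", "g", 8.0, 7.0, -0.30),
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation settings.

    The defaults define the standard study conditions used throughout the
    test-bench: 400 subjects, half from each archetype, a 368-protein
    panel with 30 planted proteins shifted by half a residual SD.
    """

    n_subjects: int = 400
    archetype_fraction: float = 0.5  # share of western subjects
    n_proteins: int = 368
    n_planted: int = 30
    planted_shift: float = 0.5  # in units of the residual NPX SD
    planted_down_fraction: float = 0.1  # share of planted proteins shifted down
    npx_subject_sd: float = 0.1
    npx_protein_sd: float = 1.0
    link_mode: str = "archetype"  # or "dii-quantile"
    portion_cv: float = 0.25
    foods_per_group: int | None = None  # cap foods per group; None = all
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.archetype_fraction < 1:
            raise ValueError("archetype_fraction must be in (0, 1)")
        if self.n_planted > self.n_proteins:
            raise ValueError("n_planted exceeds n_proteins")
        if self.npx_subject_sd <= 0 or self.npx_protein_sd <= 0:
            raise ValueError("NPX standard deviations must be > 0")
        if self.link_mode not in ("archetype", "dii-quantile"):
            raise ValueError("link_mode must be 'archetype' or 'dii-quantile'")


@dataclass(frozen=True)
class GroundTruth:
    archetype: dict[str, str]  # subject_id -> western/prudent
    planted: dict[str, int]  # protein -> shift sign (+1/-1)
    reference: DIIReferenceTable
    config: SyntheticConfig


def food_composition_table() -> FoodCompositionTable:
    """The packaged synthetic food catalogue as a validated table."""
    cols = ["food_id", "name", "group", "subgroup", "item", "energy_kcal_per_100g"]
    df = pd.DataFrame(_FOOD_ROWS, columns=cols + list(NUTRIENT_UNITS))
    return FoodCompositionTable(
        table=df.set_index("food_id").astype({c: float for c in ["energy_kcal_per_100g", *NUTRIENT_UNITS]}),
        units=dict(NUTRIENT_UNITS),
    )


def dii_reference_table() -> DIIReferenceTable:
    """The packaged illustrative DII reference."""
    df = pd.DataFrame(
        _DII_REFERENCE_ROWS,
        columns=["parameter", "unit", "global_mean", "global_sd", "effect_score"],
    )
    return DIIReferenceTable(table=df)


def _select_foods(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    comp = food_composition_table().table.reset_index()
    if config.foods_per_group is None:
        return comp
    kept = []
    for _, grp in comp.groupby("group", sort=True):
        k = min(config.foods_per_group, len(grp))
        kept.append(grp.iloc[np.sort(rng.choice(len(grp), k, replace=False))])
    return pd.concat(kept, ignore_index=True)


def _dietary_records(
    config: SyntheticConfig, archetypes: np.ndarray, subjects: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    foods = _select_foods(config, rng)
    food_ids = foods["food_id"].to_numpy()
    portion = np.array([_PREFERENCES[f][0] for f in food_ids], dtype=float)
    p_prudent = np.array([_PREFERENCES[f][1] for f in food_ids])
    p_western = np.array([_PREFERENCES[f][2] for f in food_ids])
    shape = 1.0 / config.portion_cv**2

    rows = []
    for sid, arch in zip(subjects, archetypes):
        probs = p_western if arch == WESTERN else p_prudent
        for day in range(1, 8):
            eaten = rng.random(len(food_ids)) < probs
            if not eaten.any():
                continue
            grams = portion[eaten] * rng.gamma(shape, 1.0 / shape, eaten.sum())
            for fid, g in zip(food_ids[eaten], grams):
                rows.append((sid, day, fid, round(float(g), 1)))
    return pd.DataFrame(rows, columns=["subject_id", "day", "food_id", "grams"])


def _npx_matrix(
    config: SyntheticConfig, subjects: list[str], archetypes: np.ndarray,
    rng: np.random.Generator, dii_quantile: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    n_s, n_p = len(subjects), config.n_proteins
    proteins = [f"P{i + 1:04d}" for i in range(n_p)]
    baseline = rng.normal(4.0, 1.5, n_p)
    subject_offset = rng.normal(0.0, config.npx_subject_sd, n_s)
    noise = rng.normal(0.0, config.npx_protein_sd, (n_s, n_p))

    planted_idx = np.sort(rng.choice(n_p, config.n_planted, replace=False))
    n_down = int(round(config.planted_down_fraction * config.n_planted))
    signs = np.ones(config.n_planted, dtype=int)
    if n_down:
        signs[rng.choice(config.n_planted, n_down, replace=False)] = -1

    shift = config.planted_shift * config.npx_protein_sd
    if config.link_mode == "archetype":
        exposure = (archetypes == WESTERN).astype(float)
    else:
        if dii_quantile is None:
            raise ValueError("dii-quantile link requires per-subject DII quantiles")
        exposure = 2.0 * dii_quantile - 1.0
    effect = np.zeros((n_s, n_p))
    effect[:, planted_idx] = np.outer(exposure, shift * signs)

    values = baseline[None, :] + subject_offset[:, None] + effect + noise
    npx = pd.DataFrame(values, index=pd.Index(subjects, name="subject_id"),
                       columns=proteins)
    planted = {proteins[i]: int(s) for i, s in zip(planted_idx, signs)}
    return npx, planted


def _annotation_gmt(
    proteins: list[str], planted: dict[str, int], rng: np.random.Generator,
    n_random_terms: int = 12,
) -> list[tuple[str, str, str, list[str]]]:
    """(term, description, category, members); one term collects the plants."""
    terms = [
        (
            "SYN_PLANTED_RESPONSE",
            "synthetic planted inflammatory response set",
            "immune-inflammatory",
            sorted(planted),
        )
    ]
    cats = ["immune-inflammatory", "cell-cell signaling", "metabolic", "other"]
    for i in range(n_random_terms):
        size = int(rng.integers(15, 41))
        members = sorted(rng.choice(proteins, size, replace=False))
        terms.append(
            (f"SYN_TERM_{i + 1:03d}", f"synthetic random set {i + 1}",
             cats[i % len(cats)], members)
        )
    return terms


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[FoodCompositionTable, pd.DataFrame, DIIReferenceTable, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort.

    Returns ``(composition, records, reference, npx, truth)``.  In
    ``dii-quantile`` link mode the dietary stage is run internally to rank
    subjects by DII before planting NPX shifts.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_subjects
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    n_western = int(round(config.archetype_fraction * n))
    archetypes = np.array([WESTERN] * n_western + [PRUDENT] * (n - n_western))
    rng.shuffle(archetypes)

    composition = food_composition_table()
    records = _dietary_records(config, archetypes, subjects, rng)
    reference = dii_reference_table()

    dii_quantile = None
    if config.link_mode == "dii-quantile":
        from .dietary import compute_intake
        from .dii import compute_dii_table

        profiles = compute_intake(records, composition)
        summary, _ = compute_dii_table(profiles, reference)
        ranks = summary.set_index("subject_id")["dii_total"].rank(method="average")
        dii_quantile = (
            (ranks.loc[subjects].to_numpy() - 0.5) / len(subjects)
        )

    npx, planted = _npx_matrix(config, subjects, archetypes, rng, dii_quantile)
    truth = GroundTruth(
        archetype=dict(zip(subjects, archetypes)),
        planted=planted,
        reference=reference,
        config=config,
    )
    return composition, records, reference, npx, truth


TINY = SyntheticConfig(n_subjects=20, n_proteins=40, n_planted=6,
                       planted_shift=1.0, foods_per_group=None)


def _write_composition(composition: FoodCompositionTable, path: Path) -> None:
    df = composition.table.reset_index()
    df = df.rename(columns={n: f"{n}[{u}]" for n, u in composition.units.items()})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def emit_fixture(outdir, size: str = "default", seed: int = 0) -> dict[str, Path]:
    """Write a complete input bundle for the pipeline.

    ``size`` is ``"tiny"`` (20 subjects, 40 proteins — unit-test scale) or
    ``"default"`` (the standard 400-subject cohort).  Returns the emitted
    paths keyed by artifact name.
    """
    if size == "tiny":
        config = dataclasses.replace(TINY, rng_seed=seed)
    elif size == "default":
        config = SyntheticConfig(rng_seed=seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    return emit_bundle(config, outdir)


def emit_bundle(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate a cohort under ``config`` and write every pipeline input."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    composition, records, reference, npx, truth = generate_cohort(config)
    rng = np.random.default_rng(config.rng_seed + 1)  # annotation-only stream

    paths = {
        "composition": outdir / "composition.tsv",
        "records": outdir / "records.tsv",
        "dii_reference": outdir / "dii_reference.tsv",
        "npx": outdir / "npx.tsv",
        "annotations": outdir / "annotations.gmt",
        "background": outdir / "background.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    _write_composition(composition, paths["composition"])
    records.to_csv(paths["records"], sep="\t", index=False, float_format="%.6g")
    reference.table.to_csv(paths["dii_reference"], sep="\t", index=False,
                           float_format="%.6g")
    npx.reset_index().to_csv(paths["npx"], sep="\t", index=False,
                             float_format="%.10g")
    proteins = list(npx.columns)
    terms = _annotation_gmt(proteins, truth.planted, rng)
    with open(paths["annotations"], "w") as fh:
        for term, desc, _cat, members in terms:
            fh.write("\t".join([term, desc, *members]) + "\n")
    with open(paths["background"], "w") as fh:
        fh.write("\n".join(proteins) + "\n")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "archetype": truth.archetype,
                "planted": truth.planted,
                "term_categories": {t: c for t, _d, c, _m in terms},
                "config": dataclasses.asdict(truth.config),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
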