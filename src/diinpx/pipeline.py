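"""Stage orchestration: simulate -> nutrients -> dii -> split -> diffexp
-> classify -> enrich.

Each stage reads tabular inputs, writes TSV/JSON outputs into the run
directory and records a manifest entry (row counts, inputs, outputs).
The run manifest carries the seed, a configuration hash and package
versions so a run is reproducible from the manifest alone.  All stage
outputs are byte-identical across reruns with the same configuration and
seed; only the manifest timestamp differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    ClassifierConfig,
    evaluate_roc,
    fit_boosted_classifier,
    select_top_features,
    stratified_split,
)
from .cohort import CohortSplit, median_split
from .dietary import (
    compute_energy_shares,
    compute_intake,
    food_group_frame,
    load_dietary_records,
    load_food_composition,
    load_substitutions,
    profiles_frame,
)
from .differential import DifferentialConfig, load_npx, test_all_proteins, volcano_table
from .dii import compute_dii_table, load_dii_reference
from .enrichment import category_tally, enrich, load_background, load_gmt
from .synthetic import SyntheticConfig, emit_bundle

log = logging.getLogger("diinpx")

STAGES = ("simulate", "nutrients", "dii", "split", "diffexp", "classify", "enrich")

#: upstream artifacts each stage consumes (keys of PipelineConfig paths)
_STAGE_NEEDS = {
    "simulate": (),
    "nutrients": ("composition", "records"),
    "dii": ("dii_reference", "intake_profiles"),
    "split": ("dii_scores",),
    "diffexp": ("npx", "cohort_split"),
    "classify": ("npx", "cohort_split", "differential_results"),
    "enrich": ("annotations", "differential_results"),
}


class PipelineError(RuntimeError):
    """Stage dependency or execution failure."""


@dataclass
class PipelineConfig:
    """Single flat configuration for a pipeline run."""

    outdir: str = "diinpx_run"
    seed: int = 0
    sig_mode: str = "fdr"
    alpha: float = 0.05
    alpha_normality: float = 0.05
    top_n: int | None = None
    missing_parameter_policy: str = "skip"
    #: re-derive the significant-protein selection on training subjects only
    #: before fitting the classifier; False reuses the full-cohort table,
    #: which leaks test-set signal into feature selection.
    train_only_selection: bool = True
    # external inputs; stages fall back to same-named simulate outputs
    composition: str | None = None
    records: str | None = None
    substitutions: str | None = None
    dii_reference: str | None = None
    npx: str | None = None
    annotations: str | None = None
    background: str | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        clf = ClassifierConfig(**raw.pop("classifier", {}))
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw, classifier=clf, synthetic=syn)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_seed(self) -> "PipelineConfig":
        """Propagate the global seed into the stage-level RNG fields."""
        return dataclasses.replace(
            self,
            classifier=dataclasses.replace(self.classifier, rng_seed=self.seed),
            synthetic=dataclasses.replace(self.synthetic, rng_seed=self.seed),
        )


#: canonical filenames of stage outputs inside the run directory
ARTIFACTS = {
    "composition": "composition.tsv",
    "records": "records.tsv",
    "dii_reference": "dii_reference.tsv",
    "npx": "npx.tsv",
    "annotations": "annotations.gmt",
    "background": "background.txt",
    "ground_truth": "ground_truth.json",
    "intake_profiles": "intake_profiles.tsv",
    "food_groups": "food_groups.tsv",
    "energy_shares": "energy_shares.tsv",
    "dii_scores": "dii_scores.tsv",
    "dii_contributions": "dii_contributions.tsv",
    "cohort_split": "cohort_split.tsv",
    "differential_results": "differential_results.tsv",
    "volcano": "volcano.tsv",
    "importance_ranking": "importance_ranking.tsv",
    "top_features": "top_features.txt",
    "roc_curve": "roc_curve.tsv",
    "roc_report": "roc_report.json",
    "enrichment": "enrichment.tsv",
    "enrichment_categories": "enrichment_categories.tsv",
}


def _resolve(config: PipelineConfig, key: str, outdir: Path) -> Path:
    explicit = getattr(config, key, None)
    if explicit:
        return Path(explicit)
    return outdir / ARTIFACTS[key]


def _require(config: PipelineConfig, stage: str, outdir: Path) -> dict[str, Path]:
    paths = {}
    for key in _STAGE_NEEDS[stage]:
        p = _resolve(config, key, outdir)
        if not p.exists():
            raise PipelineError(
                f"stage {stage!r} requires {key!r} at {p}; run the upstream "
                "stage or point the configuration at an existing file"
            )
        paths[key] = p
    return paths


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)
    return len(df)


def run(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in canonical order; returns the manifest."""
    config = config.with_seed()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")

    entries = []
    for stage in ordered:
        inputs = _require(config, stage, outdir)
        log.info("stage %s: starting", stage)
        counts = _STAGE_RUNNERS[stage](config, inputs, outdir)
        entries.append(
            {
                "stage": stage,
                "inputs": {k: str(v) for k, v in inputs.items()},
                "outputs": counts,
            }
        )
        log.info("stage %s: done (%s)", stage, counts)

    manifest = {
        "package": "diinpx",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.as_dict(),
        "stages": entries,
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


# ----------------------------------------------------------------- stages

def _stage_simulate(config: PipelineConfig, inputs, outdir: Path) -> dict:
    paths = emit_bundle(config.synthetic, outdir)
    return {k: str(v) for k, v in paths.items()}


def _stage_nutrients(config: PipelineConfig, inputs, outdir: Path) -> dict:
    composition = load_food_composition(inputs["composition"])
    records = load_dietary_records(inputs["records"])
    subs = {}
    if config.substitutions:
        subs = load_substitutions(config.substitutions)
    profiles = compute_intake(records, composition, subs)
    n_prof = _write_tsv(profiles_frame(profiles).reset_index(),
                        outdir / ARTIFACTS["intake_profiles"])
    _write_tsv(food_group_frame(profiles), outdir / ARTIFACTS["food_groups"])
    shares = pd.DataFrame(
        [{"subject_id": p.subject_id, **compute_energy_shares(p)} for p in profiles]
    )
    _write_tsv(shares, outdir / ARTIFACTS["energy_shares"])
    return {"subjects": n_prof}


def _stage_dii(config: PipelineConfig, inputs, outdir: Path) -> dict:
    reference = load_dii_reference(inputs["dii_reference"])
    prof_df = pd.read_csv(inputs["intake_profiles"], sep="\t",
                          dtype={"subject_id": str}).set_index("subject_id")
    # rebuild lightweight profiles from the wide intake table
    from .dietary import NutrientIntakeProfile

    units = dict(zip(reference.table["parameter"], reference.table["unit"]))
    profiles = [
        NutrientIntakeProfile(
            subject_id=sid,
            mean_daily_energy=row["mean_daily_energy"],
            mean_daily_nutrients={k: v for k, v in row.items()
                                  if k != "mean_daily_energy"},
            food_group_intake={},
            units={k: units[k] for k in row.index if k in units},
        )
        for sid, row in prof_df.iterrows()
    ]
    summary, contributions = compute_dii_table(
        profiles, reference, policy=config.missing_parameter_policy
    )
    n = _write_tsv(summary, outdir / ARTIFACTS["dii_scores"])
    _write_tsv(contributions, outdir / ARTIFACTS["dii_contributions"])
    return {"subjects": n, "parameters": int(summary["n_parameters_used"].iloc[0])}


def _stage_split(config: PipelineConfig, inputs, outdir: Path) -> dict:
    scores = pd.read_csv(inputs["dii_scores"], sep="\t", dtype={"subject_id": str})
    split = median_split(scores.set_index("subject_id")["dii_total"])
    _write_tsv(split.table, outdir / ARTIFACTS["cohort_split"])
    return {"n_high": split.n_high, "n_low": split.n_low,
            "median_dii": split.median_dii}


def _load_split(path) -> CohortSplit:
    table = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    med = float(np.median(table["dii"]))
    return CohortSplit(table=table, median_dii=med)


def _stage_diffexp(config: PipelineConfig, inputs, outdir: Path) -> dict:
    npx = load_npx(inputs["npx"])
    split = _load_split(inputs["cohort_split"])
    diff_cfg = DifferentialConfig(
        alpha_normality=config.alpha_normality,
        alpha_sig=config.alpha,
        sig_mode=config.sig_mode,
    )
    results = test_all_proteins(npx, split, diff_cfg)
    n = _write_tsv(results, outdir / ARTIFACTS["differential_results"])
    _write_tsv(volcano_table(results), outdir / ARTIFACTS["volcano"])
    return {"proteins": n, "significant": int(results["significant"].sum())}


def _stage_classify(config: PipelineConfig, inputs, outdir: Path) -> dict:
    npx = load_npx(inputs["npx"])
    split = _load_split(inputs["cohort_split"])
    labels = split.labels
    subjects = npx.index.intersection(labels.index)
    clf_cfg = config.classifier
    train, test = stratified_split(subjects, labels.loc[subjects], clf_cfg)
    if config.train_only_selection:
        train_split = CohortSplit(
            table=split.table[split.table["subject_id"].isin(train)].reset_index(drop=True),
            median_dii=split.median_dii,
        )
        diff_cfg = DifferentialConfig(
            alpha_normality=config.alpha_normality,
            alpha_sig=config.alpha,
            sig_mode=config.sig_mode,
        )
        results = test_all_proteins(npx.loc[train], train_split, diff_cfg)
    else:
        results = pd.read_csv(inputs["differential_results"], sep="\t")
    features = list(results.loc[results["significant"], "protein"])
    if len(features) < 2:
        raise PipelineError(
            f"classify needs >= 2 significant proteins, found {len(features)} "
            f"(sig_mode={config.sig_mode!r})"
        )
    model, ranking = fit_boosted_classifier(
        npx.loc[train, features], labels.loc[train], clf_cfg
    )
    _write_tsv(ranking, outdir / ARTIFACTS["importance_ranking"])
    scores = pd.Series(
        model.predict_proba(npx.loc[test, features].to_numpy())[:, 1], index=test
    )
    report = evaluate_roc(scores, labels.loc[test],
                          n_bootstrap=clf_cfg.n_bootstrap, seed=clf_cfg.rng_seed)
    _write_tsv(report.curve, outdir / ARTIFACTS["roc_curve"])
    top_n = config.top_n or len(ranking)
    top = select_top_features(ranking, min(top_n, len(ranking)))
    (outdir / ARTIFACTS["top_features"]).write_text("\n".join(top) + "\n")
    payload = {
        "auc": report.auc,
        "ci_low": report.ci_low,
        "ci_high": report.ci_high,
        "p_value": report.p_value,
        "n_high": report.n_high,
        "n_low": report.n_low,
        "n_train": len(train),
        "n_test": len(test),
        "features": features,
        "seed": clf_cfg.rng_seed,
        "config": dataclasses.asdict(clf_cfg),
    }
    with open(outdir / ARTIFACTS["roc_report"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"n_features": len(features), "auc": report.auc,
            "n_train": len(train), "n_test": len(test)}


def _stage_enrich(config: PipelineConfig, inputs, outdir: Path) -> dict:
    results = pd.read_csv(inputs["differential_results"], sep="\t")
    background = None
    bg_path = _resolve(config, "background", outdir)
    if bg_path.exists():
        background = load_background(bg_path)
    collection = load_gmt(inputs["annotations"], background=background)
    # categories may be provided alongside the simulated ground truth
    gt_path = outdir / ARTIFACTS["ground_truth"]
    if gt_path.exists():
        with open(gt_path) as fh:
            cats = json.load(fh).get("term_categories", {})
        collection = dataclasses.replace(collection, categories=cats)
    query = set(results.loc[results["significant"], "protein"])
    query &= collection.background
    if not query:
        raise PipelineError("no significant proteins within the annotation background")
    table = enrich(query, collection, alpha=config.alpha)
    n = _write_tsv(table, outdir / ARTIFACTS["enrichment"])
    tally = category_tally(table).rename("n_significant").reset_index()
    _write_tsv(tally, outdir / ARTIFACTS["enrichment_categories"])
    return {"terms_tested": n, "significant": int(table["significant"].sum())}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "nutrients": _stage_nutrients,
    "dii": _stage_dii,
    "split": _stage_split,
    "diffexp": _stage_diffexp,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
}
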