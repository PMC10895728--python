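"""Dietary Inflammatory Index (DII) scoring.

The DII summarises the inflammatory potential of a diet.  Each nutrient
parameter ``p`` with mean daily intake ``x_p`` is standardised against a
reference population, ``z_p = (x_p - mean_p) / sd_p``, mapped to a centered
percentile in (-1, 1), and weighted by a literature-derived inflammatory
effect score in [-1, +1] (negative = anti-inflammatory).  The subject's DII
is the sum of the weighted terms over the parameters available in the
intake profile.

The centered percentile is ``2 * Phi(z) - 1`` under the normality implied by
z-scoring; a reference row may instead carry empirical quantiles, in which
case the percentile is interpolated from them (see
:func:`centered_percentile_empirical`).

The reference means, SDs and effect scores are configuration: the packaged
default (see :mod:`diinpx.synthetic`) is illustrative, not the published
global database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dietary import NutrientIntakeProfile


class DIIError(ValueError):
    """Invalid DII reference or scoring input."""


@dataclass(frozen=True)
class DIIReferenceTable:
    """Per-parameter reference: global mean and SD of daily intake plus the
    inflammatory effect score.

    ``table`` has columns ``parameter unit global_mean global_sd
    effect_score`` and optionally ``quantiles`` (semicolon-separated
    ascending reference quantiles for an empirical percentile transform).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t["parameter"].duplicated().any():
            dupes = sorted(t["parameter"][t["parameter"].duplicated()])
            raise DIIError(f"duplicated reference parameters: {dupes}")
        if (t["global_sd"] <= 0).any():
            bad = sorted(t.loc[t["global_sd"] <= 0, "parameter"])
            raise DIIError(f"non-positive global_sd for: {bad}")
        if (t["effect_score"].abs() > 1).any():
            bad = sorted(t.loc[t["effect_score"].abs() > 1, "parameter"])
            raise DIIError(f"effect_score outside [-1, 1] for: {bad}")

    @property
    def parameters(self) -> list[str]:
        return list(self.table["parameter"])


@dataclass(frozen=True)
class DIIResult:
    subject_id: str
    per_parameter: pd.DataFrame  # parameter, intake, z, centered_percentile, contribution
    dii_total: float
    n_parameters_used: int


def load_dii_reference(path) -> DIIReferenceTable:
    """Read a reference TSV ``parameter unit global_mean global_sd effect_score``."""
    df = pd.read_csv(path, sep="\t", dtype={"parameter": str, "unit": str})
    required = ["parameter", "unit", "global_mean", "global_sd", "effect_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DIIError(f"reference table missing columns: {missing}")
    for c in ("global_mean", "global_sd", "effect_score"):
        df[c] = df[c].astype(float)
    return DIIReferenceTable(table=df)


def centered_percentile(z: float) -> float:
    """Map a z-score to a centered percentile ``2*Phi(z) - 1`` in (-1, 1).

    Odd and strictly increasing in ``z``.
    """
    z = float(z)
    if not math.isfinite(z):
        raise DIIError(f"non-finite z-score: {z}")
    return float(2.0 * stats.norm.cdf(z) - 1.0)


def centered_percentile_empirical(intake: float, quantiles: np.ndarray) -> float:
    """Centered percentile from empirical reference quantiles.

    ``quantiles`` are values at evenly spaced probabilities (0..1 inclusive);
    the intake's cumulative probability is linearly interpolated and mapped
    through ``2p - 1``, clipped away from ±1 at half a grid step.
    """
    q = np.asarray(quantiles, dtype=float)
    if q.size < 2 or np.any(np.diff(q) < 0):
        raise DIIError("empirical quantiles must be >= 2 ascending values")
    probs = np.linspace(0.0, 1.0, q.size)
    p = float(np.interp(intake, q, probs))
    eps = 0.5 / (q.size - 1)
    p = min(max(p, eps), 1.0 - eps)
    return 2.0 * p - 1.0


def compute_dii(
    profile: NutrientIntakeProfile,
    reference: DIIReferenceTable,
    policy: str = "skip",
) -> DIIResult:
    """Score one subject.

    ``policy`` controls reference parameters absent from the profile:
    ``"skip"`` sums over the available ones (recording how many were used),
    ``"error"`` raises.  A unit declared in both the profile and the
    reference must match exactly; no conversion is attempted.
    """
    if policy not in ("skip", "error"):
        raise DIIError(f"unknown missing-parameter policy {policy!r}")
    rows = []
    for rec in reference.table.itertuples(index=False):
        param = rec.parameter
        if param not in profile.mean_daily_nutrients:
            if policy == "error":
                raise DIIError(
                    f"subject {profile.subject_id!r}: parameter {param!r} "
                    "missing from intake profile"
                )
            continue
        declared = profile.units.get(param)
        if declared is not None and str(rec.unit) != declared:
            raise DIIError(
                f"unit mismatch for {param!r}: profile {declared!r} "
                f"vs reference {rec.unit!r}"
            )
        intake = profile.mean_daily_nutrients[param]
        z = (intake - rec.global_mean) / rec.global_sd
        quantiles = getattr(rec, "quantiles", None)
        if isinstance(quantiles, str) and quantiles.strip():
            q = np.array([float(v) for v in quantiles.split(";")])
            cp = centered_percentile_empirical(intake, q)
        else:
            cp = centered_percentile(z)
        rows.append(
            {
                "parameter": param,
                "intake": intake,
                "z": z,
                "centered_percentile": cp,
                "contribution": cp * rec.effect_score,
            }
        )
    if not rows:
        raise DIIError(
            f"subject {profile.subject_id!r}: no reference parameter present "
            "in the intake profile"
        )
    per_param = pd.DataFrame(rows)
    return DIIResult(
        subject_id=profile.subject_id,
        per_parameter=per_param,
        dii_total=float(per_param["contribution"].sum()),
        n_parameters_used=len(per_param),
    )


def compute_dii_table(
    profiles: list[NutrientIntakeProfile],
    reference: DIIReferenceTable,
    policy: str = "skip",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a cohort.

    Returns ``(summary, contributions)``: the per-subject summary
    ``subject_id dii_total n_parameters_used`` and the long per-parameter
    contribution table.
    """
    summaries, longs = [], []
    for p in profiles:
        res = compute_dii(p, reference, policy=policy)
        summaries.append(
            {
                "subject_id": res.subject_id,
                "dii_total": res.dii_total,
                "n_parameters_used": res.n_parameters_used,
            }
        )
        long = res.per_parameter.copy()
        long.insert(0, "subject_id", res.subject_id)
        longs.append(long)
    summary = pd.DataFrame(summaries)
    contributions = pd.concat(longs, ignore_index=True)
    return summary, contributions
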