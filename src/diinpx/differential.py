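"""Per-protein differential NPX analysis between DII groups.

NPX (Normalized Protein eXpression) is already log2-scale, so the log2
fold change of a protein is simply the difference of group means.  For
each protein the test is chosen by a normality gate: if a Kolmogorov-
Smirnov test against a fitted normal is not rejected in *both* groups the
two-sample t-test is used, otherwise the Mann-Whitney U test.  P-values
are adjusted across proteins with Benjamini-Hochberg.

Two significance modes are carried through the pipeline:

* ``fdr`` (default): significant iff ``q_bh < alpha``;
* ``paper``: significant iff raw ``p < alpha`` (uncorrected calls).

Both quantities are always present in the output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import HIGH, LOW, CohortSplit

T_TEST, MANN_WHITNEY = "t", "mann-whitney"
SIG_MODES = ("fdr", "paper")

#: total sample size at or below which the Mann-Whitney null is enumerated
EXACT_RANK_MAX_N = 20


@dataclass(frozen=True)
class DifferentialConfig:
    alpha_normality: float = 0.05
    alpha_sig: float = 0.05
    sig_mode: str = "fdr"

    def __post_init__(self):
        if self.sig_mode not in SIG_MODES:
            raise ValueError(f"sig_mode must be one of {SIG_MODES}")


def load_npx(path) -> pd.DataFrame:
    """Read an NPX matrix as subjects x proteins.

    Accepts either a wide TSV (first column ``subject_id``, one column per
    protein) or a long TSV with header ``subject_id protein npx``; the
    layout is auto-detected from the header.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("NPX file must have a subject_id column")
    if list(df.columns[:3]) == ["subject_id", "protein", "npx"]:
        wide = df.pivot(index="subject_id", columns="protein", values="npx")
        wide.columns.name = None
        return wide
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id in wide NPX matrix")
    return df.set_index("subject_id").astype(float)


def _normal_ks_pvalue(x: np.ndarray) -> float:
    """KS test of x against a normal with moments fitted from x."""
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # degenerate: certainly not a continuous normal sample
    return float(stats.kstest((x - x.mean()) / sd, "norm").pvalue)


def choose_test(
    values_high: np.ndarray,
    values_low: np.ndarray,
    alpha_normality: float = 0.05,
) -> str:
    """Normality gate: t-test if neither group rejects KS normality."""
    hi = np.asarray(values_high, dtype=float)
    lo = np.asarray(values_low, dtype=float)
    for name, v in (("high", hi), ("low", lo)):
        if v.size < 3:
            raise ValueError(f"{name} group has {v.size} observations; need >= 3")
    if (
        _normal_ks_pvalue(hi) > alpha_normality
        and _normal_ks_pvalue(lo) > alpha_normality
    ):
        return T_TEST
    return MANN_WHITNEY


def mann_whitney_p(values_high: np.ndarray, values_low: np.ndarray) -> float:
    """Two-sided Mann-Whitney p.

    Exact null distribution when the total sample size is at most
    ``EXACT_RANK_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    hi = np.asarray(values_high, dtype=float)
    lo = np.asarray(values_low, dtype=float)
    pooled = np.concatenate([hi, lo])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_RANK_MAX_N and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method).pvalue
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_all_proteins(
    npx: pd.DataFrame,
    split: CohortSplit,
    config: DifferentialConfig = DifferentialConfig(),
) -> pd.DataFrame:
    """Run the gated two-group test for every protein.

    Missing values are dropped per protein.  A protein with fewer than 3
    usable observations in either group is flagged ``testable = False``
    and excluded from the BH adjustment.  Returns one row per protein with
    columns ``protein mean_high mean_low log2fc test_used p_raw q_bh
    n_high n_low testable significant``.
    """
    labels = split.labels
    missing = npx.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"subjects without a split label: {sorted(missing)[:5]}")
    hi_idx = npx.index.intersection(labels.index[labels == HIGH])
    lo_idx = npx.index.intersection(labels.index[labels == LOW])

    rows = []
    for protein in npx.columns:
        hi = npx.loc[hi_idx, protein].dropna().to_numpy()
        lo = npx.loc[lo_idx, protein].dropna().to_numpy()
        row = {
            "protein": protein,
            "n_high": hi.size,
            "n_low": lo.size,
            "mean_high": hi.mean() if hi.size else np.nan,
            "mean_low": lo.mean() if lo.size else np.nan,
        }
        row["log2fc"] = row["mean_high"] - row["mean_low"]
        if hi.size < 3 or lo.size < 3:
            row.update(test_used=None, p_raw=np.nan, testable=False)
        else:
            test = choose_test(hi, lo, config.alpha_normality)
            if test == T_TEST:
                p = float(stats.ttest_ind(hi, lo, equal_var=True).pvalue)
            else:
                p = mann_whitney_p(hi, lo)
            row.update(test_used=test, p_raw=p, testable=True)
        rows.append(row)

    res = pd.DataFrame(rows)
    res["q_bh"] = np.nan
    testable = res["testable"]
    if testable.any():
        # identical samples give p = 1 exactly; guard only against p = 0 underflow
        p_adj_in = res.loc[testable, "p_raw"].clip(lower=np.finfo(float).tiny)
        res.loc[testable, "q_bh"] = bh_fdr(p_adj_in)
    if config.sig_mode == "paper":
        res["significant"] = testable & (res["p_raw"] < config.alpha_sig)
    else:
        res["significant"] = testable & (res["q_bh"] < config.alpha_sig)
    cols = [
        "protein", "mean_high", "mean_low", "log2fc", "test_used",
        "p_raw", "q_bh", "n_high", "n_low", "testable", "significant",
    ]
    return res[cols]


# keep pytest from collecting the library function when imported by name
test_all_proteins.__test__ = False  # type: ignore[attr-defined]


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates: ``log2fc``, ``-log10 p`` and the active flag."""
    if results.empty:
        raise ValueError("no test results to tabulate")
    out = results[["protein", "log2fc", "p_raw", "significant"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_raw"])
    return out[["protein", "log2fc", "neg_log10_p", "significant"]]
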