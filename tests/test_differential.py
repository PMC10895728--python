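"""Per-protein group comparison: normality gate, rank test, BH, volcano."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diinpx.cohort import CohortSplit
from diinpx.differential import (
    DifferentialConfig,
    bh_fdr,
    choose_test,
    load_npx,
    mann_whitney_p,
    test_all_proteins,
    volcano_table,
)


def exact_mw_p_by_enumeration(hi, lo):
    """Two-sided Mann-Whitney p as the doubled smaller tail over all
    C(n1+n2, n1) group assignments of the observed ranks."""
    pooled = np.concatenate([hi, lo])
    n1, n = len(hi), len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            for comb in itertools.combinations(range(n), n1)
        ]
    )
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def make_split(subjects_high, subjects_low):
    table = pd.DataFrame(
        {
            "subject_id": list(subjects_high) + list(subjects_low),
            "dii": [1.0] * len(subjects_high) + [-1.0] * len(subjects_low),
            "group": ["high"] * len(subjects_high) + ["low"] * len(subjects_low),
        }
    )
    return CohortSplit(table=table, median_dii=0.0)


def make_npx(values_by_protein, subjects):
    return pd.DataFrame(values_by_protein, index=pd.Index(subjects, name="subject_id"))


class TestChooseTest:
    def test_normal_samples_pass_the_gate(self):
        rng = np.random.default_rng(1)
        assert choose_test(rng.normal(size=200), rng.normal(size=200)) == "t"

    def test_heavy_tailed_sample_fails_the_gate(self):
        rng = np.random.default_rng(2)
        heavy = rng.standard_cauchy(200)
        assert choose_test(rng.normal(size=200), heavy) == "mann-whitney"

    def test_tiny_group_is_error(self):
        with pytest.raises(ValueError, match="2 observations"):
            choose_test(np.array([1.0, 2.0]), np.ones(5))


class TestMannWhitney:
    def test_4v4_all_distinct_matches_enumeration_of_70_assignments(self):
        hi = np.array([3.1, 0.4, 5.9, 2.6])
        lo = np.array([1.5, 9.7, 7.2, 8.1])
        assert mann_whitney_p(hi, lo) == pytest.approx(
            exact_mw_p_by_enumeration(hi, lo), abs=1e-12
        )

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 5), (4, 4), (5, 3)])
    def test_small_samples_match_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            vals = rng.permutation(rng.normal(size=n1 + n2) * 5)
            hi, lo = vals[:n1], vals[n1:]
            assert mann_whitney_p(hi, lo) == pytest.approx(
                exact_mw_p_by_enumeration(hi, lo), abs=1e-12
            )

    def test_identical_samples_give_p_one(self):
        assert mann_whitney_p(np.ones(5), np.ones(5)) == 1.0


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_computation(self):
        # m=4: q_i = min over j>=i of p_j * 4 / j
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_capped(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_empty_list_passes_through(self):
        assert len(bh_fdr([])) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestTestAllProteins:
    def _cohort(self, seed=0, n=40, shift=0.0):
        rng = np.random.default_rng(seed)
        subjects = [f"S{i}" for i in range(n)]
        hi, lo = subjects[: n // 2], subjects[n // 2:]
        npx = make_npx(
            {
                "P1": np.r_[rng.normal(shift, 1, n // 2), rng.normal(0, 1, n - n // 2)],
                "P2": rng.normal(size=n),
            },
            subjects,
        )
        return npx, make_split(hi, lo)

    def test_identical_protein_values_give_null_result(self):
        subjects = [f"S{i}" for i in range(12)]
        npx = make_npx({"P1": np.ones(12), "P2": np.arange(12.0)}, subjects)
        res = test_all_proteins(npx, make_split(subjects[:6], subjects[6:]))
        row = res.set_index("protein").loc["P1"]
        assert row["log2fc"] == 0.0
        assert row["test_used"] == "mann-whitney"
        assert row["p_raw"] == 1.0

    def test_swapping_groups_negates_log2fc_preserves_p(self):
        npx, split = self._cohort(seed=4, shift=1.0)
        res = test_all_proteins(npx, split)
        flipped = split.table.assign(
            group=split.table["group"].map({"high": "low", "low": "high"})
        )
        res_sw = test_all_proteins(npx, CohortSplit(table=flipped, median_dii=0.0))
        assert np.allclose(res["log2fc"], -res_sw["log2fc"])
        assert np.allclose(res["p_raw"], res_sw["p_raw"])

    def test_log2fc_is_difference_of_group_means(self):
        npx, split = self._cohort(seed=5, shift=0.7)
        res = test_all_proteins(npx, split).set_index("protein")
        hi = npx.loc[split.subjects("high"), "P1"].mean()
        lo = npx.loc[split.subjects("low"), "P1"].mean()
        assert res.loc["P1", "log2fc"] == pytest.approx(hi - lo, rel=1e-12)

    def test_protein_missing_in_one_group_flagged_untestable(self):
        subjects = [f"S{i}" for i in range(10)]
        vals = np.arange(10.0)
        broken = vals.copy()
        broken[:5] = np.nan  # the whole high group missing
        npx = make_npx({"P1": broken, "P2": vals}, subjects)
        res = test_all_proteins(npx, make_split(subjects[:5], subjects[5:]))
        res = res.set_index("protein")
        assert not res.loc["P1", "testable"]
        assert np.isnan(res.loc["P1", "q_bh"])
        assert res.loc["P2", "q_bh"] == pytest.approx(res.loc["P2", "p_raw"])

    def test_unlabelled_subject_is_error(self):
        npx, split = self._cohort()
        npx.index = ["X" + s for s in npx.index]
        with pytest.raises(ValueError, match="without a split label"):
            test_all_proteins(npx, split)

    def test_forced_rank_test_via_normality_alpha_one(self):
        npx, split = self._cohort(seed=6)
        res = test_all_proteins(npx, split, DifferentialConfig(alpha_normality=1.0))
        assert (res["test_used"] == "mann-whitney").all()


class TestVolcano:
    def test_neg_log10_transform(self):
        res = pd.DataFrame(
            {
                "protein": ["P1"],
                "log2fc": [0.5],
                "p_raw": [0.05],
                "significant": [True],
            }
        )
        v = volcano_table(res)
        assert v["neg_log10_p"].iloc[0] == pytest.approx(1.301029996, abs=1e-9)

    def test_null_protein_sits_at_origin_unflagged(self):
        res = pd.DataFrame(
            {"protein": ["P"], "log2fc": [0.0], "p_raw": [1.0], "significant": [False]}
        )
        v = volcano_table(res)
        assert v["log2fc"].iloc[0] == 0.0
        assert v["neg_log10_p"].iloc[0] == 0.0
        assert not v["significant"].iloc[0]

    def test_paper_mode_flags_equal_raw_p_calls(self):
        rng = np.random.default_rng(9)
        subjects = [f"S{i}" for i in range(30)]
        npx = make_npx(
            {f"P{j}": rng.normal(size=30) for j in range(25)}, subjects
        )
        split = make_split(subjects[:15], subjects[15:])
        res = test_all_proteins(npx, split, DifferentialConfig(sig_mode="paper"))
        v = volcano_table(res)
        assert v["significant"].sum() == (res["p_raw"] < 0.05).sum()


class TestLoadNPX:
    def test_wide_and_long_layouts_agree(self, tmp_path):
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(
            rng.normal(size=(4, 3)),
            index=pd.Index(["a", "b", "c", "d"], name="subject_id"),
            columns=["P1", "P2", "P3"],
        )
        wp = tmp_path / "wide.tsv"
        wide.reset_index().to_csv(wp, sep="\t", index=False)
        lp = tmp_path / "long.tsv"
        wide.stack().rename("npx").rename_axis(["subject_id", "protein"]).reset_index().to_csv(
            lp, sep="\t", index=False
        )
        pd.testing.assert_frame_equal(load_npx(wp), load_npx(lp))

    def test_duplicate_subject_rejected(self, tmp_path):
        p = tmp_path / "npx.tsv"
        p.write_text("subject_id\tP1\na\t1.0\na\t2.0\n")
        with pytest.raises(ValueError, match="duplicated"):
            load_npx(p)
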