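import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from playnet.cohort import (
    analyze_cohort,
    compute_participant_metrics,
    metrics_table,
    notched_box_summary,
    spearman,
    wilcoxon_rank_sum,
)
from playnet.simulate import (
    StrategyProfile,
    simulate_session,
    stacker_profile,
)


class TestComputeParticipantMetrics:
    def test_direct_only_session(self, zm):
        prof = StrategyProfile(n_cycles=10, p_stack=0.0, offtask_rate=0.0, seed=0)
        ev, _ = simulate_session(prof, zm)
        m = compute_participant_metrics(ev, zm, participant_id="p0")
        assert m.n_food_delivery == 40
        assert m.n_inter_plate == 0
        assert m.score_difference == 0.0

    def test_stacker_session(self, zm):
        ev, _ = simulate_session(stacker_profile(seed=1, p_stack=1.0), zm)
        m = compute_participant_metrics(ev, zm)
        assert m.n_inter_plate == 3 * 12
        assert m.score_difference > 0

    def test_empty_log_flagged_degenerate(self, zm):
        m = compute_participant_metrics([], zm)
        assert m.n_food_delivery == 0
        assert m.n_inter_plate == 0
        assert m.direct_score == 0.0
        assert m.indirect_score == 0.0
        assert m.degenerate

    def test_score_difference_consistency(self, zm):
        ev, _ = simulate_session(stacker_profile(seed=2), zm)
        m = compute_participant_metrics(ev, zm)
        assert m.score_difference == pytest.approx(
            m.indirect_score - m.direct_score, abs=1e-12
        )


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_exact_small_sample_vs_enumeration_oracle(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        stat, p = wilcoxon_rank_sum(x, y)
        # oracle: enumerate all C(6,3)=20 rank assignments and count
        # arrangements with a rank-sum at least as extreme
        ranks = range(1, 7)
        observed = sum(stats.rankdata(x + y)[:3])
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        mean = np.mean(sums)
        extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in sums)
        assert p == pytest.approx(extreme / len(sums), abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_large_shifted_normals_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-3

    @pytest.mark.parametrize("seed", [0, 1])
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(0.3, 1.2, size=25)
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(
            wilcoxon_rank_sum(y, x)[1], abs=1e-12
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_strictly_monotone(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        y = [v**2 for v in x]
        r, _ = spearman(x, y)
        assert r == pytest.approx(1.0)
        r, _ = spearman(x, [-v for v in y])
        assert r == pytest.approx(-1.0)

    def test_ties_match_pearson_on_average_ranks_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0, 8.0, 8.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 5.0, 7.0, 9.0, 8.0, 10.0]
        r, _ = spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        # n=4: enumerate all 24 orderings by hand
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        r, p = spearman(x, y)
        assert r == pytest.approx(0.8)
        rs = []
        for perm in itertools.permutations([1.0, 3.0, 2.0, 4.0]):
            rs.append(np.corrcoef(x, perm)[0, 1])
        expect = np.mean([abs(v) >= 0.8 - 1e-12 for v in rs])
        assert p == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_flagged(self):
        r, p = spearman([1, 2, 3, 4], [5, 5, 5, 5])
        assert np.isnan(r) and np.isnan(p)


class TestNotchedBoxSummary:
    def test_arithmetic_on_1_to_100(self):
        s = notched_box_summary(list(range(1, 101)))
        assert s["median"] == pytest.approx(50.5)
        assert s["q3"] - s["q1"] == pytest.approx(49.5)
        half = 1.57 * (s["q3"] - s["q1"]) / 10
        assert s["notch_hi"] - s["median"] == pytest.approx(half)

    def test_single_value_collapses(self):
        s = notched_box_summary([3.0])
        assert s["median"] == s["notch_lo"] == s["notch_hi"] == 3.0

    def test_nonoverlapping_notches_imply_wilcoxon_significance(self):
        # shifted pairs whose notches separate should almost always be
        # significant at the 5% level
        rng = np.random.default_rng(1)
        agree = 0
        total = 0
        for _ in range(200):
            x = rng.normal(0, 1, 40)
            y = rng.normal(rng.uniform(0.5, 1.5), 1, 40)
            sx, sy = notched_box_summary(x), notched_box_summary(y)
            if sx["notch_hi"] < sy["notch_lo"] or sy["notch_hi"] < sx["notch_lo"]:
                total += 1
                if wilcoxon_rank_sum(x, y)[1] < 0.05:
                    agree += 1
        assert total > 50
        assert agree / total >= 0.9


@pytest.fixture(scope="module")
def small_table():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(40):
        group = "a" if i < 20 else "b"
        shift = 0.0 if group == "a" else 0.3
        rows.append(
            {
                "participant_id": f"P{i:03d}",
                "group": group,
                "age_months": int(rng.integers(30, 73)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "severity": None,
                "n_food_delivery": int(rng.poisson(40)),
                "n_inter_plate": int(rng.poisson(5 + 20 * shift)),
                "direct_score": float(rng.normal(0.1 - shift / 3, 0.05)),
                "indirect_score": float(rng.normal(0.1, 0.05)),
                "score_difference": float(rng.normal(shift / 3, 0.05)),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


class TestAnalyzeCohort:
    def test_tidy_output_columns(self, small_table):
        out = analyze_cohort(small_table, contrasts=[("a", "b")])
        assert set(out.columns) >= {
            "contrast_or_group", "metric", "n1", "n2",
            "median1", "median2", "stat", "p", "method",
        }
        assert (out["method"] == "wilcoxon_rank_sum").any()
        assert (out["method"] == "spearman_vs_age").any()

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(5)
        base = [
            {
                "participant_id": f"x{i}",
                "group": "a",
                "age_months": 40 + i,
                "score_difference": float(rng.normal()),
            }
            for i in range(10)
        ]
        dup = [dict(r, participant_id=f"y{i}", group="b") for i, r in enumerate(base)]
        table = pd.DataFrame(base + dup)
        out = analyze_cohort(
            table, contrasts=[("a", "b")], correlates=["score_difference"]
        )
        contrast = out[out["method"] == "wilcoxon_rank_sum"]
        assert contrast["p"].tolist() == pytest.approx([1.0], abs=1e-9)

    def test_small_group_skipped(self, small_table):
        table = pd.concat(
            [
                small_table,
                pd.DataFrame(
                    [dict(small_table.iloc[0], participant_id="lone", group="c")]
                ),
            ],
            ignore_index=True,
        )
        out = analyze_cohort(table, contrasts=[("a", "c")])
        assert not (
            (out["method"] == "wilcoxon_rank_sum")
            & (out["contrast_or_group"] == "a:c")
        ).any()

    def test_sex_stratification_relabels_groups(self, small_table):
        out = analyze_cohort(small_table, stratify_by="sex")
        labels = set(out.loc[out["method"] == "wilcoxon_rank_sum", "contrast_or_group"])
        assert any("a/F" in lab for lab in labels)

    def test_duplicate_ids_rejected(self, small_table):
        bad = pd.concat([small_table, small_table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="unique"):
            analyze_cohort(bad, contrasts=[("a", "b")])

    def test_bh_column_monotone_in_p(self, small_table):
        out = analyze_cohort(
            small_table, contrasts=[("a", "b")], benjamini_hochberg=True
        )
        assert (out["p_bh"] >= out["p"] - 1e-12).all()
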