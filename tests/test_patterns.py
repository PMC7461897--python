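"""Pattern mining: combination/permutation tables, contributions, count tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mmtraj as m
from mmtraj.conditions import CONDITIONS, Condition
from mmtraj.patterns import combination_of

from conftest import traj_from_events


def two_condition_traj():
    # persons: A->B, B->A, A->B with A=CANCER, B=CVD
    rows = [
        (1, "CANCER", 1.0), (1, "CVD", 2.0),
        (2, "CVD", 1.0), (2, "CANCER", 2.0),
        (3, "CANCER", 0.5), (3, "CVD", 4.0),
    ]
    return traj_from_events(rows)


class TestPatternTable:
    def test_ordered_counts(self):
        tab = m.pattern_table(two_condition_traj(), 2, ordered=True, min_count=1)
        counts = dict(zip(tab.table["pattern"], tab.table["count"]))
        assert counts == {"CANCER|CVD": 2, "CVD|CANCER": 1}
        pcts = dict(zip(tab.table["pattern"], tab.table["pct"]))
        assert pcts["CANCER|CVD"] == pytest.approx(200 / 3)

    def test_unordered_aggregates_orderings(self):
        tab = m.pattern_table(two_condition_traj(), 2, ordered=False, min_count=1)
        assert tab.table["pattern"].tolist() == ["CANCER|CVD"]
        assert tab.table["count"].tolist() == [3]
        assert tab.table["pct"].iloc[0] == pytest.approx(100.0)

    def test_group_level_keeps_multiset_of_two_cmds(self):
        traj = traj_from_events(
            [(1, "HYPERTENSION", 1.0), (1, "DYSLIPIDEMIA", 2.0)]
        )
        tab = m.pattern_table(traj, 2, level="group", min_count=1)
        assert tab.table["pattern"].tolist() == ["CMD|CMD"]

    def test_percentages_sum_to_100(self, accelerated_traj):
        _, traj = accelerated_traj
        for k in (2, 3, 4):
            for level in ("condition", "group"):
                for ordered in (False, True):
                    tab = m.pattern_table(traj, k, level=level, ordered=ordered)
                    assert tab.table["pct"].sum() == pytest.approx(100.0, abs=1e-9)
                    assert tab.table["count"].sum() == tab.n_eligible

    def test_permutations_partition_combinations(self, accelerated_traj):
        _, traj = accelerated_traj
        for level in ("condition", "group"):
            ordered = m.pattern_table(traj, 2, level=level, ordered=True).table
            unordered = m.pattern_table(traj, 2, level=level, ordered=False).table
            grouped = (
                ordered.assign(
                    key=ordered["pattern"].map(lambda p: combination_of(p, level))
                )
                .groupby("key")["count"]
                .sum()
            )
            target = dict(zip(unordered["pattern"], unordered["count"]))
            assert grouped.to_dict() == target

    def test_group_table_recomputable_from_condition_table(self, accelerated_traj):
        _, traj = accelerated_traj
        cond = m.pattern_table(traj, 2, level="condition", ordered=True, min_count=1)
        group = m.pattern_table(traj, 2, level="group", ordered=True, min_count=1)
        mapped = {}
        for pat, cnt in zip(cond.table["pattern"], cond.table["count"]):
            key = "|".join(
                m.to_group(c).value for c in pat.split("|")
            )
            mapped[key] = mapped.get(key, 0) + cnt
        assert mapped == dict(zip(group.table["pattern"], group.table["count"]))

    def test_small_cells_suppressed_from_public_view(self):
        tab = m.pattern_table(two_condition_traj(), 2, ordered=True, min_count=2)
        public = tab.to_frame(public=True)
        assert public["pattern"].tolist() == ["CANCER|CVD"]

    def test_exchangeable_cohort_symmetric_orderings(self):
        hz = m.HazardSpec(baseline_rate={c: 0.03 for c in Condition})
        persons, events = m.simulate_screened_cohort(
            m.CohortSpec(n_persons=4000), hz, seed=21
        )
        traj = m.assign_ranks(events)
        tab = m.pattern_table(traj, 2, ordered=True, min_count=1).table
        combo = {}
        for pat, cnt in zip(tab["pattern"], tab["count"]):
            combo.setdefault(combination_of(pat), []).append(cnt)
        # each ordering of a pair is Binomial(n, 1/2): check within 4 sigma
        for counts in combo.values():
            if len(counts) == 2 and sum(counts) >= 20:
                n = sum(counts)
                assert abs(counts[0] - n / 2) < 4 * np.sqrt(n / 4)


class TestContributionByRank:
    def test_single_person(self):
        traj = traj_from_events([(1, "CANCER", 1.0), (1, "CVD", 2.0)])
        tab = m.contribution_by_rank(traj)
        at = tab.set_index(["condition", "rank"])["pct"]
        assert at[("CANCER", 1)] == 100.0 and at[("CVD", 2)] == 100.0

    def test_symmetric_two_persons(self):
        traj = two_condition_traj().query("person_id < 3")
        tab = m.contribution_by_rank(traj).set_index(["condition", "rank"])["pct"]
        for cond in ("CANCER", "CVD"):
            assert tab[(cond, 1)] == 50.0 and tab[(cond, 2)] == 50.0

    def test_per_rank_percentages_sum_to_100(self, accelerated_traj):
        _, traj = accelerated_traj
        tab = m.contribution_by_rank(traj)
        sums = tab.groupby("rank")["pct"].sum()
        assert np.allclose(sums, 100.0)

    def test_injected_asymmetry_shifts_first_rank_share(self):
        hz = m.HazardSpec(
            baseline_rate=dict(m.simulate.ILLUSTRATIVE_RATES),
            progression_multiplier={Condition.ASTHMA: {Condition.CVD: 5.0}},
        )
        persons, events = m.simulate_screened_cohort(
            m.CohortSpec(n_persons=8000), hz, seed=22
        )
        tab = m.contribution_by_rank(m.assign_ranks(events))
        at = tab.set_index(["condition", "rank"])["pct"]
        assert at[("ASTHMA", 1)] > at[("ASTHMA", 2)]


class TestChiSquare:
    def test_perfect_homogeneity(self):
        r = m.chi_square_2xk([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_computed_2x2(self):
        # Pearson formula: N (ad - bc)^2 / (row1 row2 col1 col2) = 20/3
        r = m.chi_square_2xk([[20, 10], [10, 20]])
        assert r.statistic == pytest.approx(20 / 3, abs=1e-12)
        assert r.df == 1

    def test_matches_reference_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tab = rng.integers(1, 60, size=(2, 2))
            mine = m.chi_square_2xk(tab)
            ref = sps.chi2_contingency(tab, correction=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            m.chi_square_2xk([[0, 0], [5, 10]])


class TestCochranArmitage:
    def test_no_trend_gives_zero_statistic(self):
        r = m.cochran_armitage([10, 10, 10], [40, 40, 40])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_increasing_proportions_positive_z(self):
        r = m.cochran_armitage([5, 15, 30], [50, 50, 50])
        assert r.statistic > 0 and r.p_value < 0.01

    def test_z_squared_matches_logistic_score_test(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        for _ in range(20):
            totals = rng.integers(20, 80, size=4)
            succ = np.array([rng.integers(1, t) for t in totals])
            mine = m.cochran_armitage(succ, totals)
            # expand to binary rows; score test of the rank covariate
            y = np.concatenate(
                [np.r_[np.ones(s), np.zeros(t - s)] for s, t in zip(succ, totals)]
            )
            scores = np.concatenate(
                [np.full(t, i + 1.0) for i, t in enumerate(totals)]
            )
            null = sm.GLM(y, np.ones((y.size, 1)),
                          family=sm.families.Binomial()).fit()
            stat, _, _ = null.score_test(exog_extra=scores[:, None])
            assert mine.statistic**2 == pytest.approx(float(np.ravel(stat)[0]), rel=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.cochran_armitage([0, 0, 0], [10, 10, 10])
        with pytest.raises(ValueError):
            m.cochran_armitage([10, 10], [10, 10])
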