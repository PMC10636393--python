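import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from parcelstim.outcomes import (OutcomeError, OutcomeRecord,
                                 classify_response, classify_remission,
                                 severity_band, percent_change,
                                 summarize_cohort, rank_sum_test,
                                 records_to_csv, records_from_csv)


class TestResponse:
    @pytest.mark.parametrize("baseline,later,expected", [
        (25, 12, True),   # 52% decrease
        (25, 14, False),  # 44% decrease
        (30, 15, True),   # 50%
        (10, 10, False),  # no change
        (63, 33, True),   # 47.6%
    ])
    def test_forty_seven_percent_rule(self, baseline, later, expected):
        assert classify_response(baseline, later) is expected

    def test_exact_boundary_inclusive(self):
        assert classify_response(50, 26.5) is True  # exactly 47%
        assert classify_response(50, 27) is False   # 46%

    def test_no_change_never_responds(self):
        for x in (1, 20, 63):
            assert classify_response(x, x) is False

    def test_zero_baseline_undefined(self):
        with pytest.raises(OutcomeError):
            classify_response(0, 0)


class TestRemission:
    @pytest.mark.parametrize("score,expected", [
        (12, True),   # boundary inclusive
        (13, False),
        (0, True),
        (63, False),
    ])
    def test_cutoff(self, score, expected):
        assert classify_remission(score) is expected

    def test_out_of_range(self):
        with pytest.raises(OutcomeError):
            classify_remission(64)

    def test_monotone_in_score(self):
        flags = [classify_remission(s) for s in range(64)]
        assert flags == sorted(flags, reverse=True)


class TestSeverity:
    @pytest.mark.parametrize("score,band", [
        (25.2, "moderate"),  # study cohort baseline mean
        (13, "minimal"), (14, "mild"),
        (19, "mild"), (20, "moderate"),
        (28, "moderate"), (29, "severe"),
        (0, "minimal"), (63, "severe"),
    ])
    def test_bands(self, score, band):
        assert severity_band(score) == band


def make_record(pid, base, post, fu=None, trd=False):
    return OutcomeRecord(patient_id=pid, bdi_baseline=base, bdi_post=post,
                         bdi_followup=fu, eq5d_baseline=0.5, eq5d_post=0.7,
                         eq5d_followup=0.7 if fu is not None else None,
                         trd=trd,
                         followup_interval_months=2.6 if fu else 0.0)


class TestSummaries:
    def test_denominators(self):
        records = [make_record("a", 30, 10, fu=10),
                   make_record("b", 30, 25),
                   make_record("c", 26, 15, fu=16),
                   make_record("d", 20, 19)]
        s = summarize_cohort(records, compare_trd=False)
        assert s.n == 4 and s.n_followup == 2
        assert s.response_rate_post == pytest.approx(1 / 4)
        assert s.remission_rate_post == pytest.approx(1 / 4)
        # follow-up rates over completers only
        assert s.response_rate_fu == pytest.approx(1 / 2)
        assert s.remission_rate_fu == pytest.approx(1 / 2)

    def test_all_remitted(self):
        records = [make_record(str(k), 30, 5) for k in range(5)]
        s = summarize_cohort(records, compare_trd=False)
        assert s.remission_rate_post == 1.0

    def test_all_four_outcome_combinations_reachable(self):
        # response/remission are logically independent
        combos = {
            (True, True): make_record("a", 30, 10),
            (True, False): make_record("b", 40, 20),
            (False, True): make_record("c", 20, 12),
            (False, False): make_record("d", 30, 25),
        }
        for (resp, rem), r in combos.items():
            assert r.response_post() is resp
            assert r.remission_post() is rem

    def test_trd_comparison_present(self):
        records = [make_record(str(k), 30, 10 + k, trd=k % 2 == 0)
                   for k in range(8)]
        s = summarize_cohort(records)
        assert "post" in s.trd_comparison
        assert 0 <= s.trd_comparison["post"]["pvalue"] <= 1

    def test_summary_json_and_report(self, tmp_path):
        records = [make_record("a", 30, 10, fu=9), make_record("b", 25, 20)]
        s = summarize_cohort(records, compare_trd=False)
        s.to_json(tmp_path / "s.json")
        assert (tmp_path / "s.json").exists()
        assert "Remission" in s.report()


class TestRankSum:
    def test_identical_groups_p_near_one(self):
        out = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert out["method"] == "exact"
        assert out["pvalue"] >= 0.99

    def test_disjoint_groups_exact_enumeration(self):
        out = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert out["statistic"] == 0.0
        assert out["pvalue"] == pytest.approx(0.1)  # 2 / C(6,3)

    def test_exact_matches_brute_force_oracle(self, rng):
        # independent oracle: direct enumeration computing U via rank sums
        a = list(rng.integers(0, 20, 5))
        b = list(rng.integers(0, 20, 6))
        ours = rank_sum_test(a, b)
        pooled = np.array(a + b, float)
        n1 = len(a)
        ranks = scipy.stats.rankdata(pooled)
        obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        center = n1 * len(b) / 2
        hits = total = 0
        for comb in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - center) >= abs(obs - center) - 1e-12:
                hits += 1
        assert ours["pvalue"] == pytest.approx(hits / total, abs=1e-12)
        assert ours["statistic"] == pytest.approx(obs)

    def test_exact_matches_scipy_without_ties(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(7) + 0.5
        ours = rank_sum_test(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact")
        assert ours["pvalue"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_and_normal_agree_at_n8(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(8) + 0.3
        exact = rank_sum_test(a, b)
        forced = rank_sum_test(np.concatenate([a, [a[0]]]), b)  # n=9 path
        assert forced["method"] == "normal"
        approx = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic",
                                          use_continuity=True)
        assert exact["pvalue"] == pytest.approx(approx.pvalue, abs=0.02)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(5)
        b = rng.standard_normal(6)
        p1 = rank_sum_test(a, b)["pvalue"]
        p2 = rank_sum_test(np.exp(a), np.exp(b))["pvalue"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(OutcomeError):
            rank_sum_test([], [1.0])


class TestRecordIO:
    def test_csv_round_trip(self, tmp_path):
        records = [make_record("a", 30, 10, fu=9, trd=True),
                   make_record("b", 25, 20)]
        p = tmp_path / "outcomes.csv"
        records_to_csv(records, p)
        back = records_from_csv(p)
        assert back == records

    def test_score_scale_enforced(self):
        with pytest.raises(OutcomeError):
            make_record("a", 70, 10)
        with pytest.raises(OutcomeError):
            OutcomeRecord(patient_id="x", bdi_baseline=20, bdi_post=10,
                          eq5d_baseline=1.4)
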