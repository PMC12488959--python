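"""Paired summaries, Wilcoxon tests, direction counts and Bland-Altman."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

import upsit_norms.bridging_analysis as ba
from upsit_norms import (
    ParticipantRecord,
    bland_altman,
    direction_counts,
    paired_differences,
    run_bridging,
    summarize_scores,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from upsit_norms.synthetic_data import default_bridging_params, generate_bridging_cohort


def make_record(i, orig, rev, group="HC", **kw):
    defaults = dict(sex="female", age=67.0, site="s", block_order="original_first")
    defaults.update(kw)
    return ParticipantRecord(
        id=f"r{i}", group=group, score_original=orig, score_revised=rev, **defaults
    )


class TestSummarizeScores:
    def test_def5_quartiles_on_even_sample(self):
        s = summarize_scores([1, 2, 3, 4])
        assert (s.median, s.q1, s.q3) == (2.5, 1.5, 3.5)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max

    def test_single_value_flags_undefined_sd(self):
        s = summarize_scores([5])
        assert s.mean == s.median == s.min == s.max == 5
        assert s.sd == 0.0 and not s.sd_defined

    def test_mean_sd_match_two_pass_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 200)))
            s = summarize_scores(x)
            mean = sum(x) / len(x)
            sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
            assert s.mean == pytest.approx(mean, abs=1e-12)
            assert s.sd == pytest.approx(sd, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_scores([])


class TestPairedDifferences:
    def test_examples(self):
        recs = [make_record(1, 30, 32), make_record(2, 34, 34)]
        assert paired_differences(recs).tolist() == [2.0, 0.0]

    def test_incomplete_records_excluded(self):
        recs = [make_record(1, 30, 32), make_record(2, None, 34), make_record(3, 20, None)]
        assert paired_differences(recs).tolist() == [2.0]

    def test_linearity_identity(self, rng):
        recs = [
            make_record(i, int(o), int(v))
            for i, (o, v) in enumerate(zip(rng.integers(0, 41, 50), rng.integers(0, 41, 50)))
        ]
        diffs = paired_differences(recs)
        orig = [r.score_original for r in recs]
        rev = [r.score_revised for r in recs]
        assert diffs.mean() == pytest.approx(np.mean(rev) - np.mean(orig), abs=1e-12)

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError, match="complete"):
            paired_differences([make_record(1, None, 30)])


def signed_rank_bruteforce(diffs):
    """Exact two-sided p by direct enumeration of every sign assignment."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    cdf = sum(w <= w_obs + 1e-9 for w in ws) / len(ws)
    sf = sum(w >= w_obs - 1e-9 for w in ws) / len(ws)
    return w_obs, min(1.0, 2 * min(cdf, sf))


def rank_sum_bruteforce(a, b):
    """Exact two-sided p by enumerating every group assignment of the ranks."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = [
        sum(ranks[i] for i in combo) - n_a * (n_a + 1) / 2
        for combo in itertools.combinations(range(len(pooled)), n_a)
    ]
    cdf = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    sf = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return u_obs, min(1.0, 2 * min(cdf, sf))


class TestWilcoxonSignedRank:
    def test_exact_small_examples(self):
        r = wilcoxon_signed_rank([1, 2, 3])
        assert (r.statistic, r.p_value, r.method) == (6.0, 0.25, "exact")
        r = wilcoxon_signed_rank([1, -1])
        assert (r.statistic, r.p_value, r.method) == (1.5, 1.0, "exact")

    def test_zeros_discarded_and_counted(self):
        r = wilcoxon_signed_rank([0, 0, 1, 2, 3])
        assert (r.n_zero, r.n_used, r.p_value) == (2, 3, 0.25)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all differences zero"):
            wilcoxon_signed_rank([0, 0, 0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([])

    def test_exact_matches_bruteforce_with_ties(self, rng):
        for _ in range(40):
            m = int(rng.integers(2, 11))
            d = rng.integers(-4, 5, size=m)
            if not np.any(d != 0):
                continue
            r = wilcoxon_signed_rank(d)
            w_want, p_want = signed_rank_bruteforce(d)
            assert r.statistic == pytest.approx(w_want)
            assert r.p_value == pytest.approx(p_want, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            m = int(rng.integers(4, 13))
            d = rng.permutation(np.arange(1, m + 1)) * rng.choice([-1, 1], m)
            mine = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, method="exact", alternative="two-sided")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_approx_close_to_exact_on_overlap(self, rng, monkeypatch):
        """Untied differences: with heavy ties at small m the exact null has
        large point masses no continuous approximation can track, which is
        why the exact branch covers those sizes."""
        for _ in range(30):
            m = int(rng.integers(6, 13))
            d = np.round(rng.normal(0.4, 1.0, size=m), 6)
            exact = wilcoxon_signed_rank(d)
            monkeypatch.setattr(ba, "EXACT_SIGNED_RANK_MAX", 0)
            approx = wilcoxon_signed_rank(d)
            monkeypatch.undo()
            assert approx.method == "normal_approx"
            assert abs(approx.p_value - exact.p_value) <= 0.05


class TestWilcoxonRankSum:
    def test_exact_example(self):
        r = wilcoxon_rank_sum([1, 2], [3, 4])
        assert (r.statistic, r.method) == (0.0, "exact")
        assert r.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        r = wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5])
        assert r.p_value == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])

    def test_exact_matches_bruteforce(self, rng):
        for _ in range(25):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1, n_a + n_b + 1) * 10)
            a, b = pooled[:n_a], pooled[n_a:]
            r = wilcoxon_rank_sum(a, b)
            u_want, p_want = rank_sum_bruteforce(a, b)
            assert r.method == "exact"
            assert r.statistic == pytest.approx(u_want)
            assert r.p_value == pytest.approx(p_want, abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        for _ in range(20):
            n_a = int(rng.integers(3, 6))
            n_b = int(rng.integers(3, 7))
            pooled = rng.permutation(np.arange(1, n_a + n_b + 1) * 3 + 1)
            a, b = pooled[:n_a].astype(float), pooled[n_a:].astype(float)
            mine = wilcoxon_rank_sum(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_approx_close_to_exact_on_overlap(self, rng, monkeypatch):
        for _ in range(25):
            n_a = int(rng.integers(4, 7))
            n_b = int(rng.integers(4, 7))
            pooled = rng.permutation(np.arange(1, n_a + n_b + 1) * 7)
            a, b = pooled[:n_a], pooled[n_a:]
            exact = wilcoxon_rank_sum(a, b)
            monkeypatch.setattr(ba, "EXACT_RANK_SUM_MAX", 0)
            approx = wilcoxon_rank_sum(a, b)
            monkeypatch.undo()
            assert approx.method == "normal_approx"
            assert abs(approx.p_value - exact.p_value) <= 0.05


class TestDirectionCounts:
    def test_example(self):
        recs = [make_record(1, 30, 32), make_record(2, 34, 34), make_record(3, 20, 19)]
        d = direction_counts(recs)
        assert (d.higher, d.lower, d.same, d.n) == (1, 1, 1, 3)
        assert d.percentages == (33, 33, 33)

    def test_conservation(self, rng):
        recs = [
            make_record(i, int(o), int(v))
            for i, (o, v) in enumerate(zip(rng.integers(0, 41, 80), rng.integers(0, 41, 80)))
        ]
        d = direction_counts(recs)
        assert d.higher + d.lower + d.same == len(recs)


class TestBlandAltman:
    def test_two_pair_arithmetic(self):
        stats = bland_altman([make_record(1, 30, 32), make_record(2, 34, 34)])
        assert stats.mean_difference == 1.0
        assert stats.sd_difference == pytest.approx(math.sqrt(2))
        assert stats.loa_low == pytest.approx(1 - 1.96 * math.sqrt(2))
        assert stats.loa_high == pytest.approx(1 + 1.96 * math.sqrt(2))
        assert stats.pair_means == (31.0, 34.0)

    def test_limits_symmetric_about_mean(self, rng):
        recs = [
            make_record(i, int(o), int(v))
            for i, (o, v) in enumerate(zip(rng.integers(5, 36, 40), rng.integers(5, 36, 40)))
        ]
        stats = bland_altman(recs)
        assert stats.loa_high - stats.mean_difference == pytest.approx(
            stats.mean_difference - stats.loa_low
        )

    def test_shift_invariance_of_differences(self):
        base = [make_record(1, 20, 25), make_record(2, 22, 21), make_record(3, 30, 33)]
        shifted = [make_record(r.id, r.score_original + 5, r.score_revised + 5) for r in base]
        assert bland_altman(base).mean_difference == bland_altman(shifted).mean_difference
        assert bland_altman(base).sd_difference == bland_altman(shifted).sd_difference

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError, match="2 complete pairs"):
            bland_altman([make_record(1, 30, 32)])


@pytest.fixture(scope="module")
def cohort():
    return generate_bridging_cohort(default_bridging_params(seed=11))


class TestRunBridging:
    def test_deterministic_given_seed(self, cohort):
        again = generate_bridging_cohort(default_bridging_params(seed=11))
        r1 = run_bridging(cohort)
        r2 = run_bridging(again)
        assert r1.to_dict() == r2.to_dict()

    def test_group_blocks_present(self, cohort):
        res = run_bridging(cohort)
        assert set(res.group_summaries) == {"HC", "PD"}
        assert res.between_group_rank_sum is not None
        assert res.block_order_rank_sum is not None
        assert res.directions.n == sum(1 for r in cohort if r.complete)

    def test_percentile_scale_equals_raw_pipeline_on_lookups(self, cohort, published_norms):
        """Composition identity: the percentile block is the raw pipeline
        applied to looked-up percentile values (same norms for both versions
        here, as a pure identity check)."""
        from upsit_norms import lookup_percentile

        res = run_bridging(
            cohort, norms_original=published_norms, norms_revised=published_norms
        )
        assert res.percentile_summaries is not None
        manual = {}
        for g in ("HC", "PD"):
            vals = [
                lookup_percentile(published_norms, r.sex, r.age, r.score_revised).value
                for r in cohort
                if r.group == g and r.complete
            ]
            manual[g] = summarize_scores(vals)
        for g in ("HC", "PD"):
            assert res.percentile_summaries[g]["revised"] == manual[g]

    def test_missing_norms_skips_percentile_block(self, cohort):
        res = run_bridging(cohort, norms_original=None, norms_revised=None)
        assert res.percentile_summaries is None

    def test_hc_signed_rank_strongly_significant(self, cohort):
        res = run_bridging(cohort)
        assert res.signed_rank["HC"].p_value < 1e-4
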