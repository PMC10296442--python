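"""Task generation, scoring formulas, behavioral score, group tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from alphaloop import (behavioral_score, correlate_score_iaf,
                       friedman_prepost, gen_mr_block, gen_nback_block,
                       group_tests, score_1back, score_3back, score_mr,
                       simulate_responses)
from alphaloop.behavior import TrialRecord, nback_records
from alphaloop.synth import (BEHAVIORAL_METRICS, BehavioralCohortSpec,
                             generate_behavioral_cohort)


def trial(task, target, response=None, rt=None):
    return TrialRecord(task, int(target), bool(target), response, rt)


class TestGenerators:
    def test_mr_exact_match_count_rounds_half_up(self):
        recs = gen_mr_block(15, seed=0)
        assert sum(r.is_target for r in recs) == 8
        assert len(recs) == 15

    def test_mr_all_matched_at_probability_one(self):
        recs = gen_mr_block(15, match_prob=1.0, seed=1)
        assert all(r.is_target for r in recs)

    def test_mr_seed_reproducible(self):
        a = [r.is_target for r in gen_mr_block(15, seed=9)]
        b = [r.is_target for r in gen_mr_block(15, seed=9)]
        assert a == b

    @pytest.mark.parametrize("n,trials", [(1, 28), (3, 30)])
    def test_nback_block_sizes_and_self_consistency(self, n, trials):
        slots, is_target = gen_nback_block(n, trials, seed=4)
        assert slots.shape == (trials,)
        # re-scan the sequence at lag n: flags must reproduce exactly
        rescanned = np.zeros(trials, bool)
        rescanned[n:] = slots[n:] == slots[:-n]
        assert np.array_equal(rescanned, is_target)
        expected = round(trials - n) / 3
        assert is_target.sum() == int(np.floor(expected + 0.5))

    def test_nback_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            gen_nback_block(3, 3, seed=0)

    def test_simulated_responses_attach_consistently(self):
        slots, flags = gen_nback_block(3, 30, seed=2)
        recs = simulate_responses(nback_records(slots, flags, "3back"),
                                  accuracy=1.0, seed=3)
        # perfect accuracy: press exactly on targets
        assert all((r.response == "press") == r.is_target for r in recs)


class TestScoring:
    def test_3back_printed_formula(self):
        # 30 trials, 10 targets, 2 misses, 1 false alarm -> (8 + 19)/30
        recs = (
            [trial("3back", True, "press", 0.5)] * 8 +
            [trial("3back", True)] * 2 +
            [trial("3back", False, "press", 0.5)] * 1 +
            [trial("3back", False)] * 19
        )
        assert score_3back(recs).accuracy == pytest.approx(0.9)

    def test_3back_all_correct(self):
        recs = [trial("3back", True, "press", 0.4)] * 10 + \
               [trial("3back", False)] * 20
        assert score_3back(recs).accuracy == pytest.approx(1.0)

    def test_3back_no_responses_degenerate(self):
        recs = [trial("3back", True)] * 10 + [trial("3back", False)] * 20
        m = score_3back(recs)
        assert m.accuracy == pytest.approx(20 / 30)
        assert m.rt_mean is None and m.reaction_control is None

    def test_3back_oracle_confusion_matrix(self):
        # brute-force confusion-matrix count on 1000 random trial tables
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = rng.integers(5, 40)
            targets = rng.random(n) < 0.3
            pressed = rng.random(n) < 0.4
            recs = [TrialRecord("3back", 0, bool(t), "press" if p else None,
                                0.5 if p else None)
                    for t, p in zip(targets, pressed)]
            tp = np.sum(targets & pressed)
            tn = np.sum(~targets & ~pressed)
            assert score_3back(recs).accuracy == pytest.approx((tp + tn) / n)

    def test_mr_accuracy_and_rt_stats(self):
        recs = [trial("mr", True, "match", 0.5)] * 12 + \
               [trial("mr", True, "mismatch", 0.7)] * 3
        m = score_mr(recs)
        assert m.accuracy == pytest.approx(0.8)
        rts = [0.5] * 12 + [0.7] * 3
        assert m.rt_mean == pytest.approx(np.mean(rts))
        assert m.reaction_control == pytest.approx(np.std(rts, ddof=1))

    def test_reaction_control_is_sample_sd(self):
        recs = [trial("mr", True, "match", 0.5), trial("mr", True, "match", 0.7)]
        m = score_mr(recs)
        assert m.rt_mean == pytest.approx(0.6)
        assert m.reaction_control == pytest.approx(0.14142, abs=1e-4)

    def test_single_response_reaction_control_undefined(self):
        m = score_mr([trial("mr", True, "match", 0.5), trial("mr", False)])
        assert m.reaction_control is None
        assert m.n_responded == 1

    def test_mr_late_response_counts_as_none(self):
        m = score_mr([trial("mr", True, "match", 9.0)])
        assert m.accuracy == 0.0 and m.n_responded == 0

    def test_1back_reports_rt_only(self):
        m = score_1back([trial("1back", True, "press", 0.4),
                         trial("1back", False)])
        assert m.accuracy is None and m.rt_mean == pytest.approx(0.4)


class TestBehavioralScore:
    def _metrics(self, val=1.0):
        return {(t, m): val for t, m, _ in BEHAVIORAL_METRICS}

    def test_all_improved_is_eight(self):
        pre = self._metrics(1.0)
        post = {k: (2.0 if k[1] == "accuracy" else 0.5) for k in pre}
        assert behavioral_score(pre, post) == 8

    def test_identical_is_zero(self):
        assert behavioral_score(self._metrics(), self._metrics()) == 0

    def test_counting_rule_with_ties_and_worsening(self):
        pre = self._metrics(1.0)
        post = dict(pre)
        keys = list(pre)
        directions = {(t, m): d for t, m, d in BEHAVIORAL_METRICS}
        for k in keys[:3]:      # improved
            post[k] = pre[k] + 0.5 * directions[k]
        for k in keys[3:5]:     # tied
            post[k] = pre[k]
        for k in keys[5:]:      # worsened
            post[k] = pre[k] - 0.5 * directions[k]
        assert behavioral_score(pre, post) == 3

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        pre = {k: rng.random() for k in self._metrics()}
        post = {k: rng.random() for k in pre}
        ties = sum(pre[k] == post[k] for k in pre)
        s = behavioral_score(pre, post)
        assert behavioral_score(post, pre) == 8 - s - ties

    def test_mismatched_sets_rejected(self):
        pre = self._metrics()
        bad = dict(pre)
        del bad[("mr", "accuracy")]
        with pytest.raises(ValueError):
            behavioral_score(pre, bad)


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate_score_iaf(x, x * 2)[0] == pytest.approx(1.0)
        assert correlate_score_iaf(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = correlate_score_iaf(np.array([1, 2, 3, 4.0]),
                                     np.array([0.1, 0.3, 0.2, 0.4]))
        assert rho == pytest.approx(0.8)

    def test_oracle_all_permutations_n5(self):
        # exhaustive rank computation: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        x = np.arange(5.0)
        for perm in itertools.permutations(range(5)):
            y = np.array(perm, dtype=float)
            rho, _ = correlate_score_iaf(x + 1, y + 1)  # n >= 4, no ties
            d2 = np.sum((x - y) ** 2)
            assert rho == pytest.approx(1 - 6 * d2 / (5 * 24), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_score_iaf(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            correlate_score_iaf(np.arange(3.0), np.arange(3.0))


class TestGroupTests:
    def test_friedman_two_condition_reduces_to_sign_test(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        post = np.array([2.0, 3.0, 4.0, 3.0, 6.0, 6.0])  # 4 up, 1 down, 1 tie
        q, p = friedman_prepost(pre, post)
        assert q == pytest.approx((4 - 1) ** 2 / 5)
        assert p == pytest.approx(stats.chi2.sf(q, 1))

        def rank_oracle(a, b):
            # tie-corrected midrank Friedman statistic, computed from the
            # general formula (Conover) for k = 2 conditions
            n = a.size
            r1 = np.where(a < b, 1.0, np.where(a > b, 2.0, 1.5))
            r2 = 3.0 - r1
            num = (2 - 1) * ((r1.sum() - n * 1.5) ** 2 + (r2.sum() - n * 1.5) ** 2)
            den = np.sum(r1 ** 2 + r2 ** 2) - n * 2 * 9 / 4
            return 0.0 if den == 0 else num / den

        # exhaustive sign-flip permutations of the toy data: our statistic
        # equals the rank-based oracle on every relabeling
        diffs = post - pre
        for signs in itertools.product([1, -1], repeat=6):
            d = diffs * np.array(signs)
            q_ours, _ = friedman_prepost(pre, pre + d)
            b, c = np.sum(d > 0), np.sum(d < 0)
            q_sign = 0.0 if b + c == 0 else (b - c) ** 2 / (b + c)
            assert q_ours == pytest.approx(q_sign)
            assert q_ours == pytest.approx(rank_oracle(pre, pre + d))

    def test_friedman_no_untied_pairs(self):
        assert friedman_prepost(np.ones(4), np.ones(4)) == (0.0, 1.0)

    def _cohort(self, seed, deltas):
        spec = BehavioralCohortSpec(n_subjects=len(deltas), rng_seed=seed)
        return generate_behavioral_cohort(spec, np.asarray(deltas))

    def test_identical_arms_have_null_baseline_difference(self):
        t = self._cohort(0, np.zeros(8))
        res = group_tests({"NF": t, "Sham": t.copy()})
        assert (res["mannwhitney_p"] > 0.9).all()

    def test_programmed_improvement_detected_in_one_arm_only(self):
        improved = self._cohort(1, np.full(16, 2.0))     # strong coupling
        null = self._cohort(2, np.full(16, 0.0))
        null_frozen = null.copy()
        null_frozen["post"] = null_frozen["pre"]          # no change at all
        res = group_tests({"NF": improved, "Sham": null_frozen})
        assert (res["friedman_p_NF"] < 0.05).all()
        assert (res["friedman_p_Sham"] == 1.0).all()

    def test_insufficient_subjects_rejected(self):
        t = self._cohort(3, np.zeros(2))
        single = t[t.subject == 0]
        with pytest.raises(ValueError):
            group_tests({"NF": single, "Sham": t})
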