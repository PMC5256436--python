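"""Identification procedures: showup, simultaneous rules, sequential
stopping rules, 2AFC."""

import numpy as np
import pytest
from scipy import stats

from lineuproc import (
    CriterionSet,
    DecisionRule,
    EvidenceModel,
    TrialPool,
    analytic_2afc_roc_points,
    default_sweep,
    record_trial,
    response_thresholds,
    run_2afc,
    run_sequential,
    run_showup,
    run_simultaneous,
    shared_size_pools,
    two_afc_auc,
)


def binomial_se(p: float, n: int) -> float:
    return np.sqrt(p * (1 - p) / n)


class TestShowup:
    def test_operating_point_at_criterion_one(self, model15, pool1):
        # (F, H) = (Phi(-1), Phi(0.5)) at c = 1, d' = 1.5, equal variance
        rt = run_showup(model15, [1.0], pool=pool1)
        f_true, h_true = stats.norm.cdf(-1.0), stats.norm.cdf(0.5)
        assert abs(rt.table["H"].iloc[0] - h_true) < 4 * binomial_se(h_true, 10_000)
        assert abs(rt.table["F"].iloc[0] - f_true) < 4 * binomial_se(f_true, 10_000)

    def test_zero_dprime_hit_equals_false_alarm(self):
        rt = run_showup(EvidenceModel(0.0), [0.0], 10_000, rng=8)
        h, f = rt.table["H"].iloc[0], rt.table["F"].iloc[0]
        assert abs(h - f) < 4 * np.sqrt(2 * 0.25 / 10_000)

    def test_extreme_criterion_kills_all_responses(self, model15, pool1):
        rt = run_showup(model15, [50.0], pool=pool1)
        assert rt.table["H"].iloc[0] == 0.0
        assert rt.table["F"].iloc[0] == 0.0

    def test_matches_closed_form_across_sweep(self, model15, pool1):
        # the empirical showup ROC converges on H = Phi((d'-c)/sigma),
        # F = Phi(-c) at every criterion
        crit = np.linspace(-1.5, 3.0, 10)
        rt = run_showup(model15, crit, pool=pool1)
        for c, h, f in zip(crit, rt.table["H"], rt.table["F"]):
            ht = model15.showup_hit_rate(c)
            ft = model15.showup_false_alarm_rate(c)
            assert abs(h - ht) <= 4 * binomial_se(ht, 10_000)
            assert abs(f - ft) <= 4 * binomial_se(ft, 10_000)


class TestSimultaneous:
    def test_liberal_limit_false_alarm_is_one_over_n(self, model15, pool6):
        # with the criterion below every sample, every TA lineup draws an
        # identification and the innocent-suspect rate is exactly 1/N
        rt = run_simultaneous(model15, 6, [-50.0], pool=pool6)
        assert rt.table["F"].iloc[0] == pytest.approx(1 / 6)
        assert rt.table["rejection_rate_ta"].iloc[0] == 0.0

    def test_zero_delta_relative_equals_absolute(self, model15, pool6):
        sweep = default_sweep(model15)
        abs_rt = run_simultaneous(model15, 6, sweep, pool=pool6)
        rel_rt = run_simultaneous(model15, 6, sweep, pool=pool6,
                                  rule=DecisionRule("relative_reject", 0.0))
        assert np.array_equal(abs_rt.table["H"], rel_rt.table["H"])
        assert np.array_equal(abs_rt.table["F"], rel_rt.table["F"])

    def test_guess_rule_dominates_reject_rule(self, model15, pool6):
        # guessing only ever adds identifications, never removes them
        sweep = default_sweep(model15)
        reject = run_simultaneous(model15, 6, sweep, pool=pool6,
                                  rule=DecisionRule("relative_reject", 0.15))
        guess = run_simultaneous(model15, 6, sweep, pool=pool6,
                                 rule=DecisionRule("relative_guess", 0.15), rng=3)
        assert (guess.table["H"].to_numpy() >= reject.table["H"].to_numpy()).all()
        assert (guess.table["F"].to_numpy() >= reject.table["F"].to_numpy()).all()

    def test_relative_rules_look_more_conservative(self, model15, pool6):
        sweep = default_sweep(model15)
        absolute = run_simultaneous(model15, 6, sweep, pool=pool6)
        reject = run_simultaneous(model15, 6, sweep, pool=pool6,
                                  rule=DecisionRule("relative_reject", 0.15))
        assert (reject.table["H"].to_numpy() <= absolute.table["H"].to_numpy()).all()
        assert (reject.table["F"].to_numpy() <= absolute.table["F"].to_numpy()).all()

    def test_size_one_delegates_to_showup(self, model15):
        pool = TrialPool.sample(model15, 1, 2000, 2000, 9)
        a = run_simultaneous(model15, 1, [0.5], pool=pool)
        b = run_showup(model15, [0.5], pool=pool)
        assert a.table["H"].iloc[0] == b.table["H"].iloc[0]
        assert a.table["F"].iloc[0] == b.table["F"].iloc[0]

    def test_lineup_size_reduces_both_rates(self, model15):
        # on the very same evidence, more photos means lower H and F
        pools = shared_size_pools(model15, (1, 2, 3, 6), 10_000, 10_000,
                                  np.random.default_rng(10))
        rates = {}
        for n, pool in pools.items():
            rt = run_simultaneous(model15, n, [1.0], pool=pool)
            rates[n] = (rt.table["H"].iloc[0], rt.table["F"].iloc[0])
        slack = 3 * np.sqrt(0.25 / 10_000)
        for small, big in [(1, 2), (2, 3), (3, 6)]:
            assert rates[big][0] <= rates[small][0] + slack
            assert rates[big][1] <= rates[small][1] + slack

    def test_ta_conventions_agree_in_expectation(self, model15, pool6):
        # filler positions are exchangeable, so dividing the any-ID rate by
        # N matches designating one innocent-suspect position
        crit = np.array([0.18, 0.67, 1.15])
        div = run_simultaneous(model15, 6, crit, pool=pool6)
        des = run_simultaneous(model15, 6, crit, pool=pool6,
                               ta_convention="designated_innocent")
        for f1, f2 in zip(div.table["F"], des.table["F"]):
            assert abs(f1 - f2) < 4 * binomial_se(max(f1, 1e-3), 10_000)

    def test_category_rates_sum_to_one(self, model15, pool6):
        sweep = default_sweep(model15)
        for rule in ("absolute", "relative_reject", "relative_guess"):
            rt = run_simultaneous(model15, 6, sweep, pool=pool6,
                                  rule=DecisionRule(rule), rng=0)
            tab = rt.table
            tp_sum = tab["H"] + tab["filler_id_rate_tp"] + tab["rejection_rate_tp"]
            ta_sum = tab["F"] + tab["filler_id_rate_ta"] + tab["rejection_rate_ta"]
            assert np.allclose(tp_sum, 1.0)
            assert np.allclose(ta_sum, 1.0)

    @pytest.mark.parametrize("rule", ["absolute", "relative_reject",
                                      "relative_guess"])
    def test_rates_monotone_in_criterion_exactly(self, model15, pool6, rule):
        # common random numbers across the sweep make H and F exactly
        # non-increasing as the criterion rises
        sweep = default_sweep(model15)
        rt = run_simultaneous(model15, 6, sweep, pool=pool6,
                              rule=DecisionRule(rule), rng=1)
        assert (np.diff(rt.table["H"]) <= 0).all()
        assert (np.diff(rt.table["F"]) <= 0).all()


class TestSequential:
    def test_first_id_chance_limit(self, model15, pool6):
        # any criterion below all samples: the hit rate is the probability
        # the guilty suspect comes first in the sequence, 1/6
        rt = run_sequential(model15, 6, [-10.0], variant="first_id",
                            rng=2, pool=pool6)
        h = rt.table["H"].iloc[0]
        assert abs(h - 1 / 6) < 4 * binomial_se(1 / 6, 10_000)

    def test_first_id_hit_rate_nonmonotone(self, model15, pool6):
        sweep = default_sweep(model15)
        rt = run_sequential(model15, 6, sweep, variant="first_id",
                            rng=2, pool=pool6)
        h = rt.table["H"].to_numpy()[::-1]  # liberal -> conservative
        # the interior maximum clearly exceeds the liberal-limit hit rate
        assert h.max() > h[0] + 0.1
        assert np.argmax(h) > 0

    def test_any_id_equals_absolute_simultaneous(self, model15, pool6):
        # dual-route check: the flag-then-keep-strongest sequential process
        # must reproduce the absolute simultaneous outcome on shared samples
        sweep = default_sweep(model15)
        seq = run_sequential(model15, 6, sweep, variant="any_id",
                             rng=4, pool=pool6)
        sim = run_simultaneous(model15, 6, sweep, pool=pool6)
        for col in ("H", "F", "filler_id_rate_tp", "rejection_rate_tp",
                    "filler_id_rate_ta", "rejection_rate_ta"):
            assert np.array_equal(seq.table[col], sim.table[col]), col

    def test_conservative_limit(self, model15, pool6):
        rt = run_sequential(model15, 6, [50.0], variant="first_id",
                            rng=2, pool=pool6)
        assert rt.table["H"].iloc[0] == 0.0
        assert rt.table["F"].iloc[0] == 0.0

    def test_first_id_has_no_threshold_form(self, pool6):
        with pytest.raises(ValueError):
            response_thresholds(pool6, procedure="sequential_first_id")


class TestTwoAFC:
    def test_auc_estimate_matches_area_theorem(self, model15):
        rt = run_2afc(model15, n_trials=10_000, rng=5)
        expected = two_afc_auc(model15)
        assert expected == pytest.approx(stats.norm.cdf(1.5 / np.sqrt(2)))
        assert abs(rt.meta["auc_estimate"] - expected) < 4 * binomial_se(expected, 10_000)

    def test_zero_dprime_is_chance(self):
        rt = run_2afc(EvidenceModel(0.0), n_trials=10_000, rng=6)
        assert abs(rt.meta["auc_estimate"] - 0.5) < 4 * binomial_se(0.5, 10_000)

    def test_simulated_curve_matches_analytic(self, model15):
        crit = np.linspace(-3.0, 4.0, 21)
        rt = run_2afc(model15, crit, n_trials=10_000, rng=7)
        sd = np.hypot(1.0, 1.0)
        h_true = stats.norm.cdf((1.5 - crit) / sd)
        f_true = stats.norm.cdf((-1.5 - crit) / sd)
        assert np.all(np.abs(rt.table["H"] - h_true)
                      <= 4 * binomial_se(0.5, 10_000))
        assert np.all(np.abs(rt.table["F"] - f_true)
                      <= 4 * binomial_se(0.5, 10_000))
        # and the closed-form curve is internally consistent
        pts = analytic_2afc_roc_points(model15, np.linspace(0.01, 0.99, 50))
        z = stats.norm.ppf
        assert np.allclose(z(pts["H"]) - z(pts["F"]), 2 * 1.5 / sd)


class TestRecordTrial:
    def test_absolute_rule_record(self):
        cs = CriterionSet.lampinen()
        rec = record_trial("TP", [0.1, 1.0, -0.5], 1, cs)
        assert rec.response == "suspect_id"
        assert rec.confidence == 6
        assert rec.chosen_position == 1

    def test_rejection_record(self):
        cs = CriterionSet.lampinen()
        rec = record_trial("TA", [0.1, 0.0, -0.5], None, cs)
        assert rec.response == "rejection"
        assert rec.confidence == 0
        assert rec.chosen_position is None

    def test_relative_rule_can_reject_strong_lineups(self):
        cs = CriterionSet.lampinen()
        rec = record_trial("TP", [1.0, 0.95], 0, cs,
                           rule=DecisionRule("relative_reject", 0.15))
        assert rec.response == "rejection"
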