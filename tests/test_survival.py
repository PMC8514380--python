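"""Kaplan-Meier, log-rank, Cox models, subgroups, characteristics table."""

import numpy as np
import pytest

from conftest import make_record, random_survival_cohort
from oracles import km_step, logrank_two_group
from tp53sig import (
    characteristics_table,
    cox_fit,
    kaplan_meier,
    log_rank,
    run_table3,
    subgroup_rfs,
)
from tp53sig.errors import (
    DegenerateGroupingError,
    InvalidInputError,
)


def simple_cohort(times, events, group=None):
    recs = []
    for i, (t, e) in enumerate(zip(times, events)):
        status = group[i] if group else "wild"
        recs.append(make_record(sample_id=f"S{i}", tp53_status=status,
                                rfs_time=t, rfs_event=e,
                                os_time=t, os_event=0))
    return recs


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        curves = kaplan_meier(simple_cohort([1, 2, 3], [1, 1, 1]), "rfs")
        c = curves["all"]
        assert list(c.times) == [1, 2, 3]
        assert c.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(c.at_risk) == [3, 2, 1]

    def test_all_censored_curve_stays_at_one(self):
        curves = kaplan_meier(simple_cohort([1, 2, 3], [0, 0, 0]), "rfs")
        c = curves["all"]
        assert len(c.times) == 0
        assert len(c.censor_marks) == 3

    def test_curve_is_nonincreasing_and_bounded(self, rng):
        recs = random_survival_cohort(rng, 40)
        for c in kaplan_meier(recs, "rfs", "tp53_status").values():
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert np.all((c.survival >= 0) & (c.survival <= 1))

    def test_matches_brute_force_product_limit(self, rng):
        """Estimator equals an explicit product over risk sets, many cohorts."""
        for _ in range(25):
            n = int(rng.integers(2, 51))
            recs = random_survival_cohort(rng, n, two_group=False)
            curve = kaplan_meier(recs, "rfs")["all"]
            t_or, s_or = km_step([r.rfs_time for r in recs],
                                 [r.rfs_event for r in recs])
            assert np.allclose(curve.times, t_or)
            assert np.allclose(curve.survival, s_or)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            make_record(rfs_time=-1.0)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4]
        events = [1, 1, 0, 1]
        recs = (simple_cohort(times, events, ["wild"] * 4)
                + [make_record(sample_id=f"M{i}", tp53_status="mutant",
                               rfs_time=t, rfs_event=e, os_time=t, os_event=0)
                   for i, (t, e) in enumerate(zip(times, events))])
        res = log_rank(recs, "rfs", "tp53_status")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_six_subject_hand_oracle(self):
        t1, e1 = [1.0, 3.0, 5.0], [1, 1, 0]
        t2, e2 = [2.0, 4.0, 6.0], [1, 0, 1]
        recs = (simple_cohort(t1, e1, ["wild"] * 3)
                + [make_record(sample_id=f"M{i}", tp53_status="mutant",
                               rfs_time=t, rfs_event=e, os_time=t, os_event=0)
                   for i, (t, e) in enumerate(zip(t2, e2))])
        res = log_rank(recs, "rfs", "tp53_status")
        assert res.statistic == pytest.approx(logrank_two_group(t1, e1, t2, e2))

    def test_matches_oracle_on_random_cohorts(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 51))
            recs = random_survival_cohort(rng, n)
            groups = {r.tp53_status for r in recs}
            if len(groups) < 2:
                continue
            res = log_rank(recs, "rfs", "tp53_status")
            w = [(r.rfs_time, r.rfs_event) for r in recs if r.tp53_status == "wild"]
            m = [(r.rfs_time, r.rfs_event) for r in recs if r.tp53_status == "mutant"]
            expected = logrank_two_group([x[0] for x in w], [x[1] for x in w],
                                         [x[0] for x in m], [x[1] for x in m])
            assert res.statistic == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_relabeling_invariance(self, rng):
        recs = random_survival_cohort(rng, 30)
        res1 = log_rank(recs, "rfs", "tp53_status")
        res2 = log_rank(recs, "rfs",
                        lambda r: "B" if r.tp53_status == "wild" else "A")
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_single_group_rejected(self):
        recs = simple_cohort([1, 2], [1, 1])
        with pytest.raises(DegenerateGroupingError):
            log_rank(recs, "rfs", "tp53_status")


class TestCoxFit:
    def test_three_subject_analytic_solution(self):
        """Events at t=1 (z=1) and t=2 (z=0) with a third subject (z=1,
        event t=3): the partial likelihood u/((2u+1)(1+u)), u = exp(beta),
        is maximised at u = 1/sqrt(2)."""
        recs = [
            make_record(sample_id="A", tp53_status="mutant",
                        rfs_time=1.0, rfs_event=1, os_time=1.0, os_event=0),
            make_record(sample_id="B", tp53_status="wild",
                        rfs_time=2.0, rfs_event=1, os_time=2.0, os_event=0),
            make_record(sample_id="C", tp53_status="mutant",
                        rfs_time=3.0, rfs_event=1, os_time=3.0, os_event=0),
        ]
        fit = cox_fit(recs, "rfs", ["tp53_status"], "univariate")
        assert fit.rows[0].hazard_ratio == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_ci_brackets_hazard_ratio(self, rng):
        recs = random_survival_cohort(rng, 60)
        fit = cox_fit(recs, "rfs", ["tp53_status"], "univariate")
        row = fit.rows[0]
        assert 0 < row.ci_low <= row.hazard_ratio <= row.ci_high

    def test_null_covariate_ci_covers_one(self, rng):
        """Coverage: with no true effect the 95% CI contains 1 in >= 93%
        of replicates (moderate n keeps this quick)."""
        covered = 0
        n_rep = 60
        for _ in range(n_rep):
            recs = random_survival_cohort(rng, 120)
            if len({r.tp53_status for r in recs}) < 2:
                covered += 1
                continue
            row = cox_fit(recs, "rfs", ["tp53_status"], "univariate").rows[0]
            covered += row.ci_low <= 1.0 <= row.ci_high
        assert covered / n_rep >= 0.90

    def test_single_level_variable_rejected(self):
        recs = simple_cohort([1, 2, 3], [1, 1, 0])
        with pytest.raises(DegenerateGroupingError):
            cox_fit(recs, "rfs", ["tp53_status"], "univariate")

    def test_no_events_rejected(self):
        recs = simple_cohort([1, 2], [0, 0], ["wild", "mutant"])
        with pytest.raises(InvalidInputError):
            cox_fit(recs, "rfs", ["tp53_status"], "univariate")

    def test_unknown_variable_rejected(self, rng):
        recs = random_survival_cohort(rng, 10)
        with pytest.raises(InvalidInputError, match="unknown"):
            cox_fit(recs, "rfs", ["height"], "univariate")

    def test_incomplete_cases_excluded_and_counted(self, rng):
        recs = random_survival_cohort(rng, 40)
        recs[0] = make_record(sample_id="NA1", grade=None, tp53_status="mutant",
                              rfs_time=1.0, rfs_event=1, os_time=1.0, os_event=0)
        fit = cox_fit(recs, "rfs", ["grade", "tp53_status"], "multivariate")
        assert fit.n_excluded == 1
        assert fit.n_used == 39


class TestRunTable3:
    def test_no_significant_univariate_skips_multivariate(self, rng, caplog):
        # tiny cohort with few events: nothing reaches p <= 0.05
        recs = []
        for i in range(24):
            recs.append(make_record(
                sample_id=f"S{i}",
                tp53_status="mutant" if i % 2 else "wild",
                p_stage="IIA" if i % 3 == 0 else "I",
                p_ln="positive" if i % 4 == 0 else "negative",
                er="negative" if i % 5 == 0 else "positive",
                pgr="negative" if i % 5 == 1 else "positive",
                her2="positive" if i % 6 == 0 else "negative",
                grade=(i % 3) + 1,
                ki67_pct=float(5 + (i % 4) * 4),
                tumor_size_cm=1.0 + (i % 3),
                adj_chemo="yes" if i % 2 else "no",
                adj_endocrine="no" if i % 2 else "yes",
                rfs_time=float(1 + (i % 7)), rfs_event=int(i in (3, 10)),
                os_time=float(1 + (i % 7)), os_event=0))
        rep = run_table3(recs, "rfs", entry_p=1e-6)
        assert rep["selected"] == []
        assert rep["multivariate"] is None
        assert len(rep["univariate"]) == 11

    def test_degenerate_tp53_level_raises(self):
        recs = simple_cohort([1, 2, 3, 4], [1, 1, 0, 1])
        with pytest.raises(DegenerateGroupingError):
            run_table3(recs, "rfs")

    def test_multivariate_only_over_univariately_selected(self, rng):
        from tp53sig import SimulationConfig, simulate_clinical
        from tp53sig.simulate import _draw_labels
        cfg = SimulationConfig(seed=7)
        recs = simulate_clinical(_draw_labels(cfg), cfg)
        rep = run_table3(recs, "rfs")
        uni_selected = {f.rows[0].variable for f in rep["univariate"]
                        if f.rows[0].p_value <= rep["entry_p"]}
        assert set(rep["selected"]) == uni_selected
        if rep["multivariate"] is not None:
            assert {r.variable for r in rep["multivariate"].rows} == uni_selected


class TestSubgroups:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(er="positive", ki67_pct=8.0), "LuminalA"),
        (dict(er="positive", ki67_pct=10.0), "LuminalB"),   # boundary goes high
        (dict(er="negative", pgr="negative", her2="negative"), "TNBC"),
        (dict(er="positive", ki67_pct=None), None),         # needs Ki-67
    ])
    def test_subtype_definitions(self, kwargs, expected):
        assert make_record(**kwargs).subtype == expected

    def test_report_covers_all_subgroups(self, rng):
        from tp53sig import SimulationConfig, simulate_clinical
        from tp53sig.simulate import _draw_labels
        cfg = SimulationConfig(seed=3)
        recs = simulate_clinical(_draw_labels(cfg), cfg)
        rep = subgroup_rfs(recs)
        assert set(rep) == {"ER-positive", "ER-negative", "LuminalA-like",
                            "LuminalB-like", "TNBC", "Grade1", "Grade2", "Grade3"}
        for entry in rep.values():
            assert ("log_rank" in entry) or ("skipped" in entry)

    def test_empty_subgroup_skipped_with_notice(self):
        recs = [make_record(sample_id=f"S{i}", er="positive", ki67_pct=20.0,
                            grade=2) for i in range(5)]
        rep = subgroup_rfs(recs)
        assert rep["TNBC"]["skipped"] == "empty subgroup"
        assert rep["Grade1"]["skipped"] == "empty subgroup"

    def test_single_class_subgroup_reports_condition(self):
        recs = [make_record(sample_id=f"S{i}", tp53_status="wild",
                            rfs_time=2.0, rfs_event=1, os_time=2.0)
                for i in range(4)]
        rep = subgroup_rfs(recs)
        assert "single TP53 class" in rep["ER-positive"]["skipped"]


class TestCharacteristics:
    def _two_group(self, counts_a, counts_b, var="er"):
        """counts per (group, level) for a 2x2 layout."""
        recs = []
        i = 0
        for status, (n_pos, n_neg) in (("mutant", counts_a), ("wild", counts_b)):
            for _ in range(n_pos):
                recs.append(make_record(sample_id=f"S{i}", tp53_status=status,
                                        **{var: "positive"})); i += 1
            for _ in range(n_neg):
                recs.append(make_record(sample_id=f"S{i}", tp53_status=status,
                                        **{var: "negative"})); i += 1
        return recs

    def test_hand_computed_chi_squared(self):
        """[[20,10],[10,20]] has sum (O-E)^2/E = 6.667 on 1 df."""
        recs = self._two_group((20, 10), (10, 20))
        out = characteristics_table(recs)
        assert out["er"]["statistic"] == pytest.approx(20 / 3, rel=1e-6)
        assert out["er"]["df"] == 1

    def test_identical_distributions_give_null_result(self):
        recs = self._two_group((10, 10), (10, 10))
        out = characteristics_table(recs)
        assert out["er"]["statistic"] == pytest.approx(0.0)
        assert out["er"]["p_value"] == pytest.approx(1.0)

    def test_identical_ages_give_zero_kruskal_wallis(self):
        recs = []
        for i, status in enumerate(["mutant"] * 3 + ["wild"] * 3):
            recs.append(make_record(sample_id=f"S{i}", tp53_status=status,
                                    age=[50.0, 60.0, 70.0][i % 3]))
        out = characteristics_table(recs)
        assert out["age"]["statistic"] == pytest.approx(0.0)

    def test_na_counts_reported_but_excluded_from_test(self):
        recs = self._two_group((5, 5), (5, 5))
        recs.append(make_record(sample_id="NA1", tp53_status="mutant", grade=None))
        out = characteristics_table(recs)
        assert out["grade"]["n_missing"]["mutant"] == 1
        assert int(out["grade"]["counts"].to_numpy().sum()) == 20

    def test_single_group_rejected(self):
        recs = [make_record(sample_id=f"S{i}") for i in range(4)]
        with pytest.raises(DegenerateGroupingError):
            characteristics_table(recs)
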