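"""Group comparisons, frequency tables, detector evaluation, and the random-responder oracle."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from assistqc.analysis import (
    CHECK_LABELS,
    FAMILY_LABELS,
    compare_groups,
    detection_performance,
    format_p,
    inconsistency_table,
    per_type_descriptives,
    random_flag_oracle,
    records_frame,
    summary_ttest,
)
from assistqc.consistency import (
    CheckFamily,
    CheckId,
    CheckResult,
    ConsistencyReport,
    RuleConfig,
)
from assistqc.pipeline import run_flow
from assistqc.simulator import CohortDataset, PopulationSpec, generate_cohort


def _report(pid, fired_checks, decision=None):
    results = tuple(CheckResult(c, c in fired_checks) for c in CheckId)
    if decision is None:
        decision = "screened_out" if fired_checks else "screened_in"
    return ConsistencyReport(pid, results, decision)


def _moment_matched(mean, sd, n, rng):
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return x * sd + mean


class TestSummaryTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        t, p = summary_ttest(10.0, 2.0, 50, 10.0, 2.0, 50)
        assert t == 0.0
        assert p == 1.0

    def test_published_age_cells_are_highly_significant(self):
        t, p = summary_ttest(39.5, 13.9, 626, 35.7, 12.9, 755)
        assert p < 0.001
        assert t > 0

    def test_agrees_with_raw_data_welch_t(self):
        rng = np.random.default_rng(0)
        a = _moment_matched(39.5, 13.9, 626, rng)
        b = _moment_matched(35.7, 12.9, 755, rng)
        t_summary, p_summary = summary_ttest(39.5, 13.9, 626, 35.7, 12.9, 755)
        raw = stats.ttest_ind(a, b, equal_var=False)
        assert abs(t_summary - raw.statistic) < 1e-9
        assert abs(p_summary - raw.pvalue) < 1e-9

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            summary_ttest(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            summary_ttest(1, 1.0, 1, 2, 1.0, 10)


class TestCompareGroups:
    def test_equal_proportions_give_chi_square_zero(self):
        a = pd.DataFrame({"flag": [True] * 30 + [False] * 30})
        b = pd.DataFrame({"flag": [True] * 50 + [False] * 50})
        (row,) = compare_groups(a, b, [("flag", "categorical")])
        assert row.statistic == 0.0
        assert row.p_value == 1.0

    def test_income_proportions_replicate_printed_significance(self):
        """2x2 chi-square without continuity correction on the published
        income-by-group counts lands right at the printed p = 0.047."""
        out = pd.DataFrame({"income_low": [True] * 365 + [False] * (626 - 365)})
        kept = pd.DataFrame({"income_low": [True] * 400 + [False] * (755 - 400)})
        (row,) = compare_groups(out, kept, [("income_low", "categorical")])
        assert round(row.p_value, 3) == 0.047

    def test_zero_variance_flagged_not_tested(self):
        a = pd.DataFrame({"x": [5.0] * 10})
        b = pd.DataFrame({"x": [5.0] * 12})
        (row,) = compare_groups(a, b, [("x", "continuous")])
        assert row.statistic is None
        assert "zero variance" in row.note

    def test_empty_group_rejected(self):
        a = pd.DataFrame({"x": [1.0]})
        with pytest.raises(ValueError):
            compare_groups(a, a.iloc[0:0], [("x", "continuous")])

    def test_type_one_error_close_to_nominal(self):
        """Under the null (both groups from one distribution), about 5% of
        replicates reject at alpha = 0.05."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = pd.DataFrame({"x": rng.normal(size=120)})
            b = pd.DataFrame({"x": rng.normal(size=120)})
            (row,) = compare_groups(a, b, [("x", "continuous")])
            rejections += row.p_value < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.025


def test_format_p_floors_tiny_values():
    assert format_p(0.0004) == "< 0.001"
    assert format_p(0.047) == "0.047"
    assert format_p(None) == "NA"


class TestInconsistencyTable:
    def test_counts_and_percentages(self):
        reports = [_report(f"p{i}", {CheckId.ITEM4_TO_NEVER}) for i in range(10)]
        reports += [_report(f"q{i}", set()) for i in range(40)]
        reports += [_report(f"r{i}", {CheckId.TOTAL_BELOW_MIN}) for i in range(40)]
        table = inconsistency_table(reports)
        row = table[table["check"] == "ITEM4_TO_NEVER"].iloc[0]
        assert row["count"] == 10
        assert row["pct"] == 20.0  # 10 of 50 screened out

    def test_family_any_rows_are_unions_not_sums(self):
        both = [_report(f"p{i}", {CheckId.ITEM3_TO_NEVER, CheckId.ITEM4_TO_NEVER})
                for i in range(20)]
        table = inconsistency_table(both)
        fam = table[table["check"] == "ANY_ITEM_REGRESSION"].iloc[0]
        assert fam["count"] == 20  # not 40
        members = table[
            (table["family"] == "item_regression")
            & (~table["check"].str.startswith("ANY"))
        ]
        assert fam["count"] <= members["count"].sum()

    def test_union_bound_on_simulated_cohorts(self, instrument):
        cohort = generate_cohort(PopulationSpec(n=300, seed=77), instrument)
        reports, _ = run_flow(cohort.records, instrument)
        table = inconsistency_table(reports)
        for family in CheckFamily:
            fam_row = table[table["check"] == f"ANY_{family.value.upper()}"].iloc[0]
            members = table[
                (table["family"] == family.value)
                & (~table["check"].str.startswith("ANY"))
            ]
            assert fam_row["count"] <= members["count"].sum()

    def test_replaying_printed_any_item_count_gives_its_percentage(self):
        """613 item-level-change cases among 626 screened out -> 97.9%."""
        reports = [_report(f"a{i}", {CheckId.ITEM5_TO_NEVER}) for i in range(613)]
        reports += [
            _report(f"b{i}", {CheckId.TOTAL_DELTA_GT10}) for i in range(626 - 613)
        ]
        table = inconsistency_table(reports)
        fam = table[table["check"] == "ANY_ITEM_REGRESSION"].iloc[0]
        assert fam["count"] == 613
        assert fam["pct"] == 97.9


class TestPerTypeDescriptives:
    def test_overlapping_membership(self, instrument):
        cohort = generate_cohort(PopulationSpec(n=400, seed=5), instrument)
        reports, _ = run_flow(cohort.records, instrument)
        table = per_type_descriptives(cohort.records, reports, instrument)
        n_out = sum(r.screened_out for r in reports)
        n_cols = sum(table[col]["n"] for col in table.columns)
        multi = sum(len(r.families_fired) > 1 for r in reports if r.screened_out)
        assert multi > 0  # the cohort does produce multi-family cases
        assert n_cols == n_out + sum(
            len(r.families_fired) - 1 for r in reports if r.screened_out
        )

    def test_no_screened_out_gives_empty_columns(self, instrument):
        cohort = generate_cohort(
            PopulationSpec(n=40, seed=6, mixture={"faithful": 1.0}, p_agree=1.0),
            instrument,
        )
        reports, _ = run_flow(cohort.records, instrument)
        table = per_type_descriptives(cohort.records, reports, instrument)
        assert all(table[col]["n"] == 0 for col in table.columns)


class TestDetectionPerformance:
    def test_noiseless_faithful_cohort_has_perfect_specificity(self, instrument):
        cohort = generate_cohort(
            PopulationSpec(
                n=100, seed=8, mixture={"faithful": 1.0}, p_agree=1.0,
                consent_rate=1.0, duplicate_rate=0.0, withdraw_rate=0.0,
                baseline_completion_rate=1.0, underage_rate=0.0, never_used_rate=0.0,
            ),
            instrument,
        )
        reports, _ = run_flow(cohort.records, instrument)
        perf = detection_performance(cohort, reports)
        assert perf.specificity == 1.0
        assert perf.sensitivity is None  # nobody is truly invalid

    def test_straightliners_are_never_caught(self, instrument):
        cohort = generate_cohort(
            PopulationSpec(
                n=100, seed=9, mixture={"straightliner": 1.0},
                consent_rate=1.0, duplicate_rate=0.0, withdraw_rate=0.0,
                baseline_completion_rate=1.0, underage_rate=0.0, never_used_rate=0.0,
            ),
            instrument,
        )
        reports, _ = run_flow(cohort.records, instrument)
        assert len(reports) > 0
        perf = detection_performance(cohort, reports)
        assert perf.sensitivity == 0.0  # the blind spot, quantified

    def test_missing_truth_label_is_a_join_error(self, instrument):
        cohort = generate_cohort(PopulationSpec(n=20, seed=10), instrument)
        reports, _ = run_flow(cohort.records, instrument)
        cohort.truth.clear()
        if reports:
            with pytest.raises(KeyError):
                detection_performance(cohort, reports)


class TestRandomFlagOracle:
    def test_exhaustive_matches_monte_carlo_within_sampling_error(
        self, reduced_instrument
    ):
        exact = random_flag_oracle(reduced_instrument, "exhaustive")
        mc = random_flag_oracle(
            reduced_instrument, "monte_carlo", n_draws=20_000, seed=3
        )
        assert exact.se == 0.0
        assert abs(mc.probability - exact.probability) < 3 * mc.se

    def test_monte_carlo_reproducible_under_fixed_seed(self, reduced_instrument):
        a = random_flag_oracle(reduced_instrument, "monte_carlo", n_draws=2000, seed=4)
        b = random_flag_oracle(reduced_instrument, "monte_carlo", n_draws=2000, seed=4)
        assert a.probability == b.probability

    def test_full_instrument_too_large_for_exhaustive(self, instrument):
        with pytest.raises(ValueError):
            random_flag_oracle(instrument, "exhaustive")

    def test_below_min_alone_has_closed_form_probability(self, reduced_instrument):
        """With the delta bound beyond the attainable range and every other
        check disabled, the flag probability is P(baseline total < 4) =
        3/25 under uniform baselines (item 5 at Never, item 2 scoring < 4)."""
        rules = RuleConfig(
            delta_bound=100,
            enabled=frozenset({CheckId.TOTAL_BELOW_MIN}),
        )
        est = random_flag_oracle(reduced_instrument, "exhaustive", rules)
        assert est.probability == pytest.approx(3 / 25)


def test_records_frame_joins_reports(instrument):
    cohort = generate_cohort(PopulationSpec(n=50, seed=12), instrument)
    reports, _ = run_flow(cohort.records, instrument)
    frame = records_frame(cohort.records, instrument, reports)
    assert len(frame) == 50
    assessed = frame[frame["decision"].notna()]
    assert len(assessed) == len(reports)
    assert set(CHECK_LABELS) == set(CheckId)
    assert set(FAMILY_LABELS) == set(CheckFamily)
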