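"""The 11-check consistency rule engine for screener/baseline response pairs.

A participant answers the ASSIST cannabis subscale twice: once at eligibility
screening and again at the start of the baseline interview.  The engine
compares the two administrations and fires atomic checks in three families:

* ``total_score`` (2 checks): the baseline total dropped below the moderate-
  risk eligibility floor of 4, or the total moved by more than 10 points in
  either direction.
* ``item_regression`` (5 checks): an item among 3-7 that was endorsed at
  screening (anything other than "Never"/"No, never") reverted to the never
  option at baseline.
* ``usage_report`` (4 checks): the baseline denies cannabis use outright —
  item 2 answered "Never", the weekly-pattern probe's non-use option, zero
  times per day on both weekdays and weekends, or the hours-after-waking
  probe's non-use option.

A participant is screened out when at least ``decision_threshold`` checks
fire (default 1: any single inconsistency excludes).  The engine always
evaluates every applicable check — no short-circuiting — because the per-check
frequency accounting downstream needs the complete fired set.
"""
from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .instrument import (
    AssistResponse,
    InstrumentDefinition,
    InstrumentError,
    UnknownOptionError,
    total_score,
)

__all__ = [
    "CheckId",
    "CheckFamily",
    "CHECK_FAMILIES",
    "ITEM_REGRESSION_CHECKS",
    "CheckResult",
    "ConsistencyReport",
    "RuleConfig",
    "UsageAnswers",
    "check_total_below_min",
    "check_total_delta",
    "check_item_regression",
    "check_usage_report",
    "evaluate_pair",
    "count_distribution",
]


class CheckFamily(str, enum.Enum):
    TOTAL_SCORE = "total_score"
    ITEM_REGRESSION = "item_regression"
    USAGE_REPORT = "usage_report"


class CheckId(str, enum.Enum):
    TOTAL_BELOW_MIN = "TOTAL_BELOW_MIN"
    TOTAL_DELTA_GT10 = "TOTAL_DELTA_GT10"
    ITEM3_TO_NEVER = "ITEM3_TO_NEVER"
    ITEM4_TO_NEVER = "ITEM4_TO_NEVER"
    ITEM5_TO_NEVER = "ITEM5_TO_NEVER"
    ITEM6_TO_NEVER = "ITEM6_TO_NEVER"
    ITEM7_TO_NEVER = "ITEM7_TO_NEVER"
    USE_ITEM2_NEVER = "USE_ITEM2_NEVER"
    USE_PATTERN_NONE = "USE_PATTERN_NONE"
    USE_TIMES_ZERO = "USE_TIMES_ZERO"
    USE_HOURS_NONE = "USE_HOURS_NONE"


CHECK_FAMILIES: dict[CheckId, CheckFamily] = {
    CheckId.TOTAL_BELOW_MIN: CheckFamily.TOTAL_SCORE,
    CheckId.TOTAL_DELTA_GT10: CheckFamily.TOTAL_SCORE,
    CheckId.ITEM3_TO_NEVER: CheckFamily.ITEM_REGRESSION,
    CheckId.ITEM4_TO_NEVER: CheckFamily.ITEM_REGRESSION,
    CheckId.ITEM5_TO_NEVER: CheckFamily.ITEM_REGRESSION,
    CheckId.ITEM6_TO_NEVER: CheckFamily.ITEM_REGRESSION,
    CheckId.ITEM7_TO_NEVER: CheckFamily.ITEM_REGRESSION,
    CheckId.USE_ITEM2_NEVER: CheckFamily.USAGE_REPORT,
    CheckId.USE_PATTERN_NONE: CheckFamily.USAGE_REPORT,
    CheckId.USE_TIMES_ZERO: CheckFamily.USAGE_REPORT,
    CheckId.USE_HOURS_NONE: CheckFamily.USAGE_REPORT,
}

ITEM_REGRESSION_CHECKS: dict[int, CheckId] = {
    3: CheckId.ITEM3_TO_NEVER,
    4: CheckId.ITEM4_TO_NEVER,
    5: CheckId.ITEM5_TO_NEVER,
    6: CheckId.ITEM6_TO_NEVER,
    7: CheckId.ITEM7_TO_NEVER,
}


@dataclass(frozen=True)
class CheckResult:
    check: CheckId
    fired: bool
    screener_value: object = None
    baseline_value: object = None

    @property
    def family(self) -> CheckFamily:
        return CHECK_FAMILIES[self.check]


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the rule engine; defaults reproduce the published design.

    ``min_total`` is the moderate-risk eligibility floor (baseline totals below
    it fire), ``delta_bound`` the largest tolerated total-score change (strict:
    a change of exactly ``delta_bound`` passes), and ``decision_threshold`` the
    number of fired checks that screens a participant out.  ``enabled`` can
    restrict the engine to a subset of checks for sensitivity analyses.
    """

    min_total: int = 4
    delta_bound: int = 10
    decision_threshold: int = 1
    enabled: frozenset[CheckId] = frozenset(CheckId)

    def __post_init__(self) -> None:
        if self.delta_bound < 0:
            raise ValueError("delta_bound must be >= 0")
        if not 0 <= self.min_total <= 39:
            raise ValueError("min_total must be in [0, 39]")
        if self.decision_threshold < 1:
            raise ValueError("decision_threshold must be >= 1")


@dataclass(frozen=True)
class UsageAnswers:
    """Baseline usage-pattern probe answers.

    Any probe may be absent (None); an absent probe is recorded as not fired.
    ``times_weekday``/``times_weekend`` are counts of uses per typical day.
    """

    pattern: str | None = None
    times_weekday: float | None = None
    times_weekend: float | None = None
    hours: str | None = None


@dataclass(frozen=True)
class ConsistencyReport:
    """All check outcomes for one screener/baseline pair plus the decision."""

    participant_id: str
    results: tuple[CheckResult, ...]
    decision: str  # "screened_in" | "screened_out"

    @property
    def n_fired(self) -> int:
        return sum(r.fired for r in self.results)

    @property
    def fired_checks(self) -> tuple[CheckId, ...]:
        return tuple(r.check for r in self.results if r.fired)

    @property
    def families_fired(self) -> frozenset[CheckFamily]:
        return frozenset(r.family for r in self.results if r.fired)

    @property
    def screened_out(self) -> bool:
        return self.decision == "screened_out"


def check_total_below_min(baseline_total: int, rules: RuleConfig = RuleConfig()) -> CheckResult:
    """Fires when the baseline total fell below the eligibility floor (< 4)."""
    return CheckResult(
        CheckId.TOTAL_BELOW_MIN,
        fired=baseline_total < rules.min_total,
        baseline_value=baseline_total,
    )


def check_total_delta(
    screener_total: int, baseline_total: int, rules: RuleConfig = RuleConfig()
) -> CheckResult:
    """Fires when |baseline - screener| exceeds the bound (strictly more than 10)."""
    return CheckResult(
        CheckId.TOTAL_DELTA_GT10,
        fired=abs(baseline_total - screener_total) > rules.delta_bound,
        screener_value=screener_total,
        baseline_value=baseline_total,
    )


def check_item_regression(
    item_id: int,
    screener_label: str,
    baseline_label: str,
    instrument: InstrumentDefinition,
) -> CheckResult:
    """Fires when an item endorsed at screening reverted to never at baseline.

    Endorsed means any option above ordinal 0.  A mere reduction (e.g. Weekly
    to Monthly) does not fire; only the full reversion to "Never"/"No, never".
    Items 3-7 only — item 2 reverting to "Never" is a usage-report check.
    """
    if item_id not in ITEM_REGRESSION_CHECKS:
        raise InstrumentError(f"item regression applies to items 3-7, not {item_id}")
    item = instrument.item(item_id)
    fired = item.ordinal_of(screener_label) > 0 and item.ordinal_of(baseline_label) == 0
    return CheckResult(
        ITEM_REGRESSION_CHECKS[item_id],
        fired=fired,
        screener_value=screener_label,
        baseline_value=baseline_label,
    )


def check_usage_report(
    baseline_item2_label: str | None,
    answers: UsageAnswers,
    instrument: InstrumentDefinition,
) -> list[CheckResult]:
    """The four baseline probes of whether the participant uses cannabis at all.

    Each probe fires independently when its answer denotes non-use.  Probe
    answers absent from ``answers`` are recorded as not fired.
    """
    results = []
    item2_fired = False
    if baseline_item2_label is not None:
        item2_fired = instrument.item(2).ordinal_of(baseline_item2_label) == 0
    results.append(
        CheckResult(
            CheckId.USE_ITEM2_NEVER, item2_fired, baseline_value=baseline_item2_label
        )
    )

    probes = instrument.usage_probes
    pattern_fired = False
    if answers.pattern is not None:
        if probes is None or answers.pattern not in probes.pattern_options:
            raise UnknownOptionError(f"unknown pattern answer {answers.pattern!r}")
        pattern_fired = answers.pattern == probes.pattern_nonuse
    results.append(
        CheckResult(CheckId.USE_PATTERN_NONE, pattern_fired, baseline_value=answers.pattern)
    )

    times_fired = False
    if answers.times_weekday is not None and answers.times_weekend is not None:
        if answers.times_weekday < 0 or answers.times_weekend < 0:
            raise InstrumentError("times per day must be non-negative")
        times_fired = answers.times_weekday == 0 and answers.times_weekend == 0
    results.append(
        CheckResult(
            CheckId.USE_TIMES_ZERO,
            times_fired,
            baseline_value=(answers.times_weekday, answers.times_weekend),
        )
    )

    hours_fired = False
    if answers.hours is not None:
        if probes is None or answers.hours not in probes.hours_options:
            raise UnknownOptionError(f"unknown hours answer {answers.hours!r}")
        hours_fired = answers.hours == probes.hours_nonuse
    results.append(
        CheckResult(CheckId.USE_HOURS_NONE, hours_fired, baseline_value=answers.hours)
    )
    return results


def evaluate_pair(
    screener: AssistResponse,
    baseline: AssistResponse,
    usage_answers: UsageAnswers | None,
    instrument: InstrumentDefinition,
    rules: RuleConfig = RuleConfig(),
    participant_id: str = "",
) -> ConsistencyReport:
    """Run every enabled check on a screener/baseline pair; pure and deterministic.

    On the full default instrument the report carries exactly 11 results, one
    per check id, regardless of how many fired.  The decision is screened_out
    when at least ``rules.decision_threshold`` checks fired.
    """
    screener_total = total_score(screener, instrument)
    baseline_total = total_score(baseline, instrument)
    if usage_answers is None:
        usage_answers = UsageAnswers()

    results: list[CheckResult] = [
        check_total_below_min(baseline_total, rules),
        check_total_delta(screener_total, baseline_total, rules),
    ]
    for item_id in sorted(ITEM_REGRESSION_CHECKS):
        if instrument.has_item(item_id) and instrument.item(item_id).scored:
            results.append(
                check_item_regression(
                    item_id,
                    screener.label(item_id),
                    baseline.label(item_id),
                    instrument,
                )
            )
    item2_label = baseline.selections.get(2) if instrument.has_item(2) else None
    results.extend(check_usage_report(item2_label, usage_answers, instrument))

    kept = tuple(r for r in results if r.check in rules.enabled)
    n_fired = sum(r.fired for r in kept)
    decision = "screened_out" if n_fired >= rules.decision_threshold else "screened_in"
    return ConsistencyReport(participant_id, kept, decision)


def count_distribution(reports: Sequence[ConsistencyReport]) -> dict[int, int]:
    """Frequency of fired-check counts among screened-out reports.

    Reproduces the how-many-issues tally (share excluded for one, two, three
    or more inconsistencies) at the 11-check granularity.
    """
    if not reports:
        raise ValueError("count_distribution needs at least one report")
    return dict(Counter(r.n_fired for r in reports if r.screened_out))
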