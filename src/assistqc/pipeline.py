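"""Two-stage recruitment flow with conserving consort accounting.

Records move screener -> eligibility -> consent -> duplicate exclusion ->
withdrawal -> baseline completion -> consistency assessment, and every record
ends in exactly one terminal stage, so stage counts conserve: entrants equal
exits plus continuers at every step.  Eligibility sub-criteria are tested in
the fixed order age, recent use, score, attributing a multiply-ineligible
record to the first failed criterion (single count per person, the convention
consort arithmetic needs).

``run_flow`` consumes record-level input; ``replay_flow`` accepts
pre-aggregated stage exits so a published consort chart can be replayed and
checked without reconstructing individual records.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .consistency import ConsistencyReport, RuleConfig, UsageAnswers, evaluate_pair
from .instrument import (
    AssistResponse,
    IncompleteResponseError,
    InstrumentDefinition,
    total_score,
)

__all__ = [
    "Stage",
    "Demographics",
    "ParticipantRecord",
    "ConsortTable",
    "AccountingError",
    "eligibility_check",
    "run_flow",
    "replay_flow",
    "consort_summary",
    "round_half_up",
]


class Stage(str, enum.Enum):
    SCREENER_COMPLETED = "screener_completed"
    INELIGIBLE_AGE = "ineligible_age"
    INELIGIBLE_NEVER_USED = "ineligible_never_used"
    INELIGIBLE_LOW_SCORE = "ineligible_low_score"
    NO_CONSENT = "no_consent"
    DUPLICATE_EXCLUDED = "duplicate_excluded"
    WITHDREW = "withdrew"
    BASELINE_INCOMPLETE = "baseline_incomplete"
    CONSISTENCY_ASSESSED = "consistency_assessed"
    SCREENED_OUT = "screened_out"
    SCREENED_IN = "screened_in"


EXIT_STAGES = (
    Stage.INELIGIBLE_AGE,
    Stage.INELIGIBLE_NEVER_USED,
    Stage.INELIGIBLE_LOW_SCORE,
    Stage.NO_CONSENT,
    Stage.DUPLICATE_EXCLUDED,
    Stage.WITHDREW,
    Stage.BASELINE_INCOMPLETE,
)
TERMINAL_STAGES = EXIT_STAGES + (Stage.SCREENED_OUT, Stage.SCREENED_IN)


class AccountingError(ValueError):
    """A consort table whose stage counts do not conserve."""


@dataclass
class Demographics:
    age: int
    male: bool = False
    postsecondary: bool = False
    married: bool = False
    employed: bool = False
    income_low: bool = False  # annual income <= $20,000 CAD
    cannabis_days_past30: int = 0

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if not 0 <= self.cannabis_days_past30 <= 30:
            raise ValueError("cannabis_days_past30 must be in [0, 30]")


@dataclass
class ParticipantRecord:
    """One respondent's demographics, responses and administrative fates."""

    id: str
    demographics: Demographics
    screener: AssistResponse | None
    used_past_3_months: bool = True
    consented: bool = False
    duplicate: bool = False
    withdrew: bool = False
    baseline: AssistResponse | None = None
    usage_answers: UsageAnswers | None = None
    stage_history: list[Stage] = field(default_factory=list)

    def _advance(self, stage: Stage) -> Stage:
        self.stage_history.append(stage)
        return stage

    @property
    def terminal_stage(self) -> Stage | None:
        for st in reversed(self.stage_history):
            if st in TERMINAL_STAGES:
                return st
        return None


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the reporting convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def eligibility_check(
    record: ParticipantRecord,
    instrument: InstrumentDefinition,
    rules: RuleConfig = RuleConfig(),
) -> Stage:
    """First failed criterion in the order age -> recent use -> score, or a pass.

    Eligibility requires age >= 18, cannabis use in the previous three months,
    and a screener total of at least ``rules.min_total`` (moderate risk).
    """
    if record.screener is None:
        raise ValueError(f"record {record.id}: screener response missing")
    if record.demographics.age < 18:
        return Stage.INELIGIBLE_AGE
    if not record.used_past_3_months:
        return Stage.INELIGIBLE_NEVER_USED
    if total_score(record.screener, instrument) < rules.min_total:
        return Stage.INELIGIBLE_LOW_SCORE
    return Stage.SCREENER_COMPLETED  # passed; continues in the flow


@dataclass
class ConsortTable:
    """Stage -> count map with conservation invariants.

    ``screener_completed`` counts entrants; the seven exit stages plus
    screened_out/screened_in are terminal, and
    screened_out + screened_in = consistency_assessed.
    """

    counts: dict[Stage, int]

    def __getitem__(self, stage: Stage) -> int:
        return self.counts.get(stage, 0)

    def validate(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise AccountingError("negative stage count")
        entrants = self[Stage.SCREENER_COMPLETED]
        exits = sum(self[s] for s in EXIT_STAGES)
        assessed = self[Stage.CONSISTENCY_ASSESSED]
        if entrants != exits + assessed:
            raise AccountingError(
                f"entrants {entrants} != exits {exits} + assessed {assessed}"
            )
        out, kept = self[Stage.SCREENED_OUT], self[Stage.SCREENED_IN]
        if out + kept != assessed:
            raise AccountingError(
                f"screened_out {out} + screened_in {kept} != assessed {assessed}"
            )

    @property
    def n_ineligible(self) -> int:
        return (
            self[Stage.INELIGIBLE_AGE]
            + self[Stage.INELIGIBLE_NEVER_USED]
            + self[Stage.INELIGIBLE_LOW_SCORE]
        )

    @property
    def screened_out_pct(self) -> float:
        assessed = self[Stage.CONSISTENCY_ASSESSED]
        if assessed == 0:
            return 0.0
        return round_half_up(100.0 * self[Stage.SCREENED_OUT] / assessed)


def run_flow(
    records: Sequence[ParticipantRecord],
    instrument: InstrumentDefinition,
    rules: RuleConfig = RuleConfig(),
) -> tuple[list[ConsistencyReport], ConsortTable]:
    """Route every record to a terminal stage and tally the consort table.

    Consistency is evaluated only for records that reach assessment (eligible,
    consented, not duplicate, did not withdraw, completed the baseline ASSIST
    and usage probes).  Incomplete baselines become baseline_incomplete exits.
    """
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate participant ids in input")

    counts: dict[Stage, int] = {s: 0 for s in Stage}
    reports: list[ConsistencyReport] = []
    for rec in records:
        counts[Stage.SCREENER_COMPLETED] += 1
        rec._advance(Stage.SCREENER_COMPLETED)
        elig = eligibility_check(rec, instrument, rules)
        if elig is not Stage.SCREENER_COMPLETED:
            counts[rec._advance(elig)] += 1
            continue
        if not rec.consented:
            counts[rec._advance(Stage.NO_CONSENT)] += 1
            continue
        if rec.duplicate:
            counts[rec._advance(Stage.DUPLICATE_EXCLUDED)] += 1
            continue
        if rec.withdrew:
            counts[rec._advance(Stage.WITHDREW)] += 1
            continue
        if rec.baseline is None or rec.usage_answers is None:
            counts[rec._advance(Stage.BASELINE_INCOMPLETE)] += 1
            continue
        try:
            report = evaluate_pair(
                rec.screener,
                rec.baseline,
                rec.usage_answers,
                instrument,
                rules,
                participant_id=rec.id,
            )
        except IncompleteResponseError:
            counts[rec._advance(Stage.BASELINE_INCOMPLETE)] += 1
            continue
        counts[Stage.CONSISTENCY_ASSESSED] += 1
        rec._advance(Stage.CONSISTENCY_ASSESSED)
        final = Stage.SCREENED_OUT if report.screened_out else Stage.SCREENED_IN
        counts[rec._advance(final)] += 1
        reports.append(report)

    table = ConsortTable({s: n for s, n in counts.items() if n})
    table.validate()
    return reports, table


def replay_flow(
    completed: int,
    exits: Mapping[Stage, int],
    screened_out: int | None = None,
) -> ConsortTable:
    """Build a conserving consort table from pre-aggregated stage exits.

    ``completed`` is the number of completed screeners; ``exits`` maps each
    exit stage to its count.  The assessable sample is what remains, and if
    ``screened_out`` is given, screened_in is the complement.
    """
    bad = set(exits) - set(EXIT_STAGES)
    if bad:
        raise ValueError(f"not exit stages: {sorted(s.value for s in bad)}")
    counts = {Stage.SCREENER_COMPLETED: completed}
    counts.update({s: int(n) for s, n in exits.items()})
    assessed = completed - sum(exits.values())
    if assessed < 0:
        raise AccountingError("exits exceed completed screeners")
    counts[Stage.CONSISTENCY_ASSESSED] = assessed
    if screened_out is not None:
        if screened_out > assessed:
            raise AccountingError("screened_out exceeds assessable sample")
        counts[Stage.SCREENED_OUT] = screened_out
        counts[Stage.SCREENED_IN] = assessed - screened_out
    table = ConsortTable(counts)
    table.validate()
    return table


def consort_summary(table: ConsortTable) -> str:
    """Human-readable flow report; raises AccountingError on a non-conserving table."""
    table.validate()
    lines = ["consort flow"]
    order = (Stage.SCREENER_COMPLETED,) + EXIT_STAGES + (
        Stage.CONSISTENCY_ASSESSED,
        Stage.SCREENED_OUT,
        Stage.SCREENED_IN,
    )
    for stage in order:
        if stage in table.counts:
            lines.append(f"  {stage.value}: {table[stage]}")
    if table[Stage.CONSISTENCY_ASSESSED]:
        lines.append(f"  screened_out_pct: {table.screened_out_pct}")
    return "\n".join(lines)
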