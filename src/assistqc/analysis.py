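"""Group comparisons, inconsistency frequency tables, and detector evaluation.

Three table shapes mirror how two-stage screening studies report results:
bivariate screened-in vs screened-out comparisons (chi-square for 2x2
categorical variables, Welch's t for continuous ones), the per-check
frequency table among those screened out (with family "any" rows computed as
unions, never sums — one participant can fire several checks in a family),
and per-family descriptive columns with overlapping membership.

Because the consistency method has no ground truth on real data, the module
also evaluates it against the simulator's behavior labels (sensitivity over
non-faithful respondents, specificity over faithful ones) and against an
independent brute-force oracle for the uniform-random responder: exhaustive
enumeration of every eligible screener x baseline pair on instruments small
enough, Monte Carlo with a reported standard error otherwise.  The exhaustive
oracle re-derives every predicate inline, so it is an independent check on
the rule engine rather than a second call into it.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import (
    CHECK_FAMILIES,
    CheckFamily,
    CheckId,
    ConsistencyReport,
    RuleConfig,
    evaluate_pair,
)
from .instrument import AssistResponse, InstrumentDefinition, total_score
from .pipeline import ParticipantRecord, round_half_up
from .simulator import CohortDataset

__all__ = [
    "GroupComparisonRow",
    "DetectionPerformance",
    "OracleEstimate",
    "compare_groups",
    "summary_ttest",
    "inconsistency_table",
    "per_type_descriptives",
    "detection_performance",
    "random_flag_oracle",
    "records_frame",
    "format_p",
]

CHECK_LABELS = {
    CheckId.TOTAL_BELOW_MIN: "Baseline total score < 4",
    CheckId.TOTAL_DELTA_GT10: "Difference total score of more than +/- 10 points",
    CheckId.ITEM3_TO_NEVER: "Item 3 (strong desire or urge) changed to never",
    CheckId.ITEM4_TO_NEVER: "Item 4 (health/social/legal/financial problems) changed to never",
    CheckId.ITEM5_TO_NEVER: "Item 5 (failed normal expectations) changed to never",
    CheckId.ITEM6_TO_NEVER: "Item 6 (concern expressed by others) changed to never",
    CheckId.ITEM7_TO_NEVER: "Item 7 (tried to cut down or stop) changed to never",
    CheckId.USE_ITEM2_NEVER: "Baseline item 2: did not use cannabis",
    CheckId.USE_PATTERN_NONE: "Weekly pattern probe: non-use option",
    CheckId.USE_TIMES_ZERO: "Times per day: zero on weekday and weekend",
    CheckId.USE_HOURS_NONE: "Hours after waking probe: non-use option",
}
FAMILY_LABELS = {
    CheckFamily.TOTAL_SCORE: "Any change in total score",
    CheckFamily.ITEM_REGRESSION: "Any change to ASSIST answers",
    CheckFamily.USAGE_REPORT: "Any change to never use",
}


def format_p(p: float | None) -> str:
    """Render a p-value the way the tables print it (floor at '< 0.001')."""
    if p is None:
        return "NA"
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3f}"


@dataclass(frozen=True)
class GroupComparisonRow:
    variable: str
    group_a_summary: str
    group_b_summary: str
    statistic: float | None
    p_value: float | None
    test_kind: str  # "chi_square" | "two_sample_t"
    note: str = ""


def summary_ttest(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test from summary statistics (Welch by default).

    Lets printed table cells (mean, SD, n per group) be checked without the
    underlying raw data.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    variables: Sequence[tuple[str, str]],
    equal_var: bool = False,
    continuity_correction: bool = False,
) -> list[GroupComparisonRow]:
    """Bivariate comparison rows for two record partitions.

    ``variables`` is a list of (column, kind) with kind "categorical" (binary;
    2x2 chi-square, no continuity correction by default) or "continuous"
    (two-sample t, Welch by default).  Zero-variance continuous columns get an
    undefined-statistic note instead of a spurious test.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    rows: list[GroupComparisonRow] = []
    for name, kind in variables:
        a, b = group_a[name].to_numpy(), group_b[name].to_numpy()
        if kind == "categorical":
            ka, kb = int(np.sum(a)), int(np.sum(b))
            table = np.array([[ka, len(a) - ka], [kb, len(b) - kb]])
            summary_a = f"{ka} ({round_half_up(100 * ka / len(a))})"
            summary_b = f"{kb} ({round_half_up(100 * kb / len(b))})"
            if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                rows.append(GroupComparisonRow(
                    name, summary_a, summary_b, None, None, "chi_square",
                    note="degenerate 2x2 table",
                ))
                continue
            stat, p, _, _ = stats.chi2_contingency(
                table, correction=continuity_correction
            )
            rows.append(GroupComparisonRow(
                name, summary_a, summary_b, float(stat), float(p), "chi_square"
            ))
        elif kind == "continuous":
            summary_a = f"{np.mean(a):.1f} ({np.std(a, ddof=1):.1f})"
            summary_b = f"{np.mean(b):.1f} ({np.std(b, ddof=1):.1f})"
            if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
                rows.append(GroupComparisonRow(
                    name, summary_a, summary_b, None, None, "two_sample_t",
                    note="zero variance in both groups",
                ))
                continue
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append(GroupComparisonRow(
                name, summary_a, summary_b,
                float(res.statistic), float(res.pvalue), "two_sample_t",
            ))
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return rows


def inconsistency_table(reports: Sequence[ConsistencyReport]) -> pd.DataFrame:
    """Per-check counts and percentages among screened-out reports.

    Family "any" rows are unions over member checks (a participant firing two
    checks of one family counts once in that family's row), so a family row
    never exceeds the sum of its member rows.
    """
    if not reports:
        raise ValueError("inconsistency_table needs at least one report")
    out = [r for r in reports if r.screened_out]
    denom = len(out)
    rows = []
    for family in CheckFamily:
        members = [c for c in CheckId if CHECK_FAMILIES[c] == family]
        for check in members:
            n = sum(any(res.check == check and res.fired for res in r.results) for r in out)
            rows.append({
                "label": CHECK_LABELS[check],
                "check": check.value,
                "family": family.value,
                "count": n,
                "pct": round_half_up(100 * n / denom) if denom else 0.0,
            })
        n_any = sum(family in r.families_fired for r in out)
        rows.append({
            "label": FAMILY_LABELS[family],
            "check": f"ANY_{family.value.upper()}",
            "family": family.value,
            "count": n_any,
            "pct": round_half_up(100 * n_any / denom) if denom else 0.0,
        })
    return pd.DataFrame(rows)


def records_frame(
    records: Sequence[ParticipantRecord],
    instrument: InstrumentDefinition,
    reports: Sequence[ConsistencyReport] | None = None,
) -> pd.DataFrame:
    """Flatten records (and optional reports) into an analysis DataFrame."""
    by_id = {r.participant_id: r for r in reports} if reports else {}
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "age": rec.demographics.age,
            "male": rec.demographics.male,
            "postsecondary": rec.demographics.postsecondary,
            "married": rec.demographics.married,
            "employed": rec.demographics.employed,
            "income_low": rec.demographics.income_low,
            "days_past30": rec.demographics.cannabis_days_past30,
            "screener_total": (
                total_score(rec.screener, instrument) if rec.screener else None
            ),
            "baseline_total": (
                total_score(rec.baseline, instrument) if rec.baseline else None
            ),
        }
        rep = by_id.get(rec.id)
        row["decision"] = rep.decision if rep else None
        if rep is not None:
            for fam in CheckFamily:
                row[f"fired_{fam.value}"] = fam in rep.families_fired
        rows.append(row)
    return pd.DataFrame(rows)


DESCRIPTIVE_VARIABLES: tuple[tuple[str, str], ...] = (
    ("male", "categorical"),
    ("postsecondary", "categorical"),
    ("married", "categorical"),
    ("employed", "categorical"),
    ("income_low", "categorical"),
    ("age", "continuous"),
    ("screener_total", "continuous"),
    ("baseline_total", "continuous"),
    ("days_past30", "continuous"),
)


def per_type_descriptives(
    records: Sequence[ParticipantRecord],
    reports: Sequence[ConsistencyReport],
    instrument: InstrumentDefinition,
    variables: Sequence[tuple[str, str]] = DESCRIPTIVE_VARIABLES,
) -> pd.DataFrame:
    """Descriptives of screened-out participants by inconsistency family.

    Membership overlaps: a participant who fired checks in two families
    appears in both columns, so column n's may sum to more than the
    screened-out count.
    """
    frame = records_frame(records, instrument, reports)
    out = frame[frame["decision"] == "screened_out"]
    cols: dict[str, dict[str, object]] = {}
    for fam in CheckFamily:
        col = f"fired_{fam.value}"
        if col in out:
            mask = out[col].astype("boolean").fillna(False).to_numpy(dtype=bool)
            members = out[mask]
        else:
            members = out.iloc[0:0]
        cells: dict[str, object] = {"n": len(members)}
        for name, kind in variables:
            if len(members) == 0:
                cells[name] = ""
            elif kind == "categorical":
                k = int(members[name].sum())
                cells[name] = f"{round_half_up(100 * k / len(members))} ({k})"
            else:
                vals = members[name].astype(float)
                sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
                cells[name] = f"{vals.mean():.1f} ({sd:.1f})"
        cols[FAMILY_LABELS[fam]] = cells
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class DetectionPerformance:
    """Flag rates by true behavior plus sensitivity/specificity of the method."""

    per_behavior_flag_rate: Mapping[str, float]
    sensitivity: float | None  # flagged among truly non-faithful
    specificity: float | None  # unflagged among truly faithful

    def __post_init__(self) -> None:
        for v in list(self.per_behavior_flag_rate.values()) + [
            x for x in (self.sensitivity, self.specificity) if x is not None
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError("rates must be in [0, 1]")


def detection_performance(
    dataset: CohortDataset, reports: Sequence[ConsistencyReport]
) -> DetectionPerformance:
    """Score the screen against the simulator's ground-truth behavior labels.

    Only assessed records (those with a report) enter the rates.  Sensitivity
    is the flagged fraction of truly non-faithful respondents; specificity the
    unflagged fraction of faithful ones; either is None if its denominator is
    empty.
    """
    missing = [r.participant_id for r in reports if r.participant_id not in dataset.truth]
    if missing:
        raise KeyError(f"no truth label for {missing[:3]}")
    flagged_by_kind: dict[str, list[bool]] = {}
    for rep in reports:
        kind = dataset.truth[rep.participant_id]
        flagged_by_kind.setdefault(kind, []).append(rep.screened_out)
    rates = {k: float(np.mean(v)) for k, v in flagged_by_kind.items()}
    invalid = [f for k, v in flagged_by_kind.items() if k != "faithful" for f in v]
    faithful = flagged_by_kind.get("faithful", [])
    return DetectionPerformance(
        per_behavior_flag_rate=rates,
        sensitivity=float(np.mean(invalid)) if invalid else None,
        specificity=float(np.mean([not f for f in faithful])) if faithful else None,
    )


@dataclass(frozen=True)
class OracleEstimate:
    """Flag probability for a uniform-random responder, with sampling error."""

    probability: float
    se: float
    n_pairs: int
    mode: str


def _exhaustive_flag_probability(
    instrument: InstrumentDefinition, rules: RuleConfig
) -> OracleEstimate:
    """Enumerate every eligible screener x baseline pair and apply the
    predicates inline (independent of the rule engine)."""
    items = instrument.scored_items
    space = 1
    for it in items:
        space *= len(it.options)
    if space * space > 10_000_000:
        raise ValueError(
            f"paired response space {space * space} too large for exhaustive mode"
        )
    weight_rows = [
        [it.weights[o.label] for o in it.options] for it in items
    ]
    ids = [it.item_id for it in items]
    combos = list(itertools.product(*[range(len(it.options)) for it in items]))
    totals = [sum(w[o] for w, o in zip(weight_rows, combo)) for combo in combos]
    eligible = [c for c, t in zip(combos, totals) if t >= rules.min_total]
    total_of = dict(zip(combos, totals))

    enabled = rules.enabled
    n_pairs = 0
    n_flagged = 0
    for scr in eligible:
        t_scr = total_of[scr]
        for base in combos:
            n_pairs += 1
            t_base = total_of[base]
            fired = 0
            if CheckId.TOTAL_BELOW_MIN in enabled and t_base < rules.min_total:
                fired += 1
            if CheckId.TOTAL_DELTA_GT10 in enabled and abs(t_base - t_scr) > rules.delta_bound:
                fired += 1
            for pos, iid in enumerate(ids):
                if 3 <= iid <= 7:
                    check = CheckId(f"ITEM{iid}_TO_NEVER")
                    if check in enabled and scr[pos] > 0 and base[pos] == 0:
                        fired += 1
            if 2 in ids and CheckId.USE_ITEM2_NEVER in enabled:
                if base[ids.index(2)] == 0:
                    fired += 1
            if fired >= rules.decision_threshold:
                n_flagged += 1
    return OracleEstimate(n_flagged / n_pairs, 0.0, n_pairs, "exhaustive")


def _monte_carlo_flag_probability(
    instrument: InstrumentDefinition,
    rules: RuleConfig,
    n_draws: int,
    seed: int,
) -> OracleEstimate:
    """Sample eligible uniform-random pairs and run them through the rule engine."""
    from .simulator import sample_random

    rng = np.random.default_rng(seed)
    flagged = 0
    kept = 0
    while kept < n_draws:
        scr, base = sample_random(rng, instrument)
        if total_score(scr, instrument) < rules.min_total:
            continue
        kept += 1
        rep = evaluate_pair(scr, base, None, instrument, rules)
        flagged += rep.screened_out
    p = flagged / n_draws
    se = float(np.sqrt(p * (1 - p) / n_draws))
    return OracleEstimate(p, se, n_draws, "monte_carlo")


def random_flag_oracle(
    instrument: InstrumentDefinition,
    mode: str = "exhaustive",
    rules: RuleConfig = RuleConfig(),
    n_draws: int = 100_000,
    seed: int = 0,
) -> OracleEstimate:
    """Probability that a uniform-random responder (eligible at screening)
    is flagged by the consistency screen.

    Exhaustive mode enumerates the full paired response space (instruments
    with at most 1e7 pairs) and is exact; monte_carlo estimates it by running
    the actual rule engine on sampled pairs, reporting a binomial standard
    error.  The two modes are deliberately independent code paths.
    """
    if mode == "exhaustive":
        return _exhaustive_flag_probability(instrument, rules)
    if mode == "monte_carlo":
        return _monte_carlo_flag_probability(instrument, rules, n_draws, seed)
    raise ValueError(f"unknown mode {mode!r}")
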