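"""Delimited-text readers and writers for records, check matrices and consort tables.

All files are UTF-8 CSV with explicit headers; response options are stored as
their display labels (not numeric codes) so files are self-describing.
Unparseable rows are collected into a rejects list with a reason — never
silently dropped — while structural problems (a missing mandatory column)
fail the whole read.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import yaml

from .consistency import CheckId, CheckResult, ConsistencyReport, UsageAnswers
from .instrument import (
    AssistResponse,
    InstrumentDefinition,
    InstrumentError,
)
from .pipeline import ConsortTable, Demographics, ParticipantRecord, Stage

__all__ = [
    "SchemaError",
    "RejectedRow",
    "read_records",
    "write_records",
    "write_truth",
    "read_truth",
    "write_check_matrix",
    "read_check_matrix",
    "write_consort",
    "read_consort",
]

SCORED_ITEMS = (2, 3, 4, 5, 6, 7)
RECORD_COLUMNS = (
    ["id", "age", "male", "postsecondary", "married", "employed", "income_low",
     "days_past30", "used_past_3_months", "consented", "duplicate", "withdrew"]
    + [f"scr_item{i}" for i in SCORED_ITEMS]
    + [f"base_item{i}" for i in SCORED_ITEMS]
    + ["use_pattern", "times_weekday", "times_weekend", "use_hours"]
)


class SchemaError(ValueError):
    """The file header does not match the documented record schema."""


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based, excluding the header
    id: str
    reason: str


def _bool_out(v: bool) -> str:
    return "true" if v else "false"


def _bool_in(v: str, col: str) -> bool:
    if v.strip().lower() in ("true", "1", "yes"):
        return True
    if v.strip().lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"column {col}: not a boolean: {v!r}")


def write_records(records: Sequence[ParticipantRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=RECORD_COLUMNS)
        w.writeheader()
        for rec in records:
            d = rec.demographics
            row = {
                "id": rec.id,
                "age": d.age,
                "male": _bool_out(d.male),
                "postsecondary": _bool_out(d.postsecondary),
                "married": _bool_out(d.married),
                "employed": _bool_out(d.employed),
                "income_low": _bool_out(d.income_low),
                "days_past30": d.cannabis_days_past30,
                "used_past_3_months": _bool_out(rec.used_past_3_months),
                "consented": _bool_out(rec.consented),
                "duplicate": _bool_out(rec.duplicate),
                "withdrew": _bool_out(rec.withdrew),
            }
            for i in SCORED_ITEMS:
                row[f"scr_item{i}"] = rec.screener.selections.get(i, "") if rec.screener else ""
                row[f"base_item{i}"] = rec.baseline.selections.get(i, "") if rec.baseline else ""
            ua = rec.usage_answers
            row["use_pattern"] = ua.pattern if ua and ua.pattern is not None else ""
            row["times_weekday"] = (
                ua.times_weekday if ua and ua.times_weekday is not None else ""
            )
            row["times_weekend"] = (
                ua.times_weekend if ua and ua.times_weekend is not None else ""
            )
            row["use_hours"] = ua.hours if ua and ua.hours is not None else ""
            w.writerow(row)


def _parse_record(
    row: dict[str, str], instrument: InstrumentDefinition
) -> ParticipantRecord:
    demo = Demographics(
        age=int(row["age"]),
        male=_bool_in(row["male"], "male"),
        postsecondary=_bool_in(row["postsecondary"], "postsecondary"),
        married=_bool_in(row["married"], "married"),
        employed=_bool_in(row["employed"], "employed"),
        income_low=_bool_in(row["income_low"], "income_low"),
        cannabis_days_past30=int(row["days_past30"]),
    )
    scr_sel: dict[int, str] = {}
    base_sel: dict[int, str] = {}
    for i in SCORED_ITEMS:
        label = row[f"scr_item{i}"].strip()
        if label:
            instrument.item(i).option(label)  # raises UnknownOptionError
            scr_sel[i] = label
        label = row[f"base_item{i}"].strip()
        if label:
            instrument.item(i).option(label)
            base_sel[i] = label
    usage = None
    if any(row[c].strip() for c in ("use_pattern", "times_weekday", "times_weekend", "use_hours")):
        probes = instrument.usage_probes
        pattern = row["use_pattern"].strip() or None
        hours = row["use_hours"].strip() or None
        if pattern and probes and pattern not in probes.pattern_options:
            raise InstrumentError(f"unknown pattern answer {pattern!r}")
        if hours and probes and hours not in probes.hours_options:
            raise InstrumentError(f"unknown hours answer {hours!r}")
        usage = UsageAnswers(
            pattern=pattern,
            times_weekday=float(row["times_weekday"]) if row["times_weekday"].strip() else None,
            times_weekend=float(row["times_weekend"]) if row["times_weekend"].strip() else None,
            hours=hours,
        )
    return ParticipantRecord(
        id=row["id"],
        demographics=demo,
        screener=AssistResponse(scr_sel, "screener") if scr_sel else None,
        used_past_3_months=_bool_in(row["used_past_3_months"], "used_past_3_months"),
        consented=_bool_in(row["consented"], "consented"),
        duplicate=_bool_in(row["duplicate"], "duplicate"),
        withdrew=_bool_in(row["withdrew"], "withdrew"),
        baseline=AssistResponse(base_sel, "baseline") if base_sel else None,
        usage_answers=usage,
    )


def read_records(
    path, instrument: InstrumentDefinition
) -> tuple[list[ParticipantRecord], list[RejectedRow]]:
    """Read typed records; malformed rows become rejects with a reason."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(RECORD_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
        records: list[ParticipantRecord] = []
        rejects: list[RejectedRow] = []
        for n, row in enumerate(reader, start=1):
            try:
                records.append(_parse_record(row, instrument))
            except (ValueError, InstrumentError) as exc:
                rejects.append(RejectedRow(n, row.get("id", ""), str(exc)))
    return records, rejects


def write_truth(truth: dict[str, str], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "behavior"])
        for pid, kind in truth.items():
            w.writerow([pid, kind])


def read_truth(path) -> dict[str, str]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if set(reader.fieldnames or []) < {"id", "behavior"}:
            raise SchemaError("truth file needs columns id, behavior")
        return {row["id"]: row["behavior"] for row in reader}


def write_check_matrix(reports: Sequence[ConsistencyReport], path) -> None:
    """Participant x 11-check boolean matrix plus n_fired and the decision."""
    cols = ["id"] + [c.value for c in CheckId] + ["n_fired", "decision"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for rep in reports:
            fired = {r.check: r.fired for r in rep.results}
            row = {"id": rep.participant_id, "n_fired": rep.n_fired, "decision": rep.decision}
            for c in CheckId:
                row[c.value] = _bool_out(fired.get(c, False))
            w.writerow(row)


def read_check_matrix(path) -> list[ConsistencyReport]:
    """Rebuild reports from a check matrix (fired flags and decisions only)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = ({c.value for c in CheckId} | {"id", "decision"}) - set(
            reader.fieldnames or []
        )
        if missing:
            raise SchemaError(f"check matrix missing columns: {sorted(missing)}")
        reports = []
        for row in reader:
            results = tuple(
                CheckResult(c, _bool_in(row[c.value], c.value)) for c in CheckId
            )
            reports.append(ConsistencyReport(row["id"], results, row["decision"]))
    return reports


def write_consort(table: ConsortTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {stage.value: int(n) for stage, n in table.counts.items()},
            fh, sort_keys=False,
        )


def read_consort(path) -> ConsortTable:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return ConsortTable({Stage(k): int(v) for k, v in raw.items()})
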