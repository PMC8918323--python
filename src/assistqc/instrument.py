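"""The ASSIST cannabis subscale: items, response options, weights, risk bands.

The Alcohol, Smoking and Substance Involvement Screening Test (ASSIST) is the
WHO's 8-item substance-involvement screener.  For a single substance the total
score is the sum of the item weights for items 2-7; for cannabis the total
ranges 0-39 and is banded into lower (0-3), moderate (4-26) and high (27-39)
risk.  Items 2-5 use five frequency options from "Never" to "Daily or Almost
Daily"; items 6-7 use three lifetime/recency options.  Item 1 (lifetime use)
and item 8 (injection) are carried for completeness but never scored.

The full per-option weight table is the published WHO ASSIST V3.0 cannabis
table.  It is validated at load time against the two hallmark cells
(Q2 "Weekly" = 4, Q5 "Weekly" = 7) and the 39-point maximum, so a corrupted
or substituted table fails fast.

Instruments are plain data and serialise to YAML, so alternative substances
or locally adapted weight tables can be declared in configuration; the
cannabis definition ships embedded as the default.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ResponseOption",
    "ItemDefinition",
    "UsageProbes",
    "InstrumentDefinition",
    "AssistResponse",
    "RiskCategory",
    "InstrumentError",
    "UnknownOptionError",
    "UnscoredItemError",
    "IncompleteResponseError",
    "score_item",
    "total_score",
    "categorize_risk",
    "max_attainable",
    "default_instrument",
    "load_instrument",
    "save_instrument",
]

FREQUENCY_LABELS = (
    "Never",
    "Once or Twice",
    "Monthly",
    "Weekly",
    "Daily or Almost Daily",
)
# Printed in this order on the instrument; note weights are NOT monotone in
# this display order (past-3-months use scores above older use).
RECENCY_LABELS = (
    "No, never",
    "Yes, in the past 3 months",
    "Yes, but not in the past 3 months",
)


class InstrumentError(ValueError):
    """Malformed instrument, response, or score."""


class UnknownOptionError(InstrumentError):
    """An option label that does not belong to the item."""


class UnscoredItemError(InstrumentError):
    """Scoring was requested for an item outside the scored set (2-7)."""


class IncompleteResponseError(InstrumentError):
    """A scored item has no selection; the caller decides the record's fate."""


@dataclass(frozen=True)
class ResponseOption:
    """One selectable answer: display label plus its position in the item."""

    label: str
    ordinal: int

    def __post_init__(self) -> None:
        if self.ordinal < 0:
            raise InstrumentError(f"ordinal must be >= 0, got {self.ordinal}")


@dataclass(frozen=True)
class ItemDefinition:
    """A single ASSIST item with its option list and weight map.

    ``weights`` maps option label -> integer score.  For frequency items
    (2-5) weights are strictly increasing in ordinal; for the recency items
    (6-7) they are attached by label and deliberately not monotone in the
    printed order.
    """

    item_id: int
    prompt_key: str
    options: tuple[ResponseOption, ...]
    weights: Mapping[str, int] = field(default_factory=dict)
    scored: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= 8:
            raise InstrumentError(f"item_id must be in 1..8, got {self.item_id}")
        ordinals = [o.ordinal for o in self.options]
        if ordinals != list(range(len(self.options))):
            raise InstrumentError(
                f"item {self.item_id}: ordinals must match declared order"
            )
        if self.options and self.options[0].label not in ("Never", "No, never"):
            raise InstrumentError(
                f"item {self.item_id}: ordinal-0 option must be a 'never' label"
            )
        if self.scored:
            missing = {o.label for o in self.options} - set(self.weights)
            if missing:
                raise InstrumentError(
                    f"item {self.item_id}: weights missing for {sorted(missing)}"
                )
            if self.weights[self.options[0].label] != 0:
                raise InstrumentError(
                    f"item {self.item_id}: ordinal-0 option must weigh 0"
                )
            if any(w < 0 for w in self.weights.values()):
                raise InstrumentError(f"item {self.item_id}: negative weight")
            if 2 <= self.item_id <= 5:
                seq = [self.weights[o.label] for o in self.options]
                if any(b <= a for a, b in zip(seq, seq[1:])):
                    raise InstrumentError(
                        f"item {self.item_id}: weights must strictly increase"
                    )

    def option(self, label: str) -> ResponseOption:
        for o in self.options:
            if o.label == label:
                return o
        raise UnknownOptionError(
            f"item {self.item_id}: unknown option {label!r}"
        )

    def ordinal_of(self, label: str) -> int:
        return self.option(label).ordinal

    def weight_of(self, label: str) -> int:
        self.option(label)  # raises UnknownOptionError for foreign labels
        return int(self.weights[label])

    @property
    def max_weight(self) -> int:
        return max(self.weights.values()) if self.scored else 0


@dataclass(frozen=True)
class UsageProbes:
    """Baseline usage-pattern follow-up questions and their non-use encodings.

    The pattern and hours-after-waking questions each declare exactly one
    canonical non-use option; the times-per-day probe denotes non-use when
    both the weekday and weekend counts are zero.  Option lists are
    configuration, not a property of the ASSIST itself.
    """

    pattern_options: tuple[str, ...]
    pattern_nonuse: str
    hours_options: tuple[str, ...]
    hours_nonuse: str

    def __post_init__(self) -> None:
        if self.pattern_nonuse not in self.pattern_options:
            raise InstrumentError("pattern_nonuse must be a pattern option")
        if self.hours_nonuse not in self.hours_options:
            raise InstrumentError("hours_nonuse must be an hours option")


class RiskCategory(str, enum.Enum):
    """ASSIST risk band; brief intervention is indicated for moderate risk."""

    LOWER = "lower"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class InstrumentDefinition:
    """An ordered set of items plus the risk-category bounds.

    ``category_bounds`` maps category name -> (low, high) inclusive bounds on
    the total score.  The intervals must partition [0, max_attainable] and the
    top of the high band must equal the attainable maximum, so a custom weight
    table that breaks the banding is rejected at construction.
    """

    items: tuple[ItemDefinition, ...]
    category_bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"lower": (0, 3), "moderate": (4, 26), "high": (27, 39)}
    )
    usage_probes: UsageProbes | None = None

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise InstrumentError("duplicate item ids")
        bounds = sorted(self.category_bounds.values())
        if bounds[0][0] != 0:
            raise InstrumentError("category bounds must start at 0")
        for (_, hi), (lo2, _) in zip(bounds, bounds[1:]):
            if lo2 != hi + 1:
                raise InstrumentError("category intervals must tile with no gap")
        if bounds[-1][1] != max_attainable(self):
            raise InstrumentError(
                "top category bound must equal the attainable maximum "
                f"({bounds[-1][1]} != {max_attainable(self)})"
            )

    def item(self, item_id: int) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise InstrumentError(f"no item {item_id} in instrument")

    def has_item(self, item_id: int) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def scored_items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.scored)

    @property
    def scored_ids(self) -> tuple[int, ...]:
        return tuple(it.item_id for it in self.scored_items)


@dataclass(frozen=True)
class AssistResponse:
    """One administration: item id -> selected option label.

    ``administration`` tags whether this is the eligibility screener or the
    post-consent baseline re-administration.
    """

    selections: Mapping[int, str]
    administration: str = "screener"
    answered_at: str | None = None

    def label(self, item_id: int) -> str:
        try:
            return self.selections[item_id]
        except KeyError:
            raise IncompleteResponseError(
                f"{self.administration}: no selection for item {item_id}"
            ) from None


def score_item(item: ItemDefinition, option: ResponseOption | str) -> int:
    """Weight of ``option`` on ``item``; 0 for every ordinal-0 option."""
    if not item.scored:
        raise UnscoredItemError(f"item {item.item_id} is not scored")
    label = option.label if isinstance(option, ResponseOption) else option
    return item.weight_of(label)


def total_score(response: AssistResponse, instrument: InstrumentDefinition) -> int:
    """Sum of item weights over the instrument's scored items (2-7)."""
    return sum(
        score_item(it, response.label(it.item_id)) for it in instrument.scored_items
    )


def max_attainable(instrument: InstrumentDefinition) -> int:
    """Largest total the weight table allows (39 for the default cannabis scale)."""
    return sum(it.max_weight for it in instrument.scored_items)


def categorize_risk(total: int, instrument: InstrumentDefinition) -> RiskCategory:
    """Map a total score onto its risk band via the instrument's bounds."""
    top = max(hi for _, hi in instrument.category_bounds.values())
    if not 0 <= total <= top:
        raise InstrumentError(f"total {total} outside [0, {top}]")
    for name, (lo, hi) in instrument.category_bounds.items():
        if lo <= total <= hi:
            return RiskCategory(name)
    raise InstrumentError(f"no category covers total {total}")  # pragma: no cover


# --- embedded default: WHO ASSIST V3.0 cannabis subscale ---------------------

_V3_FREQ_WEIGHTS: dict[int, tuple[int, int, int, int, int]] = {
    2: (0, 2, 3, 4, 6),
    3: (0, 3, 4, 5, 6),
    4: (0, 4, 5, 6, 7),
    5: (0, 5, 6, 7, 8),
}
_V3_RECENCY_WEIGHTS = {
    "No, never": 0,
    "Yes, in the past 3 months": 6,
    "Yes, but not in the past 3 months": 3,
}
_PROMPTS = {
    1: "ever_used",
    2: "frequency_of_use",
    3: "strong_desire_or_urge",
    4: "health_social_legal_financial_problems",
    5: "failed_normal_expectations",
    6: "concern_expressed_by_others",
    7: "tried_to_cut_down_or_stop",
    8: "ever_injected",
}

DEFAULT_USAGE_PROBES = UsageProbes(
    pattern_options=(
        "I don't use cannabis in a typical week",
        "Mostly on weekends",
        "Mostly on weekdays",
        "Spread evenly through the week",
        "Every day or almost every day",
    ),
    pattern_nonuse="I don't use cannabis in a typical week",
    hours_options=(
        "I don't use cannabis",
        "Within 1 hour of waking",
        "1 to 3 hours after waking",
        "3 to 6 hours after waking",
        "More than 6 hours after waking",
    ),
    hours_nonuse="I don't use cannabis",
)


def _freq_item(item_id: int) -> ItemDefinition:
    opts = tuple(ResponseOption(l, i) for i, l in enumerate(FREQUENCY_LABELS))
    weights = dict(zip(FREQUENCY_LABELS, _V3_FREQ_WEIGHTS[item_id]))
    return ItemDefinition(item_id, _PROMPTS[item_id], opts, weights, scored=True)


def _recency_item(item_id: int) -> ItemDefinition:
    opts = tuple(ResponseOption(l, i) for i, l in enumerate(RECENCY_LABELS))
    return ItemDefinition(
        item_id, _PROMPTS[item_id], opts, dict(_V3_RECENCY_WEIGHTS), scored=True
    )


def _flag_item(item_id: int) -> ItemDefinition:
    opts = (ResponseOption("No, never", 0), ResponseOption("Yes", 1))
    return ItemDefinition(item_id, _PROMPTS[item_id], opts, scored=False)


def default_instrument() -> InstrumentDefinition:
    """The embedded ASSIST cannabis subscale (V3.0 weights, risk bands 0-3/4-26/27-39)."""
    inst = InstrumentDefinition(
        items=(
            _flag_item(1),
            _freq_item(2),
            _freq_item(3),
            _freq_item(4),
            _freq_item(5),
            _recency_item(6),
            _recency_item(7),
            _flag_item(8),
        ),
        usage_probes=DEFAULT_USAGE_PROBES,
    )
    # Hallmark cells of the published table; a substituted table fails here.
    assert score_item(inst.item(2), "Weekly") == 4
    assert score_item(inst.item(5), "Weekly") == 7
    assert max_attainable(inst) == 39
    assert inst.scored_ids == (2, 3, 4, 5, 6, 7)
    return inst


# --- YAML serialisation ------------------------------------------------------


def _instrument_to_dict(inst: InstrumentDefinition) -> dict:
    d: dict = {
        "items": [
            {
                "item_id": it.item_id,
                "prompt_key": it.prompt_key,
                "scored": it.scored,
                "options": [
                    {"label": o.label, "weight": int(it.weights.get(o.label, 0))}
                    for o in it.options
                ],
            }
            for it in inst.items
        ],
        "category_bounds": {k: list(v) for k, v in inst.category_bounds.items()},
    }
    if inst.usage_probes is not None:
        d["usage_probes"] = {
            "pattern_options": list(inst.usage_probes.pattern_options),
            "pattern_nonuse": inst.usage_probes.pattern_nonuse,
            "hours_options": list(inst.usage_probes.hours_options),
            "hours_nonuse": inst.usage_probes.hours_nonuse,
        }
    return d


def _instrument_from_dict(d: Mapping) -> InstrumentDefinition:
    items = []
    for raw in d["items"]:
        opts = tuple(
            ResponseOption(o["label"], i) for i, o in enumerate(raw["options"])
        )
        weights = {o["label"]: int(o.get("weight", 0)) for o in raw["options"]}
        items.append(
            ItemDefinition(
                int(raw["item_id"]),
                raw.get("prompt_key", f"item_{raw['item_id']}"),
                opts,
                weights if raw.get("scored", True) else {},
                scored=bool(raw.get("scored", True)),
            )
        )
    probes = None
    if "usage_probes" in d:
        p = d["usage_probes"]
        probes = UsageProbes(
            tuple(p["pattern_options"]),
            p["pattern_nonuse"],
            tuple(p["hours_options"]),
            p["hours_nonuse"],
        )
    bounds = {k: (int(v[0]), int(v[1])) for k, v in d["category_bounds"].items()}
    return InstrumentDefinition(tuple(items), bounds, probes)


def save_instrument(inst: InstrumentDefinition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_instrument_to_dict(inst), fh, sort_keys=False)


def load_instrument(path) -> InstrumentDefinition:
    with open(path, encoding="utf-8") as fh:
        return _instrument_from_dict(yaml.safe_load(fh))
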