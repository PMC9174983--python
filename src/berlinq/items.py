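"""Berlin Questionnaire instrument definition, risk scoring, and encoding.

The Berlin Questionnaire (BQ) is a ten-item screening instrument for
obstructive sleep apnea (OSA).  Its items form three symptom categories:

* category 1 — snoring (items B1–B5),
* category 2 — daytime somnolence (items B6–B8; B9 is an uncategorised
  frequency follow-up to B8),
* category 3 — hypertension / obesity (item B10, plus BMI > 30 kg/m²).

A category is positive when it accumulates enough frequent-symptom
answers (two or more positive items for categories 1 and 2; a reported
history of hypertension or BMI > 30 for category 3), and a respondent is
scored *high risk* when two or more categories are positive.

The positive-answer rule table is the canonical one of the original
instrument: an answer counts as a positive symptom response when it
reports the symptom at least 3–4 times a week (plus ``Yes`` for the
yes/no items, and loud snoring / witnessed apneas at the lower
``1–2 times a week`` cut-off for B5).  The table is data, not code, so
alternative conventions can be scored for sensitivity analysis.

This module also fixes the ordinal encoding used by all downstream
statistics: each item's levels are coded by their position in canonical
questionnaire order, with two selectable treatments of "Do not know"
(dropped as missing, or kept as the literal middle code).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .printed_tables import (
    BQ_TEXT,
    EXTENDED_TABLES,
    EXTENDED_TEXT,
    FREQ5,
    LOUDNESS,
    NDY,
)

HIGH = "high"
LOW = "low"
MISSING = None
DONT_KNOW = "Do not know"

BQ_ITEM_IDS = tuple(f"B{i}" for i in range(1, 11))
BMI_ITEM_ID = "BMI"
#: default machine-learning feature set: the ten BQ items plus continuous BMI
DEFAULT_FEATURES = BQ_ITEM_IDS + (BMI_ITEM_ID,)

BMI_MIN, BMI_MAX = 10.0, 80.0
BMI_OBESITY_CUTOFF = 30.0

#: positive symptom responses of the original BQ scoring rule
DEFAULT_RULE_TABLE: dict[str, frozenset[str]] = {
    "B1": frozenset({"Yes"}),
    "B2": frozenset({"Louder than talking",
                     "Very loud—it can be heard from adjacent rooms"}),
    "B3": frozenset({"3–4 times a week", "Every day"}),
    "B4": frozenset({"Yes"}),
    "B5": frozenset({"1–2 times a week", "3–4 times a week", "Every day"}),
    "B6": frozenset({"3–4 times a week", "Every day"}),
    "B7": frozenset({"3–4 times a week", "Every day"}),
    "B8": frozenset({"Yes"}),
    "B9": frozenset(),
    "B10": frozenset({"Yes"}),
}

_BQ_LEVELS: dict[str, tuple[str, ...]] = {
    "B1": NDY, "B2": LOUDNESS, "B3": FREQ5, "B4": NDY, "B5": FREQ5,
    "B6": FREQ5, "B7": FREQ5, "B8": NDY, "B9": FREQ5, "B10": NDY,
}
_BQ_CATEGORY: dict[str, int | None] = {
    "B1": 1, "B2": 1, "B3": 1, "B4": 1, "B5": 1,
    "B6": 2, "B7": 2, "B8": 2, "B9": None, "B10": 3,
}
_BQ_PARENT: dict[str, str | None] = {"B2": "B1", "B9": "B8"}


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item: its answer scale and scoring role."""

    item_id: str
    text: str
    levels: tuple[str, ...]
    category: int | None = None
    positive_levels: frozenset[str] = frozenset()
    parent_item: str | None = None
    continuous: bool = False

    def __post_init__(self) -> None:
        if not self.continuous:
            if not self.levels:
                raise ValueError(f"{self.item_id}: empty level list")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"{self.item_id}: duplicate levels")
            if not self.positive_levels <= set(self.levels):
                raise ValueError(f"{self.item_id}: positive levels not a subset")
        if self.category not in (None, 1, 2, 3):
            raise ValueError(f"{self.item_id}: bad category {self.category}")


def load_item_dictionary(
    rule_table: Mapping[str, Iterable[str]] | None = None,
) -> list[ItemDef]:
    """Return all item definitions: B1–B10, the BMI pseudo-item, Q1–Q38.

    ``rule_table`` overrides the default positive-answer rule per BQ item.
    """
    rules = {k: frozenset(v) for k, v in (rule_table or DEFAULT_RULE_TABLE).items()}
    items: list[ItemDef] = []
    for iid in BQ_ITEM_IDS:
        items.append(ItemDef(
            item_id=iid,
            text=BQ_TEXT[iid],
            levels=_BQ_LEVELS[iid],
            category=_BQ_CATEGORY[iid],
            positive_levels=rules.get(iid, frozenset()),
            parent_item=_BQ_PARENT.get(iid),
        ))
    items.append(ItemDef(
        item_id=BMI_ITEM_ID,
        text="Body mass index (kg/m^2)",
        levels=(),
        category=3,
        continuous=True,
    ))
    for tab in EXTENDED_TABLES:
        items.append(ItemDef(
            item_id=tab.item_id,
            text=EXTENDED_TEXT[tab.item_id],
            levels=tab.levels,
        ))
    return items


ITEMS: dict[str, ItemDef] = {it.item_id: it for it in load_item_dictionary()}


def item_dictionary_json() -> list[dict]:
    """Data dictionary in a JSON-serialisable form."""
    return [
        {
            "item_id": it.item_id,
            "text": it.text,
            "levels": list(it.levels),
            "category": it.category,
            "positive_levels": sorted(it.positive_levels),
            "parent_item": it.parent_item,
            "continuous": it.continuous,
        }
        for it in ITEMS.values()
    ]


# --- subject records ---------------------------------------------------------


@dataclass
class SubjectRecord:
    """One respondent: answers by item id (level label or None) and BMI."""

    subject_id: str
    answers: dict[str, str | None] = field(default_factory=dict)
    bmi: float | None = None

    def answer(self, item_id: str) -> str | None:
        return self.answers.get(item_id, MISSING)


class RecordError(ValueError):
    """A subject record violates the questionnaire schema."""


def validate_record(record: SubjectRecord,
                    items: Mapping[str, ItemDef] = ITEMS) -> None:
    """Raise :class:`RecordError` on any illegal answer or BMI value."""
    for iid, ans in record.answers.items():
        if ans is MISSING:
            continue
        item = items.get(iid)
        if item is None:
            raise RecordError(f"{record.subject_id}: unknown item {iid!r}")
        if item.continuous:
            raise RecordError(f"{record.subject_id}: {iid} takes numeric values")
        if ans not in item.levels:
            raise RecordError(
                f"{record.subject_id}: {ans!r} is not a level of {iid}")
    if record.bmi is not None:
        if not (BMI_MIN <= record.bmi <= BMI_MAX) or math.isnan(record.bmi):
            raise RecordError(
                f"{record.subject_id}: BMI {record.bmi} outside "
                f"[{BMI_MIN}, {BMI_MAX}]")


# --- scoring -----------------------------------------------------------------


@dataclass(frozen=True)
class CategoryScores:
    cat1_positive: bool
    cat2_positive: bool
    cat3_positive: bool

    @property
    def positive_count(self) -> int:
        return int(self.cat1_positive) + int(self.cat2_positive) + int(self.cat3_positive)


def _is_positive(record: SubjectRecord, item: ItemDef) -> bool:
    ans = record.answer(item.item_id)
    return ans is not MISSING and ans in item.positive_levels


def score_categories(record: SubjectRecord,
                     items: Mapping[str, ItemDef] = ITEMS,
                     validate: bool = True) -> CategoryScores:
    """Evaluate the three BQ symptom categories for one respondent.

    Missing answers (and "Do not know") never count as positive; a
    category is simply evaluated from the answers that are available.
    """
    if validate:
        validate_record(record, items)
    cat1 = sum(_is_positive(record, items[i]) for i in ("B1", "B2", "B3", "B4", "B5"))
    cat2 = sum(_is_positive(record, items[i]) for i in ("B6", "B7", "B8"))
    cat3 = (_is_positive(record, items["B10"])
            or (record.bmi is not None and record.bmi > BMI_OBESITY_CUTOFF))
    return CategoryScores(cat1 >= 2, cat2 >= 2, bool(cat3))


def classify_risk(record: SubjectRecord,
                  items: Mapping[str, ItemDef] = ITEMS,
                  validate: bool = True) -> str:
    """BQ risk label: ``"high"`` iff two or more categories are positive."""
    scores = score_categories(record, items, validate=validate)
    return HIGH if scores.positive_count >= 2 else LOW


# --- cohort containers and encoding ------------------------------------------

Cohort = Union[Sequence[SubjectRecord], pd.DataFrame]


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a DataFrame (subject_id, B1..B10, BMI, Q1..Q38 columns)."""
    if isinstance(cohort, pd.DataFrame):
        return cohort
    rows = []
    for rec in cohort:
        row = {"subject_id": rec.subject_id, BMI_ITEM_ID: rec.bmi}
        row.update(rec.answers)
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = ["subject_id"] + [c for c in ITEMS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    return frame[ordered + extra]


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Inverse of :func:`cohort_to_frame`; NaN/None cells become MISSING."""
    records = []
    item_cols = [c for c in frame.columns if c in ITEMS and c != BMI_ITEM_ID]
    for idx, row in frame.iterrows():
        answers = {}
        for c in item_cols:
            v = row[c]
            answers[c] = None if (v is None or (isinstance(v, float) and math.isnan(v))) else v
        bmi = row.get(BMI_ITEM_ID)
        bmi = None if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)) else float(bmi)
        sid = str(row["subject_id"]) if "subject_id" in frame.columns else str(idx)
        records.append(SubjectRecord(sid, answers, bmi))
    return records


def as_records(cohort: Cohort) -> list[SubjectRecord]:
    if isinstance(cohort, pd.DataFrame):
        return frame_to_records(cohort)
    return list(cohort)


DontKnowPolicy = Literal["as_missing", "as_middle"]


@dataclass(frozen=True)
class EncodingPolicy:
    """Ordinal coding convention for converting answers to numbers.

    ``dontknow="as_missing"`` drops "Do not know" (the remaining levels
    are re-indexed, so yes/no items code No=0, Yes=1); ``"as_middle"``
    keeps it at its literal middle position (No=0, Do not know=1, Yes=2).
    Missing answers always become NaN.
    """

    dontknow: DontKnowPolicy = "as_missing"

    def codes(self, item: ItemDef) -> dict[str, float]:
        """Map each level label to its numeric code (NaN = treat as missing)."""
        if item.continuous:
            raise ValueError(f"{item.item_id} is continuous; no level codes")
        if self.dontknow == "as_missing":
            kept = [lv for lv in item.levels if lv != DONT_KNOW]
            out = {lv: float(i) for i, lv in enumerate(kept)}
            for lv in item.levels:
                out.setdefault(lv, float("nan"))
            return out
        return {lv: float(i) for i, lv in enumerate(item.levels)}

    def decode(self, item: ItemDef, code: float) -> str:
        """Level label for a numeric code (inverse of :meth:`codes`)."""
        inverse = {v: k for k, v in self.codes(item).items() if not math.isnan(v)}
        return inverse[float(code)]


@dataclass
class EncodedDataset:
    """Numeric design matrix plus scorer-derived labels.

    ``X`` holds ordinal codes with NaN for missing; ``y`` is 1 for high
    risk, 0 for low — always recomputed by :func:`classify_risk`, never
    supplied externally.
    """

    X: np.ndarray
    feature_ids: list[str]
    y: np.ndarray
    policy: EncodingPolicy

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def column(self, item_id: str) -> np.ndarray:
        return self.X[:, self.feature_ids.index(item_id)]


def encode_cohort(cohort: Cohort,
                  policy: EncodingPolicy | None = None,
                  features: Sequence[str] = DEFAULT_FEATURES,
                  items: Mapping[str, ItemDef] = ITEMS) -> EncodedDataset:
    """Encode a cohort into a numeric matrix, recomputing risk labels."""
    records = as_records(cohort)
    if not records:
        raise ValueError("empty cohort")
    policy = policy or EncodingPolicy()
    codes = {f: (None if items[f].continuous else policy.codes(items[f]))
             for f in features}
    X = np.full((len(records), len(features)), np.nan)
    y = np.zeros(len(records), dtype=int)
    for r, rec in enumerate(records):
        validate_record(rec, items)
        for c, f in enumerate(features):
            if items[f].continuous:
                if rec.bmi is not None:
                    X[r, c] = rec.bmi
            else:
                ans = rec.answer(f)
                if ans is not MISSING:
                    X[r, c] = codes[f][ans]
        y[r] = int(classify_risk(rec, items, validate=False) == HIGH)
    return EncodedDataset(X, list(features), y, policy)
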