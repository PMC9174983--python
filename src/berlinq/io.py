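"""CSV formats, validation, run manifests and report assembly.

Subject-level data travels as UTF-8 CSV with a header row and one row per
subject.  Two dialects are supported:

* ``labels`` — cells hold the printed answer labels ("Every day");
* ``codes`` — cells hold the integer position of the answer in canonical
  level order (so for yes/no items 0=No, 1=Do not know, 2=Yes).

Empty cells mean MISSING in both dialects; BMI is numeric in both.
Grouped counts are accepted as long-format CSV with columns
``item,level,class,count`` (class ``low``/``high``; level ``missing``
for unanswered respondents).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .items import (
    BMI_ITEM_ID,
    BMI_MAX,
    BMI_MIN,
    ITEMS,
    ItemDef,
)
from .printed_tables import ClassConditionalTable


@dataclass
class ValidationReport:
    rows_read: int = 0
    rows_kept: int = 0
    problems: list[str] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return self.rows_read - self.rows_kept

    @property
    def ok(self) -> bool:
        return not self.problems


def _is_empty(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) \
        or (isinstance(value, str) and value.strip() == "")


def _decode_cell(item: ItemDef, raw, dialect: str, problems: list[str],
                 row_label: str) -> tuple[str | None, bool]:
    """Return (level or None, ok)."""
    if _is_empty(raw):
        return None, True
    if dialect == "labels":
        value = str(raw)
        if value not in item.levels:
            problems.append(f"{row_label}: {value!r} is not a level of {item.item_id}")
            return None, False
        return value, True
    try:
        code = int(float(raw))
    except (TypeError, ValueError):
        problems.append(f"{row_label}: non-integer code {raw!r} for {item.item_id}")
        return None, False
    if not 0 <= code < len(item.levels):
        problems.append(f"{row_label}: code {code} out of range for {item.item_id}")
        return None, False
    return item.levels[code], True


def read_cohort_csv(path, dialect: str = "labels",
                    items: Mapping[str, ItemDef] = ITEMS,
                    ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a subject-level CSV; invalid rows are rejected.

    Returns the kept rows as a labels-dialect DataFrame plus a report of
    every rejected row with its diagnostic.
    """
    if dialect not in ("labels", "codes"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, dtype=object)
    item_cols = [c for c in raw.columns if c in items and not items[c].continuous]
    if not item_cols:
        raise ValueError("no recognised item columns in header")
    if "subject_id" in raw.columns and raw["subject_id"].duplicated().any():
        dupes = raw["subject_id"][raw["subject_id"].duplicated()].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")

    report = ValidationReport(rows_read=len(raw))
    kept_rows = []
    for i, row in raw.iterrows():
        sid = row.get("subject_id", f"row{i}")
        problems_before = len(report.problems)
        out: dict[str, object] = {"subject_id": sid}
        for c in item_cols:
            level, ok = _decode_cell(items[c], row[c], dialect,
                                     report.problems, str(sid))
            out[c] = level
        if BMI_ITEM_ID in raw.columns:
            bmi_raw = row[BMI_ITEM_ID]
            if _is_empty(bmi_raw):
                out[BMI_ITEM_ID] = np.nan
            else:
                try:
                    bmi = float(bmi_raw)
                except (TypeError, ValueError):
                    bmi = float("nan")
                if math.isnan(bmi) or not BMI_MIN <= bmi <= BMI_MAX:
                    report.problems.append(f"{sid}: bad BMI value {bmi_raw!r}")
                else:
                    out[BMI_ITEM_ID] = bmi
        if len(report.problems) == problems_before:
            kept_rows.append(out)
    report.rows_kept = len(kept_rows)
    cols = ["subject_id"] + [c for c in raw.columns if c != "subject_id"]
    frame = pd.DataFrame(kept_rows, columns=[c for c in cols if c == "subject_id"
                                             or c in item_cols or c == BMI_ITEM_ID])
    return frame, report


def write_cohort_csv(frame: pd.DataFrame, path, dialect: str = "labels",
                     items: Mapping[str, ItemDef] = ITEMS) -> None:
    """Write a labels-dialect cohort frame to CSV in either dialect."""
    if dialect not in ("labels", "codes"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = frame.copy()
    if dialect == "codes":
        for c in out.columns:
            item = items.get(c)
            if item is None or item.continuous:
                continue
            mapping = {lv: i for i, lv in enumerate(item.levels)}
            out[c] = out[c].map(lambda v: "" if _is_empty(v) else mapping[v])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_grouped_csv(path) -> list[ClassConditionalTable]:
    """Read long-format grouped counts (item,level,class,count)."""
    frame = pd.read_csv(path)
    required = {"item", "level", "class", "count"}
    if not required <= set(frame.columns):
        raise ValueError(f"grouped CSV needs columns {sorted(required)}")
    tables = []
    for item_id, grp in frame.groupby("item", sort=False):
        levels, low, high = [], {}, {}
        missing = {"low": 0, "high": 0}
        for _, r in grp.iterrows():
            klass = str(r["class"])
            if str(r["level"]) == "missing":
                missing[klass] = int(r["count"])
                continue
            lv = str(r["level"])
            if lv not in levels:
                levels.append(lv)
            (low if klass == "low" else high)[lv] = int(r["count"])
        tables.append(ClassConditionalTable(
            item_id=str(item_id), levels=tuple(levels),
            counts_low=tuple(low.get(lv, 0) for lv in levels),
            counts_high=tuple(high.get(lv, 0) for lv in levels),
            missing_low=missing["low"], missing_high=missing["high"]))
    return tables


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config: dict
    seed: int
    inputs: list[str]
    outputs: list[str]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc)
        .isoformat(timespec="seconds"))


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2,
                                     default=str) + "\n", encoding="utf-8")


def write_report(bundle: Mapping[str, object], outdir) -> list[Path]:
    """Assemble a Markdown + CSV report from any pipeline stage's results.

    Recognised bundle keys (all optional): ``summary`` (DataFrame),
    ``discrimination`` (DataFrame), ``curve`` (DataFrame),
    ``frequencies`` (Series), ``cooccurrence`` (DataFrame),
    ``selected_items`` (iterable of item ids).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    lines = ["# Berlin Questionnaire analysis report", ""]

    for key, fname, title in (("summary", "summary_table.csv", "Group summary"),
                              ("discrimination", "discrimination_scores.csv",
                               "Single-variable discrimination"),
                              ("curve", "selection_curve.csv",
                               "AUROC vs number of features"),
                              ("cooccurrence", "cooccurrence.csv",
                               "Best-subset co-occurrence")):
        obj = bundle.get(key)
        if obj is None:
            continue
        p = outdir / fname
        obj.to_csv(p, index=key == "cooccurrence")
        written.append(p)
        lines += [f"## {title}", "", f"See `{fname}`.", ""]

    freqs = bundle.get("frequencies")
    if freqs is not None:
        p = outdir / "selection_frequencies.csv"
        freqs.rename("frequency").to_csv(p)
        written.append(p)
        lines += ["## Selection frequencies", "", "See `selection_frequencies.csv`.", ""]

    selected = bundle.get("selected_items")
    if selected is not None:
        lines += ["## Reduced questionnaire", ""]
        for iid in selected:
            item = ITEMS[iid]
            lines.append(f"* **{iid}** — {item.text}")
            for lv in item.levels:
                lines.append(f"    * {lv}")
        lines.append("")

    md = outdir / "report.md"
    md.write_text("\n".join(lines), encoding="utf-8")
    written.append(md)
    return written
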