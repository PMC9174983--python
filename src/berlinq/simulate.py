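"""Synthetic survey-cohort generator calibrated to the reference tables.

The raw individual-level survey responses behind the reference cohort were
never deposited, so this module generates stand-in cohorts whose
class-conditional item distributions match the published per-group answer
counts.  The sampling model is:

1. draw a latent risk class per subject, Bernoulli(prevalence), default
   prevalence 0.20 (76/387 high in the reference cohort);
2. draw every item's answer independently from that item's
   class-conditional distribution (published counts normalised, with the
   unanswered mass included as an explicit "missing" outcome);
3. draw a BMI group from the class-conditional BMI-group table, then a
   continuous BMI uniformly within the group's range (top group capped at
   46 kg/m², the survey maximum);
4. enforce follow-up skip logic: a subject answering "No" to B1 (do you
   snore?) skips B2 (loudness), and one answering "No" to B8 (dozing at
   the wheel) skips B9 (how often).

The usable high/low label of a synthetic subject is *recomputed* by the
deterministic BQ scorer, never copied from the latent class, preserving
the deterministic label–feature relationship of the real study.  Items
are conditionally independent given the latent class (only per-class
marginals are published); see the methods note for what this does and
does not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .items import BMI_ITEM_ID, HIGH, ITEMS, classify_risk, frame_to_records
from .printed_tables import (
    ALL_TABLES,
    BMI_BIN_EDGES,
    BQ_TABLES,
    ClassConditionalTable,
    get_table,
)

logger = logging.getLogger(__name__)

_MISSING_TOKEN = "__missing__"

#: follow-up gating: child item -> (parent item, parent answer that closes the gate)
SKIP_GATES: dict[str, tuple[str, str]] = {"B2": ("B1", "No"), "B9": ("B8", "No")}


def default_conditionals() -> list[ClassConditionalTable]:
    """All published class-conditional tables (BQ items B1–B10 and Q1–Q38)."""
    return list(ALL_TABLES)


def bq_conditionals() -> list[ClassConditionalTable]:
    """Class-conditional tables of the ten BQ items only."""
    return list(BQ_TABLES)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the reference survey: 387 subjects, 20% latent
    high-class prevalence, published class-conditional answer tables for
    every item, BMI-group table for continuous BMI, skip logic enabled.
    """

    n_subjects: int = 387
    prevalence: float = 0.20
    conditionals: Sequence[ClassConditionalTable] = field(default_factory=default_conditionals)
    bmi_groups: ClassConditionalTable = field(default_factory=lambda: get_table("Q3"))
    bmi_bins: tuple[tuple[float, float], ...] = BMI_BIN_EDGES
    skip_logic: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")
        if len(self.bmi_bins) != len(self.bmi_groups.levels):
            raise ValueError("bmi_bins must match the BMI-group levels")
        for (lo, hi) in self.bmi_bins:
            if not lo < hi:
                raise ValueError(f"degenerate BMI bin ({lo}, {hi})")


def _class_probs(table: ClassConditionalTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-class outcome probabilities over levels + trailing missing mass."""
    low = np.array(table.counts_low + (table.missing_low,), dtype=float)
    high = np.array(table.counts_high + (table.missing_high,), dtype=float)
    return low / low.sum(), high / high.sum()


def _sample_outcomes(rng: np.random.Generator, table: ClassConditionalTable,
                     latent_high: np.ndarray) -> np.ndarray:
    """Sample level indices (len(levels) means missing) for every subject."""
    p_low, p_high = _class_probs(table)
    k = len(p_low)
    out = np.empty(latent_high.size, dtype=int)
    idx_low = np.flatnonzero(~latent_high)
    idx_high = np.flatnonzero(latent_high)
    out[idx_low] = rng.choice(k, size=idx_low.size, p=p_low)
    out[idx_high] = rng.choice(k, size=idx_high.size, p=p_high)
    return out


def generate_cohort(config: GeneratorConfig | None = None,
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a cohort; returns ``(frame, latent_high)``.

    The frame has one row per subject with level-label columns and a
    continuous ``BMI`` column; missing answers are ``None``.  The latent
    class vector is returned for generator diagnostics only — analysis
    labels must come from the BQ scorer.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    latent = rng.random(n) < config.prevalence

    columns: dict[str, object] = {
        "subject_id": [f"S{i + 1:05d}" for i in range(n)]}
    bmi_group_item = config.bmi_groups.item_id

    for table in config.conditionals:
        if table.item_id == bmi_group_item:
            continue  # derived from the BMI draw below
        idx = _sample_outcomes(rng, table, latent)
        lv = np.array(table.levels + (_MISSING_TOKEN,), dtype=object)
        columns[table.item_id] = lv[idx]

    # BMI group, then continuous BMI uniform within the group's range
    gidx = _sample_outcomes(rng, config.bmi_groups, latent)
    gidx = np.minimum(gidx, len(config.bmi_bins) - 1)  # missing mass -> top bin guard
    lo = np.array([b[0] for b in config.bmi_bins])[gidx]
    hi = np.array([b[1] for b in config.bmi_bins])[gidx]
    columns[BMI_ITEM_ID] = lo + rng.random(n) * (hi - lo)
    if any(t.item_id == bmi_group_item for t in config.conditionals):
        columns[bmi_group_item] = np.array(config.bmi_groups.levels, dtype=object)[gidx]

    frame = pd.DataFrame(columns)

    if config.skip_logic:
        for child, (parent, closing) in SKIP_GATES.items():
            if child in frame.columns and parent in frame.columns:
                frame.loc[frame[parent] == closing, child] = _MISSING_TOKEN

    frame = frame.replace({_MISSING_TOKEN: None})
    # column order: subject_id, items in dictionary order, BMI
    known = [c for c in ITEMS if c in frame.columns]
    frame = frame[["subject_id"] + known]
    return frame, latent


def scorer_labels(frame: pd.DataFrame) -> np.ndarray:
    """Recompute the usable high/low label for every row (1 = high)."""
    return np.array([classify_risk(rec) == HIGH for rec in frame_to_records(frame)],
                    dtype=int)


def apply_missingness(frame: pd.DataFrame, rates: Mapping[str, float],
                      seed: int) -> pd.DataFrame:
    """Add completely-at-random missingness at per-item rates.

    Cells already missing (e.g. via skip logic) stay missing.
    """
    for item, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate {rate} for {item} outside [0, 1]")
        if item not in frame.columns:
            raise KeyError(f"unknown item {item!r}")
    rng = np.random.default_rng(seed)
    out = frame.copy()
    for item, rate in rates.items():
        mask = rng.random(len(out)) < rate
        out.loc[mask, item] = np.nan if item == BMI_ITEM_ID else None
    return out


def goodness_of_fit(frame: pd.DataFrame, latent_high: np.ndarray,
                    config: GeneratorConfig) -> pd.DataFrame:
    """Per-item chi-square goodness of fit against the configured conditionals.

    For gated follow-up items the comparison is restricted to subjects
    whose gate is open (the configured distribution applies only there);
    for all other items the full class subpopulation is used.  BMI is
    checked through its group bins.  Returns one row per item and class
    with the chi-square statistic, degrees of freedom and p-value.
    """
    latent_high = np.asarray(latent_high, dtype=bool)
    rows = []
    tables = list(config.conditionals)
    if all(t.item_id != config.bmi_groups.item_id for t in tables):
        tables.append(config.bmi_groups)
    for table in tables:
        item = table.item_id
        if item == config.bmi_groups.item_id:
            edges = [b[0] for b in config.bmi_bins] + [config.bmi_bins[-1][1]]
            binned = pd.cut(frame[BMI_ITEM_ID], bins=edges, right=False,
                            include_lowest=True,
                            labels=list(table.levels))
            observed_col = binned.astype(object)
        else:
            observed_col = frame[item]
        gate = np.ones(len(frame), dtype=bool)
        if config.skip_logic and item in SKIP_GATES:
            parent, closing = SKIP_GATES[item]
            gate = (frame[parent] != closing).to_numpy()
        for klass, mask in (("low", ~latent_high & gate), ("high", latent_high & gate)):
            probs = _class_probs(table)["low high".split().index(klass)]
            sub = observed_col[mask]
            obs = np.array(
                [int((sub == lv).sum()) for lv in table.levels] + [int(sub.isna().sum())],
                dtype=float)
            keep = probs > 0
            if np.any(obs[~keep] > 0):
                rows.append({"item_id": item, "klass": klass, "n": int(obs.sum()),
                             "statistic": np.inf, "dof": int(keep.sum() - 1),
                             "p_value": 0.0})
                continue
            obs_k, probs_k = obs[keep], probs[keep]
            if len(obs_k) < 2 or obs_k.sum() == 0:
                continue
            expected = probs_k / probs_k.sum() * obs_k.sum()
            stat, p = stats.chisquare(obs_k, expected)
            rows.append({"item_id": item, "klass": klass, "n": int(obs_k.sum()),
                         "statistic": float(stat), "dof": len(obs_k) - 1,
                         "p_value": float(p)})
    return pd.DataFrame(rows)
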