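"""Single-variable discrimination scores: Fisher score and rank AUROC.

Two complementary univariate separability indices between the low- and
high-risk groups:

* the Fisher score ``F = (x̄_low − x̄_high)² / (σ²_low + σ²_high)``, with
  population (divide-by-n) class variances — the ratio of inter-class
  distance to total intra-class variance;
* the rank-based AUROC, the probability that a randomly drawn high-risk
  value exceeds a randomly drawn low-risk one, ties credited one half —
  identical to the Mann–Whitney U statistic divided by ``n_low·n_high``.

Both are computable from individual values or in closed form from
grouped level-by-class counts (:func:`grouped_scores`), which is how the
published values are reproduced from summary tables alone.  AUROC
orientation follows the coding direction (more symptomatic codes score
toward the high class); it is never flipped to the larger of ``a`` and
``1 − a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

import pandas as pd

from .items import EncodedDataset, EncodingPolicy, ItemDef
from .printed_tables import ClassConditionalTable


@dataclass(frozen=True)
class DiscriminationScore:
    item_id: str
    fisher_f: float
    auroc: float
    n_low: int
    n_high: int
    policy: EncodingPolicy

    def __post_init__(self) -> None:
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError(f"AUROC {self.auroc} outside [0, 1]")


def fisher_score(values_low, values_high) -> float:
    """Fisher score between two samples (population variances).

    Returns ``inf`` when both variances vanish but the means differ, and
    0 when the two samples are constant and equal.
    """
    low = np.asarray(values_low, dtype=float)
    high = np.asarray(values_high, dtype=float)
    if low.size == 0 or high.size == 0:
        raise ValueError("both classes must be non-empty")
    diff = low.mean() - high.mean()
    denom = low.var() + high.var()  # ddof=0
    if denom == 0.0:
        return math.inf if diff != 0.0 else 0.0
    return float(diff * diff / denom)


def rank_auroc(values_low, values_high) -> float:
    """AUROC of high vs low values: (high>low pairs + ½ ties) / (n_l·n_h)."""
    low = np.asarray(values_low, dtype=float)
    high = np.asarray(values_high, dtype=float)
    if low.size == 0 or high.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(np.concatenate([low, high]))
    r_high = ranks[low.size:].sum()
    u = r_high - high.size * (high.size + 1) / 2.0
    return float(u / (low.size * high.size))


def _grouped_moments(codes: np.ndarray, counts: np.ndarray) -> tuple[float, float, int]:
    n = int(counts.sum())
    mean = float((codes * counts).sum() / n)
    var = float((counts * (codes - mean) ** 2).sum() / n)
    return mean, var, n


def grouped_scores(table: ClassConditionalTable,
                   policy: EncodingPolicy | None = None) -> DiscriminationScore:
    """Closed-form Fisher score and AUROC from level-by-class counts.

    Identical to expanding the counts into individual subjects and
    calling :func:`fisher_score` / :func:`rank_auroc`, but O(levels²).
    Levels coded per ``policy`` ("Do not know" dropped by default);
    explicitly missing respondents are always excluded.
    """
    policy = policy or EncodingPolicy()
    code_map = policy.codes(ItemDef(table.item_id, "", table.levels))
    keep = [i for i, lv in enumerate(table.levels) if not math.isnan(code_map[lv])]
    codes = np.array([code_map[table.levels[i]] for i in keep])
    c_low = np.array([table.counts_low[i] for i in keep], dtype=float)
    c_high = np.array([table.counts_high[i] for i in keep], dtype=float)
    if c_low.sum() == 0 or c_high.sum() == 0:
        raise ValueError(f"{table.item_id}: a class is empty after missing removal")

    order = np.argsort(codes)
    codes, c_low, c_high = codes[order], c_low[order], c_high[order]
    m_low, v_low, n_low = _grouped_moments(codes, c_low)
    m_high, v_high, n_high = _grouped_moments(codes, c_high)
    denom = v_low + v_high
    if denom == 0.0:
        f = math.inf if m_low != m_high else 0.0
    else:
        f = (m_low - m_high) ** 2 / denom

    # pair counting over sorted distinct codes
    cum_low = np.concatenate([[0.0], np.cumsum(c_low)])
    wins = float((c_high * cum_low[:-1]).sum())      # high strictly above low
    ties = float((c_high * c_low).sum())
    auroc = (wins + 0.5 * ties) / (n_low * n_high)
    return DiscriminationScore(table.item_id, float(f), float(auroc),
                               n_low, n_high, policy)


def score_all(dataset: EncodedDataset) -> list[DiscriminationScore]:
    """Score every feature of an encoded cohort, best discriminators first.

    Sorted by AUROC descending, ties by Fisher score descending, then by
    feature order.  Per feature, rows with a missing value are dropped.
    """
    if dataset.n_subjects == 0:
        raise ValueError("empty dataset")
    scores = []
    for pos, item_id in enumerate(dataset.feature_ids):
        col = dataset.column(item_id)
        ok = ~np.isnan(col)
        low, high = col[ok & (dataset.y == 0)], col[ok & (dataset.y == 1)]
        scores.append((pos, DiscriminationScore(
            item_id, fisher_score(low, high), rank_auroc(low, high),
            int(low.size), int(high.size), dataset.policy)))
    scores.sort(key=lambda t: (-t[1].auroc, -t[1].fisher_f, t[0]))
    return [s for _, s in scores]


def scores_frame(scores: list[DiscriminationScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"item_id": s.item_id, "auroc": s.auroc, "fisher_f": s.fisher_f,
          "n_low": s.n_low, "n_high": s.n_high} for s in scores])


class DiscriminationRanker(BaseEstimator):
    """Univariate feature ranker over an encoded design matrix.

    A scikit-learn style estimator: ``fit(X, y)`` computes the Fisher
    score and rank AUROC of every column against the binary label
    (missing values dropped per column) and exposes the ranking.

    Attributes
    ----------
    scores_ : pandas.DataFrame
        One row per feature (item_id, auroc, fisher_f, n_low, n_high),
        sorted best-first.
    ranking_ : list of str
        Feature names, best discriminator first.
    """

    def __init__(self, policy: EncodingPolicy | None = None):
        self.policy = policy

    def fit(self, X, y):
        feature_ids = (list(X.columns) if isinstance(X, pd.DataFrame)
                       else [f"x{i}" for i in range(np.asarray(X).shape[1])])
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=int)
        if Xa.shape[0] != ya.shape[0]:
            raise ValueError("X and y length mismatch")
        ds = EncodedDataset(Xa, feature_ids, ya,
                            self.policy or EncodingPolicy())
        ranked = score_all(ds)
        self.feature_names_in_ = np.array(feature_ids, dtype=object)
        self.n_features_in_ = len(feature_ids)
        self.scores_ = scores_frame(ranked)
        self.ranking_ = [s.item_id for s in ranked]
        return self

    def top(self, k: int) -> list[str]:
        check_is_fitted(self, "ranking_")
        return self.ranking_[:k]
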