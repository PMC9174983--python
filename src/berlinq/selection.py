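"""Robustness-voted backward sequential feature selection (bSFS).

The procedure reduces a questionnaire to a small item subset whose
trained-classifier output reproduces the full instrument's risk label:

1. split the cohort into a feature-selection part P1 (70%) and a quality
   assessment part P2 (30%), stratified by label;
2. at each elimination step, repeat one backward-elimination move R times
   (default 100) on reshuffled P1 with a reseeded classifier, each time
   *downvoting* the feature whose removal costs the least internal
   AUROC; remove the feature downvoted most often;
3. after each removal, estimate the surviving subset's AUROC on P2 as the
   mean ± SD over ``eval_reps`` (default 50) reseeded refits;
4. iterate until one feature remains, yielding an AUROC-vs-cardinality
   curve and a removal order (least predictive first);
5. repeat the whole procedure over many P1/P2 splits (default 60) and
   aggregate which features appear in the size-k best subsets, including
   their pairwise co-occurrence matrix;
6. evaluate candidate reduced questionnaires by repeated stratified
   k-fold cross-validation on the full cohort.

The default classifier is gradient-boosted trees (XGBoost), whose
sparsity-aware split finding consumes the questionnaires' missing
answers natively, with no imputation.  Any object implementing the small
``fit`` / ``score`` / ``with_seed`` contract can stand in, which the test
suite uses to validate the machinery against closed-form oracles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .discrim import rank_auroc
from .items import EncodedDataset

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@runtime_checkable
class ClassifierSpec(Protocol):
    """Trainable binary scorer: higher score means higher risk."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierSpec": ...

    def score(self, X: np.ndarray) -> np.ndarray: ...

    def with_seed(self, seed: int) -> "ClassifierSpec": ...


class XGBoostScorer:
    """Gradient-boosted tree scorer with native missing-value handling.

    Thin wrapper over ``xgboost.train``; missing entries (NaN) are routed
    by sparsity-aware split finding, so no imputation is performed.
    Stochastic gradient boosting (row subsampling, default 0.8) makes the
    fit seed-sensitive, which is what gives the protocol's repeated
    reseeded refits a meaningful spread; set ``subsample=1.0`` for a
    fully deterministic learner.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 3,
                 learning_rate: float = 0.1, seed: int = 0,
                 subsample: float = 0.8, **params):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.seed = seed
        self.subsample = subsample
        self.params = params
        self._booster: xgb.Booster | None = None

    def with_seed(self, seed: int) -> "XGBoostScorer":
        return XGBoostScorer(self.n_estimators, self.max_depth,
                             self.learning_rate, int(seed) % _SEED_MOD,
                             self.subsample, **self.params)

    def deterministic(self) -> "XGBoostScorer":
        """Variant without row subsampling (seed-insensitive fit)."""
        return XGBoostScorer(self.n_estimators, self.max_depth,
                             self.learning_rate, self.seed, 1.0, **self.params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "XGBoostScorer":
        train_params = {
            "objective": "binary:logistic",
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "tree_method": "hist",
            "subsample": self.subsample,
            "nthread": 1,
            "seed": self.seed,
            "verbosity": 0,
            **self.params,
        }
        dtrain = xgb.DMatrix(np.asarray(X, dtype=float), label=np.asarray(y))
        self._booster = xgb.train(train_params, dtrain,
                                  num_boost_round=self.n_estimators)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        if self._booster is None:
            raise RuntimeError("scorer is not fitted")
        return self._booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)))


@dataclass
class ProtocolConfig:
    """Tunable parameters of the selection protocol (defaults = study protocol)."""

    train_fraction: float = 0.70
    inner_reps: int = 100      # R: downvote repetitions per elimination step
    eval_reps: int = 50        # reseeded refits per P2 quality estimate
    outer_runs: int = 60       # independent P1/P2 splits aggregated
    cv_folds: int = 5          # folds of the final cross-validated check
    inner_cv: int = 3          # folds of the inner criterion; 1 = single stratified holdout
    subset_size: int = 3       # k: cardinality of the "best" subsets collected
    seed: int = 0
    classifier: ClassifierSpec = field(default_factory=XGBoostScorer)

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1); P1 and P2 "
                             "must both be non-empty")
        for name in ("inner_reps", "eval_reps", "outer_runs", "cv_folds",
                     "subset_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class StepRecord:
    """One elimination step: who was downvoted, who was removed."""

    step: int
    candidates: tuple[str, ...]
    tally: dict[str, int]
    removed: str
    mean_auroc: float | None = None
    sd_auroc: float | None = None


@dataclass
class SelectionTrace:
    """Full record of one protocol run on one P1/P2 split."""

    feature_ids: tuple[str, ...]
    steps: list[StepRecord]
    removal_order: list[str]
    curve: pd.DataFrame            # cardinality, mean_auroc, sd_auroc, features
    train_idx: np.ndarray
    test_idx: np.ndarray

    def subset_at(self, cardinality: int) -> tuple[str, ...]:
        """Features surviving at the given cardinality, in item order."""
        if not 1 <= cardinality <= len(self.feature_ids):
            raise ValueError(f"cardinality {cardinality} out of range")
        removed = set(self.removal_order[: len(self.feature_ids) - cardinality])
        return tuple(f for f in self.feature_ids if f not in removed)


@dataclass
class RunAggregate:
    """Selection frequencies of the size-k best subsets across outer runs."""

    frequencies: pd.Series
    best_subsets: list[tuple[str, ...]]


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if isinstance(dataset, EncodedDataset):
        return dataset.X, dataset.y, tuple(dataset.feature_ids)
    if len(dataset) == 3:
        X, y, names = dataset
        names = tuple(names)
    else:
        X, y = dataset
        names = None
    X = np.asarray(X, dtype=float)
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, np.asarray(y, dtype=int), names


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % _SEED_MOD


def split_dataset(dataset, config: ProtocolConfig,
                  seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Stratified P1/P2 split; |P1| = floor(train_fraction · N)."""
    X, y, _ = _as_xy(dataset)
    config.validate()
    n = len(y)
    if n < 10 or len(np.unique(y)) < 2:
        raise ValueError("need >= 10 rows with both classes for a split")
    n_train = int(np.floor(config.train_fraction * n))
    seed = config.seed if seed is None else seed
    for attempt in range(10):
        tr, te = train_test_split(np.arange(n), train_size=n_train,
                                  stratify=y, random_state=int((seed + attempt) % _SEED_MOD))
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
            if attempt:
                logger.warning("resampled split %d times to keep both classes", attempt)
            return tr, te
    raise ValueError("could not produce a split with both classes in P1 and P2")


def _inner_auroc(classifier: ClassifierSpec, X: np.ndarray, y: np.ndarray,
                 folds: int, seed: int) -> float:
    """Internal criterion: cross-validated (or holdout) AUROC on P1."""
    seed = int(seed) % _SEED_MOD
    if folds <= 1:
        tr, te = train_test_split(np.arange(len(y)), train_size=0.7,
                                  stratify=y, random_state=seed)
        clf = classifier.with_seed(seed).fit(X[tr], y[tr])
        s = clf.score(X[te])
        return rank_auroc(s[y[te] == 0], s[y[te] == 1])
    oof = np.empty(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        clf = classifier.with_seed(seed).fit(X[tr], y[tr])
        oof[te] = clf.score(X[te])
    return rank_auroc(oof[y == 0], oof[y == 1])


def downvote_round(X1: np.ndarray, y1: np.ndarray, candidates: Sequence[int],
                   feature_ids: Sequence[str], config: ProtocolConfig,
                   seed: int, step: int = 0) -> StepRecord:
    """One voted backward-elimination step over ``inner_reps`` repetitions.

    Each repetition shuffles P1, reseeds the classifier, evaluates the
    internal AUROC with each single feature left out (same inner split
    for every candidate, so comparisons are paired), and downvotes the
    feature whose removal loses least.  The step removes the feature
    with the highest tally; ties break toward earlier item order.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two features to run an elimination step")
    rng = np.random.default_rng(seed)
    tally = {feature_ids[c]: 0 for c in candidates}
    # vote with a deterministic learner variant where available: the
    # rep-to-rep variability should come from the prescribed resampling,
    # and paired leave-one-out comparisons are sharper without fit noise
    inner_clf = getattr(config.classifier, "deterministic",
                        lambda: config.classifier)()
    for _ in range(config.inner_reps):
        perm = rng.permutation(len(y1))
        rep_seed = int(rng.integers(_SEED_MOD))
        Xp, yp = X1[perm], y1[perm]
        best_auc, best_feat = -np.inf, None
        for c in candidates:
            cols = [g for g in candidates if g != c]
            auc = _inner_auroc(inner_clf, Xp[:, cols], yp,
                               config.inner_cv, rep_seed)
            if auc > best_auc:  # strict: ties keep the earlier candidate
                best_auc, best_feat = auc, feature_ids[c]
        tally[best_feat] += 1
    max_votes = max(tally.values())
    removed = next(feature_ids[c] for c in candidates
                   if tally[feature_ids[c]] == max_votes)
    return StepRecord(step=step, candidates=tuple(feature_ids[c] for c in candidates),
                      tally=tally, removed=removed)


def evaluate_subset(X1, y1, X2, y2, cols: Sequence[int],
                    config: ProtocolConfig, seed: int) -> tuple[float, float]:
    """Mean ± SD AUROC of a feature subset on P2 over reseeded refits."""
    if len(cols) == 0:
        raise ValueError("empty feature subset")
    if len(np.unique(y2)) < 2:
        raise ValueError("P2 must contain both classes")
    cols = list(cols)
    aurocs = []
    for s in _seeds(seed, config.eval_reps):
        clf = config.classifier.with_seed(int(s)).fit(X1[:, cols], y1)
        scores = clf.score(X2[:, cols])
        aurocs.append(rank_auroc(scores[y2 == 0], scores[y2 == 1]))
    return float(np.mean(aurocs)), float(np.std(aurocs))


def run_protocol(dataset, config: ProtocolConfig,
                 evaluate: bool = True) -> SelectionTrace:
    """Run the full elimination loop from all features down to one.

    Produces the AUROC-vs-cardinality curve (one point per cardinality
    n..1, NaN when ``evaluate=False``) and the removal order.  Fully
    deterministic given the dataset and ``config.seed``.
    """
    X, y, feature_ids = _as_xy(dataset)
    config.validate()
    nf = X.shape[1]
    if nf < 2:
        raise ValueError("need at least two features")
    split_seed, *step_seeds = (int(s) for s in _seeds(config.seed, nf + 1))
    eval_seeds = _seeds(config.seed + 1, nf + 1)
    tr, te = split_dataset((X, y), config, seed=split_seed)
    X1, y1, X2, y2 = X[tr], y[tr], X[te], y[te]

    current = list(range(nf))
    steps: list[StepRecord] = []
    removal_order: list[str] = []
    curve_rows = []

    def _curve_point(card: int, cols: list[int], eval_seed: int,
                     rec: StepRecord | None) -> None:
        if evaluate:
            mean, sd = evaluate_subset(X1, y1, X2, y2, cols, config, eval_seed)
        else:
            mean = sd = float("nan")
        if rec is not None:
            rec.mean_auroc, rec.sd_auroc = mean, sd
        curve_rows.append({"cardinality": card, "mean_auroc": mean,
                           "sd_auroc": sd,
                           "features": tuple(feature_ids[c] for c in cols)})

    _curve_point(nf, current, int(eval_seeds[0]), None)
    for m in range(nf - 1):
        rec = downvote_round(X1, y1, current, feature_ids, config,
                             seed=step_seeds[m], step=m)
        steps.append(rec)
        removal_order.append(rec.removed)
        current = [c for c in current if feature_ids[c] != rec.removed]
        _curve_point(len(current), current, int(eval_seeds[m + 1]), rec)
    removal_order.append(feature_ids[current[0]])  # last survivor, removed "last"

    curve = pd.DataFrame(curve_rows)
    return SelectionTrace(feature_ids, steps, removal_order, curve,
                          np.asarray(tr), np.asarray(te))


def aggregate_runs(dataset, config: ProtocolConfig,
                   evaluate: bool = False) -> RunAggregate:
    """Repeat the protocol over ``outer_runs`` fresh P1/P2 splits.

    Collects the size-k surviving subset of each run and reports each
    feature's selection frequency.  P2 evaluation is skipped by default
    (the aggregate needs only removal orders).
    """
    X, y, feature_ids = _as_xy(dataset)
    config.validate()
    subsets: list[tuple[str, ...]] = []
    for s in _seeds(config.seed, config.outer_runs):
        trace = run_protocol((X, y, feature_ids), replace(config, seed=int(s)),
                             evaluate=evaluate)
        subsets.append(trace.subset_at(config.subset_size))
    counts = pd.Series(0.0, index=list(feature_ids))
    for sub in subsets:
        for f in sub:
            counts[f] += 1
    return RunAggregate(frequencies=counts / len(subsets), best_subsets=subsets)


def cooccurrence(best_subsets: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Normalised co-occurrence matrix of features across best subsets.

    Counts unordered feature pairs over all subsets and divides by the
    total number of pairs, so entries sum to 1 over the upper triangle.
    """
    if not best_subsets:
        raise ValueError("no subsets given")
    pair_counts: dict[tuple[str, str], int] = {}
    total = 0
    for sub in best_subsets:
        for a, b in itertools.combinations(sorted(set(sub)), 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
            total += 1
    if total == 0:
        logger.warning("all subsets are singletons; co-occurrence matrix empty")
        return pd.DataFrame()
    order: list[str] = []
    for sub in best_subsets:
        for f in sub:
            if f not in order:
                order.append(f)
    mat = pd.DataFrame(0.0, index=order, columns=order)
    for (a, b), c in pair_counts.items():
        mat.loc[a, b] = mat.loc[b, a] = c / total
    return mat


def cv_auroc(dataset, subset: Sequence[str] | Sequence[int],
             config: ProtocolConfig) -> tuple[float, float]:
    """Repeated stratified k-fold AUROC of a feature subset on the full data.

    Each repetition reshuffles the fold assignment and reseeds the
    classifier; out-of-fold scores are pooled into one AUROC per
    repetition.  Returns mean ± SD over ``eval_reps`` repetitions.
    """
    X, y, feature_ids = _as_xy(dataset)
    config.validate()
    if len(subset) == 0:
        raise ValueError("empty feature subset")
    cols = [feature_ids.index(f) if isinstance(f, str) else int(f) for f in subset]
    if min(np.bincount(y)) < config.cv_folds:
        raise ValueError("a class has fewer members than cv_folds")
    aurocs = []
    for s in _seeds(config.seed, config.eval_reps):
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=int(s))
        oof = np.empty(len(y))
        for tr, te in skf.split(X, y):
            clf = config.classifier.with_seed(int(s)).fit(X[tr][:, cols], y[tr])
            oof[te] = clf.score(X[te][:, cols])
        aurocs.append(rank_auroc(oof[y == 0], oof[y == 1]))
    return float(np.mean(aurocs)), float(np.std(aurocs))


class VotedBackwardSelector(BaseEstimator):
    """Scikit-learn style transformer around the voted elimination protocol.

    ``fit(X, y)`` runs the full protocol on one stratified P1/P2 split of
    the training data; ``transform`` keeps the ``subset_size`` surviving
    features.  Missing values are allowed (NaN) and consumed natively by
    the boosted-tree scorer.

    Attributes
    ----------
    removal_order_ : list of str
        Features in removal order, least predictive first.
    curve_ : pandas.DataFrame
        AUROC-vs-cardinality curve with SDs.
    support_ : ndarray of bool
        Mask of the surviving ``subset_size`` features.
    trace_ : SelectionTrace
        Full per-step record (downvote tallies, split indices).
    """

    def __init__(self, subset_size: int = 3, train_fraction: float = 0.70,
                 inner_reps: int = 100, eval_reps: int = 50,
                 inner_cv: int = 3, evaluate: bool = True,
                 n_estimators: int = 100, max_depth: int = 3,
                 learning_rate: float = 0.1, random_state: int = 0):
        self.subset_size = subset_size
        self.train_fraction = train_fraction
        self.inner_reps = inner_reps
        self.eval_reps = eval_reps
        self.inner_cv = inner_cv
        self.evaluate = evaluate
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _config(self) -> ProtocolConfig:
        return ProtocolConfig(
            train_fraction=self.train_fraction, inner_reps=self.inner_reps,
            eval_reps=self.eval_reps, inner_cv=self.inner_cv,
            subset_size=self.subset_size, seed=self.random_state,
            classifier=XGBoostScorer(self.n_estimators, self.max_depth,
                                     self.learning_rate))

    def fit(self, X, y):
        names = (tuple(X.columns) if isinstance(X, pd.DataFrame)
                 else tuple(f"x{i}" for i in range(np.asarray(X).shape[1])))
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=int)
        if Xa.ndim != 2 or Xa.shape[0] != ya.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not 1 <= self.subset_size <= Xa.shape[1]:
            raise ValueError("subset_size out of range")
        trace = run_protocol((Xa, ya, names), self._config(),
                             evaluate=self.evaluate)
        self.feature_names_in_ = np.array(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        self.trace_ = trace
        self.removal_order_ = trace.removal_order
        self.curve_ = trace.curve
        selected = set(trace.subset_at(self.subset_size))
        self.support_ = np.array([n in selected for n in names])
        self.selected_features_ = [n for n in names if n in selected]
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
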