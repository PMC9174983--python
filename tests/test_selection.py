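"""Voted backward elimination: splits, downvotes, traces, aggregation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from berlinq.discrim import rank_auroc
from berlinq.selection import (
    ProtocolConfig,
    VotedBackwardSelector,
    aggregate_runs,
    cooccurrence,
    cv_auroc,
    downvote_round,
    evaluate_subset,
    run_protocol,
    split_dataset,
)


class SumScorer:
    """Deterministic stub: score = row sum over non-missing entries."""

    def __init__(self, seed=0):
        self.seed = seed

    def with_seed(self, seed):
        return type(self)(seed)

    def fit(self, X, y):
        return self

    def score(self, X):
        return np.nansum(np.asarray(X, dtype=float), axis=1)


class ConstantScorer(SumScorer):
    """Stub whose scores are all equal: every comparison ties."""

    def score(self, X):
        return np.zeros(len(X))


def _planted(n=300, noise=4, seed=0):
    """Binary label plus a feature that equals it, among pure noise."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.2).astype(int)
    X = np.column_stack([y.astype(float)] +
                        [rng.normal(size=n) for _ in range(noise)])
    names = ("planted",) + tuple(f"noise{i}" for i in range(noise))
    return X, y, names


def _stub_config(**kw):
    defaults = dict(inner_reps=5, eval_reps=3, outer_runs=2, inner_cv=1,
                    seed=0, classifier=SumScorer())
    defaults.update(kw)
    return ProtocolConfig(**defaults)


class TestSplit:
    def test_70_30_floor_rule(self):
        y = np.array([0] * 310 + [1] * 77)
        X = np.zeros((387, 2))
        tr, te = split_dataset((X, y), _stub_config())
        assert (len(tr), len(te)) == (270, 117)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 387

    def test_stratified(self):
        y = np.array([0] * 310 + [1] * 77)
        tr, te = split_dataset((np.zeros((387, 2)), y), _stub_config())
        assert abs(y[tr].mean() - y.mean()) < 0.01

    def test_deterministic(self):
        y = np.array([0, 1] * 20)
        X = np.zeros((40, 2))
        a = split_dataset((X, y), _stub_config(seed=3))
        b = split_dataset((X, y), _stub_config(seed=3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset((np.zeros((40, 2)), np.array([0, 1] * 20)),
                          _stub_config(train_fraction=1.0))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset((np.zeros((40, 2)), np.zeros(40, dtype=int)),
                          _stub_config())


class TestDownvote:
    def test_single_rep_is_one_hot(self):
        X, y, names = _planted(seed=1)
        rec = downvote_round(X, y, range(5), names, _stub_config(inner_reps=1),
                             seed=0)
        assert sum(rec.tally.values()) == 1
        assert rec.tally[rec.removed] == 1

    def test_tally_sums_to_reps(self):
        X, y, names = _planted(seed=1)
        rec = downvote_round(X, y, range(5), names, _stub_config(inner_reps=7),
                             seed=0)
        assert sum(rec.tally.values()) == 7

    def test_noise_downvoted_not_signal(self):
        X, y, names = _planted(n=200, noise=1, seed=2)
        rec = downvote_round(X, y, [0, 1], names, _stub_config(inner_reps=10),
                             seed=0)
        assert rec.removed == "noise0"
        assert rec.tally["noise0"] >= 9

    def test_tie_breaks_to_earlier_item(self):
        X, y, names = _planted(seed=3)
        rec = downvote_round(X, y, range(5), names,
                             _stub_config(classifier=ConstantScorer()), seed=0)
        assert rec.removed == "planted"  # all tie; earliest item wins

    def test_needs_two_features(self):
        X, y, names = _planted()
        with pytest.raises(ValueError):
            downvote_round(X, y, [0], names, _stub_config(), seed=0)


class TestEvaluateSubset:
    def test_label_feature_perfect(self):
        X, y, _ = _planted(seed=4)
        mean, sd = evaluate_subset(X[:200], y[:200], X[200:], y[200:], [0],
                                   _stub_config(), seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_oracle_equivalence_with_stub(self):
        """eval_reps=1 with a fixed scoring stub reduces to rank_auroc."""
        X, y, _ = _planted(seed=5)
        X1, y1, X2, y2 = X[:200], y[:200], X[200:], y[200:]
        cols = [0, 2, 3]
        mean, sd = evaluate_subset(X1, y1, X2, y2, cols,
                                   _stub_config(eval_reps=1), seed=9)
        s = SumScorer().score(X2[:, cols])
        assert mean == pytest.approx(rank_auroc(s[y2 == 0], s[y2 == 1]))
        assert sd == 0.0

    def test_single_class_p2_rejected(self):
        X, y, _ = _planted(seed=4)
        with pytest.raises(ValueError):
            evaluate_subset(X[:200], y[:200], X[200:], np.zeros(100, dtype=int),
                            [0], _stub_config(), seed=0)

    def test_empty_subset_rejected(self):
        X, y, _ = _planted(seed=4)
        with pytest.raises(ValueError):
            evaluate_subset(X[:200], y[:200], X[200:], y[200:], [],
                            _stub_config(), seed=0)


class TestRunProtocol:
    def test_shape_and_conservation(self):
        X, y, names = _planted(seed=6)
        trace = run_protocol((X, y, names), _stub_config())
        assert len(trace.steps) == len(names) - 1
        assert sorted(trace.curve["cardinality"]) == list(range(1, len(names) + 1))
        assert sorted(trace.removal_order) == sorted(names)

    def test_deterministic_given_seed(self):
        X, y, names = _planted(seed=6)
        a = run_protocol((X, y, names), _stub_config(seed=11))
        b = run_protocol((X, y, names), _stub_config(seed=11))
        assert a.removal_order == b.removal_order
        pd.testing.assert_frame_equal(a.curve, b.curve)

    def test_planted_signal_survives_to_last(self):
        X, y, names = _planted(seed=7)
        trace = run_protocol((X, y, names), _stub_config(inner_reps=10),
                             evaluate=False)
        assert trace.removal_order[-1] == "planted"

    def test_subset_at(self):
        X, y, names = _planted(seed=6)
        trace = run_protocol((X, y, names), _stub_config(), evaluate=False)
        assert trace.subset_at(len(names)) == names
        assert len(trace.subset_at(2)) == 2
        with pytest.raises(ValueError):
            trace.subset_at(0)

    def test_needs_two_features(self):
        X, y, _ = _planted(seed=6)
        with pytest.raises(ValueError):
            run_protocol((X[:, :1], y), _stub_config())


class TestAggregateRuns:
    def test_single_run_indicator_frequencies(self):
        X, y, names = _planted(seed=8)
        agg = aggregate_runs((X, y, names), _stub_config(outer_runs=1,
                                                         subset_size=2))
        assert set(agg.frequencies.unique()) <= {0.0, 1.0}
        assert agg.frequencies.sum() == 2

    def test_planted_frequency_one(self):
        X, y, names = _planted(seed=9)
        agg = aggregate_runs((X, y, names), _stub_config(outer_runs=3,
                                                         inner_reps=10))
        assert agg.frequencies["planted"] == 1.0


class TestCooccurrence:
    def test_pair_counting(self):
        mat = cooccurrence([("A", "B"), ("A", "B"), ("A", "C")])
        assert mat.loc["A", "B"] == pytest.approx(2 / 3)
        assert mat.loc["A", "C"] == pytest.approx(1 / 3)
        assert mat.loc["B", "C"] == 0.0

    def test_single_pair(self):
        mat = cooccurrence([("A", "B")])
        assert mat.loc["A", "B"] == 1.0

    def test_symmetric_and_normalised(self):
        subsets = [("A", "B", "C"), ("B", "C", "D"), ("A", "C", "D")]
        mat = cooccurrence(subsets)
        assert np.allclose(mat.values, mat.values.T)
        assert np.triu(mat.values, k=1).sum() == pytest.approx(1.0)

    def test_all_singletons_empty(self):
        assert cooccurrence([("A",), ("B",)]).empty


class TestCvAuroc:
    def test_label_feature_perfect(self):
        X, y, names = _planted(seed=10)
        mean, sd = cv_auroc((X, y, names), ["planted"],
                            _stub_config(eval_reps=2))
        assert mean == 1.0 and sd == 0.0

    def test_noise_near_half(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 500)
        X = rng.normal(size=(1000, 3))
        mean, _ = cv_auroc((X, y), [0, 1, 2], _stub_config(eval_reps=2))
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_candidate_reduced_questionnaires_comparable(self, encoded_default):
        """The two natural 3-item reduced questionnaires ({B1,B6,B10} and
        {B1,B7,B10}) both predict the full-BQ label well and are nearly
        interchangeable on a default synthetic cohort."""
        from berlinq.selection import XGBoostScorer
        cfg = ProtocolConfig(eval_reps=5, cv_folds=5, seed=0,
                             classifier=XGBoostScorer(n_estimators=30))
        mean_a, _ = cv_auroc(encoded_default, ["B1", "B6", "B10"], cfg)
        mean_b, _ = cv_auroc(encoded_default, ["B1", "B7", "B10"], cfg)
        assert mean_a >= 0.90 and mean_b >= 0.90
        assert abs(mean_a - mean_b) <= 0.02

    def test_small_class_rejected(self):
        X = np.zeros((8, 2))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            cv_auroc((X, y), [0], _stub_config(cv_folds=5))


class TestVotedBackwardSelector:
    def test_sklearn_clone_contract(self):
        sel = VotedBackwardSelector(subset_size=2, inner_reps=3)
        assert clone(sel).get_params() == sel.get_params()

    def test_fit_selects_planted_feature(self):
        X, y, names = _planted(n=150, noise=3, seed=12)
        frame = pd.DataFrame(X, columns=names)
        sel = VotedBackwardSelector(subset_size=2, inner_reps=3, inner_cv=1,
                                    evaluate=False, n_estimators=10,
                                    random_state=0)
        sel.fit(frame, y)
        assert "planted" in sel.selected_features_
        assert sel.support_.sum() == 2
        assert sel.transform(frame).shape == (150, 2)
        assert len(sel.get_support(indices=True)) == 2
        assert sorted(sel.removal_order_) == sorted(names)

    def test_pipeline_composition(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import Pipeline

        X, y, names = _planted(n=150, noise=3, seed=13)
        pipe = Pipeline([
            ("select", VotedBackwardSelector(subset_size=2, inner_reps=2,
                                             inner_cv=1, evaluate=False,
                                             n_estimators=10)),
            ("clf", LogisticRegression()),
        ])
        pipe.fit(X, y)
        assert pipe.predict(X).shape == (150,)

    def test_invalid_subset_size(self):
        X, y, _ = _planted(seed=6)
        with pytest.raises(ValueError):
            VotedBackwardSelector(subset_size=9).fit(X, y)
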