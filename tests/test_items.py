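"""Questionnaire dictionary, deterministic risk scoring, ordinal encoding."""

import itertools
import math

import numpy as np
import pytest

from berlinq.items import (
    BMI_ITEM_ID,
    BQ_ITEM_IDS,
    DEFAULT_FEATURES,
    DONT_KNOW,
    HIGH,
    ITEMS,
    LOW,
    EncodingPolicy,
    RecordError,
    SubjectRecord,
    classify_risk,
    cohort_to_frame,
    encode_cohort,
    frame_to_records,
    load_item_dictionary,
    score_categories,
)

from conftest import make_record


class TestItemDictionary:
    def test_item_counts(self):
        items = load_item_dictionary()
        ids = [it.item_id for it in items]
        assert sum(i.startswith("B") and i != BMI_ITEM_ID for i in ids) == 10
        assert sum(i.startswith("Q") for i in ids) == 38
        assert BMI_ITEM_ID in ids

    def test_b3_levels_in_presentation_order(self):
        assert ITEMS["B3"].levels == (
            "Never or almost never", "1–2 times a month", "1–2 times a week",
            "3–4 times a week", "Every day")

    def test_category_assignments(self):
        expected = {"B1": 1, "B2": 1, "B3": 1, "B4": 1, "B5": 1,
                    "B6": 2, "B7": 2, "B8": 2, "B9": None, "B10": 3}
        assert {i: ITEMS[i].category for i in BQ_ITEM_IDS} == expected
        assert ITEMS[BMI_ITEM_ID].category == 3
        assert all(ITEMS[f"Q{i}"].category is None for i in range(1, 39))

    def test_follow_up_parents(self):
        assert ITEMS["B2"].parent_item == "B1"
        assert ITEMS["B9"].parent_item == "B8"

    def test_positive_levels_upward_closed(self):
        # escalating an answer can only add symptoms, never remove them
        for iid in BQ_ITEM_IDS:
            item = ITEMS[iid]
            positives = {item.levels.index(lv) for lv in item.positive_levels
                         if lv != DONT_KNOW}
            if positives:
                assert positives == set(range(min(positives), len(item.levels)))


class TestScoring:
    def test_category3_only(self):
        rec = make_record(B10="Yes", bmi=31.0)
        scores = score_categories(rec)
        assert (scores.cat1_positive, scores.cat2_positive,
                scores.cat3_positive) == (False, False, True)

    def test_all_least_symptomatic_is_negative(self):
        scores = score_categories(make_record(bmi=22.0))
        assert scores.positive_count == 0
        assert classify_risk(make_record()) == LOW

    def test_two_snoring_positives_trigger_category1(self):
        rec = make_record(B1="Yes", B3="Every day",
                          B2="Slightly louder than breathing", B4="No",
                          B5="Never or almost never")
        assert score_categories(rec).cat1_positive
        assert not score_categories(rec).cat2_positive

    def test_single_positive_not_enough_for_cat1(self):
        assert not score_categories(make_record(B1="Yes")).cat1_positive

    def test_bmi_threshold_strict(self):
        assert not score_categories(make_record(bmi=30.0)).cat3_positive
        assert score_categories(make_record(bmi=30.1)).cat3_positive

    def test_high_iff_two_categories(self):
        # realise each of the 8 category patterns with concrete answers
        cat1 = {"B1": "Yes", "B3": "Every day"}
        cat2 = {"B6": "Every day", "B7": "Every day"}
        cat3 = {"B10": "Yes"}
        n_high = 0
        for bits in itertools.product([0, 1], repeat=3):
            overrides = {}
            for bit, answers in zip(bits, (cat1, cat2, cat3)):
                if bit:
                    overrides.update(answers)
            rec = make_record(**overrides)
            assert score_categories(rec).positive_count == sum(bits)
            label = classify_risk(rec)
            assert (label == HIGH) == (sum(bits) >= 2)
            n_high += label == HIGH
        assert n_high == 4

    def test_missing_never_positive(self):
        rec = SubjectRecord("s", {}, bmi=None)
        assert score_categories(rec).positive_count == 0
        assert classify_risk(rec) == LOW

    def test_dont_know_never_positive(self):
        rec = make_record(B1=DONT_KNOW, B4=DONT_KNOW, B10=DONT_KNOW)
        assert score_categories(rec).positive_count == 0

    def test_invalid_level_rejected(self):
        with pytest.raises(RecordError):
            classify_risk(make_record(B1="maybe"))
        with pytest.raises(RecordError):
            classify_risk(make_record(bmi=150.0))

    def test_monotone_under_escalation(self, rng):
        """Raising any single answer, or BMI, never flips high to low."""
        from berlinq import GeneratorConfig, generate_cohort
        frame, _ = generate_cohort(GeneratorConfig(n_subjects=250, seed=7))
        records = frame_to_records(frame)
        escalatable = [i for i in BQ_ITEM_IDS]
        flips = 0
        for _ in range(2000):
            rec = records[rng.integers(len(records))]
            before = classify_risk(rec)
            iid = escalatable[rng.integers(len(escalatable))]
            item = ITEMS[iid]
            ans = rec.answer(iid)
            idx = item.levels.index(ans) if ans is not None else -1
            if idx >= len(item.levels) - 1:
                continue
            answers = dict(rec.answers)
            answers[iid] = item.levels[idx + 1]
            # skip non-monotone moves into "Do not know"
            if answers[iid] == DONT_KNOW:
                continue
            after = classify_risk(SubjectRecord("e", answers, rec.bmi))
            if before == HIGH and after == LOW:
                flips += 1
        assert flips == 0


class TestEncoding:
    def test_yes_no_codes_per_policy(self):
        item = ITEMS["B1"]
        middle = EncodingPolicy(dontknow="as_middle").codes(item)
        assert middle == {"No": 0.0, DONT_KNOW: 1.0, "Yes": 2.0}
        missing = EncodingPolicy(dontknow="as_missing").codes(item)
        assert missing["No"] == 0.0 and missing["Yes"] == 1.0
        assert math.isnan(missing[DONT_KNOW])

    def test_frequency_scale_codes_identical_across_policies(self):
        item = ITEMS["B3"]
        for policy in (EncodingPolicy("as_missing"), EncodingPolicy("as_middle")):
            assert policy.codes(item) == {lv: float(i)
                                          for i, lv in enumerate(item.levels)}

    @pytest.mark.parametrize("dontknow", ["as_missing", "as_middle"])
    def test_decode_round_trip(self, dontknow):
        policy = EncodingPolicy(dontknow=dontknow)
        for item in ITEMS.values():
            if item.continuous:
                continue
            for lv, code in policy.codes(item).items():
                if not math.isnan(code):
                    assert policy.decode(item, code) == lv

    def test_encode_cohort_labels_match_scorer(self, default_cohort):
        frame, _ = default_cohort
        ds = encode_cohort(frame)
        recomputed = np.array([classify_risk(r) == HIGH
                               for r in frame_to_records(frame)])
        assert np.array_equal(ds.y.astype(bool), recomputed)
        assert ds.feature_ids == list(DEFAULT_FEATURES)
        assert ds.X.shape == (len(frame), len(DEFAULT_FEATURES))

    def test_skip_logic_missing_becomes_nan_row_kept(self):
        rec = make_record(B1="No")
        rec.answers["B2"] = None
        ds = encode_cohort([rec, make_record("t")])
        assert math.isnan(ds.X[0, ds.feature_ids.index("B2")])
        assert ds.n_subjects == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            encode_cohort([])

    def test_frame_record_round_trip(self, default_cohort):
        frame, _ = default_cohort
        back = cohort_to_frame(frame_to_records(frame))
        assert back.shape[0] == frame.shape[0]
        for col in ("B1", "B2", "B10"):
            a = frame[col].fillna("·")
            b = back[col].fillna("·")
            assert (a.values == b.values).all()
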