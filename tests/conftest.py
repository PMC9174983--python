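import numpy as np
import pytest

from berlinq import GeneratorConfig, encode_cohort, generate_cohort
from berlinq.items import BQ_ITEM_IDS, ITEMS, SubjectRecord


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized synthetic cohort (n=387, defaults) plus latent classes."""
    frame, latent = generate_cohort(GeneratorConfig(seed=387))
    return frame, latent


@pytest.fixture(scope="session")
def encoded_default(default_cohort):
    frame, _ = default_cohort
    return encode_cohort(frame)


def make_record(subject_id="s", bmi=22.0, **overrides) -> SubjectRecord:
    """Record with every BQ item at its least symptomatic level."""
    answers = {iid: ITEMS[iid].levels[0] for iid in BQ_ITEM_IDS}
    answers.update(overrides)
    return SubjectRecord(subject_id, answers, bmi)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
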