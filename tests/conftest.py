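import numpy as np
import pytest

import myogrid as mg
from myogrid import experiment

STUDY_SEED = 1
USER_SEED = 777


@pytest.fixture(scope="session")
def base_clf():
    """Base network pre-trained on the synthetic multi-subject cohort."""
    return experiment.pretrain_cohort(STUDY_SEED)


@pytest.fixture(scope="session")
def user_subject():
    """A held-out synthetic end user (not in the pretraining cohort)."""
    return mg.make_subject(USER_SEED)


@pytest.fixture(scope="session")
def adapted_clf(base_clf, user_subject):
    """Base network after one-time all-layer adaptation to the user."""
    return experiment.adapt_user(base_clf, user_subject, 5)


@pytest.fixture(scope="session")
def user_test_set(user_subject):
    """Held-out steady-state frames from an independent recording."""
    return experiment.training_arrays(user_subject, "reduced", 99, stride=10)


@pytest.fixture(scope="session")
def small_training_set():
    """Tiny steady-state frame set for fast classifier unit tests."""
    subj = mg.make_subject(11)
    X, y = experiment.training_arrays(subj, "reduced", 3, stride=40)
    return X, y
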