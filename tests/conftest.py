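import numpy as np
import pytest

from tonelab.corpus import build_corpus, recordings_from_fixtures
from tonelab.experiment import make_mono_set, make_session_plan
from tonelab.fixtures import make_word_set

FEMALE_SEED = 7
MALE_SEED = 8
BUILD_SEED = 1
PLAN_SEED = 2


@pytest.fixture(scope="session")
def word_fixtures():
    """Five synthetic disyllables per speaker — the standard corpus input."""
    return make_word_set(5, "female", FEMALE_SEED) + make_word_set(5, "male", MALE_SEED)


@pytest.fixture(scope="session")
def full_corpus(word_fixtures):
    """The full 270-token factorial corpus (manifest, audio)."""
    recs = recordings_from_fixtures(word_fixtures)
    return build_corpus(recs, seed=BUILD_SEED)


@pytest.fixture(scope="session")
def manifest(full_corpus):
    return full_corpus[0]


@pytest.fixture(scope="session")
def corpus_audio(full_corpus):
    return full_corpus[1]


@pytest.fixture(scope="session")
def mono_set():
    return make_mono_set(25)


@pytest.fixture(scope="session")
def mono_map(mono_set):
    return {m.token_id: m for m in mono_set}


@pytest.fixture(scope="session")
def session_plan(manifest, mono_set):
    return make_session_plan(manifest, [m.token_id for m in mono_set], seed=PLAN_SEED)


@pytest.fixture(scope="session")
def di_plan(manifest):
    """A Di-only plan (no Mono block), for congruence-focused simulations."""
    return make_session_plan(manifest, None, seed=PLAN_SEED)
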