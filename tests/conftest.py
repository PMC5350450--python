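import pytest
from hypothesis import HealthCheck, settings

from depsignal.corpus import AnnotatedCorpus, CategoryAnnotation, Tweet
from depsignal.lexicon import load_lexicon
from depsignal.scheme import DEFAULT_SCHEME

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture
def build_corpus():
    """Factory: records are (tweet_id, text, {annotator: [categories]})."""

    def _build(records, scheme=DEFAULT_SCHEME):
        tweets = [Tweet(tid, text) for tid, text, _ in records]
        annotations = [
            CategoryAnnotation(tid, annotator, cat)
            for tid, _, labels in records
            for annotator, cats in labels.items()
            for cat in cats
        ]
        return AnnotatedCorpus(tweets, annotations, scheme)

    return _build
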