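import pytest

from latscreen import (
    RuleScreener,
    load_default_lexicon,
    load_default_ruleset,
    load_default_synonyms,
)


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def ruleset():
    return load_default_ruleset()


@pytest.fixture(scope="session")
def synonyms():
    return load_default_synonyms()


@pytest.fixture(scope="session")
def screener(ruleset, lexicon):
    return RuleScreener(ruleset=ruleset, lexicon=lexicon).fit([])


@pytest.fixture(scope="session")
def screener_builtin(ruleset, lexicon):
    return RuleScreener(ruleset=ruleset, lexicon=lexicon, extractor="builtin").fit([])
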