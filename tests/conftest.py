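import pytest

from picosense import (
    Abstract,
    Element,
    GenConfig,
    build_corpus,
    default_cues,
    default_headings,
    default_semantic,
    generate,
    segment,
)

# The structured-abstract fragment used throughout the docs (PMID 19318702):
# three PICO sections, with a second outcome sentence that must stay unlabeled.
FRAGMENT = (
    "PARTICIPANTS: 2426 nulliparous, non-diabetic women at term, with a "
    "singleton cephalic presenting fetus and in labour with a cervical "
    "dilatation of less than 6 cm. "
    "INTERVENTION: Consumption of a light diet or water during labour. "
    "MAIN OUTCOME MEASURES: The primary outcome measure was spontaneous "
    "vaginal delivery rate. "
    "Other outcomes measured included duration of labour"
)


@pytest.fixture(scope="session")
def headings():
    return default_headings()


@pytest.fixture(scope="session")
def cues():
    return default_cues()


@pytest.fixture(scope="session")
def sems():
    return default_semantic()


@pytest.fixture(scope="session")
def fragment_abstract():
    return Abstract("19318702", "Effect of food intake during labour", segment(FRAGMENT))


@pytest.fixture(scope="session")
def small_corpus(headings):
    """120 structured synthetic abstracts plus their per-element datasets."""
    abstracts, gold = generate(GenConfig(n_abstracts=120, seed=11))
    datasets, stats = build_corpus(abstracts, headings)
    return {"abstracts": abstracts, "gold": gold, "datasets": datasets, "stats": stats}
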