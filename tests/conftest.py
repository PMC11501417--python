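import pytest

from semiokit.extraction import default_rules
from semiokit.lexicon import Lexicon, Term, build_surface_index
from semiokit.resources import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def index(lexicon):
    return build_surface_index(lexicon, "en")


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture()
def toy_lexicon():
    """Tiny lexicon with a nested fixed phrase ('tonic clonic' vs 'tonic')."""
    terms = {
        "T1": Term("T1", {"en": "tonic clonic"}, {"en": ["tonic clonic seizure"]},
                   "symptom"),
        "T2": Term("T2", {"en": "tonic"}, {}, "symptom"),
        "T3": Term("T3", {"en": "clonic"}, {"en": ["jerking"]}, "symptom"),
        "T4": Term("T4", {"en": "left arm"}, {}, "location"),
    }
    return Lexicon(name="toy", version="1", languages=["en"], terms=terms)
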