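import pytest

from sisterates.wordlist_io import CognateMatrix


@pytest.fixture
def toy_family_matrix() -> CognateMatrix:
    """Four languages, three concepts, seven cognate classes, built so that
    pair (A, B) has exactly gains1=1, loss2=1, noninformative=2, excluded=3.

    Classification of each class for pair (A, B), worked out by hand from
    the presence sets below (C and D are the rest of the family):

    hand/h1: A+B               -> noninformative
    hand/h2: A only, also in C -> loss2 (B lost an ancestral class)
    hand/h3: C only            -> excluded (absent from both members)
    eye/e1:  A+B+C             -> noninformative
    eye/e2:  A only, nowhere else -> gain1
    eye/e3:  D only            -> excluded
    leg/l1:  C+D only          -> excluded
    """
    languages = ["A", "B", "C", "D"]
    concepts = ["hand", "eye", "leg"]
    presence = {
        ("A", "hand"): {"h1", "h2"},
        ("B", "hand"): {"h1"},
        ("C", "hand"): {"h2", "h3"},
        ("A", "eye"): {"e1", "e2"},
        ("B", "eye"): {"e1"},
        ("C", "eye"): {"e1"},
        ("D", "eye"): {"e3"},
        ("C", "leg"): {"l1"},
        ("D", "leg"): {"l1"},
        ("A", "leg"): set(),
        ("B", "leg"): set(),
    }
    attested = [(lang, concept) for lang in languages for concept in concepts]
    return CognateMatrix(languages, concepts, presence, attested)
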