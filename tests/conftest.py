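import pytest

from phenoharvest import start_empty_glossary


@pytest.fixture
def small_glossary():
    """A minimal hand-built vocabulary used across parser tests."""
    g = start_empty_glossary(extra_categories=("Sex",))
    for term in ("leaf", "petiole", "cone", "bark", "bract", "cone bract",
                 "phyllode", "scale"):
        g.categorize_term(term, "Structure")
    g.categorize_term("scale", "Shape")
    for term in ("red", "green", "brown", "gray"):
        g.categorize_term(term, "Coloration")
    for term in ("ovate", "obovate", "oblong", "lanceolate"):
        g.categorize_term(term, "Shape")
    for term in ("smooth", "rough", "glossy", "exfoliating"):
        g.categorize_term(term, "Texture")
    for term in ("adult", "juvenile", "persistent"):
        g.categorize_term(term, "Duration")
    for term in ("male", "female"):
        g.categorize_term(term, "Sex")
    g.add_synonym("shiny", "glossy")
    g.add_synonym("ash-gray", "gray")
    return g
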