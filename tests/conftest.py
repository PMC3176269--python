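import pytest
from hypothesis import HealthCheck, settings

from wsdsumm.kb import Concept, KnowledgeBase, Relation

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    """Hand-built six-concept knowledge base around the ambiguous term
    "cold" (disease sense vs temperature sense)."""
    concepts = [
        Concept("CROOT", "organism", {"organism"}, {"Organism"},
                ["living thing"]),
        Concept("CMID", "disorder", {"disorder"}, {"Finding"},
                ["abnormal clinical state"]),
        Concept("CCOLD1", "common cold", {"common cold", "cold"},
                {"Disease or syndrome"},
                ["viral infection nose throat sneezing"]),
        Concept("CCOLD2", "cold temperature", {"cold temperature", "cold"},
                {"Natural phenomenon"},
                ["absence heat low temperature chill"]),
        Concept("CSTORE", "cold storage", {"cold storage"},
                {"Manufactured object"},
                ["refrigerated warehouse freezing preservation"]),
        Concept("CSIB", "fever", {"fever"}, {"Finding"},
                ["elevated body temperature pyrexia"]),
    ]
    relations = [
        Relation("CROOT", "is_a", "CMID"),
        Relation("CMID", "is_a", "CCOLD1"),
        Relation("CMID", "is_a", "CCOLD2"),
        Relation("CMID", "is_a", "CSIB"),
        Relation("CCOLD2", "other_related", "CSTORE"),
    ]
    associations = [("Disease or syndrome", "Natural phenomenon")]
    return KnowledgeBase(concepts, relations, associations)
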