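import math

import numpy as np
import pytest
from hypothesis import settings

from forumhealth.corpus_io import Lexicon
from forumhealth.semantic_model import EmbeddingModel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def model_with_cosines(anchor: str, cosines: dict[str, float]) -> EmbeddingModel:
    """A 2-D model where cosine(anchor, t) equals cosines[t] exactly."""
    vocab = [anchor] + sorted(cosines)
    vectors = [np.array([1.0, 0.0])]
    for term in sorted(cosines):
        theta = math.acos(cosines[term])
        vectors.append(np.array([math.cos(theta), math.sin(theta)]))
    return EmbeddingModel(vocab, np.vstack(vectors))


def random_model(n_terms: int = 50, dim: int = 8, seed: int = 0) -> EmbeddingModel:
    rng = np.random.default_rng(seed)
    vocab = [f"w{i:02d}" for i in range(n_terms)]
    return EmbeddingModel(vocab, rng.normal(size=(n_terms, dim)))


@pytest.fixture
def drug_lexicon() -> Lexicon:
    return Lexicon(
        entries={
            "marijuana": "substance",
            "weed": "substance",
            "ak47": "substance",
            "cannabis": "substance",
            "ketamine": "substance",
            "paracetamol": "medicines_supplements",
            "hypertension": "medical_conditions",
            "cardiologist": "medical_specializations",
            "pharmacotherapy": "medical_procedures",
            "pancreas": "body_parts_tissues",
            "metabolism": "organism_processes",
            "pubmed": "knowledge_sources",
        },
        synonym_map={"weed": "marijuana", "ak47": "marijuana", "cannabis": "marijuana"},
    )
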