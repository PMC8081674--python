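import numpy as np
import pandas as pd
import pytest

from objectnorms import norms, synth


@pytest.fixture
def basic_rules() -> norms.NormalizationRules:
    """Cleaning rules covering every rule type, with the classic examples."""
    return norms.NormalizationRules(
        adverb_list=frozenset({"really", "very"}),
        spelling_map={"wngs": "wings"},
        plural_map={"stingers": "stinger"},
        synonym_map={
            "does travel in packs": "does travel in groups",
            "does travel in a flock": "does travel in groups",
            "is used by cooks": "is used in cooking",
        },
        split_rules={"has a round face": ("has a round face", "has a face")},
        taxonomic_features=frozenset({"is an insect"}),
    )


#: pf values for one concept, mirroring a published example row set: ten
#: features for "bee" with production frequencies 21 down to 6.
BEE_FEATURES = [
    ("has", "wings", 21),
    ("is", "an insect", 13),
    ("does", "make honey", 12),
    ("does", "sting", 11),
    ("has", "a stinger", 11),
    ("does", "fly", 10),
    ("is", "black", 8),
    ("is", "yellow", 8),
    ("has", "legs", 7),
    ("does", "pollinate flowers", 6),
]


@pytest.fixture
def bee_responses() -> pd.DataFrame:
    """Raw responses reproducing the bee example pf column exactly."""
    rows = []
    for rel, text, pf in BEE_FEATURES:
        for r in range(pf):
            rows.append((f"p{r:02d}", "bee", rel, text))
    return pd.DataFrame(
        rows, columns=["participant_id", "concept", "relation", "feature"]
    )


@pytest.fixture
def small_matrix() -> norms.ConceptFeatureMatrix:
    """Cutoff-applied 10-concept matrix from the norming generator."""
    cfg = synth.NormGenConfig(
        n_categories=2, concepts_per_category=5, shared_pool_size=8,
        distinctive_per_concept=4, n_raters=20, seed=42,
    )
    responses, truth = synth.generate_norms(cfg)
    rules = norms.NormalizationRules(
        taxonomic_features=frozenset(truth["taxonomic_features"])
    )
    m = norms.build_production_matrix(responses, rules)
    return norms.apply_cutoffs(m, cell_cutoff=3, min_concepts=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
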