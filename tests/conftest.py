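"""Shared fixtures: the published example record and small synthetic corpora."""

import numpy as np
import pytest
from hypothesis import settings

from litnet.corpus import DependencyGraph, PathRecord
from litnet.simulate import SyntheticConfig, generate_theme_corpus

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# the published example record: a chemical-gene sentence whose dependency
# path runs through an appositive trial/inhibitor construction
# ---------------------------------------------------------------------------

EXAMPLE_SENTENCE_TOKENS = [
    # (index, form, head, deprel)
    (1, "A", 4, "det"),
    (2, "Phase", 4, "compound"),
    (3, "I", 2, "compound"),
    (4, "trial", 0, "root"),
    (5, "of", 9, "case"),
    (6, "a", 9, "det"),
    (7, "potent", 9, "amod"),
    (8, "P-glycoprotein", 9, "amod"),
    (9, "inhibitor", 4, "nmod"),
    (10, ",", 4, "punct"),
    (11, "zosuquidar_trihydrochloride", 4, "appos"),
    (12, "-LRB-", 13, "punct"),
    (13, "LY335979", 11, "appos"),
    (14, "-RRB-", 13, "punct"),
    (15, ",", 4, "punct"),
    (16, "administered", 4, "acl"),
    (17, "intravenously", 16, "advmod"),
    (18, "in", 19, "case"),
    (19, "combination", 16, "nmod"),
    (20, "with", 21, "case"),
    (21, "doxorubicin", 19, "nmod"),
    (22, "in", 23, "case"),
    (23, "patients", 16, "nmod"),
    (24, "with", 26, "case"),
    (25, "advanced", 26, "amod"),
    (26, "malignancy", 23, "nmod"),
    (27, ".", 4, "punct"),
]

EXAMPLE_PATH = (
    "trial|appos|START_ENTITY trial|nmod|inhibitor inhibitor|amod|END_ENTITY"
)

EXAMPLE_TOKENIZED = (
    "A Phase I trial of a potent P-glycoprotein inhibitor, "
    "zosuquidar_trihydrochloride -LRB- LY335979 -RRB-, administered "
    "intravenously in combination with doxorubicin in patients with "
    "advanced malignancy."
)


@pytest.fixture(scope="session")
def example_graph() -> DependencyGraph:
    tokens = [(i, form, form.lower()) for i, form, _, _ in EXAMPLE_SENTENCE_TOKENS]
    edges = [
        (head, deprel, i)
        for i, _, head, deprel in EXAMPLE_SENTENCE_TOKENS
        if head != 0
    ]
    return DependencyGraph(tokens=tokens, edges=edges, root=4)


@pytest.fixture(scope="session")
def example_record() -> PathRecord:
    """The example chemical-gene record, field for field."""
    return PathRecord(
        doc_id="15161679",
        sentence_number=0,
        entity1_formatted="zosuquidar_trihydrochloride",
        entity1_start=54,
        entity1_end=81,
        entity2_formatted="P-glycoprotein",
        entity2_start=28,
        entity2_end=42,
        entity1_raw="zosuquidar trihydrochloride",
        entity2_raw="P-glycoprotein",
        entity1_db_id="MESH: C095179",
        entity2_db_id="5243",
        entity1_type="Chemical",
        entity2_type="Gene",
        path=EXAMPLE_PATH,
        sentence=EXAMPLE_TOKENIZED,
    )


# ---------------------------------------------------------------------------
# synthetic corpora
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def clean_corpus():
    """Noise-free corpus: 3 themes x 6 templates x 12 pairs."""
    return generate_theme_corpus(
        SyntheticConfig(
            n_themes=3, paths_per_theme=6, pairs_per_theme=12, noise=0.0, seed=11
        )
    )


@pytest.fixture(scope="session")
def clean_records(clean_corpus):
    from litnet.pipeline import extract_synthetic

    return extract_synthetic(clean_corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
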