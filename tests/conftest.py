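import numpy as np
import pytest

from docgraphre.corpus_io import (DependencyParse, Document, EntityMention,
                                  EntityType, GoldRelation, Token,
                                  align_mentions)
from docgraphre.neural_model import ModelConfig, ModelParameters
from docgraphre.representation import EmbeddingTables, HashEmbedder
from docgraphre.synthetic_corpus import SyntheticSpec, generate_corpus


def make_document(doc_id, sentence_specs, relations=(), heads=None):
    """Build a parsed, aligned document from per-sentence token specs.

    ``sentence_specs`` is a list of sentences; each sentence is a list of
    either plain surface strings or ``(surface, entity_type, concept_id)``
    triples.  ``heads`` optionally gives per-sentence 1-based head arrays;
    the default is a chain rooted at the first token.
    """
    sentences, mentions, parses = [], [], []
    offset = 0
    for si, spec in enumerate(sentence_specs):
        row = []
        for item in spec:
            if isinstance(item, tuple):
                surface, etype, cid = item
            else:
                surface, etype, cid = item, None, None
            start, end = offset, offset + len(surface)
            row.append(Token(surface=surface, char_start=start, char_end=end,
                             sentence_index=si, pos_tag="NOUN"))
            if etype is not None:
                mentions.append(EntityMention(
                    entity_type=EntityType(etype), concept_id=cid,
                    char_start=start, char_end=end, text=surface))
            offset = end + 1
        sentences.append(row)
        n = len(row)
        h = heads[si] if heads else [0] + [i for i in range(1, n)]
        parses.append(DependencyParse(heads=list(h), deprels=["dep"] * n))
    text_parts = [" ".join(t.surface for t in s) for s in sentences]
    doc = Document(
        doc_id=doc_id, title=text_parts[0],
        abstract=" ".join(text_parts[1:]),
        sentences=sentences, mentions=mentions,
        relations=[GoldRelation(*r) for r in relations],
        parses=parses,
    )
    align_mentions(doc)
    doc.validate()
    return doc


@pytest.fixture
def fig1_document():
    """Document mirroring the worked instance-construction scenario:
    chemical D007545 in sentences 0, 1, 3; disease D006332 in sentences
    0-1; D006984 in sentences 3-4; D006965 in sentence 4; one gold
    relation (D007545, D006332)."""
    C, D = EntityType.CHEMICAL.value, EntityType.DISEASE.value
    return make_document(
        "6203632",
        [
            ["treatment", "with", ("hydralazine", C, "D007545"), "caused",
             ("lupus", D, "D006332"), "syndrome", "."],
            [("hydralazine", C, "D007545"), "was", "linked", "to",
             ("lupus", D, "D006332"), "."],
            ["the", "patient", "was", "observed", "closely", "."],
            [("hydralazine", C, "D007545"), "therapy", "and",
             ("disease", D, "D006984"), "were", "reviewed", "."],
            ["later", ("anemia", D, "D006965"), "and", ("disease", D, "D006984"),
             "appeared", "."],
        ],
        relations=[("D007545", "D006332")],
    )


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(SyntheticSpec(n_docs=20, seed=7))


@pytest.fixture(scope="session")
def tiny_pipeline():
    """Small embedder + tables + matching model config for fast tests."""
    embedder = HashEmbedder(dim=12, seed=3)
    tables = EmbeddingTables(dim_pos=4, dim_dist=4, clip=10, seed=3)
    input_dim = 12 + 4 + 2 * 4
    config = ModelConfig(input_dim=input_dim, lstm_dim=8, gcn_dim=8,
                         gcn_layers=2, n_heads=2, mlp_dim=8, dropout=0.0,
                         seed=3)
    return embedder, tables, config


@pytest.fixture
def tiny_params(tiny_pipeline):
    _, _, config = tiny_pipeline
    return ModelParameters(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
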