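# docgraphre

Document-level chemical–disease relation (CID) extraction. The pipeline
reads PubTator-format abstracts with CoNLL-U dependency parses, builds
labeled candidate instances with heuristic nearest-mention rules (one
instance per chemical/disease concept pair, intrasentence or
intersentence, with a configurable sentence-distance cutoff), assembles a
document-level dependency graph (per-sentence syntactic arcs, edges
between the roots of adjacent sentences, and self-loops), and classifies
each instance with a BiLSTM encoder combined with a self-attention branch
(additive / general / scaled dot-product / multihead) and a
degree-normalized graph-convolution branch over the document graph,
followed by max-pooling, entity pooling, and a 2-layer perceptron with
softmax output.

The neural model is implemented on a small reverse-mode autodiff engine
over numpy (`docgraphre.autodiff`) — no deep-learning framework is
required. A synthetic-corpus generator with a planted decision rule
(`dependency_path`: the label is decidable only from the dependency
structure, not from token surfaces or linear positions) makes the whole
pipeline trainable and testable offline at desk scale.

## CLI

```bash
# write synthetic train/dev/test splits (PubTator + CoNLL-U)
docgraphre simulate --out-dir data/ --seed 1

# candidate-instance TSV for inspection
docgraphre preprocess --pubtator data/train.pubtator \
    --conllu data/train.conllu --out instances.tsv

# train, evaluate, ablate
docgraphre train --pubtator data/train.pubtator --conllu data/train.conllu \
    --dev-pubtator data/dev.pubtator --dev-conllu data/dev.conllu \
    --checkpoint model --profile test --seed 1
docgraphre evaluate --pubtator data/test.pubtator --conllu data/test.conllu \
    --checkpoint model --profile test
docgraphre ablate --pubtator data/train.pubtator --conllu data/train.conllu \
    --test-pubtator data/test.pubtator --test-conllu data/test.conllu \
    --grid grid.yaml --out ablation.tsv
```

Two profiles are provided: `paper` (contextual dim 1024, POS/position
embeddings 100, LSTM/GCN/perceptron dims 500, 5 attention heads, dropout
0.5, Adam lr 0.001, batch 32) and `test` (small dims for fast runs). A
YAML file passed with `--config` can override any model or training field;
`ablate` takes a YAML grid mapping cell names to config deltas (infeasible
cells, e.g. a head count that does not divide the BiLSTM output width, are
recorded as skipped).

The contextual embedder is pluggable: the default is a deterministic hash
embedder (weakly context-sensitive, unit-norm rows); per-token vectors
from an external contextual model can be supplied via
`representation.PrecomputedEmbedder`.

## Layout

| Module | Role |
| --- | --- |
| `corpus_io` | PubTator and CoNLL-U reading/writing, mention-to-token alignment |
| `instance_builder` | intra/intersentence candidate construction heuristics |
| `doc_graph` | document-level dependency graph and normalized adjacency |
| `representation` | contextual ⊕ POS ⊕ pairwise-position token features |
| `autodiff` | minimal reverse-mode automatic differentiation over numpy |
| `neural_model` | BiLSTM, attention variants, GCN, pooling, classifier |
| `train_eval` | Adam training loop, prediction, intra/inter/merged P/R/F, ablations |
| `synthetic_corpus` | planted-rule corpus generator (PubTator + CoNLL-U dialects) |
| `baselines` | bag-of-words logistic and majority-class reference baselines |
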